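import pandas as pd

from isocurate import fixtures
from isocurate.models import ReferenceIndex
from isocurate.pipeline import run_qc
from isocurate.rescue import (MappingHit, automatic_rescue,
                              expanded_transcriptome, map_candidates,
                              resolve_hits, run_rescue,
                              select_rescue_candidates,
                              validate_reference_targets)
from isocurate.rules_filter import FilterDecision, apply_rules, parse_rules

from conftest import make_tx


def frame(rows):
    return pd.DataFrame(rows)


def dec(tid, verdict, p=None):
    return FilterDecision(tid, verdict, reasons=["x"] if
                          verdict == "artifact" else [], probability=p)


class TestAutomaticRescue:
    def _records(self):
        return frame([
            {"isoform": "a", "structural_category": "FSM",
             "associated_transcript": "R1"},
            {"isoform": "b", "structural_category": "FSM",
             "associated_transcript": "R1"},
            {"isoform": "c", "structural_category": "FSM",
             "associated_transcript": "R2"},
        ])

    def _index(self):
        r1 = make_tx("R1", [(0, 300), (600, 900)], gene="g1")
        r2 = make_tx("R2", [(5000, 5300), (5600, 5900)], gene="g2")
        return ReferenceIndex.build([r1, r2], min_ref_len=0)

    def test_two_removed_fsm_of_same_reference_add_once(self):
        decisions = {"a": dec("a", "artifact"), "b": dec("b", "artifact"),
                     "c": dec("c", "isoform")}
        adds = automatic_rescue(self._records(), decisions, self._index(),
                                {"c"})
        assert adds == ["R1"]

    def test_reference_with_passing_fsm_not_added(self):
        decisions = {"a": dec("a", "artifact"), "b": dec("b", "isoform"),
                     "c": dec("c", "isoform")}
        adds = automatic_rescue(self._records(), decisions, self._index(),
                                {"b", "c"})
        assert adds == []

    def test_no_removed_fsm_no_additions(self):
        decisions = {k: dec(k, "isoform") for k in "abc"}
        assert automatic_rescue(self._records(), decisions, self._index(),
                                set("abc")) == []


class TestCandidateSelection:
    def test_category_and_fsm_counterpart_rules(self):
        records = frame([
            {"isoform": "ism1", "structural_category": "ISM",
             "associated_transcript": "R1"},
            {"isoform": "ism2", "structural_category": "ISM",
             "associated_transcript": "R2"},
            {"isoform": "fsm1", "structural_category": "FSM",
             "associated_transcript": "R1"},
            {"isoform": "nnc1", "structural_category": "NNC",
             "associated_transcript": "novel"},
            {"isoform": "anti", "structural_category": "antisense",
             "associated_transcript": "novel"},
        ])
        decisions = {k: dec(k, "artifact") for k in
                     ["ism1", "ism2", "nnc1", "anti"]}
        decisions["fsm1"] = dec("fsm1", "isoform")
        cands = select_rescue_candidates(records, decisions)
        # ism1 is excluded: an FSM of R1 exists in the dataset
        assert cands == ["ism2", "nnc1"]


class TestMapping:
    def test_degraded_fragment_scores_source_highest_and_caps_hits(self):
        ref_main = make_tx("R1", [(0, 300), (600, 900), (1200, 1500)],
                           gene="g1")
        others = [make_tx(f"R{i}", [(0, 300), (600, 900 + 10 * i)], gene="g1")
                  for i in range(2, 12)]
        idx = ReferenceIndex.build([ref_main] + others, min_ref_len=0)
        cand = make_tx("c1", [(600, 900), (1200, 1500)], gene="g1")
        records = frame([{"isoform": "c1", "associated_gene": "g1"}])
        hits = map_candidates([cand], records, {}, idx, curated_ids=set())
        assert len(hits) == 7  # primary + six secondary
        assert hits[0].target_id == "R1"
        assert hits[0].score == max(h.score for h in hits)


class TestResolution:
    def test_ml_mode_keeps_single_best_probability(self):
        hits = [MappingHit("c", "refA", "reference", 1.0),
                MappingHit("c", "refB", "reference", 2.0)]
        tdec = {"refA": dec("refA", "isoform", p=0.9),
                "refB": dec("refB", "isoform", p=0.8)}
        res = resolve_hits(hits, tdec, "ml", curated_ids=set())
        assert res.rescued_reference_ids == ["refA"]
        assert res.outcomes[0].action == "rescued_reference"

    def test_failed_targets_are_dropped(self):
        hits = [MappingHit("c", "refA", "reference", 1.0)]
        tdec = {"refA": dec("refA", "artifact")}
        res = resolve_hits(hits, tdec, "ml", curated_ids=set())
        assert res.outcomes[0].action == "unrescued"

    def test_long_read_best_hit_is_already_represented(self):
        hits = [MappingHit("c", "lr1", "long_read", 2.0),
                MappingHit("c", "refA", "reference", 1.0)]
        tdec = {"lr1": dec("lr1", "isoform", p=0.95),
                "refA": dec("refA", "isoform", p=0.9)}
        res = resolve_hits(hits, tdec, "ml", curated_ids={"lr1"})
        assert res.outcomes[0].action == "already_represented"
        assert res.rescued_reference_ids == []

    def test_rules_mode_keeps_all_passing_reference_targets(self):
        hits = [MappingHit("c1", "refA", "reference", 1.0),
                MappingHit("c1", "refB", "reference", 0.5),
                MappingHit("c2", "refA", "reference", 0.9)]
        tdec = {"refA": dec("refA", "isoform"),
                "refB": dec("refB", "isoform")}
        res = resolve_hits(hits, tdec, "rules", curated_ids=set())
        assert sorted(res.rescued_reference_ids) == ["refA", "refB"]
        # refA requested by both candidates but added once
        assert res.rescued_reference_ids.count("refA") == 1

    def test_ties_break_on_mapping_score_then_id(self):
        hits = [MappingHit("c", "refB", "reference", 1.0),
                MappingHit("c", "refA", "reference", 1.0)]
        tdec = {"refA": dec("refA", "isoform", p=0.9),
                "refB": dec("refB", "isoform", p=0.9)}
        res = resolve_hits(hits, tdec, "ml", curated_ids=set())
        assert res.rescued_reference_ids == ["refA"]


class TestReferenceValidation:
    def test_reference_classifies_as_reference_match_against_itself(
            self, label_bundle):
        rules = parse_rules('{"rest":[{"exons": 0}]}',
                            ["exons", "structural_category"])
        decisions = validate_reference_targets(
            label_bundle.reference,
            lambda df: apply_rules(df, rules))
        assert set(decisions) == {t.transcript_id
                                  for t in label_bundle.reference}
        assert all(d.is_isoform for d in decisions.values())

    def test_short_reference_retained_under_min_ref_len_zero(self):
        short = make_tx("S1", [(100, 250)], gene="g")  # 150 bp spliced
        rules = parse_rules('{"rest":[{"exons": 0}]}', ["exons"])
        decisions = validate_reference_targets(
            [short], lambda df: apply_rules(df, rules))
        assert "S1" in decisions


class TestEndToEnd:
    def _run(self, mode="rules"):
        # queries: degraded fragments and novel-site artifacts whose true
        # source models are absent from the long-read set
        spec = fixtures.FixtureSpec(seed=11, perturbations={
            "ism_3prime_fragment": 3, "nnc": 3})
        b = fixtures.generate(spec)
        idx = ReferenceIndex.build(b.reference, min_ref_len=200)
        evidence = dict(genome=b.genome, cage_peaks=b.cage,
                        polya_peaks=b.polya_peaks, polya_motifs=b.motifs,
                        coverage=b.coverage, sj=b.sj)
        records, _ = run_qc(b.queries, idx, **evidence)
        # strict rules: every transcript needs CAGE support at the TSS
        rules = parse_rules(
            '{"rest":[{"within_CAGE_peak": ["TRUE"], "all_canonical": '
            '["TRUE"], "intrapriming": ["FALSE"]}]}', records.columns)
        decisions = apply_rules(records, rules)
        target_decisions = validate_reference_targets(
            b.reference, lambda df: apply_rules(df, parse_rules(
                '{"rest":[{"within_CAGE_peak": ["TRUE"], "all_canonical": '
                '["TRUE"], "intrapriming": ["FALSE"]}]}', df.columns)),
            **evidence)
        result = run_rescue(records, decisions, b.queries, idx,
                            target_decisions, mode=mode)
        return b, records, decisions, idx, result

    def test_rescue_recovers_deleted_source_models(self):
        b, records, decisions, idx, result = self._run()
        truth = b.truth.set_index("isoform")
        deleted_sources = {truth.loc[t.transcript_id, "source_transcript"]
                           for t in b.queries}
        recovered = set(result.all_added_reference_ids)
        frac = len(recovered & deleted_sources) / len(deleted_sources)
        assert frac >= 0.9

    def test_conservation_and_gene_monotonicity(self):
        b, records, decisions, idx, result = self._run()
        kept = {d.transcript_id for d in decisions if d.is_isoform}
        artifacts = {d.transcript_id for d in decisions if not d.is_isoform}
        assert kept | artifacts == {t.transcript_id for t in b.queries}
        assert not (kept & artifacts)
        added = result.all_added_reference_ids
        assert len(added) == len(set(added))
        assert not (set(added) & kept)
        final = expanded_transcriptome(b.queries, decisions, idx, result)
        assoc = records.set_index("isoform")["associated_gene"]
        genes_after_filter = {assoc[t] for t in kept if t in assoc.index}
        genes_after_rescue = genes_after_filter | {
            idx.transcripts[r].gene_id for r in added}
        assert genes_after_filter <= genes_after_rescue
        assert len(final) == len(kept) + len(added)
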
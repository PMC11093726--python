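"""Spike-in (SIRV-style) benchmarking of transcriptome curation.

Synthetic spike-in RNA variants with known isoform structure let detection
be scored against ground truth. To probe annotation-dependence, the true
annotation is deliberately corrupted in two directions before use as a
reference: an *over-annotated* scenario adds fabricated isoforms that are
not in the sample, and an *insufficient* scenario removes true isoforms
that are still present in the sample. Detections are then classified
against both the true and the modified annotation and tallied into the
TP/FP taxonomy feeding six performance metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classify import (REFERENCE_MATCH_WINDOW, classify_transcript)
from .models import Exon, ReferenceIndex, TranscriptModel


@dataclass
class SirvScenario:
    true_annotation: list[TranscriptModel]
    modified_annotation: list[TranscriptModel]
    removed_ids: list[str] = field(default_factory=list)
    fabricated_ids: list[str] = field(default_factory=list)

    @property
    def n_false_added(self) -> int:
        return len(self.fabricated_ids)

    @property
    def n_true_removed(self) -> int:
        return len(self.removed_ids)


@dataclass
class SirvTally:
    known_TP: int = 0
    novel_TP: int = 0
    partial_TP: int = 0
    overannot_FP: int = 0
    FP: int = 0
    n_introduced: int = 0
    n_detected: int = 0


def _shift_end(tx: TranscriptModel, rng, which: str) -> TranscriptModel:
    """Move the 5' or 3' genomic end outward by 100-300 bp."""
    shift = int(rng.integers(100, 301))
    exons = list(tx.exons)
    grow_left = (which == "five" and tx.strand == "+") or \
                (which == "three" and tx.strand == "-")
    if grow_left:
        first = exons[0]
        exons[0] = Exon(first.chrom, max(0, first.start - shift), first.end)
    else:
        last = exons[-1]
        exons[-1] = Exon(last.chrom, last.start, last.end + shift)
    return TranscriptModel(tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
                           exons)


def _skip_exon(tx: TranscriptModel, rng) -> Optional[TranscriptModel]:
    if len(tx.exons) < 3:
        return None
    k = int(rng.integers(1, len(tx.exons) - 1))
    exons = tx.exons[:k] + tx.exons[k + 1:]
    return TranscriptModel(tx.transcript_id, tx.gene_id, tx.chrom, tx.strand,
                           exons)


def _signature(tx: TranscriptModel) -> tuple:
    return (tx.chrom, tx.strand, tuple((e.start, e.end) for e in tx.exons))


def build_scenario(true_annotation: Sequence[TranscriptModel],
                   n_false: int, n_true_removed: int,
                   seed: int = 0) -> SirvScenario:
    """Corrupt a true annotation deterministically.

    ``n_true_removed`` transcripts are removed from the annotation (the
    simulated sample still contains them); ``n_false`` fabricated variants
    (exon skips or 100-300 bp end shifts of true models, deduplicated) are
    added.
    """
    true_list = list(true_annotation)
    rng = np.random.default_rng(seed)
    if n_true_removed > len(true_list):
        raise ValueError("cannot remove more transcripts than the "
                         "annotation contains")
    removed_idx = set(rng.choice(len(true_list), size=n_true_removed,
                                 replace=False).tolist())
    removed_ids = [true_list[i].transcript_id for i in sorted(removed_idx)]
    modified = [t for i, t in enumerate(true_list) if i not in removed_idx]

    existing = {_signature(t) for t in true_list}
    fabricated: list[TranscriptModel] = []
    attempts = 0
    while len(fabricated) < n_false:
        attempts += 1
        if attempts > 200 * max(n_false, 1):
            raise ValueError("cannot fabricate the requested number of "
                             "distinct false models from this annotation")
        src = true_list[int(rng.integers(len(true_list)))]
        if rng.random() < 0.5:
            variant = _skip_exon(src, rng)
        else:
            variant = _shift_end(src, rng, "five" if rng.random() < 0.5
                                 else "three")
        if variant is None:
            continue
        sig = _signature(variant)
        if sig in existing:
            continue
        existing.add(sig)
        fid = f"{src.transcript_id}_false{len(fabricated) + 1}"
        fabricated.append(TranscriptModel(fid, src.gene_id, variant.chrom,
                                          variant.strand, variant.exons))
    modified = modified + fabricated
    return SirvScenario(true_annotation=true_list,
                        modified_annotation=modified,
                        removed_ids=removed_ids,
                        fabricated_ids=[t.transcript_id for t in fabricated])


def tally_detections(detected: Sequence[TranscriptModel],
                     scenario: SirvScenario,
                     window: int = REFERENCE_MATCH_WINDOW) -> SirvTally:
    """Classify detections against both annotations and count TP/FP classes.

    * known TP: reference match to a true transcript also in the modified
      annotation
    * novel TP: reference match to a true transcript absent from the
      modified annotation
    * partial TP: FSM to a true transcript but >``window`` bp off at
      either end
    * over-annotation FP: reference match only to a fabricated model
    * FP: NIC or NNC against both annotations
    """
    true_idx = ReferenceIndex.build(scenario.true_annotation, min_ref_len=0)
    mod_idx = ReferenceIndex.build(scenario.modified_annotation, min_ref_len=0)
    removed = set(scenario.removed_ids)
    fabricated = set(scenario.fabricated_ids)
    tally = SirvTally(n_introduced=len(scenario.true_annotation),
                      n_detected=len(detected))
    for tx in detected:
        call_true = classify_transcript(tx, true_idx)
        call_mod = classify_transcript(tx, mod_idx)
        if call_true.category == "FSM":
            if call_true.subcategory == "reference_match" or (
                    call_true.subcategory == "mono-exon"
                    and abs(call_true.diff_to_TSS) <= window
                    and abs(call_true.diff_to_TTS) <= window):
                if call_true.associated_transcript in removed:
                    tally.novel_TP += 1
                else:
                    tally.known_TP += 1
            else:
                tally.partial_TP += 1
        elif call_mod.category == "FSM" and \
                call_mod.associated_transcript in fabricated and \
                abs(call_mod.diff_to_TSS) <= window and \
                abs(call_mod.diff_to_TTS) <= window:
            tally.overannot_FP += 1
        elif call_true.category in ("NIC", "NNC") and \
                call_mod.category in ("NIC", "NNC"):
            tally.FP += 1
    return tally


def curation_benchmark(seed: int = 0, n_genes: int = 300,
                       n_true_models: int = 300, n_artifacts: int = 300,
                       n_partial: int = 20, n_false: int = 39,
                       n_true_removed: int = 26,
                       n_overannot_detections: int = 15,
                       mode: str = "ml") -> dict[str, dict[str, float]]:
    """Detection metrics before filtering, after filtering, after rescue.

    A spike-in style true annotation is generated, corrupted into the
    reference actually used for classification (``n_false`` fabricated
    models added, ``n_true_removed`` true models removed), and a noisy
    detection set is scored through the full curation pipeline. Returns
    the six metrics at the ``unfiltered``, ``filtered`` and ``rescued``
    stages.
    """
    from .fixtures import FixtureSpec, generate
    from .ml_filter import TrainingSpec, run_ml_filter
    from .pipeline import run_qc
    from .rescue import expanded_transcriptome, run_rescue
    from .rules_filter import apply_rules, default_rules

    spec = FixtureSpec(seed=seed, n_genes=n_genes, end_jitter=30,
                       perturbations={"reference_match": n_true_models,
                                      "nnc": n_artifacts,
                                      "intrapriming": n_partial})
    bundle = generate(spec)
    scenario = build_scenario(bundle.reference, n_false, n_true_removed,
                              seed=seed)
    true_idx = ReferenceIndex.build(scenario.true_annotation, min_ref_len=0)

    detections = list(bundle.queries)
    fab_by_id = {t.transcript_id: t for t in scenario.modified_annotation
                 if t.transcript_id in set(scenario.fabricated_ids)}
    n_over = 0
    for fid in scenario.fabricated_ids:
        if n_over >= n_overannot_detections:
            break
        fab = fab_by_id[fid]
        # only structurally novel fabrications yield clean over-annotation
        # detections; end-shifted ones would score as partial TPs
        if classify_transcript(fab, true_idx).category not in ("NIC", "NNC"):
            continue
        n_over += 1
        detections.append(TranscriptModel(f"det_over_{n_over}",
                                          f"det_over_{n_over}", fab.chrom,
                                          fab.strand, list(fab.exons)))

    mod_idx = ReferenceIndex.build(scenario.modified_annotation,
                                   min_ref_len=200)
    evidence = dict(genome=bundle.genome, cage_peaks=bundle.cage,
                    polya_peaks=bundle.polya_peaks,
                    polya_motifs=bundle.motifs, coverage=bundle.coverage,
                    sj=bundle.sj)
    records, _ = run_qc(detections, mod_idx, **evidence)

    if mode == "ml":
        ml_spec = TrainingSpec(seed=seed)
        decisions, model = run_ml_filter(records, ml_spec)

        def ref_filter(df):
            from .ml_filter import score_and_filter
            return score_and_filter(df, model, ml_spec)
    else:
        rules = default_rules()
        decisions = apply_rules(records, rules)

        def ref_filter(df):
            return apply_rules(df, rules)

    ref_records, _ = run_qc(scenario.modified_annotation,
                            ReferenceIndex.build(scenario.modified_annotation,
                                                 min_ref_len=0), **evidence)
    target_decisions = {d.transcript_id: d
                        for d in ref_filter(ref_records)}
    rescue_result = run_rescue(records, decisions, detections, mod_idx,
                               target_decisions, mode=mode)
    final = expanded_transcriptome(detections, decisions, mod_idx,
                                   rescue_result)

    kept_ids = {d.transcript_id for d in decisions if d.is_isoform}
    filtered = [t for t in detections if t.transcript_id in kept_ids]
    stages = {"unfiltered": detections, "filtered": filtered,
              "rescued": final}
    return {name: compute_metrics(tally_detections(txs, scenario))
            for name, txs in stages.items()}


def compute_metrics(t: SirvTally) -> dict[str, float]:
    """The six detection metrics; undefined ratios are NaN."""
    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    sensitivity = ratio(t.known_TP + t.novel_TP, t.n_introduced)
    precision = ratio(t.known_TP + t.novel_TP, t.n_detected)
    if (not math.isnan(sensitivity) and not math.isnan(precision)
            and sensitivity + precision > 0):
        fscore = 2 * sensitivity * precision / (sensitivity + precision)
    else:
        fscore = math.nan
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "fscore": fscore,
        "fdr": ratio(t.FP + t.overannot_FP + t.partial_TP, t.n_detected),
        "odr": ratio(t.overannot_FP, t.n_detected),
        "ndr": ratio(t.novel_TP + t.FP, t.n_detected),
    }
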
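"""Rescue of transcriptional signal lost to artifact filtering.

Filtering removes transcript models, but an artifact often still marks a
genuinely expressed gene whose correct model simply was not built from the
long reads. Rescue re-incorporates that signal in four steps:

1. *Automatic rescue*: the reference transcript associated with each
   removed FSM is added to the curated transcriptome (once), unless a
   passing FSM of that reference already represents it.
2. *Candidate selection*: removed ISM/NIC/NNC transcripts become rescue
   candidates; an ISM is skipped when any FSM in the dataset shares its
   associated reference transcript.
3. *Target validation*: the reference transcriptome is itself classified,
   QC'd and filtered under the same configuration (with ``min_ref_len`` 0),
   so only filter-passing targets can be rescued.
4. *Hit resolution*: candidates are mapped against same-gene targets
   (filter-passing long-read models and reference transcripts). In ML mode
   the single best target by filter probability wins; in rules mode every
   passing reference target is kept. Targets already present in the
   curated transcriptome are never added twice.

The built-in mapper scores a candidate/target pair as the fraction of
candidate junctions present in the target plus the base-level exon-overlap
Jaccard index, and keeps at most 7 hits per candidate (primary plus six
secondary, mirroring a spliced aligner's default). Externally computed
alignments can be substituted by supplying pre-built hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .models import ReferenceIndex, TranscriptModel
from .rules_filter import FilterDecision

MAX_HITS_PER_CANDIDATE = 7  # primary alignment + 6 secondary


@dataclass(frozen=True)
class MappingHit:
    candidate_id: str
    target_id: str
    target_kind: str  # reference | long_read
    score: float


@dataclass
class RescueOutcome:
    artifact_id: str
    action: str  # rescued_reference | rescued_long_read | already_represented | unrescued
    chosen_target: Optional[str] = None


@dataclass
class RescueResult:
    automatic_additions: list[str] = field(default_factory=list)
    outcomes: list[RescueOutcome] = field(default_factory=list)
    rescued_reference_ids: list[str] = field(default_factory=list)

    @property
    def all_added_reference_ids(self) -> list[str]:
        seen = dict.fromkeys(self.automatic_additions)
        seen.update(dict.fromkeys(self.rescued_reference_ids))
        return list(seen)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "artifact": [o.artifact_id for o in self.outcomes],
            "action": [o.action for o in self.outcomes],
            "target": [o.chosen_target or "NA" for o in self.outcomes],
        })


# ---------------------------------------------------------------------------
# Step 1: automatic FSM rescue
# ---------------------------------------------------------------------------

def automatic_rescue(records: pd.DataFrame,
                     decisions: dict[str, FilterDecision],
                     index: ReferenceIndex,
                     curated_ids: set[str]) -> list[str]:
    """Reference transcripts recovered from removed FSM models.

    A reference transcript is added when at least one of its FSM models was
    removed, no FSM of the same reference passed the filter, and it is not
    already in the curated set. Each id is added at most once.
    """
    fsm = records[records["structural_category"] == "FSM"]
    passing_refs = set()
    removed_refs: list[str] = []
    for _, row in fsm.iterrows():
        d = decisions.get(row["isoform"])
        if d is None:
            continue
        ref = row["associated_transcript"]
        if d.is_isoform:
            passing_refs.add(ref)
        else:
            removed_refs.append(ref)
    additions = []
    for ref in removed_refs:
        if ref in passing_refs or ref in curated_ids or ref in additions:
            continue
        if ref in index.transcripts:
            additions.append(ref)
    return additions


# ---------------------------------------------------------------------------
# Step 2: rescue candidates
# ---------------------------------------------------------------------------

def select_rescue_candidates(records: pd.DataFrame,
                             decisions: dict[str, FilterDecision]
                             ) -> list[str]:
    """Removed ISM/NIC/NNC models eligible for rescue by mapping.

    ISM artifacts whose associated reference transcript also has an FSM
    model anywhere in the dataset are excluded: the FSM already carries
    (or rescued) that signal.
    """
    fsm_refs = set(records.loc[records["structural_category"] == "FSM",
                               "associated_transcript"])
    candidates = []
    for _, row in records.iterrows():
        d = decisions.get(row["isoform"])
        if d is None or d.is_isoform:
            continue
        cat = row["structural_category"]
        if cat not in ("ISM", "NIC", "NNC"):
            continue
        if cat == "ISM" and row["associated_transcript"] in fsm_refs:
            continue
        candidates.append(row["isoform"])
    return candidates


# ---------------------------------------------------------------------------
# Step 3: mapping candidates to same-gene targets
# ---------------------------------------------------------------------------

def _compatibility_score(candidate: TranscriptModel,
                         target: TranscriptModel) -> float:
    """Junction-chain containment plus exon-overlap Jaccard (0..2)."""
    if candidate.chrom != target.chrom or candidate.strand != target.strand:
        return 0.0
    cand_j = candidate.junction_chain()
    if cand_j:
        tgt_j = set(target.junction_chain())
        junction_frac = sum(j in tgt_j for j in cand_j) / len(cand_j)
    else:
        junction_frac = 0.0
    overlap = 0
    for ce in candidate.exons:
        for te in target.exons:
            overlap += max(0, min(ce.end, te.end) - max(ce.start, te.start))
    union = candidate.spliced_length + target.spliced_length - overlap
    jaccard = overlap / union if union else 0.0
    return junction_frac + jaccard


def map_candidates(candidates: Sequence[TranscriptModel],
                   records: pd.DataFrame,
                   long_read_models: dict[str, TranscriptModel],
                   index: ReferenceIndex,
                   curated_ids: set[str],
                   max_hits: int = MAX_HITS_PER_CANDIDATE
                   ) -> list[MappingHit]:
    """Score each candidate against its same-gene rescue targets.

    Targets are the reference transcripts of the candidate's associated
    gene(s) plus the curated (filter-passing) long-read models classified
    to the same gene(s). At most ``max_hits`` hits are kept per candidate.
    """
    assoc = records.set_index("isoform")["associated_gene"]
    gene_to_longreads: dict[str, list[str]] = {}
    for tid, gene in assoc.items():
        if tid in curated_ids and tid in long_read_models:
            for g in str(gene).split("_"):
                gene_to_longreads.setdefault(g, []).append(tid)

    hits: list[MappingHit] = []
    for cand in candidates:
        genes = str(assoc.get(cand.transcript_id, "")).split("_")
        scored: list[MappingHit] = []
        seen: set[str] = set()
        for g in genes:
            for ref_tx in index.genes.get(g, []):
                if ref_tx.transcript_id in seen:
                    continue
                seen.add(ref_tx.transcript_id)
                s = _compatibility_score(cand, ref_tx)
                if s > 0:
                    scored.append(MappingHit(cand.transcript_id,
                                             ref_tx.transcript_id,
                                             "reference", s))
            for tid in gene_to_longreads.get(g, []):
                if tid in seen or tid == cand.transcript_id:
                    continue
                seen.add(tid)
                s = _compatibility_score(cand, long_read_models[tid])
                if s > 0:
                    scored.append(MappingHit(cand.transcript_id, tid,
                                             "long_read", s))
        scored.sort(key=lambda h: (-h.score, h.target_kind, h.target_id))
        hits.extend(scored[:max_hits])
    return hits


# ---------------------------------------------------------------------------
# Step 3b: reference-side validation
# ---------------------------------------------------------------------------

def validate_reference_targets(reference: Sequence[TranscriptModel],
                               filter_fn, index: Optional[ReferenceIndex] = None,
                               **qc_inputs) -> dict[str, FilterDecision]:
    """Run QC + filter on the reference transcriptome itself.

    The reference is classified against itself with ``min_ref_len`` 0 so
    short transcripts are retained, then ``filter_fn`` (the same filter
    configuration used for the long reads: a callable mapping a
    classification table to decisions) produces a verdict per reference
    transcript.
    """
    from .pipeline import run_qc

    if index is None:
        index = ReferenceIndex.build(reference, min_ref_len=0)
    class_df, _ = run_qc(reference, index, **qc_inputs)
    decisions = filter_fn(class_df)
    return {d.transcript_id: d for d in decisions}


# ---------------------------------------------------------------------------
# Step 4: hit resolution
# ---------------------------------------------------------------------------

def resolve_hits(hits: Sequence[MappingHit],
                 target_decisions: dict[str, FilterDecision],
                 mode: str,
                 curated_ids: set[str],
                 already_added: Sequence[str] = ()) -> RescueResult:
    """Select rescue targets among filter-passing mapping hits.

    ML mode keeps the single best target per candidate by filter
    probability (ties: higher mapping score, then lexicographic id); rules
    mode keeps every passing reference target. Reference additions are
    deduplicated across candidates and against the curated set.
    """
    if mode not in ("ml", "rules"):
        raise ValueError("mode must be 'ml' or 'rules'")
    result = RescueResult(automatic_additions=list(already_added))
    added: set[str] = set(already_added)
    by_candidate: dict[str, list[MappingHit]] = {}
    for h in hits:
        by_candidate.setdefault(h.candidate_id, []).append(h)

    for cand in sorted(by_candidate):
        passing = [h for h in by_candidate[cand]
                   if (d := target_decisions.get(h.target_id)) is not None
                   and d.is_isoform]
        if not passing:
            result.outcomes.append(RescueOutcome(cand, "unrescued"))
            continue
        if mode == "ml":
            def ml_key(h: MappingHit):
                d = target_decisions[h.target_id]
                p = d.probability if d.probability is not None else 0.0
                return (-p, -h.score, h.target_id)
            best = min(passing, key=ml_key)
            if best.target_kind == "long_read":
                result.outcomes.append(RescueOutcome(
                    cand, "already_represented", chosen_target=best.target_id))
            elif best.target_id in curated_ids or best.target_id in added:
                result.outcomes.append(RescueOutcome(
                    cand, "already_represented", chosen_target=best.target_id))
            else:
                added.add(best.target_id)
                result.rescued_reference_ids.append(best.target_id)
                result.outcomes.append(RescueOutcome(
                    cand, "rescued_reference", chosen_target=best.target_id))
        else:
            ref_targets = [h.target_id for h in passing
                           if h.target_kind == "reference"]
            new_refs = [t for t in dict.fromkeys(ref_targets)
                        if t not in curated_ids and t not in added]
            if new_refs:
                for t in new_refs:
                    added.add(t)
                    result.rescued_reference_ids.append(t)
                result.outcomes.append(RescueOutcome(
                    cand, "rescued_reference",
                    chosen_target=",".join(new_refs)))
            else:
                result.outcomes.append(RescueOutcome(
                    cand, "already_represented",
                    chosen_target=passing[0].target_id))
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_rescue(records: pd.DataFrame,
               decisions: Sequence[FilterDecision],
               queries: Sequence[TranscriptModel],
               index: ReferenceIndex,
               target_decisions: dict[str, FilterDecision],
               mode: str = "rules") -> RescueResult:
    """Full rescue pass over a filtered transcriptome.

    ``target_decisions`` must hold a verdict for every reference transcript
    (from :func:`validate_reference_targets`) and, for long-read targets,
    the original filter decisions are consulted directly.
    """
    dmap = {d.transcript_id: d for d in decisions}
    models = {t.transcript_id: t for t in queries}
    curated_ids = {tid for tid, d in dmap.items() if d.is_isoform}

    auto = automatic_rescue(records, dmap, index, curated_ids)
    cand_ids = select_rescue_candidates(records, dmap)
    candidates = [models[c] for c in cand_ids if c in models]
    hits = map_candidates(candidates, records, models, index, curated_ids)
    all_target_decisions = dict(target_decisions)
    for tid in curated_ids:
        all_target_decisions.setdefault(tid, dmap[tid])
    result = resolve_hits(hits, all_target_decisions, mode, curated_ids,
                          already_added=auto)
    mapped = {o.artifact_id for o in result.outcomes}
    for c in sorted(cand_ids):
        if c not in mapped:
            result.outcomes.append(RescueOutcome(c, "unrescued"))
    return result


def expanded_transcriptome(queries: Sequence[TranscriptModel],
                           decisions: Sequence[FilterDecision],
                           index: ReferenceIndex,
                           result: RescueResult) -> list[TranscriptModel]:
    """Curated long-read models plus all rescued reference transcripts."""
    keep = {d.transcript_id for d in decisions if d.is_isoform}
    out = [t for t in queries if t.transcript_id in keep]
    for rid in result.all_added_reference_ids:
        if rid not in keep and rid in index.transcripts:
            out.append(index.transcripts[rid])
    return out
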
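"""Structural classification of query transcripts against a reference.

Each query transcript receives exactly one of eight structural categories
(FSM, ISM, NIC, NNC, fusion, antisense, genic_genomic, intergenic) and one
subcategory; the admissible (category, subcategory) label space has 22
reachable members:

* FSM: reference_match, alternative_5end, alternative_3end,
  alternative_3end5end, mono-exon
* ISM: 3prime_fragment, 5prime_fragment, internal_fragment,
  intron_retention, mono-exon
* NIC: combination_of_known_junctions, combination_of_known_splicesites,
  mono-exon, mono-exon_by_intron_retention
* NNC: at_least_one_novel_splicesite
* antisense / genic_genomic / intergenic: mono-exon, multi-exon
* fusion: multi-exon (a fusion call requires a junction chain)

The decision order is FSM > ISM > fusion > NIC > NNC > genic_genomic >
antisense > intergenic. Fusion is tested before NIC/NNC because a junction
chain spanning two disjoint gene loci would otherwise always satisfy the
novelty tests first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .models import Junction, ReferenceIndex, TranscriptModel

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "fusion", "antisense",
              "genic_genomic", "intergenic")

#: Maximum end distance (bp, inclusive) for the FSM reference_match call.
REFERENCE_MATCH_WINDOW = 50


@dataclass
class StructuralCall:
    """Category, subcategory and reference association for one transcript."""

    category: str
    subcategory: str = "na"
    associated_gene: str = "novel"
    associated_transcript: str = "novel"
    diff_to_TSS: Optional[int] = None
    diff_to_TTS: Optional[int] = None
    diff_to_gene_TSS: Optional[int] = None
    diff_to_gene_TTS: Optional[int] = None


# --- end-distance conventions ----------------------------------------------

def signed_end_diff(query_pos: int, ref_pos: int, strand: str) -> int:
    """Signed distance from a reference end to the query end.

    Positive means the query end lies downstream of the reference end in
    transcription direction; negative means upstream.
    """
    d = query_pos - ref_pos
    return d if strand == "+" else -d


def end_diffs(query: TranscriptModel, ref: TranscriptModel) -> tuple[int, int]:
    return (signed_end_diff(query.tss, ref.tss, query.strand),
            signed_end_diff(query.tts, ref.tts, query.strand))


def _nearest_signed(query_pos: int, positions, strand: str) -> Optional[int]:
    if not positions:
        return None
    return min((signed_end_diff(query_pos, p, strand) for p in positions),
               key=abs)


# --- junction-chain matching -------------------------------------------------

def match_splice_chain(query: TranscriptModel, ref: TranscriptModel) -> str:
    """Compare two junction chains.

    Returns ``"full"`` when the chains are identical,
    ``"consecutive_subchain"`` when the query chain is a non-empty contiguous
    sublist of the reference chain, and ``"none"`` otherwise.
    """
    if query.is_mono_exon or ref.is_mono_exon:
        raise ValueError("splice-chain matching requires multi-exon transcripts")
    if query.chrom != ref.chrom or query.strand != ref.strand:
        return "none"
    q, r = query.junction_chain(), ref.junction_chain()
    if q == r:
        return "full"
    if len(q) < len(r):
        for i in range(len(r) - len(q) + 1):
            if r[i:i + len(q)] == q:
                return "consecutive_subchain"
    return "none"


def _end_closeness(query: TranscriptModel, ref: TranscriptModel) -> int:
    d5, d3 = end_diffs(query, ref)
    return abs(d5) + abs(d3)


# --- subcategory assignment --------------------------------------------------

def assign_fsm_subcategory(query: TranscriptModel, ref: TranscriptModel,
                           window: int = REFERENCE_MATCH_WINDOW) -> str:
    d5, d3 = end_diffs(query, ref)
    alt5 = abs(d5) > window
    alt3 = abs(d3) > window
    if alt5 and alt3:
        return "alternative_3end5end"
    if alt5:
        return "alternative_5end"
    if alt3:
        return "alternative_3end"
    return "reference_match"


def assign_ism_subcategory(query: TranscriptModel, ref: TranscriptModel) -> str:
    ref_chain = ref.junction_chain()
    query_chain = query.junction_chain()
    # retained intron: a query exon bridges a reference junction entirely
    qset = set(query_chain)
    for exon in query.exons:
        for j in ref_chain:
            if j not in qset and exon.start < j.intron_start and \
                    j.intron_end < exon.end:
                return "intron_retention"
    # locate the matched window in the reference chain
    k = len(query_chain)
    offset = next(i for i in range(len(ref_chain) - k + 1)
                  if ref_chain[i:i + k] == query_chain)
    missing_left = offset > 0
    missing_right = offset + k < len(ref_chain)
    # genomic left = transcription 5' on +, transcription 3' on -
    if query.strand == "+":
        missing_5, missing_3 = missing_left, missing_right
    else:
        missing_5, missing_3 = missing_right, missing_left
    if missing_5 and missing_3:
        return "internal_fragment"
    if missing_5:
        return "3prime_fragment"
    return "5prime_fragment"


# --- gene-overlap helpers ----------------------------------------------------

def _exonic_overlap_genes(query: TranscriptModel, index: ReferenceIndex,
                          strand: str) -> list[str]:
    """Same-chrom genes on ``strand`` whose exons overlap query exons."""
    genes = index.overlapping_genes(query.chrom, query.start, query.end, strand)
    hit = []
    for g in genes:
        for tx in index.genes[g]:
            if any(qe.start < re.end and re.start < qe.end
                   for qe in query.exons for re in tx.exons):
                hit.append(g)
                break
    return hit


def _loci_disjoint(index: ReferenceIndex, g1: str, g2: str) -> bool:
    _, _, lo1, hi1 = index.gene_span(g1)
    _, _, lo2, hi2 = index.gene_span(g2)
    return hi1 <= lo2 or hi2 <= lo1


def _gene_end_diffs(query: TranscriptModel, index: ReferenceIndex,
                    genes: Sequence[str]) -> tuple[Optional[int], Optional[int]]:
    tss_set: set[int] = set()
    tts_set: set[int] = set()
    for g in genes:
        tss_set |= index.gene_tss.get(g, set())
        tts_set |= index.gene_tts.get(g, set())
    return (_nearest_signed(query.tss, tss_set, query.strand),
            _nearest_signed(query.tts, tts_set, query.strand))


# --- main entry points -------------------------------------------------------

def classify_transcript(query: TranscriptModel,
                        index: ReferenceIndex) -> StructuralCall:
    """Assign the structural category and subcategory of one transcript."""
    if query.is_mono_exon:
        return classify_mono_exon(query, index)

    same_genes = index.overlapping_genes(query.chrom, query.start, query.end,
                                         query.strand)
    candidates = [index.transcripts[tid]
                  for g in same_genes
                  for tid in sorted(t.transcript_id for t in index.genes[g])]
    candidates = [t for t in candidates if not t.is_mono_exon]

    # FSM: identical junction chain; tie-break by closest ends, then id
    full = [t for t in candidates if match_splice_chain(query, t) == "full"]
    if full:
        ref = min(full, key=lambda t: (_end_closeness(query, t), t.transcript_id))
        call = _associate(query, index, ref, "FSM")
        call.subcategory = assign_fsm_subcategory(query, ref)
        return call

    # ISM: contiguous sub-chain; prefer the longest reference chain coverage
    isms = [t for t in candidates
            if match_splice_chain(query, t) == "consecutive_subchain"]
    if isms:
        ref = min(isms, key=lambda t: (_end_closeness(query, t),
                                       t.transcript_id))
        call = _associate(query, index, ref, "ISM")
        call.subcategory = assign_ism_subcategory(query, ref)
        return call

    exonic_genes = _exonic_overlap_genes(query, index, query.strand)

    # fusion: the chain spans >=2 mutually non-overlapping gene loci
    if len(exonic_genes) >= 2 and any(
            _loci_disjoint(index, g1, g2)
            for i, g1 in enumerate(exonic_genes)
            for g2 in exonic_genes[i + 1:]):
        call = StructuralCall("fusion", "multi-exon",
                              associated_gene="_".join(exonic_genes))
        call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
            _gene_end_diffs(query, index, exonic_genes)
        return call

    if exonic_genes:
        call = _classify_novel(query, index, exonic_genes)
        return call

    if same_genes:
        # same-strand locus overlap without exonic overlap (intron-contained)
        call = StructuralCall("genic_genomic", "multi-exon",
                              associated_gene="_".join(same_genes))
        call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
            _gene_end_diffs(query, index, same_genes)
        return call

    anti = index.overlapping_genes(query.chrom, query.start, query.end,
                                   "-" if query.strand == "+" else "+")
    if anti:
        return StructuralCall("antisense", "multi-exon")
    return StructuralCall("intergenic", "multi-exon")


def _classify_novel(query: TranscriptModel, index: ReferenceIndex,
                    genes: Sequence[str]) -> StructuralCall:
    """NIC/NNC split over the exon-overlapped gene set."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    junctions: set[Junction] = set()
    for g in genes:
        donors |= index.gene_donors.get(g, set())
        acceptors |= index.gene_acceptors.get(g, set())
        junctions |= index.gene_junctions.get(g, set())
    chain = query.junction_chain()
    novel_site = any(j.donor_pos not in donors or j.acceptor_pos not in acceptors
                     for j in chain)
    category = "NNC" if novel_site else "NIC"
    if category == "NNC":
        sub = "at_least_one_novel_splicesite"
    elif all(j in junctions for j in chain):
        sub = "combination_of_known_junctions"
    else:
        sub = "combination_of_known_splicesites"
    call = StructuralCall(category, sub, associated_gene="_".join(genes))
    call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
        _gene_end_diffs(query, index, genes)
    return call


def classify_mono_exon(query: TranscriptModel,
                       index: ReferenceIndex) -> StructuralCall:
    """Category rules for single-exon queries (overlap-based association)."""
    exon = query.exons[0]
    same_genes = index.overlapping_genes(query.chrom, query.start, query.end,
                                         query.strand)
    same_txs = [index.transcripts[tid]
                for g in same_genes
                for tid in sorted(t.transcript_id for t in index.genes[g])]

    mono_refs = [t for t in same_txs if t.is_mono_exon
                 and t.start < query.end and query.start < t.end]
    if mono_refs:
        ref = min(mono_refs,
                  key=lambda t: (_end_closeness(query, t), t.transcript_id))
        call = _associate(query, index, ref, "FSM")
        call.subcategory = "mono-exon"
        return call

    containing = [t for t in same_txs if not t.is_mono_exon
                  and any(e.start <= exon.start and exon.end <= e.end
                          for e in t.exons)]
    if containing:
        ref = min(containing,
                  key=lambda t: (_end_closeness(query, t), t.transcript_id))
        call = _associate(query, index, ref, "ISM")
        call.subcategory = "mono-exon"
        return call

    gene_juncs: set[Junction] = set()
    for g in same_genes:
        gene_juncs |= index.gene_junctions.get(g, set())
    if any(exon.start < j.intron_start and j.intron_end < exon.end
           for j in gene_juncs):
        call = StructuralCall("NIC", "mono-exon_by_intron_retention",
                              associated_gene="_".join(same_genes))
        call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
            _gene_end_diffs(query, index, same_genes)
        return call

    exonic_genes = _exonic_overlap_genes(query, index, query.strand)
    if exonic_genes:
        call = StructuralCall("NIC", "mono-exon",
                              associated_gene="_".join(exonic_genes))
        call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
            _gene_end_diffs(query, index, exonic_genes)
        return call

    if same_genes:  # inside an intron, or locus overlap without exon contact
        call = StructuralCall("genic_genomic", "mono-exon",
                              associated_gene="_".join(same_genes))
        call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
            _gene_end_diffs(query, index, same_genes)
        return call

    anti = index.overlapping_genes(query.chrom, query.start, query.end,
                                   "-" if query.strand == "+" else "+")
    if anti:
        return StructuralCall("antisense", "mono-exon")
    return StructuralCall("intergenic", "mono-exon")


def _associate(query: TranscriptModel, index: ReferenceIndex,
               ref: TranscriptModel, category: str) -> StructuralCall:
    d5, d3 = end_diffs(query, ref)
    call = StructuralCall(category,
                          associated_gene=ref.gene_id,
                          associated_transcript=ref.transcript_id,
                          diff_to_TSS=d5, diff_to_TTS=d3)
    call.diff_to_gene_TSS, call.diff_to_gene_TTS = \
        _gene_end_diffs(query, index, [ref.gene_id])
    return call


def classify_all(queries: Sequence[TranscriptModel],
                 index: ReferenceIndex) -> dict[str, StructuralCall]:
    return {q.transcript_id: classify_transcript(q, index) for q in queries}
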
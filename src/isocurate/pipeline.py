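"""Assembly of the per-transcript classification and junction tables."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .classify import StructuralCall, classify_transcript
from .models import (CoverageTrack, PeakSet, ReferenceIndex, SJSupport,
                     TranscriptModel)
from .qc import TranscriptQC, transcript_qc


def run_qc(queries: Sequence[TranscriptModel], index: ReferenceIndex,
           genome=None,
           cage_peaks: Optional[PeakSet] = None,
           polya_peaks: Optional[PeakSet] = None,
           polya_motifs: Optional[Sequence[str]] = None,
           coverage: Optional[Sequence[CoverageTrack]] = None,
           sj: Optional[SJSupport] = None,
           **qc_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every query transcript and compute its QC attributes.

    Returns the classification table (one row per transcript) and the
    junction table (one row per transcript junction).
    """
    class_rows = []
    junction_rows = []
    for tx in queries:
        call = classify_transcript(tx, index)
        qc = transcript_qc(tx, genome=genome, cage_peaks=cage_peaks,
                           polya_peaks=polya_peaks, polya_motifs=polya_motifs,
                           coverage=coverage, sj=sj, **qc_kwargs)
        class_rows.append(_classification_row(tx, call, qc))
        for n, jqc in enumerate(qc.junctions, start=1):
            junction_rows.append({
                "isoform": tx.transcript_id,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "junction_number": n,
                "genomic_start_coord": jqc.junction.intron_start,
                "genomic_end_coord": jqc.junction.intron_end,
                "splice_motif": jqc.splice_motif,
                "canonical": jqc.canonical,
                "RTS_junction": jqc.rts_flag,
                "total_coverage": jqc.total_cov,
            })
    class_df = pd.DataFrame(class_rows)
    junc_df = pd.DataFrame(junction_rows)
    return class_df, junc_df


def _classification_row(tx: TranscriptModel, call: StructuralCall,
                        qc: TranscriptQC) -> dict:
    return {
        "isoform": tx.transcript_id,
        "chrom": tx.chrom,
        "strand": tx.strand,
        "length": tx.spliced_length,
        "exons": len(tx.exons),
        "structural_category": call.category,
        "subcategory": call.subcategory,
        "associated_gene": call.associated_gene,
        "associated_transcript": call.associated_transcript,
        "diff_to_TSS": call.diff_to_TSS,
        "diff_to_TTS": call.diff_to_TTS,
        "diff_to_gene_TSS": call.diff_to_gene_TSS,
        "diff_to_gene_TTS": call.diff_to_gene_TTS,
        "min_cov": qc.min_cov,
        "all_canonical": qc.all_canonical,
        "RTS_stage": qc.rts_any,
        "perc_A_downstream_TTS": qc.perc_A_downstream_TTS,
        "intrapriming": qc.intrapriming,
        "polyA_motif": qc.polyA_motif,
        "polyA_dist": qc.polyA_dist,
        "within_CAGE_peak": qc.within_CAGE_peak,
        "dist_to_CAGE_peak": qc.dist_to_CAGE_peak,
        "within_polyA_site": qc.within_polyA_site,
        "dist_to_polyA_site": qc.dist_to_polyA_site,
        "ratio_TSS": qc.ratio_TSS,
    }
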
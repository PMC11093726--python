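"""Readers and writers for the standard formats.

GTF is consumed in the GENCODE dialect (exon and optional CDS features with
``transcript_id``/``gene_id`` attributes). Internally everything is 0-based
half-open; the converters here are the only place the 1-based inclusive GTF
convention appears.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .models import CoverageTrack, Exon, PeakSet, SJSupport, TranscriptModel

PathLike = Union[str, Path]


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def load_gtf(path: PathLike, min_len: int = 0) -> list[TranscriptModel]:
    """Load transcript models from a GTF file.

    Parameters
    ----------
    path
        GTF file with ``exon`` (and optionally ``CDS``) features carrying a
        ``transcript_id`` attribute. ``gene_id`` falls back to the
        transcript id when absent.
    min_len
        Transcripts with spliced (exonic) length below this are dropped.
        Reference annotations use 200 by default to avoid spurious matches
        to annotated fragments; set 0 to keep everything.
    """
    exons: dict[str, list[Exon]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    cds: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated "
                                    f"fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = \
                fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise GtfParseError(f"line {lineno}: missing transcript_id")
            gid = attributes.get("gene_id", tid)
            if tid not in meta:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            elif meta[tid][1] != chrom or meta[tid][2] != strand:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} has features on mixed "
                    f"chromosome or strand")
            if feature == "exon":
                exons.setdefault(tid, []).append(Exon(chrom, start, end))
            else:
                cds.setdefault(tid, []).append((start, end))

    out: list[TranscriptModel] = []
    for tid in order:
        if tid not in exons:
            continue
        gid, chrom, strand = meta[tid]
        blocks = _merge_exons(sorted(exons[tid]))
        cds_span = None
        if tid in cds:
            cds_span = (min(s for s, _ in cds[tid]), max(e for _, e in cds[tid]))
        tx = TranscriptModel(tid, gid, chrom, strand, blocks, cds=cds_span)
        if tx.spliced_length >= min_len:
            out.append(tx)
    return out


def _merge_exons(blocks: list[Exon]) -> list[Exon]:
    """Merge touching/overlapping exon blocks of one transcript."""
    merged: list[Exon] = []
    for b in blocks:
        if merged and b.start <= merged[-1].end:
            last = merged.pop()
            merged.append(Exon(b.chrom, last.start, max(last.end, b.end)))
        else:
            merged.append(b)
    return merged


def write_gtf(transcripts: Sequence[TranscriptModel], path: PathLike,
              source: str = "isocurate") -> None:
    """Write transcripts back out as 1-based inclusive GTF."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (f'gene_id "{tx.gene_id}"; '
                     f'transcript_id "{tx.transcript_id}";')
            fh.write("\t".join([
                tx.chrom, source, "transcript", str(tx.start + 1), str(tx.end),
                ".", tx.strand, ".", attrs]) + "\n")
            for e in tx.exons:
                fh.write("\t".join([
                    tx.chrom, source, "exon", str(e.start + 1), str(e.end),
                    ".", tx.strand, ".", attrs]) + "\n")
            if tx.cds is not None:
                for e in tx.cds_exons():
                    fh.write("\t".join([
                        tx.chrom, source, "CDS", str(e.start + 1), str(e.end),
                        ".", tx.strand, ".", attrs]) + "\n")


def load_sj_tab(path: PathLike, replicate: int = 0,
                support: Optional[SJSupport] = None) -> SJSupport:
    """Read one STAR ``SJ.out.tab`` file into an :class:`SJSupport`.

    Columns: chrom, intron start (1-based), intron end (1-based inclusive),
    strand code (0 undefined, 1 '+', 2 '-'), intron motif, annotated,
    unique-read count, multi-read count, max overhang. Only the unique-read
    count (column 7) is used.
    """
    sj = support if support is not None else SJSupport(n_replicates=replicate + 1)
    strand_map = {"0": ".", "1": "+", "2": "-"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                chrom = fields[0]
                start = int(fields[1]) - 1  # 1-based -> 0-based inclusive
                end = int(fields[2])        # 1-based inclusive -> exclusive
                strand = strand_map[fields[3]]
                unique = int(fields[6])
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed SJ.out.tab row") from exc
            sj.add(chrom, strand, start, end, replicate, unique)
    return sj


def load_sj_tabs(paths: Sequence[PathLike]) -> SJSupport:
    sj = SJSupport(n_replicates=len(paths))
    for i, p in enumerate(paths):
        load_sj_tab(p, replicate=i, support=sj)
    return sj


def load_bed(path: PathLike, kind: str = "generic") -> PeakSet:
    """Read a BED4/BED6 peak file (half-open intervals)."""
    intervals: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            intervals.append((chrom, start, end, strand))
    return PeakSet(intervals, kind=kind)


def load_bedgraph(path: PathLike, replicate_id: Optional[str] = None) -> CoverageTrack:
    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            segments.append((chrom, int(start), int(end), float(value)))
    return CoverageTrack(replicate_id or str(path), segments)


def load_motifs(path: PathLike) -> list[str]:
    """PolyA motif list: one motif per line, order = priority."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            m = line.strip().upper()
            if m:
                motifs.append(m)
    return motifs


# ---------------------------------------------------------------------------
# Output tables. Column order is fixed so downstream filters can rely on it.
# ---------------------------------------------------------------------------

CLASSIFICATION_COLUMNS = [
    "isoform", "chrom", "strand", "length", "exons",
    "structural_category", "subcategory",
    "associated_gene", "associated_transcript",
    "diff_to_TSS", "diff_to_TTS", "diff_to_gene_TSS", "diff_to_gene_TTS",
    "min_cov", "all_canonical", "RTS_stage",
    "perc_A_downstream_TTS", "intrapriming",
    "polyA_motif", "polyA_dist",
    "within_CAGE_peak", "dist_to_CAGE_peak",
    "within_polyA_site", "dist_to_polyA_site",
    "ratio_TSS",
]

JUNCTION_COLUMNS = [
    "isoform", "chrom", "strand", "junction_number",
    "genomic_start_coord", "genomic_end_coord",
    "splice_motif", "canonical", "RTS_junction", "total_coverage",
]


def _serialize(value):
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if value is None:
        return "NA"
    return value


def write_classification_table(records: pd.DataFrame, path: PathLike) -> None:
    """Write the per-transcript classification table as TSV.

    Booleans become TRUE/FALSE, missing values NA. Columns beyond the
    documented roster are passed through after it.
    """
    cols = [c for c in CLASSIFICATION_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    df = records[cols].map(_serialize)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_classification_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in df.columns:
        if df[col].dtype == object:
            vals = set(df[col].dropna().unique())
            if vals and vals <= {"TRUE", "FALSE"}:
                df[col] = df[col].map({"TRUE": True, "FALSE": False})
    return df


def write_junction_table(records: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in JUNCTION_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    records[cols].map(_serialize).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_fasta(sequences: dict[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
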
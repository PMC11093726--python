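"""Core genomic data containers.

All coordinates are 0-based, half-open ``[start, end)`` on the forward
genomic strand. GTF input/output converts to and from the 1-based inclusive
convention at the boundary; BED and bedGraph are consumed natively.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

CANONICAL_SPLICE_MOTIFS = frozenset({"GT-AG", "GC-AG", "AT-AC"})


@dataclass(frozen=True, order=True)
class Exon:
    """A single exon block on the forward genomic strand."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon start must precede end: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Junction:
    """An intron: the gap between two consecutive exons."""

    chrom: str
    strand: str
    intron_start: int  # 0-based inclusive (first intronic base)
    intron_end: int    # 0-based exclusive

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError("intron start must precede end")

    @property
    def donor_pos(self) -> int:
        """Strand-aware donor (5') splice-site position."""
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor_pos(self) -> int:
        """Strand-aware acceptor (3') splice-site position."""
        return self.intron_end if self.strand == "+" else self.intron_start


@dataclass
class TranscriptModel:
    """One transcript model: ordered exons plus optional CDS span."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon]
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(f"{self.transcript_id}: exons on mixed chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    # --- geometry -------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Strand-aware 5'-most genomic position (0-based base position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware 3'-most genomic position (0-based base position)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def junctions(self) -> list[Junction]:
        """Introns in genomic (left-to-right) order."""
        return [
            Junction(self.chrom, self.strand, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def junction_chain(self) -> tuple[Junction, ...]:
        return tuple(self.junctions)

    def cds_exons(self) -> list[Exon]:
        """Exon blocks intersected with the genomic CDS span."""
        if self.cds is None:
            return []
        lo, hi = self.cds
        out = []
        for e in self.exons:
            s, t = max(e.start, lo), min(e.end, hi)
            if s < t:
                out.append(Exon(self.chrom, s, t))
        return out

    def spliced_sequence(self, genome) -> str:
        """Spliced, strand-corrected (5'->3') transcript sequence."""
        seq = "".join(str(genome[self.chrom][e.start:e.end]) for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq.upper()


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1].upper()


@dataclass
class PeakSet:
    """Peak intervals from a BED file (CAGE, Quant-seq/polyA-site, ...)."""

    intervals: list[tuple]  # (chrom, start, end, strand-or-None)
    kind: str = "generic"   # five_prime | three_prime | generic

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[tuple]] = {}
        for iv in self.intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            strand = iv[3] if len(iv) > 3 else None
            self._by_chrom.setdefault(chrom, []).append((start, end, strand))
        for lst in self._by_chrom.values():
            lst.sort()

    def peaks_on(self, chrom: str, strand: Optional[str] = None) -> list[tuple]:
        """Peaks on a chromosome matching ``strand`` (strandless peaks match all)."""
        out = []
        for start, end, pstrand in self._by_chrom.get(chrom, []):
            if strand is None or pstrand is None or pstrand == strand:
                out.append((start, end))
        return out

    @staticmethod
    def midpoint(start: int, end: int) -> int:
        return (start + end) // 2


class CoverageTrack:
    """Per-chromosome step-function depth from a bedGraph; gaps read as 0."""

    def __init__(self, replicate_id: str,
                 segments: Iterable[tuple[str, int, int, float]]):
        self.replicate_id = replicate_id
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._vals: dict[str, list[float]] = {}
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if value < 0:
                raise ValueError("coverage must be non-negative")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, segs in per_chrom.items():
            segs.sort()
            self._starts[chrom] = [s for s, _, _ in segs]
            self._ends[chrom] = [e for _, e, _ in segs]
            self._vals[chrom] = [v for _, _, v in segs]

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean depth over [start, end); uncovered bases count as depth 0."""
        start = max(start, 0)
        if end <= start or chrom not in self._starts:
            return 0.0
        starts, ends, vals = self._starts[chrom], self._ends[chrom], self._vals[chrom]
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            i = 0
        total = 0.0
        for j in range(i, len(starts)):
            if starts[j] >= end:
                break
            lo, hi = max(starts[j], start), min(ends[j], end)
            if lo < hi:
                total += vals[j] * (hi - lo)
        return total / (end - start)


class SJSupport:
    """Short-read unique-read counts per splice junction and replicate.

    Junctions with STAR strand code 0 are stored strand-agnostically and
    match a query on either strand.
    """

    def __init__(self, n_replicates: int = 0):
        self.n_replicates = n_replicates
        self._counts: dict[tuple, list[int]] = {}

    @staticmethod
    def _key(chrom: str, strand: str, start: int, end: int) -> tuple:
        return (chrom, strand, start, end)

    def add(self, chrom: str, strand: str, intron_start: int, intron_end: int,
            replicate: int, count: int) -> None:
        if count < 0:
            raise ValueError("junction counts must be non-negative")
        key = self._key(chrom, strand, intron_start, intron_end)
        per_rep = self._counts.setdefault(key, [0] * self.n_replicates)
        if replicate >= len(per_rep):
            per_rep.extend([0] * (replicate + 1 - len(per_rep)))
            self.n_replicates = max(self.n_replicates, replicate + 1)
        per_rep[replicate] += count

    def counts(self, junction: Junction) -> list[int]:
        """Per-replicate counts; strand-agnostic entries match either strand."""
        n = max(self.n_replicates, 1)
        base = [0] * n
        for strand in (junction.strand, "."):
            per_rep = self._counts.get(
                self._key(junction.chrom, strand, junction.intron_start,
                          junction.intron_end))
            if per_rep is not None:
                for i, c in enumerate(per_rep):
                    if i < len(base):
                        base[i] += c
                    else:
                        base.append(c)
        return base

    def total(self, junction: Junction) -> int:
        return sum(self.counts(junction))


@dataclass
class ReferenceIndex:
    """Queryable catalogs built from a reference annotation.

    Transcripts whose spliced length is below ``min_ref_len`` are excluded
    from every catalog.
    """

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genes: dict[str, list[TranscriptModel]] = field(default_factory=dict)
    min_ref_len: int = 200

    def __post_init__(self) -> None:
        self._gene_trees: dict[tuple[str, str], IntervalTree] = {}
        self._gene_span: dict[str, tuple[str, str, int, int]] = {}
        self.junctions: set[Junction] = set()
        self.donors: set[tuple[str, str, int]] = set()
        self.acceptors: set[tuple[str, str, int]] = set()
        self.gene_junctions: dict[str, set[Junction]] = {}
        self.gene_donors: dict[str, set[int]] = {}
        self.gene_acceptors: dict[str, set[int]] = {}
        self.gene_tss: dict[str, set[int]] = {}
        self.gene_tts: dict[str, set[int]] = {}

    @classmethod
    def build(cls, transcripts: Sequence[TranscriptModel],
              min_ref_len: int = 200) -> "ReferenceIndex":
        idx = cls(min_ref_len=min_ref_len)
        for tx in sorted(transcripts, key=lambda t: t.transcript_id):
            if tx.spliced_length < min_ref_len:
                continue
            idx._add(tx)
        idx._finalize()
        return idx

    def _add(self, tx: TranscriptModel) -> None:
        self.transcripts[tx.transcript_id] = tx
        self.genes.setdefault(tx.gene_id, []).append(tx)
        for j in tx.junctions:
            self.junctions.add(j)
            self.donors.add((j.chrom, j.strand, j.donor_pos))
            self.acceptors.add((j.chrom, j.strand, j.acceptor_pos))
            self.gene_junctions.setdefault(tx.gene_id, set()).add(j)
            self.gene_donors.setdefault(tx.gene_id, set()).add(j.donor_pos)
            self.gene_acceptors.setdefault(tx.gene_id, set()).add(j.acceptor_pos)
        self.gene_tss.setdefault(tx.gene_id, set()).add(tx.tss)
        self.gene_tts.setdefault(tx.gene_id, set()).add(tx.tts)

    def _finalize(self) -> None:
        self._gene_trees.clear()
        self._gene_span.clear()
        for gene_id, txs in self.genes.items():
            chrom, strand = txs[0].chrom, txs[0].strand
            lo = min(t.start for t in txs)
            hi = max(t.end for t in txs)
            self._gene_span[gene_id] = (chrom, strand, lo, hi)
            tree = self._gene_trees.setdefault((chrom, strand), IntervalTree())
            tree[lo:hi] = gene_id

    def gene_span(self, gene_id: str) -> tuple[str, str, int, int]:
        return self._gene_span[gene_id]

    def overlapping_genes(self, chrom: str, start: int, end: int,
                          strand: Optional[str] = None) -> list[str]:
        """Gene ids whose locus overlaps [start, end); sorted for determinism."""
        hits: set[str] = set()
        strands = [strand] if strand else ["+", "-"]
        for s in strands:
            tree = self._gene_trees.get((chrom, s))
            if tree is not None:
                hits.update(iv.data for iv in tree.overlap(start, end))
        return sorted(hits)
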
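"""Transcript- and junction-level QC attributes from orthogonal evidence.

The attributes computed here are the ones consumed by the default filters
and the rescue stage: intrapriming (genomic A-content downstream of the
TTS), polyA motif presence near the 3' end, CAGE / polyA-site peak support
at the ends, the short-read TSS ratio, splice-motif canonicality,
short-read junction support, and a direct-repeat flag for reverse
transcriptase template switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .models import (CANONICAL_SPLICE_MOTIFS, CoverageTrack, Junction,
                     PeakSet, SJSupport, TranscriptModel, revcomp)

TSS_RATIO_WINDOW = 100          # bp on each side of the TSS
TSS_RATIO_PSEUDOCOUNT = 0.01
INTRAPRIMING_WINDOW = 20        # bp downstream of the TTS
INTRAPRIMING_THRESHOLD = 0.60   # adenine fraction, inclusive
POLYA_MOTIF_WINDOW = 50         # 3'-terminal bp searched for a motif
RTS_REPEAT_LEN = 8              # nt of exact direct repeat flagged as RTS


# ---------------------------------------------------------------------------
# TSS ratio
# ---------------------------------------------------------------------------

def compute_tss_ratio(tss: int, strand: str, chrom: str,
                      coverage: Sequence[CoverageTrack],
                      window: int = TSS_RATIO_WINDOW,
                      aggregate: str = "max") -> float:
    """Short-read coverage ratio across the TSS.

    Per replicate, ``ratio = (mean inside + 0.01) / (mean outside + 0.01)``
    where *inside* is the ``window`` bp downstream of the TSS (into the
    first exon) and *outside* the ``window`` bp upstream. A genuine TSS
    shows a coverage step (ratio > 1); a degraded 5' end shows uniform
    coverage (ratio ~ 1). Replicates are aggregated with ``max`` by
    default; ``mean``, ``median`` and ``q3`` are also available.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not coverage:
        raise ValueError("at least one coverage track is required")
    if strand == "+":
        inside = (tss, tss + window)
        outside = (max(tss - window, 0), tss)
    else:
        inside = (max(tss - window + 1, 0), tss + 1)
        outside = (tss + 1, tss + 1 + window)
    ratios = []
    for track in coverage:
        cov_in = track.mean_depth(chrom, *inside)
        cov_out = track.mean_depth(chrom, *outside)
        ratios.append((cov_in + TSS_RATIO_PSEUDOCOUNT) /
                      (cov_out + TSS_RATIO_PSEUDOCOUNT))
    return _aggregate(ratios, aggregate)


def _aggregate(values: list[float], how: str) -> float:
    s = pd.Series(values, dtype=float)
    if how == "max":
        return float(s.max())
    if how == "mean":
        return float(s.mean())
    if how == "median":
        return float(s.median())
    if how == "q3":
        return float(s.quantile(0.75))
    raise ValueError(f"unknown aggregation {how!r}")


# ---------------------------------------------------------------------------
# Intrapriming
# ---------------------------------------------------------------------------

def compute_intrapriming(tts: int, strand: str, chrom: str, genome,
                         window: int = INTRAPRIMING_WINDOW,
                         threshold: float = INTRAPRIMING_THRESHOLD
                         ) -> tuple[float, bool]:
    """Adenine fraction of the genomic window immediately downstream of the
    TTS (transcript strand), and the intrapriming flag (``>= threshold``).

    A-rich genomic stretches downstream of the called 3' end indicate
    internal oligo-dT priming rather than a genuine polyadenylation site.
    """
    chrom_len = len(genome[chrom])
    if strand == "+":
        lo, hi = tts + 1, min(tts + 1 + window, chrom_len)
        seq = str(genome[chrom][lo:hi]).upper() if lo < hi else ""
    else:
        lo, hi = max(tts - window, 0), tts
        seq = revcomp(str(genome[chrom][lo:hi])) if lo < hi else ""
    if not seq:
        return 0.0, False
    perc_a = seq.count("A") / len(seq)
    return perc_a, perc_a >= threshold


# ---------------------------------------------------------------------------
# PolyA motif
# ---------------------------------------------------------------------------

def find_polya_motif(transcript_seq: str, motifs: Sequence[str],
                     window: int = POLYA_MOTIF_WINDOW
                     ) -> Optional[tuple[str, int]]:
    """Search the 3'-terminal ``window`` bases for a polyadenylation motif.

    Returns ``(motif, distance)`` where distance counts the bases between
    the motif end and the transcript 3' end, for the occurrence whose end
    lies closest to the 3' end (ties broken by motif list order), or None
    when no motif ends within the window.
    """
    if not motifs:
        raise ValueError("motif list must be non-empty")
    seq = transcript_seq.upper()
    best: Optional[tuple[int, int, str]] = None  # (dist, motif_rank, motif)
    for rank, motif in enumerate(m.upper() for m in motifs):
        pos = seq.find(motif)
        while pos != -1:
            dist = len(seq) - (pos + len(motif))
            if dist <= window:
                key = (dist, rank, motif)
                if best is None or key < best:
                    best = key
            pos = seq.find(motif, pos + 1)
    if best is None:
        return None
    return best[2], best[0]


# ---------------------------------------------------------------------------
# Peak support (CAGE at the 5' end, Quant-seq / polyA sites at the 3' end)
# ---------------------------------------------------------------------------

def peak_support(end: int, strand: str, chrom: str, peaks: PeakSet,
                 side: str) -> tuple[bool, Optional[int]]:
    """Peak containment and signed distance to the nearest eligible peak.

    ``within`` is true when the transcript end falls inside a peak.
    Eligible peaks are those whose midpoint lies upstream of the TSS
    (``side="five_prime"``) or downstream of the TTS (``side="three_prime"``)
    in transcription direction; a containing peak is always eligible. The
    distance is signed: negative upstream, positive downstream.
    """
    if side not in ("five_prime", "three_prime"):
        raise ValueError("side must be five_prime or three_prime")
    within = False
    best: Optional[int] = None
    for start, stop in peaks.peaks_on(chrom, strand):
        contains = start <= end < stop
        within = within or contains
        mid = PeakSet.midpoint(start, stop)
        d = mid - end
        if strand == "-":
            d = -d
        eligible = contains or (d < 0 if side == "five_prime" else d > 0)
        if eligible and (best is None or abs(d) < abs(best)):
            best = d
    return within, best


# ---------------------------------------------------------------------------
# Junction-level attributes
# ---------------------------------------------------------------------------

@dataclass
class JunctionQC:
    junction: Junction
    splice_motif: str
    canonical: bool
    sample_cov: list[int] = field(default_factory=list)
    rts_flag: bool = False

    @property
    def total_cov(self) -> int:
        return sum(self.sample_cov)


def splice_motif(junction: Junction, genome) -> str:
    """Strand-corrected donor/acceptor dinucleotides, e.g. ``GT-AG``."""
    left = str(genome[junction.chrom]
               [junction.intron_start:junction.intron_start + 2]).upper()
    right = str(genome[junction.chrom]
                [junction.intron_end - 2:junction.intron_end]).upper()
    if junction.strand == "+":
        return f"{left}-{right}"
    return f"{revcomp(right)}-{revcomp(left)}"


def rts_flag(junction: Junction, genome,
             repeat_len: int = RTS_REPEAT_LEN) -> bool:
    """Direct-repeat test for reverse-transcriptase template switching.

    True when an exact repeat of ``repeat_len`` nt is shared between the
    donor boundary region (``repeat_len`` nt on each side of the exon/intron
    boundary) and the acceptor boundary region.
    """
    chrom_len = len(genome[junction.chrom])

    def window(center: int) -> str:
        lo = max(center - repeat_len, 0)
        hi = min(center + repeat_len, chrom_len)
        return str(genome[junction.chrom][lo:hi]).upper()

    donor = window(junction.intron_start)
    acceptor = window(junction.intron_end)
    if len(donor) < repeat_len or len(acceptor) < repeat_len:
        return False
    kmers = {donor[i:i + repeat_len]
             for i in range(len(donor) - repeat_len + 1)}
    return any(acceptor[i:i + repeat_len] in kmers
               for i in range(len(acceptor) - repeat_len + 1))


def junction_qc(junction: Junction, genome, sj: Optional[SJSupport] = None,
                repeat_len: int = RTS_REPEAT_LEN) -> JunctionQC:
    motif = splice_motif(junction, genome)
    cov = sj.counts(junction) if sj is not None else []
    return JunctionQC(junction=junction, splice_motif=motif,
                      canonical=motif in CANONICAL_SPLICE_MOTIFS,
                      sample_cov=cov,
                      rts_flag=rts_flag(junction, genome, repeat_len))


# ---------------------------------------------------------------------------
# Per-transcript roll-up
# ---------------------------------------------------------------------------

@dataclass
class TranscriptQC:
    perc_A_downstream_TTS: float = 0.0
    intrapriming: bool = False
    polyA_motif: Optional[str] = None
    polyA_dist: Optional[int] = None
    within_CAGE_peak: bool = False
    dist_to_CAGE_peak: Optional[int] = None
    within_polyA_site: bool = False
    dist_to_polyA_site: Optional[int] = None
    ratio_TSS: float = 1.0
    min_cov: Optional[int] = None
    all_canonical: bool = True
    rts_any: bool = False
    junctions: list[JunctionQC] = field(default_factory=list)


def transcript_qc(tx: TranscriptModel, genome=None,
                  cage_peaks: Optional[PeakSet] = None,
                  polya_peaks: Optional[PeakSet] = None,
                  polya_motifs: Optional[Sequence[str]] = None,
                  coverage: Optional[Sequence[CoverageTrack]] = None,
                  sj: Optional[SJSupport] = None,
                  tss_window: int = TSS_RATIO_WINDOW,
                  tss_aggregate: str = "max",
                  intrapriming_window: int = INTRAPRIMING_WINDOW,
                  intrapriming_threshold: float = INTRAPRIMING_THRESHOLD,
                  polya_window: int = POLYA_MOTIF_WINDOW,
                  rts_repeat_len: int = RTS_REPEAT_LEN) -> TranscriptQC:
    """Compute every QC attribute available from the supplied evidence."""
    qc = TranscriptQC()
    if genome is not None:
        qc.perc_A_downstream_TTS, qc.intrapriming = compute_intrapriming(
            tx.tts, tx.strand, tx.chrom, genome,
            window=intrapriming_window, threshold=intrapriming_threshold)
        if polya_motifs:
            hit = find_polya_motif(tx.spliced_sequence(genome), polya_motifs,
                                   window=polya_window)
            if hit is not None:
                qc.polyA_motif, qc.polyA_dist = hit
        for j in tx.junctions:
            qc.junctions.append(junction_qc(j, genome, sj, rts_repeat_len))
        if qc.junctions:
            qc.all_canonical = all(j.canonical for j in qc.junctions)
            qc.rts_any = any(j.rts_flag for j in qc.junctions)
            qc.min_cov = min(j.total_cov for j in qc.junctions)
    if cage_peaks is not None:
        qc.within_CAGE_peak, qc.dist_to_CAGE_peak = peak_support(
            tx.tss, tx.strand, tx.chrom, cage_peaks, "five_prime")
    if polya_peaks is not None:
        qc.within_polyA_site, qc.dist_to_polyA_site = peak_support(
            tx.tts, tx.strand, tx.chrom, polya_peaks, "three_prime")
    if coverage:
        qc.ratio_TSS = compute_tss_ratio(tx.tss, tx.strand, tx.chrom,
                                         coverage, window=tss_window,
                                         aggregate=tss_aggregate)
    return qc
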
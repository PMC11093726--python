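"""Deterministic synthetic data: genomes, annotations, queries with planted
truth, and the orthogonal evidence tracks.

The generator builds a small genome (uniform ACGT background) with
canonical GT-AG introns, a reference annotation, and a query transcript set
in which every transcript carries a known (category, subcategory) truth
label. Orthogonal evidence mirrors what a real experiment would supply:
CAGE-like peaks at true transcription start sites, polyA-site peaks at true
termination sites, polyA motifs planted 16-18 nt upstream of true 3' ends,
exon-plateau short-read coverage giving true TSSs a coverage step (ratio
well above 1.5) and degraded 5' ends a flat profile (ratio ~ 1), and
short-read junction counts supporting annotated junctions only.

Planted artifacts (intrapriming A-tracts, RT-switching direct repeats) are
explicit; light scrubbing passes remove *accidental* occurrences of the
same signals from the random background so attribute calls match planted
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as iio
from .models import CoverageTrack, Exon, PeakSet, SJSupport, TranscriptModel
from .qc import INTRAPRIMING_WINDOW, RTS_REPEAT_LEN, rts_flag

DEFAULT_MOTIFS = ["AATAAA", "ATTAAA"]

#: Perturbation label -> expected (category, subcategory).
PERTURBATIONS = {
    "reference_match": ("FSM", "reference_match"),
    "alternative_5end": ("FSM", "alternative_5end"),
    "alternative_3end": ("FSM", "alternative_3end"),
    "alternative_3end5end": ("FSM", "alternative_3end5end"),
    "fsm_mono": ("FSM", "mono-exon"),
    "ism_3prime_fragment": ("ISM", "3prime_fragment"),
    "ism_5prime_fragment": ("ISM", "5prime_fragment"),
    "ism_internal_fragment": ("ISM", "internal_fragment"),
    "ism_intron_retention": ("ISM", "intron_retention"),
    "ism_mono": ("ISM", "mono-exon"),
    "nic_known_junctions": ("NIC", "combination_of_known_junctions"),
    "nic_known_splicesites": ("NIC", "combination_of_known_splicesites"),
    "nic_mono": ("NIC", "mono-exon"),
    "nic_mono_ir": ("NIC", "mono-exon_by_intron_retention"),
    "nnc": ("NNC", "at_least_one_novel_splicesite"),
    "fusion": ("fusion", "multi-exon"),
    "antisense_multi": ("antisense", "multi-exon"),
    "antisense_mono": ("antisense", "mono-exon"),
    "genic_multi": ("genic_genomic", "multi-exon"),
    "genic_mono": ("genic_genomic", "mono-exon"),
    "intergenic_multi": ("intergenic", "multi-exon"),
    "intergenic_mono": ("intergenic", "mono-exon"),
    "intrapriming": ("FSM", "alternative_3end"),
    "rts": ("NIC", "combination_of_known_splicesites"),
}

#: The full admissible label space the classifier can emit.
EXPECTED_LABELS = sorted(set(PERTURBATIONS.values()))
assert len(EXPECTED_LABELS) == 22


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 6                      # single-isoform multi-exon genes
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_len: tuple[int, int] = (200, 400)
    intron_len: tuple[int, int] = (300, 600)
    intergenic_gap: int = 3000
    n_chroms: int = 1
    perturbations: dict[str, int] = field(
        default_factory=lambda: {label: 1 for label in PERTURBATIONS})
    coverage_step: float = 10.0           # exon plateau depth, replicate 1
    base_coverage: float = 1.0            # intron/intergenic depth
    n_replicates: int = 2
    sj_count: int = 15                    # per annotated junction, per replicate
    peak_halfwidth: int = 25
    jitter: int = 10                      # peak-placement jitter (bp)
    end_jitter: int = 0                   # end jitter for reference_match copies

    def __post_init__(self) -> None:
        unknown = set(self.perturbations) - set(PERTURBATIONS)
        if unknown:
            raise ValueError(f"unknown perturbation labels: {sorted(unknown)}")
        if self.exon_len[0] < 150:
            raise ValueError("exons must be >=150 bp for the planted windows")
        if self.intron_len[0] < 300:
            raise ValueError("introns must be >=300 bp for the genic plants")


def label_coverage_spec(seed: int = 0) -> FixtureSpec:
    """One exemplar per perturbation type, zero jitter."""
    return FixtureSpec(seed=seed, jitter=0, end_jitter=0)


@dataclass
class Bundle:
    spec: FixtureSpec
    genome: dict[str, str]
    reference: list[TranscriptModel]
    queries: list[TranscriptModel]
    truth: pd.DataFrame
    cage: PeakSet
    polya_peaks: PeakSet
    motifs: list[str]
    coverage: list[CoverageTrack]
    sj: SJSupport

    def write(self, outdir) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["genome"] = out / "genome.fa"
        iio.write_fasta(self.genome, paths["genome"])
        paths["reference"] = out / "reference.gtf"
        iio.write_gtf(self.reference, paths["reference"])
        paths["query"] = out / "query.gtf"
        iio.write_gtf(self.queries, paths["query"])
        paths["cage"] = out / "cage.bed"
        _write_bed(self.cage, paths["cage"])
        paths["polya_peaks"] = out / "polya_peaks.bed"
        _write_bed(self.polya_peaks, paths["polya_peaks"])
        paths["motifs"] = out / "polya_motifs.txt"
        paths["motifs"].write_text("\n".join(self.motifs) + "\n")
        for i, track in enumerate(self.coverage, start=1):
            p = out / f"coverage_rep{i}.bedGraph"
            _write_bedgraph(track, p)
            paths[f"coverage_rep{i}"] = p
        for i in range(self.sj.n_replicates):
            p = out / f"SJ_rep{i + 1}.tab"
            _write_sj_tab(self.sj, i, p)
            paths[f"sj_rep{i + 1}"] = p
        paths["truth"] = out / "truth_labels.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            chrom, start, end = iv[0], iv[1], iv[2]
            strand = iv[3] if len(iv) > 3 and iv[3] else "."
            fh.write(f"{chrom}\t{start}\t{end}\tpeak{i + 1}\t0\t{strand}\n")


def _write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track._starts):
            for s, e, v in zip(track._starts[chrom], track._ends[chrom],
                               track._vals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _write_sj_tab(sj: SJSupport, replicate: int, path) -> None:
    code = {"+": "1", "-": "2", ".": "0"}
    rows = []
    for (chrom, strand, start, end), counts in sorted(sj._counts.items()):
        c = counts[replicate] if replicate < len(counts) else 0
        rows.append(f"{chrom}\t{start + 1}\t{end}\t{code[strand]}\t1\t1\t{c}\t0\t30")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class _Chrom:
    def __init__(self, name: str, rng: np.random.Generator, length: int):
        self.name = name
        self.seq = rng.choice(_BASES, size=length).copy()
        self.protected = np.zeros(length, dtype=bool)

    def plant(self, pos: int, s: str, protect: bool = True) -> None:
        arr = np.frombuffer(s.encode(), dtype="S1")
        self.seq[pos:pos + len(arr)] = arr
        if protect:
            self.protected[pos:pos + len(arr)] = True

    def protect(self, start: int, end: int) -> None:
        self.protected[start:end] = True

    def text(self) -> str:
        return self.seq.tobytes().decode()


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]


def _rint(rng, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


class _Builder:
    """Stateful fixture construction; one pass, fully seeded."""

    def __init__(self, spec: FixtureSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.chroms: dict[str, _Chrom] = {}
        self.genes: list[_Gene] = []
        self.mono_gene: Optional[_Gene] = None
        self.ckj_gene: Optional[_Gene] = None
        self.reference: list[TranscriptModel] = []
        self.queries: list[TranscriptModel] = []
        self.truth_rows: list[dict] = []
        self.intergenic_zone: dict[str, tuple[int, int]] = {}
        self.planted_motif_dist: dict[str, int] = {}
        self._counter = 0
        self._gene_cursor = 0

    # -- layout ------------------------------------------------------------
    def build(self) -> Bundle:
        spec = self.spec
        self._layout_genome()
        self._plant_reference_signal()
        self._make_queries()
        self._scrub_background()
        genome = {name: c.text() for name, c in self.chroms.items()}
        cage, polya = self._peaks()
        coverage = self._coverage()
        sj = self._sj_support()
        truth = pd.DataFrame(self.truth_rows, columns=[
            "isoform", "category", "subcategory", "source_gene",
            "source_transcript", "intrapriming_planted", "rts_planted"])
        return Bundle(spec=spec, genome=genome, reference=self.reference,
                      queries=self.queries, truth=truth, cage=cage,
                      polya_peaks=polya, motifs=list(DEFAULT_MOTIFS),
                      coverage=coverage, sj=sj)

    def _layout_genome(self) -> None:
        spec, rng = self.spec, self.rng
        n_chroms = max(1, min(spec.n_chroms, 3))
        per_chrom = [spec.n_genes // n_chroms +
                     (1 if i < spec.n_genes % n_chroms else 0)
                     for i in range(n_chroms)]
        gene_no = 0
        for ci in range(n_chroms):
            name = f"chr{ci + 1}"
            plan: list[tuple[str, str]] = []
            for _ in range(per_chrom[ci]):
                gene_no += 1
                # first two genes share '+': guarantees a fusion-eligible pair
                strand = "+" if gene_no <= 2 else ("+" if rng.random() < 0.5
                                                   else "-")
                plan.append((f"G{gene_no}", strand))
            if ci == 0:
                plan.append(("GMONO", "+"))
                plan.append(("GCKJ", "+"))
            # provisional layout on a generous scratch coordinate system
            layouts = []
            cursor = spec.intergenic_gap
            for gid, strand in plan:
                exons, end = self._gene_geometry(gid, cursor)
                layouts.append((gid, strand, exons))
                cursor = end + spec.intergenic_gap
            zone = (cursor, cursor + 2000)
            length = zone[1] + spec.intergenic_gap
            chrom = _Chrom(name, rng, length)
            self.chroms[name] = chrom
            self.intergenic_zone[name] = zone
            for gid, strand, exons in layouts:
                gene = _Gene(gid, name, strand, exons)
                self._register_gene(gene, chrom)

    def _gene_geometry(self, gid: str, start: int) -> tuple[list, int]:
        spec, rng = self.spec, self.rng
        if gid == "GMONO":
            return [(start, start + 400)], start + 400
        n_ex = 5 if gid == "GCKJ" else _rint(rng, spec.exons_per_gene)
        exons = []
        pos = start
        for i in range(n_ex):
            elen = _rint(rng, spec.exon_len)
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_ex - 1:
                pos += _rint(rng, spec.intron_len)
        return exons, pos

    def _register_gene(self, gene: _Gene, chrom: _Chrom) -> None:
        for s, e in gene.exons:
            chrom.protect(s, e)
        for s, e in gene.introns:
            if gene.strand == "+":
                chrom.plant(s, "GT")
                chrom.plant(e - 2, "AG")
            else:
                chrom.plant(s, "CT")
                chrom.plant(e - 2, "AC")
        mk = lambda tid, idxs: TranscriptModel(
            tid, gene.gene_id, gene.chrom, gene.strand,
            [Exon(gene.chrom, *gene.exons[i]) for i in idxs])
        if gene.gene_id == "GMONO":
            gene.transcripts = [mk("GMONO.T1", [0])]
            self.mono_gene = gene
        elif gene.gene_id == "GCKJ":
            # two isoforms with interleaved junction sets; the full exon
            # chain is then a novel combination of known junctions
            gene.transcripts = [mk("GCKJ.T1", [0, 1, 2, 4]),
                                mk("GCKJ.T2", [0, 2, 3, 4])]
            self.ckj_gene = gene
        else:
            gene.transcripts = [mk(f"{gene.gene_id}.T1",
                                   list(range(len(gene.exons))))]
            self.genes.append(gene)
        self.reference.extend(gene.transcripts)

    # -- planted reference-level signal -------------------------------------
    def _plant_reference_signal(self) -> None:
        planted_ends: dict[tuple, int] = {}
        for tx in self.reference:
            key = (tx.chrom, tx.strand, tx.tts)
            if key in planted_ends:  # isoforms sharing a 3' end share a motif
                self.planted_motif_dist[tx.transcript_id] = planted_ends[key]
                continue
            planted_ends[key] = self._plant_polya_motif(tx)

    def _plant_polya_motif(self, tx: TranscriptModel) -> int:
        d = int(self.rng.integers(16, 19))
        motif = DEFAULT_MOTIFS[0]
        chrom = self.chroms[tx.chrom]
        if tx.strand == "+":
            le = tx.exons[-1].end
            chrom.plant(le - d - len(motif), motif)
        else:
            from .models import revcomp
            fs = tx.exons[0].start
            chrom.plant(fs + d, revcomp(motif))
        self.planted_motif_dist[tx.transcript_id] = d
        return d

    # -- query construction --------------------------------------------------
    def _make_queries(self) -> None:
        for label in sorted(self.spec.perturbations):
            for _ in range(self.spec.perturbations[label]):
                self._make_query(label)

    def _next_gene(self) -> _Gene:
        gene = self.genes[self._gene_cursor % len(self.genes)]
        self._gene_cursor += 1
        return gene

    def _emit(self, label: str, exons: list[Exon], gene: _Gene | None,
              source_tx: Optional[str], strand: Optional[str] = None,
              chrom: Optional[str] = None, intrapriming: bool = False,
              rts: bool = False) -> TranscriptModel:
        self._counter += 1
        tid = f"tx_{label}_{self._counter}"
        cat, sub = PERTURBATIONS[label]
        tx = TranscriptModel(
            tid, f"query_{tid}",
            chrom or (gene.chrom if gene else "chr1"),
            strand or (gene.strand if gene else "+"),
            exons)
        self.queries.append(tx)
        self.truth_rows.append({
            "isoform": tid, "category": cat, "subcategory": sub,
            "source_gene": gene.gene_id if gene else "NA",
            "source_transcript": source_tx or "NA",
            "intrapriming_planted": intrapriming, "rts_planted": rts,
        })
        for e in tx.exons:
            self.chroms[tx.chrom].protect(e.start, e.end)
        return tx

    def _make_query(self, label: str) -> None:
        rng, spec = self.rng, self.spec
        if label in ("reference_match", "alternative_5end",
                     "alternative_3end", "alternative_3end5end",
                     "intrapriming"):
            gene = self._next_gene()
            ref = gene.transcripts[0]
            exons = [Exon(e.chrom, e.start, e.end) for e in ref.exons]
            shift5 = shift3 = 0
            if label in ("alternative_5end", "alternative_3end5end"):
                shift5 = int(rng.integers(51, min(501, spec.intergenic_gap - 600)))
            if label in ("alternative_3end", "alternative_3end5end"):
                shift3 = int(rng.integers(51, min(501, spec.intergenic_gap - 600)))
            if label == "intrapriming":
                shift3 = 60
            if label == "reference_match" and spec.end_jitter:
                j = min(spec.end_jitter, 50)
                shift5 = -int(rng.integers(0, j + 1))   # inward, stays FSM rm
                shift3 = -int(rng.integers(0, j + 1))
            exons = _shift_ends(exons, ref.strand, shift5, shift3)
            tx = self._emit(label, exons, gene, ref.transcript_id,
                            intrapriming=(label == "intrapriming"))
            if label == "intrapriming":
                self._plant_a_tract(tx)
            return
        if label.startswith("ism_") and label != "ism_mono":
            self._make_ism(label)
            return
        dispatch = {
            "fsm_mono": self._make_fsm_mono,
            "ism_mono": self._make_ism_mono,
            "nic_known_junctions": self._make_ckj,
            "nic_known_splicesites": self._make_cks,
            "nic_mono": self._make_nic_mono,
            "nic_mono_ir": self._make_nic_mono_ir,
            "nnc": self._make_nnc,
            "fusion": self._make_fusion,
            "antisense_multi": self._make_antisense_multi,
            "antisense_mono": self._make_antisense_mono,
            "genic_multi": self._make_genic_multi,
            "genic_mono": self._make_genic_mono,
            "intergenic_multi": self._make_intergenic_multi,
            "intergenic_mono": self._make_intergenic_mono,
            "rts": self._make_rts,
        }
        dispatch[label]()

    def _plant_a_tract(self, tx: TranscriptModel) -> None:
        chrom = self.chroms[tx.chrom]
        w = INTRAPRIMING_WINDOW
        if tx.strand == "+":
            chrom.plant(tx.tts + 1, "A" * w)
        else:
            chrom.plant(tx.tts - w, "T" * w)

    def _make_ism(self, label: str) -> None:
        gene = self._next_gene()
        ref = gene.transcripts[0]
        exons = [Exon(e.chrom, e.start, e.end) for e in ref.exons]
        plus = ref.strand == "+"
        trim = 110  # 5'-degradation depth into the new first exon
        if label == "ism_3prime_fragment":    # lost junctions at the 5' side
            exons = exons[1:] if plus else exons[:-1]
            exons = _trim_five_prime(exons, ref.strand, trim)
        elif label == "ism_5prime_fragment":  # lost junctions at the 3' side
            exons = exons[:-1] if plus else exons[1:]
        elif label == "ism_internal_fragment":
            exons = exons[1:-1]
            exons = _trim_five_prime(exons, ref.strand, trim)
        elif label == "ism_intron_retention":
            # drop the transcription-3'-most junction by retaining its intron
            if plus:
                merged = Exon(ref.chrom, exons[-2].start, exons[-1].end)
                exons = exons[:-2] + [merged]
                exons = [Exon(ref.chrom, e.start, e.end - 150)
                         if e is exons[-1] else e for e in exons]
            else:
                merged = Exon(ref.chrom, exons[0].start, exons[1].end)
                exons = [merged] + exons[2:]
                exons = [Exon(ref.chrom, e.start + 150, e.end)
                         if e is exons[0] else e for e in exons]
        self._emit(label, exons, gene, ref.transcript_id)

    def _make_fsm_mono(self) -> None:
        gene = self.mono_gene
        ref = gene.transcripts[0]
        s, e = gene.exons[0]
        self._emit("fsm_mono", [Exon(gene.chrom, s, e)], gene,
                   ref.transcript_id)

    def _make_ism_mono(self) -> None:
        gene = self._next_gene()
        ref = gene.transcripts[0]
        s, e = gene.exons[1]
        self._emit("ism_mono", [Exon(gene.chrom, s + 20, e - 20)], gene,
                   ref.transcript_id)

    def _make_ckj(self) -> None:
        gene = self.ckj_gene
        exons = [Exon(gene.chrom, s, e) for s, e in gene.exons]
        self._emit("nic_known_junctions", exons, gene, "GCKJ.T1")

    def _make_cks(self, rts: bool = False) -> None:
        gene = self._next_gene()
        ref = gene.transcripts[0]
        k = len(ref.exons) // 2  # skip an internal exon
        exons = ref.exons[:k] + ref.exons[k + 1:]
        label = "rts" if rts else "nic_known_splicesites"
        tx = self._emit(label, [Exon(e.chrom, e.start, e.end) for e in exons],
                        gene, ref.transcript_id, rts=rts)
        if rts:
            j = tx.junctions[k - 1]  # the exon-skipping (novel) junction
            # repeat starts GT and ends AG, so the splice motif survives;
            # both copies lie fully inside the boundary windows
            repeat = ("GTAGGTAG" * 4)[:RTS_REPEAT_LEN]
            chrom = self.chroms[tx.chrom]
            chrom.plant(j.intron_start, repeat)
            chrom.plant(j.intron_end - RTS_REPEAT_LEN, repeat)

    def _make_rts(self) -> None:
        self._make_cks(rts=True)

    def _make_nic_mono(self) -> None:
        gene = self._next_gene()
        s, e = gene.exons[0]
        # overlaps exon 1 and runs into intron 1, short of the next exon
        self._emit("nic_mono", [Exon(gene.chrom, s + 50, e + 100)], gene, None)

    def _make_nic_mono_ir(self) -> None:
        gene = self._next_gene()
        (s1, e1), (s2, e2) = gene.exons[0], gene.exons[1]
        self._emit("nic_mono_ir", [Exon(gene.chrom, s1 + 20, e2 - 20)],
                   gene, None)

    def _make_nnc(self) -> None:
        gene = self._next_gene()
        ref = gene.transcripts[0]
        exons = [Exon(e.chrom, e.start, e.end) for e in ref.exons]
        # extend an internal exon 9 bp into its intron: novel donor/acceptor
        k = len(exons) // 2 - 1
        if ref.strand == "+":
            exons[k] = Exon(ref.chrom, exons[k].start, exons[k].end + 9)
            self.chroms[ref.chrom].plant(exons[k].end, "CC")  # noncanonical
        else:
            exons[k + 1] = Exon(ref.chrom, exons[k + 1].start - 9,
                                exons[k + 1].end)
            self.chroms[ref.chrom].plant(exons[k + 1].start - 2, "CC")
        self._emit("nnc", exons, gene, ref.transcript_id)

    def _make_fusion(self) -> None:
        pairs = [(a, b) for a, b in zip(self.genes, self.genes[1:])
                 if a.chrom == b.chrom and a.strand == b.strand]
        if not pairs:
            raise ValueError("no adjacent same-strand gene pair for fusion")
        a, b = pairs[0]
        exons = ([Exon(a.chrom, s, e) for s, e in a.exons[-2:]] +
                 [Exon(b.chrom, s, e) for s, e in b.exons[:2]])
        self._emit("fusion", exons, a, None)

    def _make_antisense_multi(self) -> None:
        gene = self._next_gene()
        s = gene.exons[0][0]
        flipped = "-" if gene.strand == "+" else "+"
        exons = [Exon(gene.chrom, s + 10, s + 130),
                 Exon(gene.chrom, s + 430, s + 550)]
        self._emit("antisense_multi", exons, gene, None, strand=flipped)

    def _make_antisense_mono(self) -> None:
        gene = self._next_gene()
        s = gene.exons[1][0]
        flipped = "-" if gene.strand == "+" else "+"
        self._emit("antisense_mono", [Exon(gene.chrom, s + 5, s + 160)],
                   gene, None, strand=flipped)

    def _make_genic_multi(self) -> None:
        gene = self._next_gene()
        s, e = gene.introns[0]
        exons = [Exon(gene.chrom, s + 20, s + 80),
                 Exon(gene.chrom, s + 180, s + 240)]
        self._emit("genic_multi", exons, gene, None)

    def _make_genic_mono(self) -> None:
        gene = self._next_gene()
        s, e = gene.introns[-1]
        self._emit("genic_mono", [Exon(gene.chrom, s + 30, s + 180)],
                   gene, None)

    def _make_intergenic_multi(self) -> None:
        chrom = "chr1"
        zs, ze = self.intergenic_zone[chrom]
        exons = [Exon(chrom, zs + 50, zs + 250),
                 Exon(chrom, zs + 550, zs + 750)]
        self._emit("intergenic_multi", exons, None, None, chrom=chrom)

    def _make_intergenic_mono(self) -> None:
        chrom = "chr1"
        zs, ze = self.intergenic_zone[chrom]
        self._emit("intergenic_mono", [Exon(chrom, zs + 1000, zs + 1300)],
                   None, None, chrom=chrom)

    # -- background scrubbing -------------------------------------------------
    def _scrub_background(self) -> None:
        genome = {name: c for name, c in self.chroms.items()}
        view = {name: _SeqView(c) for name, c in genome.items()}
        planted_ip = {r["isoform"] for r in self.truth_rows
                      if r["intrapriming_planted"]}
        planted_rts = {r["isoform"] for r in self.truth_rows
                       if r["rts_planted"]}
        for tx in self.reference + self.queries:
            if tx.transcript_id not in planted_ip:
                self._scrub_a_tract(tx, view[tx.chrom])
        for tx in self.reference + self.queries:
            skip = tx.transcript_id in planted_rts
            for j in tx.junctions:
                if skip:
                    continue
                self._scrub_rts(j, view[tx.chrom])
        for tx in self.reference:
            self._scrub_motif(tx, view[tx.chrom])

    def _scrub_a_tract(self, tx: TranscriptModel, view: "_SeqView") -> None:
        chrom = self.chroms[tx.chrom]
        w = INTRAPRIMING_WINDOW
        if tx.strand == "+":
            lo, hi = tx.tts + 1, min(tx.tts + 1 + w, len(chrom.seq))
            target = b"A"
        else:
            lo, hi = max(tx.tts - w, 0), tx.tts
            target = b"T"
        window = chrom.seq[lo:hi]
        count = int((window == target).sum())
        i = lo
        while count / max(len(window), 1) >= 0.55 and i < hi:
            if chrom.seq[i] == target and not chrom.protected[i]:
                chrom.seq[i] = b"C"
                count -= 1
            i += 1

    def _scrub_rts(self, junction, view: "_SeqView") -> None:
        chrom = self.chroms[junction.chrom]
        for _ in range(10):
            if not rts_flag(junction, view.genome_proxy()):
                return
            for off in range(2, RTS_REPEAT_LEN):
                pos = junction.intron_start + off
                if not chrom.protected[pos]:
                    chrom.seq[pos] = (b"C" if chrom.seq[pos] != b"C" else b"G")
                    view.refresh()
                    break

    def _scrub_motif(self, tx: TranscriptModel, view: "_SeqView") -> None:
        from .qc import find_polya_motif
        planted_d = self.planted_motif_dist[tx.transcript_id]
        chrom = self.chroms[tx.chrom]
        for _ in range(10):
            seq = tx.spliced_sequence(view.genome_proxy())
            hit = find_polya_motif(seq, DEFAULT_MOTIFS)
            if hit is not None and hit == (DEFAULT_MOTIFS[0], planted_d):
                return
            if hit is None:
                return
            _motif, d = hit
            # mutate the last base of the offending occurrence
            i_from_end = d  # bases after the motif end
            if tx.strand == "+":
                pos = tx.exons[-1].end - 1 - i_from_end
            else:
                pos = tx.exons[0].start + i_from_end
            base = chrom.seq[pos]
            chrom.seq[pos] = b"C" if base != b"C" else b"G"
            view.refresh()

    # -- evidence tracks ------------------------------------------------------
    def _peaks(self) -> tuple[PeakSet, PeakSet]:
        spec, rng = self.spec, self.rng
        hw = spec.peak_halfwidth
        cage, polya = [], []
        seen5, seen3 = set(), set()
        for tx in self.reference:
            jit5 = int(rng.integers(-spec.jitter, spec.jitter + 1)) \
                if spec.jitter else 0
            jit3 = int(rng.integers(-spec.jitter, spec.jitter + 1)) \
                if spec.jitter else 0
            k5 = (tx.chrom, tx.tss)
            if k5 not in seen5:
                seen5.add(k5)
                cage.append((tx.chrom, max(0, tx.tss - hw + jit5),
                             tx.tss + hw + 1 + jit5, tx.strand))
            k3 = (tx.chrom, tx.tts)
            if k3 not in seen3:
                seen3.add(k3)
                polya.append((tx.chrom, max(0, tx.tts - hw + jit3),
                              tx.tts + hw + 1 + jit3, tx.strand))
        return (PeakSet(cage, kind="five_prime"),
                PeakSet(polya, kind="three_prime"))

    def _coverage(self) -> list[CoverageTrack]:
        spec = self.spec
        tracks = []
        for rep in range(spec.n_replicates):
            depth = spec.coverage_step * (1.0 - 0.2 * rep)
            segments = []
            for name, chrom in self.chroms.items():
                exonic = []
                for tx in self.reference:
                    if tx.chrom == name:
                        exonic.extend((e.start, e.end) for e in tx.exons)
                merged = _merge_intervals(exonic)
                cursor = 0
                for s, e in merged:
                    if cursor < s:
                        segments.append((name, cursor, s, spec.base_coverage))
                    segments.append((name, s, e, depth))
                    cursor = e
                if cursor < len(chrom.seq):
                    segments.append((name, cursor, len(chrom.seq),
                                     spec.base_coverage))
            tracks.append(CoverageTrack(f"rep{rep + 1}", segments))
        return tracks

    def _sj_support(self) -> SJSupport:
        spec = self.spec
        sj = SJSupport(n_replicates=spec.n_replicates)
        seen = set()
        for tx in self.reference:
            for j in tx.junctions:
                if j in seen:
                    continue
                seen.add(j)
                for rep in range(spec.n_replicates):
                    sj.add(j.chrom, j.strand, j.intron_start, j.intron_end,
                           rep, spec.sj_count)
        return sj


class _SeqView:
    """Adapts a mutable chromosome to the genome mapping protocol,
    caching the decoded sequence until invalidated."""

    def __init__(self, chrom: _Chrom):
        self._chrom = chrom
        self._cache: Optional[dict[str, str]] = None

    def refresh(self) -> None:
        self._cache = None

    def genome_proxy(self) -> dict[str, str]:
        if self._cache is None:
            self._cache = {self._chrom.name: self._chrom.seq.tobytes().decode()}
        return self._cache


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _shift_ends(exons: list[Exon], strand: str, shift5: int,
                shift3: int) -> list[Exon]:
    """Positive shifts move an end outward (longer transcript)."""
    exons = list(exons)
    chrom = exons[0].chrom
    if strand == "+":
        first, last = exons[0], exons[-1]
        exons[0] = Exon(chrom, first.start - shift5, first.end)
        exons[-1] = Exon(chrom, exons[-1].start, last.end + shift3)
    else:
        first, last = exons[0], exons[-1]
        exons[-1] = Exon(chrom, last.start, last.end + shift5)
        exons[0] = Exon(chrom, first.start - shift3, first.end)
    return exons


def _trim_five_prime(exons: list[Exon], strand: str, trim: int) -> list[Exon]:
    exons = list(exons)
    chrom = exons[0].chrom
    if strand == "+":
        e = exons[0]
        exons[0] = Exon(chrom, e.start + trim, e.end)
    else:
        e = exons[-1]
        exons[-1] = Exon(chrom, e.start, e.end - trim)
    return exons


def generate(spec: Optional[FixtureSpec] = None, outdir=None) -> Bundle:
    """Build a fixture bundle; optionally write it to ``outdir``."""
    bundle = _Builder(spec or FixtureSpec()).build()
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def load_bundle(indir) -> dict:
    """Read a written bundle back through the standard-format readers."""
    from pyfaidx import Fasta

    d = Path(indir)
    coverage = sorted(d.glob("coverage_rep*.bedGraph"))
    sj_paths = sorted(d.glob("SJ_rep*.tab"))
    return {
        "genome": Fasta(str(d / "genome.fa")),
        "reference": iio.load_gtf(d / "reference.gtf"),
        "queries": iio.load_gtf(d / "query.gtf"),
        "cage": iio.load_bed(d / "cage.bed", kind="five_prime"),
        "polya_peaks": iio.load_bed(d / "polya_peaks.bed", kind="three_prime"),
        "motifs": iio.load_motifs(d / "polya_motifs.txt"),
        "coverage": [iio.load_bedgraph(p) for p in coverage],
        "sj": iio.load_sj_tabs(sj_paths),
        "truth": pd.read_csv(d / "truth_labels.tsv", sep="\t"),
    }
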
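"""Transfer of functional feature annotations between transcript models.

Feature *donors* are transcripts already annotated with functional features
(UTR motifs, coding-region features, protein domains, gene-level terms);
*acceptors* are transcript models to annotate. Features live on genomic
coordinates and transfer by coordinate matching, with per-level rules:

* ``UTR``: every feature block must lie inside the acceptor's exons and
  outside its CDS region.
* ``CDS_transcript``: blocks must lie inside the exons and inside the CDS;
  a feature spanning two exons transfers only when the junction between
  those blocks is shared by donor and acceptor.
* ``protein``: when donor and acceptor have identical CDS exon sets, all
  protein features transfer; otherwise at least one CDS exon must partially
  overlap (>=1 bp) and only features inside the shared CDS region transfer.
* ``gene``: always transferred across matching gene ids.

Duplicated annotations (same level, label and genomic span, regardless of
donor) are emitted once.

The GFF3 dialect used here is minimal and round-trip stable: feature rows
use the feature level as the GFF3 type and carry ``Parent`` (transcript),
``label`` and ``level`` attributes; multi-block features repeat the ID.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .models import Exon, TranscriptModel

LEVELS = ("UTR", "CDS_transcript", "protein", "gene")


@dataclass(frozen=True)
class FunctionalFeature:
    donor_transcript_id: str
    level: str
    blocks: tuple[tuple[str, int, int], ...]  # (chrom, start, end)
    label: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown feature level {self.level!r}")

    def identity(self) -> tuple:
        return (self.level, self.label, self.blocks)

    @property
    def span(self) -> tuple[int, int]:
        return (min(b[1] for b in self.blocks),
                max(b[2] for b in self.blocks))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _inside(block: tuple[str, int, int], exons: Sequence[Exon]) -> bool:
    chrom, s, e = block
    return any(x.chrom == chrom and x.start <= s and e <= x.end for x in exons)


def _overlaps(block: tuple[str, int, int], exons: Sequence[Exon]) -> bool:
    chrom, s, e = block
    return any(x.chrom == chrom and s < x.end and x.start < e for x in exons)


def _block_exon_index(block: tuple[str, int, int],
                      exons: Sequence[Exon]) -> Optional[int]:
    for i, x in enumerate(exons):
        if x.chrom == block[0] and x.start <= block[1] and block[2] <= x.end:
            return i
    return None


def _cds_exon_set(tx: TranscriptModel) -> set[tuple[int, int]]:
    return {(e.start, e.end) for e in tx.cds_exons()}


# ---------------------------------------------------------------------------
# Transfer rules
# ---------------------------------------------------------------------------

def _transferable(feature: FunctionalFeature, donor: TranscriptModel,
                  acceptor: TranscriptModel) -> bool:
    if feature.level == "gene":
        return donor.gene_id == acceptor.gene_id
    cds_exons = acceptor.cds_exons()
    if feature.level == "UTR":
        return (all(_inside(b, acceptor.exons) for b in feature.blocks)
                and not any(_overlaps(b, cds_exons) for b in feature.blocks))
    if feature.level == "CDS_transcript":
        if acceptor.cds is None:
            return False
        if not all(_inside(b, acceptor.exons) and _inside(b, cds_exons)
                   for b in feature.blocks):
            return False
        # multi-exon features: the bridged junctions must be shared
        idxs = [_block_exon_index(b, acceptor.exons) for b in feature.blocks]
        if len(set(idxs)) > 1:
            donor_junctions = set(donor.junction_chain())
            acceptor_junctions = set(acceptor.junction_chain())
            blocks = sorted(feature.blocks, key=lambda b: b[1])
            for a, b in zip(blocks, blocks[1:]):
                gap = (a[2], b[1])
                shared = any(
                    j.intron_start == gap[0] and j.intron_end == gap[1]
                    for j in donor_junctions & acceptor_junctions)
                if not shared:
                    return False
        return True
    # protein level
    if donor.cds is None or acceptor.cds is None:
        return False
    donor_cds = _cds_exon_set(donor)
    acceptor_cds = _cds_exon_set(acceptor)
    if donor_cds == acceptor_cds:
        return True
    shared_regions = []
    for ds, de in donor_cds:
        for as_, ae in acceptor_cds:
            lo, hi = max(ds, as_), min(de, ae)
            if lo < hi:
                shared_regions.append((lo, hi))
    if not shared_regions:
        return False
    return all(any(lo <= b[1] and b[2] <= hi for lo, hi in shared_regions)
               for b in feature.blocks)


def transfer_features(acceptors: Sequence[TranscriptModel],
                      donors: Sequence[TranscriptModel],
                      features: Sequence[FunctionalFeature],
                      acceptor_genes: Optional[dict[str, str]] = None,
                      novel_mode: bool = True
                      ) -> dict[str, list[FunctionalFeature]]:
    """Annotate acceptors with donor features.

    ``acceptor_genes`` maps acceptor transcript ids to their associated
    gene (from classification); when absent, the acceptor's own gene_id is
    used. In ``novel_mode`` every same-gene donor contributes; otherwise a
    donor contributes only to the acceptor with the same transcript id.
    """
    donor_by_id = {d.transcript_id: d for d in donors}
    donors_by_gene: dict[str, list[TranscriptModel]] = {}
    for d in donors:
        donors_by_gene.setdefault(d.gene_id, []).append(d)
    feats_by_donor: dict[str, list[FunctionalFeature]] = {}
    for f in features:
        feats_by_donor.setdefault(f.donor_transcript_id, []).append(f)

    out: dict[str, list[FunctionalFeature]] = {}
    for acc in acceptors:
        gene = (acceptor_genes or {}).get(acc.transcript_id, acc.gene_id)
        if novel_mode:
            pool = []
            for g in str(gene).split("_"):
                pool.extend(donors_by_gene.get(g, []))
        else:
            d = donor_by_id.get(acc.transcript_id)
            pool = [d] if d is not None else []
        seen: set[tuple] = set()
        kept: list[FunctionalFeature] = []
        for donor in pool:
            for f in feats_by_donor.get(donor.transcript_id, []):
                if f.identity() in seen:
                    continue
                if _transferable(f, donor, acc):
                    seen.add(f.identity())
                    kept.append(f)
        out[acc.transcript_id] = kept
    return out


# ---------------------------------------------------------------------------
# GFF3 emission / parsing (minimal tappAS-style dialect)
# ---------------------------------------------------------------------------

def emit_gff3(acceptors: Sequence[TranscriptModel],
              annotations: Optional[dict[str, list[FunctionalFeature]]],
              path) -> None:
    """Write structural records plus any transferred functional features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in acceptors:
            base = (f"ID={tx.transcript_id};gene_id={tx.gene_id}")
            fh.write("\t".join([
                tx.chrom, "isocurate", "transcript", str(tx.start + 1),
                str(tx.end), ".", tx.strand, ".", base]) + "\n")
            for e in tx.exons:
                fh.write("\t".join([
                    tx.chrom, "isocurate", "exon", str(e.start + 1),
                    str(e.end), ".", tx.strand, ".",
                    f"Parent={tx.transcript_id}"]) + "\n")
            for e in tx.cds_exons():
                fh.write("\t".join([
                    tx.chrom, "isocurate", "CDS", str(e.start + 1),
                    str(e.end), ".", tx.strand, "0",
                    f"Parent={tx.transcript_id}"]) + "\n")
            for i, f in enumerate((annotations or {}).get(tx.transcript_id,
                                                          []), start=1):
                fid = f"{tx.transcript_id}.f{i}"
                for chrom, s, e in f.blocks:
                    attrs = (f"ID={fid};Parent={tx.transcript_id};"
                             f"level={f.level};label={f.label}")
                    fh.write("\t".join([
                        chrom, "tappas_feature", f.level, str(s + 1), str(e),
                        ".", tx.strand, ".", attrs]) + "\n")


def emit_structural_only(acceptors: Sequence[TranscriptModel], path) -> None:
    """tappAS-compatible GFF3 with structural records only."""
    emit_gff3(acceptors, None, path)


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def parse_gff3(path) -> tuple[list[TranscriptModel],
                              list[FunctionalFeature]]:
    """Read the dialect written by :func:`emit_gff3`."""
    meta: dict[str, dict] = {}
    feature_blocks: dict[tuple[str, str, str], list] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = \
            line.split("\t")
        start, end = int(start_s) - 1, int(end_s)
        attrs = _parse_attrs(attrs_s)
        if ftype == "transcript":
            tid = attrs["ID"]
            meta[tid] = {"gene": attrs.get("gene_id", tid), "chrom": chrom,
                         "strand": strand, "exons": [], "cds": []}
            order.append(tid)
        elif ftype == "exon":
            meta[attrs["Parent"]]["exons"].append(Exon(chrom, start, end))
        elif ftype == "CDS":
            meta[attrs["Parent"]]["cds"].append((start, end))
        elif ftype in LEVELS:
            key = (attrs["Parent"], attrs.get("ID", ""), attrs["label"])
            feature_blocks.setdefault(key, []).append(
                (ftype, (chrom, start, end)))
    transcripts = []
    for tid in order:
        m = meta[tid]
        cds = None
        if m["cds"]:
            cds = (min(s for s, _ in m["cds"]), max(e for _, e in m["cds"]))
        transcripts.append(TranscriptModel(tid, m["gene"], m["chrom"],
                                           m["strand"], m["exons"], cds=cds))
    features = []
    for (parent, _fid, label), rows in feature_blocks.items():
        level = rows[0][0]
        blocks = tuple(sorted(b for _, b in rows))
        features.append(FunctionalFeature(parent, level, blocks, label))
    return transcripts, features
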
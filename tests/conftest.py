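import pytest

from isocurate import fixtures
from isocurate.models import Exon, ReferenceIndex, TranscriptModel
from isocurate.pipeline import run_qc


def make_tx(tid, blocks, strand="+", chrom="chr1", gene=None, cds=None):
    return TranscriptModel(tid, gene or f"g_{tid}", chrom, strand,
                           [Exon(chrom, s, e) for s, e in blocks], cds=cds)


@pytest.fixture(scope="session")
def label_bundle():
    """One exemplar per perturbation label, zero jitter."""
    return fixtures.generate(fixtures.label_coverage_spec(seed=3))


@pytest.fixture(scope="session")
def label_index(label_bundle):
    return ReferenceIndex.build(label_bundle.reference, min_ref_len=200)


@pytest.fixture(scope="session")
def label_tables(label_bundle, label_index):
    b = label_bundle
    return run_qc(b.queries, label_index, genome=b.genome, cage_peaks=b.cage,
                  polya_peaks=b.polya_peaks, polya_motifs=b.motifs,
                  coverage=b.coverage, sj=b.sj)


@pytest.fixture(scope="session")
def simple_gene():
    """A single-isoform three-exon reference gene on the plus strand."""
    ref = make_tx("R1", [(1000, 1200), (1500, 1700), (2000, 2200)],
                  gene="GENE1")
    return ref, ReferenceIndex.build([ref], min_ref_len=0)


def mirror_bundle(bundle):
    """Reverse-complement the genome and flip every transcript's strand and
    coordinates; category calls must be invariant under this transform."""
    from isocurate.models import revcomp

    lengths = {c: len(s) for c, s in bundle.genome.items()}
    genome = {c: revcomp(s) for c, s in bundle.genome.items()}

    def flip_tx(tx):
        L = lengths[tx.chrom]
        exons = [Exon(tx.chrom, L - e.end, L - e.start) for e in tx.exons]
        strand = "-" if tx.strand == "+" else "+"
        return TranscriptModel(tx.transcript_id, tx.gene_id, tx.chrom,
                               strand, exons)

    return (genome, [flip_tx(t) for t in bundle.reference],
            [flip_tx(t) for t in bundle.queries])
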
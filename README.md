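# isocurate

Quality control and curation of long-read transcriptomes. Long-read RNA-seq
(PacBio, ONT) yields transcript models that mix genuine isoforms with
artifacts of library preparation and processing: 5'-degraded fragments,
intrapriming products from genomic A-rich tracts, spurious splice junctions
from reverse-transcriptase template switching, and misassemblies.
`isocurate` classifies each query model against a reference annotation,
scores it with orthogonal evidence, removes likely artifacts, rescues the
transcriptional signal the removed models still carried, and measures the
whole procedure against spike-in style ground truth.

It is aimed at transcriptomics researchers curating de-novo long-read
transcriptomes (bulk or single-cell) before downstream isoform-level
analysis.

## What it computes

**Structural classification.** Every query transcript gets one of eight
categories by comparing its splice-junction chain with the reference:
FSM (full splice match: identical junction chain), ISM (incomplete splice
match: a consecutive sub-chain), NIC (novel in catalog: only known splice
sites/junctions in a novel arrangement), NNC (novel not in catalog: at
least one novel splice site), fusion, antisense, genic_genomic and
intergenic — plus a subcategory describing end variability (e.g. FSM
*reference match* when both the TSS and TTS lie within 50 bp of the
reference ends) or fragment type. The admissible label space has 22
members.

**QC attributes.** From a genome FASTA, peak BEDs (CAGE-like 5' evidence,
Quant-seq-like 3' evidence), a polyA motif list, per-replicate bedGraph
coverage and STAR `SJ.out.tab` junction counts, the QC stage computes per
transcript: the TSS ratio

```
ratio_TSS = (mean coverage 100 bp downstream of TSS + 0.01)
          / (mean coverage 100 bp upstream  of TSS + 0.01)
```

(> 1 supports a genuine start; ~1 suggests 5' degradation), the adenine
fraction of the 20 bp downstream of the TTS (intrapriming flag at >= 60%),
polyA motif presence in the final 50 bp of the transcript, distances to
peak midpoints, splice-motif canonicality (GT-AG, GC-AG, AT-AC),
short-read junction support, and a direct-repeat flag for RT switching.

**Filtering.** Either declarative JSON rules (requisites AND-ed within a
rule, rules OR-ed within a category; the defaults remove FSM transcripts
only on intrapriming and require other categories to be free of
intrapriming and RT switching and have every junction supported by >= 3
short reads or all-canonical), or a random forest trained on
true-positive/true-negative sets (>= 250 transcripts each; by default FSM
reference-match vs noncanonical NNC) that keeps transcripts with
P(isoform) >= 0.7.

**Rescue.** Removed FSMs automatically pull in their associated reference
transcript; removed ISM/NIC/NNC models are mapped against same-gene
targets, targets are validated by running QC + the same filter on the
reference itself, and the best (ML) or all passing (rules) reference
targets are added without duplication.

**Benchmarking.** Spike-in style evaluation against deliberately corrupted
annotations (over-annotated and insufficient), with sensitivity,
precision, F-score, FDR, over-annotation detection rate and novel
detection rate.

## Worked example

Everything below runs offline on generated data:

```sh
isocurate simulate --out sim --seed 5
isocurate qc --query sim/query.gtf --reference sim/reference.gtf \
    --genome sim/genome.fa --cage sim/cage.bed \
    --polya-peaks sim/polya_peaks.bed --polya-motifs sim/polya_motifs.txt \
    --coverage sim/coverage_rep1.bedGraph --coverage sim/coverage_rep2.bedGraph \
    --sj sim/SJ_rep1.tab --sj sim/SJ_rep2.tab --out work
isocurate filter rules --workdir work
isocurate rescue --query sim/query.gtf --reference sim/reference.gtf \
    --mode rules --workdir work
isocurate report --workdir work
```

The run prints:

```
classified 24 transcripts
isoforms: 16  artifacts: 8
final transcriptome: 20 models (4 rescued from reference)
```

and the report lists one non-zero count per admissible label, e.g.

```
FSM     reference_match 1
ISM     3prime_fragment 1
NIC     combination_of_known_splicesites        2
NNC     at_least_one_novel_splicesite   1
...
```

The 24 simulated transcripts cover all 22 (category, subcategory) labels.
The eight artifacts are the planted intrapriming product, the
RT-switching junction, the novel-splice-site model, and the
antisense/fusion/genic/intergenic models whose junctions are noncanonical
and lack short-read support. Rescue re-adds the reference transcripts
whose only models were removed. The same objects are available as a
library (`isocurate.fixtures.generate`, `isocurate.run_qc`,
`isocurate.rules_filter`, `isocurate.ml_filter`, `isocurate.rescue`,
`isocurate.sirv`).

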
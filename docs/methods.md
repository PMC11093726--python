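# Methods

This note documents the models and procedures `isocurate` implements, the
defaults it ships with, what the synthetic data emulates, and the design
choices made where the problem was genuinely open.

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward genomic
strand. GTF input/output converts to/from 1-based inclusive at the
boundary; BED, bedGraph and the internal tables are consumed and written
natively. TSS and TTS are the strand-aware 5'- and 3'-most base positions
of a transcript model. Signed end distances are reported in transcription
direction: positive means the query end lies downstream of the reference
end, negative upstream.

Reference transcripts with spliced (exonic) length below `min_ref_len`
(default 200 bp) are excluded from every catalog, to avoid spurious
matches to annotated fragments that long-read protocols would not capture.
Whether this threshold applies to spliced or genomic length is not
externally fixed; spliced length was chosen because the threshold's
purpose is to exclude short *transcripts*, and a short transcript with a
long intron is still short. Setting `min_ref_len=0` (as done when the
reference itself is characterized for rescue) retains everything.

## Structural classification

The classifier compares the query's ordered intron list ("junction
chain") with every same-strand reference transcript whose gene locus
overlaps the query:

1. **FSM** — identical chain. Among multiple full matches the associated
   transcript is the one minimizing |ΔTSS| + |ΔTTS|, ties broken by
   lexicographic transcript id (a deterministic, order-independent rule).
2. **ISM** — the query chain is a non-empty *contiguous* sublist of a
   reference chain. Association prefers closest ends, then id.
3. **fusion** — the chain spans two or more reference gene loci that do
   not overlap each other (this guards multi-isoform genes against
   spurious fusion calls). Fusion is tested before the novelty classes
   because any multi-exon transcript with same-strand exonic overlap
   would otherwise be absorbed by NIC/NNC first.
4. **NIC / NNC** — for the genes whose exons overlap the query's exons:
   NNC if any donor or acceptor position is absent from those genes'
   site catalogs, otherwise NIC (known sites, novel arrangement).
5. **genic_genomic** — same-strand locus overlap without exonic overlap
   (e.g. a model fully inside an annotated intron). No separate
   "genic intron" label exists; intron-contained models land here.
6. **antisense** — gene overlap only on the opposite strand.
7. **intergenic** — no gene overlap.

Subcategories: FSM splits on end distances with an inclusive 50 bp window
(both ends ≤ 50 bp → *reference_match*; otherwise alternative 5'/3'/both).
ISM splits into 3'/5'/internal fragments by which transcription side of
the reference chain is missing, with *intron_retention* taking precedence
when a query exon fully bridges a reference intron. NIC distinguishes
novel combinations of known junctions from novel junctions built from
known sites. Mono-exon queries are associated by overlap: FSM on a
mono-exonic reference, ISM when contained in one exon of a multi-exonic
reference, NIC when crossing exon boundaries (with a distinct
*mono-exon_by_intron_retention* label when a complete reference intron is
bridged), genic_genomic when intron-contained. The four categories
without reference association carry mono-exon/multi-exon subcategories.
Exactly 22 (category, subcategory) pairs are reachable; fusion/mono-exon
is not a label because a fusion call requires a junction chain.

The 50 bp window is inclusive (a 50 bp offset is still a reference
match); the boundary is asserted in tests at 50/51.

## QC attributes

* **TSS ratio** = (mean coverage in the 100 bp downstream of the TSS +
  0.01) / (mean coverage in the 100 bp upstream + 0.01), per replicate,
  aggregated with `max` by default (`mean`, `median`, `q3` available).
  Window means treat bedGraph gaps as zero depth; windows are clipped at
  chromosome edges. The pseudocount keeps the ratio defined at zero
  coverage (equal coverage gives exactly 1.0).
* **Intrapriming**: adenine fraction of the 20 bp genomic window
  immediately downstream of the TTS, read on the transcript strand;
  flagged at ≥ 60% (inclusive — 12 of 20 A's is flagged).
* **PolyA motif**: exact, uppercase match of a prioritized motif list
  (default AATAAA, ATTAAA) whose occurrence *ends* within the final 50 nt
  of the spliced transcript sequence; the occurrence closest to the 3'
  end wins, ties broken by list order. Ambiguity codes are not supported.
* **Peak support**: a transcript end is supported when it falls inside a
  peak; the reported distance is to the *midpoint* of the nearest
  eligible peak (eligible = upstream of the TSS or downstream of the TTS
  in transcription direction; a containing peak is always eligible).
  Upstream distances are negative.
* **Junction attributes**: splice motif from the first and last two
  intron bases (strand-corrected); canonical set {GT-AG, GC-AG, AT-AC}.
  Short-read support is the per-replicate unique-read count from
  `SJ.out.tab` files (STAR dialect; strand code 0 matches either strand,
  because dropping undefined-strand junctions would silently lose
  support). RT-switching is flagged when an exact direct repeat of ≥ 8 nt
  is shared between the donor and acceptor boundary windows (8 nt each
  side of each boundary); the repeat length is a configuration knob since
  no single value is canonical.

## Filters

**Rules filter.** A JSON document maps structural categories (or `rest`)
to rule lists; a rule is a set of column requisites (closed numeric
interval, bare lower bound, or accepted categorical levels — booleans as
TRUE/FALSE). Requisites AND, rules OR. Missing values fail numeric
requisites (conservative). The defaults: FSM is removed solely on the
intrapriming flag; every other category must be negative for intrapriming
and RT switching and have all junctions supported by ≥ 3 short reads *or*
only canonical junctions. Removing mono-exonic models outright is an
optional flag, off by default. The default rules test the boolean
intrapriming flag rather than an interval on the A-percentage, so the
≥ 60% boundary lands exactly where the flag does.

**ML filter.** A 500-tree random forest (scikit-learn) is trained on
classification-table attributes of a true-positive and a true-negative
set, each ≥ 250 transcripts (smaller sets are refused). With no
user-supplied lists, TP = FSM reference-match and TN = NNC with ≥ 1
noncanonical junction, and the junction-canonicality and
distance-to-reference-end columns are excluded from training to avoid
learning the set definitions. Sets are balanced by seeded downsampling of
the larger, then capped at `max_size`. Identifier, genome-structure
(chromosome/strand), associated gene/transcript, and category columns are
never features. Missing numeric features are imputed with the training
median (rank-preserving); categoricals get an explicit "NA" level and
one-hot encoding. Diagnostics (held-out accuracy from a stratified 80/20
split and variable importances) are computed first; the final model is
refitted on all training rows. Multi-exon transcripts are kept when
P(isoform) ≥ 0.7 (inclusive); mono-exon transcripts carry no junction
attributes and are not scored — they pass unless explicitly dropped; FSM
can be forced in.

## Rescue

Four steps. (1) Automatic: each removed FSM's associated reference
transcript is added once, unless a passing FSM already represents it.
(2) Candidates: removed ISM/NIC/NNC models; an ISM is skipped when any
FSM in the dataset shares its reference. (3) Target validation: the
reference transcriptome is itself QC'd (against itself, `min_ref_len=0`)
and filtered under the same configuration — in ML mode by reusing the
trained forest. (4) Resolution: candidates are mapped against same-gene
targets (the genes come from the candidate's classification, not from all
overlapping loci) using a built-in scorer — matched-junction fraction
plus base-level exon-overlap Jaccard, at most 7 hits per candidate
(primary + six secondary, mirroring a spliced aligner's default).
Hits to failed targets are dropped; ML mode keeps the single best target
by filter probability (ties: mapping score, then id — the tie-break is
surfaced in the output table); rules mode keeps all passing reference
targets. Nothing already in the curated transcriptome is added twice; a
best hit that is an already-kept long-read model resolves to
"already_represented".

## Spike-in evaluation

`build_scenario` corrupts a true annotation deterministically: removing
true models that remain in the sample (insufficient annotation) and
adding fabricated variants — exon skips or 100-300 bp end shifts of true
models, deduplicated — that are absent from the sample (over-annotation).
Detections classified against both annotations fall into known TP, novel
TP (reference match to a removed true model), partial TP (FSM with an end
> 50 bp off), over-annotation FP (reference match only to a fabricated
model) and FP (NIC/NNC against both). Six metrics follow:
sensitivity = (known+novel TP)/introduced; precision =
(known+novel TP)/detected; F-score = their harmonic mean; FDR =
(FP+overannot FP+partial TP)/detected; ODR = overannot FP/detected;
NDR = (novel TP+FP)/detected. Partial TPs count toward FDR, not
sensitivity. Undefined ratios are reported as NA.

`curation_benchmark` runs the full pipeline on a generated scenario
(300 spike-in-like genes, one true detection per gene with ≤ 30 bp end
jitter, 300 noncanonical novel-splice-site artifacts, 20 intrapriming
artifacts, 39 fabricated and 26 removed annotation entries — sizes chosen
so the automatic ML training sets comfortably clear the 250-transcript
floor) and reports the metrics before filtering, after filtering and
after rescue.

## Synthetic data: what it does and does not emulate

The generator builds a uniform-ACGT genome with canonical GT-AG introns
and plants every signal the pipeline reads: one perturbed query per truth
label, CAGE-like peaks at true TSSs (± configurable jitter), polyA-site
peaks at true TTSs, AATAAA motifs ending 16-18 nt before true 3' ends,
exon-plateau coverage (default 10× on exons over a 1× background, giving
true TSSs a ratio near 9.9 and 5'-degraded models a ratio near 1), full
short-read support for annotated junctions and none for novel ones,
A-tracts downstream of intrapriming artifacts and direct repeats at
RT-switching junctions. Scrubbing passes remove *accidental* occurrences
of planted signals from the random background (extra polyA motifs near
3' ends, chance A-rich windows, chance boundary repeats) so planted truth
is recovered exactly at zero jitter.

The generator does not emulate read-level error profiles, expression
variation, overlapping genes, alternative TSS/TTS within a gene beyond
the planted variants, or non-uniform genome composition. Passing tests
therefore demonstrate the correctness of the decision rules and formulas
under clean, fully-specified evidence — not robustness to the noise
structure of any particular platform.

## Numerical and degenerate-input choices

Zero-length or off-chromosome windows contribute zero coverage; windows
clip at chromosome edges (an empty intrapriming window yields 0%, not a
flag). Classification is a total function — every transcript receives
exactly one label, independent of input order. The forest, downsampling,
holdout split and scenario corruption all derive from one integer seed;
fixed seed means bit-identical probabilities and byte-identical fixture
bundles. Problem sizes throughout the tests (6-gene fixtures for unit
work, 200 small fixtures for oracle comparison, 300-gene scenarios for
the pipeline benchmark) keep every check analytic or quick while
exercising the same code paths as full-scale runs.

## Known limitations

ORF/coding-status prediction, expression quantification and the full
feature roster of mature QC suites are out of scope; the implemented
attribute set is the one the default filters and rescue consume. The
built-in rescue mapper scores junction and exon concordance rather than
performing sequence alignment; pre-computed alignments can be substituted
by constructing mapping hits externally. The functional-annotation
transfer module defines a minimal, round-trip-stable GFF3 dialect rather
than the full vocabulary of downstream functional-analysis suites;
"partial CDS exon match" is any ≥ 1 bp genomic overlap between donor and
acceptor CDS exons.
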
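# Methods

## Scope and model

fusewalk implements a fusion-transcript analysis stack for bulk tumor
RNA-seq in two regimes. For single-end 50 bp color-space (SOLiD) data it
performs de novo discovery: expression outliers point at candidate genes,
abrupt 5′/3′ expression imbalance points at the breakpoint exon, and
junction-spanning reads assembled into a consensus are split-aligned to the
genome. For paired-end data it does not call fusions itself; it curates the
candidate lists of external callers with filters derived from the validated
single-end set, then annotates every retained fusion with a likely genomic
mechanism (from segmented copy-number data) and a predicted transcript
structure. All coordinates are 0-based half-open internally and 1-based
inclusive in every file and report.

## Outlier statistic

Per exon, RPKM = count / (length_kb × total_mapped_reads_millions); the
identity is enforced on construction of the expression matrix. The outlier
z-score uses trimmed estimators: values sorted ascending, k = ⌈f·n⌉ with
f = 0.75 by default, μ and σ (sample sd, n−1 denominator) over the lowest k
values, z = (x − μ)/σ for every sample. σ below 1e-8 (constant exons) sets
all z to 0. The lowest-k trimming follows the COPA idea of robustifying the
center and spread against the very outliers being sought; f is configuration
(`trim_fraction`) because different cohort sizes may warrant different
trims. Thresholds: outlier when z > 4 strictly; exons enter the screen only
if their max-across-samples RPKM > 20 strictly; both configurable.

COPA is computed over all samples in the matrix, including any non-tumor
samples present — callers that want tumor-only baselines subset the matrix
first.

## Exon walking

The per-exon normalizer is the cohort 70th percentile (interpreted from
decile language; linear-interpolation percentile), exposed as
`walk.quantile`. Exons silent cohort-wide (zero percentile) borrow the
gene's smallest positive percentile; a gene with no expressed exon is
skipped. The two-fold rule is inclusive (≥ 2-fold counts); a drop at the
boundary (j, j+1) nominates exon j's transcript-oriented end as a candidate
5′ breakpoint. Only drops seed discovery: reads are anchored on the 5′ gene,
whose retained exons are overexpressed; rises mark the 3′ partner and are
recovered implicitly through the split alignment.

## Color-space consensus

SOLiD colors are XOR over 2-bit bases (identical pair → 0; AC/CA/GT/TG → 1;
AG/GA/CT/TC → 2; AT/TA/CG/GC → 3); decoding requires the primer base, and a
single color error corrupts every downstream base. Consensus voting is
therefore done per color column, not on decoded bases: a color error stays
local and is outvoted. Each read's first color encodes the primer
transition and is excluded from voting. Clustering is greedy, longest seed
first, admitting a read when its color mismatch fraction over shared columns
is ≤ 0.1; each cluster of ≥ 2 reads yields one consensus (plurality per
column; ties broken by summed quality then lowest color). Two junction
isoforms anchored at the same boundary separate into two clusters and yield
two consensus sequences. Partial reads qualify with ≥ 10 and < 35 bases
matching the exon — the lower bound suppresses 1-bp spurious anchors, the
upper bound is what makes a read "partially mapped".

## Split alignment

The aligner is deliberately minimal and deterministic: exact 16-mer seeds
over the forward strand, ungapped extension with match +1 / mismatch −2 and
x-drop 8, minus-strand hits via the reverse-complemented query. The
exon-side part must reach one end of the consensus and align to the anchor
gene at identity ≥ 0.95; the remainder (≥ 20 bp, mirroring a 20 bp anchor
length convention for junction evidence) must align with a best-vs-second
score margin ≥ 8 at distinct loci, must not fall back inside the anchor gene
("intragenic"), and ties reject the call ("non-unique"). Because seed
extension can overshoot a junction wherever flanking bases coincide by
chance, the final split point is chosen by maximizing total matches over the
two fixed diagonals jointly; ties break toward the seeded split. When a
junction has real micro-homology the choice among equivalent split points is
arbitrary but deterministic. Gapped or spliced distal alignment is out of
scope: a 3′ partner entered mid-intron would need a spliced aligner.

Junction support counts reads aligning to a 45 bp + 45 bp junction window
(edit distance ≤ 2 via edlib) with ≥ 10 bases on each side; wild-type
counts use the spliced exon-exon junction of each partner at the
corresponding breakpoint, and are undefined (NA) for unannotated (UAR)
partners.

## Curation

The six retention conditions and the adjacency discard are stated in the
README. Boundary-rule tolerance defaults to 0 (exact exon boundary).
Decisions the written rules leave open, resolved here: a wild-type junction
count of 0 passes the ratio rule (the wild-type junction is simply not
expressed — an infinite-ratio reading, consistent with retained fusions
whose wild-type counts are printed as 0); the outlier z of a fusion is the
max z over all exons of both partner genes in that sample (the permissive
reading; which exon carries the outlier is not specified); the ratio is
evaluated per partner separately ("at least one of the ratios"); ratio is
strict >, z thresholds are ≥, spanning-read threshold is ≥. "Adjacent
genes" means immediate genomic neighbors: same chromosome with no third
annotated gene lying wholly in the gap between their spans, at any distance
— no distance rule is stated anywhere, so none is invented. The blacklist
is an extensible set of gene pairs; the default contains the one pair known
to occur in normal tissues (TFG→GPR128). Records merged from several
callers keep the union of provenance, the max spanning count, and are
"candidate-only" only when every source appearance was.

## Mechanism classification

Segment endpoints are genomic breakpoints. Defaults: matching window 30 kb
(SNP-array marker-resolution scale), amplification threshold seg_mean ≥ 0.9
(≈ high-level gain on log2 scale), deletion contrast 0.3 below the flanking
minimum. None of the three is a recovered constant; all are configuration
reported with the output. The decision order is fixed to make ambiguous
profiles deterministic: inter-chromosomal → focal amplification → none →
tandem duplication → deletion → complex → none. The focal-amplification
test (both points interior to one amplified segment, > window from its
ends) runs *before* the no-breakpoint shortcut; otherwise a fusion inside a
broad amplicon — by definition far from any breakpoint — could never be
called focal. "Multiple segments between" means strictly more than one
whole segment between the matched breakpoints. Partner copy-number
correlation is the Pearson r of the 5′- and 3′-point segment means.

## Structure prediction

The chimeric transcript is the 5′ gene's exons through the breakpoint
(transcript orientation) joined to the 3′ partner's exons from its
breakpoint onward, or to 10 kb of genomic sequence for a UAR partner
(`uar_extension`; long enough for a stop-codon scan to settle every class).
Frame preservation is coding-bases-retained mod 3 against the partner's CDS
phase at the entry point, with a translation check that no stop intervenes
(a hybrid codon straddling the junction can terminate an arithmetically
in-frame fusion). The peptide is translated from the 5′ start codon to the
first stop. Calling any protein product requires an open reading frame of
≥ 50 codons. When a gene needs a single representative transcript, the
longest coding transcript is used (tie: lowest id). A noncoding 5′ partner
with no qualifying ORF is "no protein"; with one, the product is reported
as a truncation. A junction in the 5′ UTR joined to unannotated or
noncoding sequence is also "no protein" unless an ORF qualifies. Kinase
domains (or any protein domain) are user-supplied protein-coordinate
intervals; retention means the unbroken domain image of the wild-type
peptide appears in the fusion peptide. Homology searching is out of scope.

## Cohort reporting

Recurrence counts distinct *patients*: TCGA barcodes collapse at the
3-field participant prefix (aliquot suffixes -01A/-01B/-02A are one
patient) and discovery-cohort samples with known TCGA aliases map to those
patients — both required to reproduce the packaged recurrent-gene census
(27 genes). "UAR" is never counted as a gene. Fisher's exact test is the
two-sided conditional sum of hypergeometric probabilities ≤ the observed
table's probability (with a 1e-9 relative slack against floating-point
ties); the odds ratio is the sample odds ratio ad/bc. The chromosome and
cytoband histograms count both partners' breakpoints; samples without a
subtype label group as "unlabeled". No multiple-testing correction is
applied to pairwise association tests; a note accompanies any batch of them.

## Synthetic cohorts

The simulator is a pure function of (config, seed) — byte-identical outputs
per seed — and defines the package's study conditions:

* genome: uniform-random chromosomes (default 2 × 400 kb) carrying
  non-overlapping 7–9-exon genes on a regular grid (exons 100–220 bp,
  introns 400–900 bp), one annotation-free 40 kb gap per chromosome as UAR
  substrate; every 5th gene noncoding;
* coding transcripts are built codon-wise — ATG, non-stop codons with a
  methionine planted every 25 codons (so N-truncated products always have a
  start), terminal TAA — making frame arithmetic on planted junctions
  exact. Non-coding transcripts and UAR gaps are "ORF-poor": stop codons
  planted in all three frames every ~100 bp, so no spurious ≥ 50-codon ORF
  can arise;
* junctions: the two reference bases that could extend an alignment across
  a planted junction are adjusted (one intron/intergenic base per side) so
  planted breakpoints carry no micro-homology and exact recovery is
  well-defined;
* reads: 50 bp single-end junction reads at Poisson(depth) coverage
  (default depth 30), uniform offsets, primer-T color-space encoding,
  independent per-color errors at the configured rate (default 0);
  wild-type junction reads at Poisson(8) for each partner;
* expression: per-gene baseline RPKM log-normal around 30 with per-sample
  log-normal noise σ = 0.2 — small enough that a planted fold of 8 yields
  z ≫ 4 while two-fold walk steps stay rare in the background — with the
  fused sample's 5′ gene elevated through the breakpoint exon and the 3′
  partner elevated from its entry exon (the drop/rise walk signature);
* copy number: per-sample SEG profiles constructed to embody the planted
  mechanism (amplified segment containing / delimited by the fusion
  points, deleted segment between them, ≥ 2 alternating segments between
  matched breakpoints, or a breakpoint on one of two chromosomes);
* caller files: truths rendered in the TopHat-Fusion-style and
  SnowShoes-style dialects plus decoys violating exactly one curation rule
  each, labelled in a sidecar table.

What the simulator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: spliced/multi-isoform backgrounds,
repeat and paralog structure (the toy genome is almost repeat-free, so
split-alignment uniqueness is easier than on a real genome), realistic
SOLiD error profiles (errors are independent and uniform), library-prep
biases, subclonal mixtures, and noisy SNP-array segmentation. Mechanism
recovery of 6/6 on noise-free profiles validates the decision tree, not
its robustness to segmentation error.

## Problem sizes and numerical choices

The shared test cohort uses 8 samples / 8 fusions on a 2 × 400 kb genome;
the statistical round trip uses 20 fusions across 20 samples on 3
chromosomes at depth 30 with 1% color error. These sizes give every
mechanism and structure class at least one instance and put ~600 junction
reads through the consensus/alignment path. Percentiles use linear
interpolation; plurality ties in consensus voting and equal-score split
points resolve deterministically (documented tie-breaks); the σ floor
(1e-8), the identity floor (0.95), and the uniqueness margin (8) are fixed
numerical guards exposed in configuration.

## Known limitations

Discovery anchors only on the 5′ gene's expression drop; a fusion whose 5′
partner is lowly expressed but whose 3′ partner rises would be found only
through the external-caller curation path. The split aligner is ungapped
and unspliced. Curation rule 5 (5′→3′ direction) is evaluated as strand
consistency of the reported breakpoints with the annotated gene strands.
The TopHat-Fusion and SnowShoes file layouts implemented here are
simplified single-block dialects documented in `fusewalk/curation.py`, not
byte-level replicas of those tools' outputs.
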
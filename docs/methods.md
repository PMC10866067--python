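# Methods

This note records the models, conventions and numerical choices behind
`linctools`, and what the synthetic fixtures do and do not establish.

## Coordinates and the genomic model

GTF input is 1-based inclusive; internally every interval is 0-based
half-open, converted once at the I/O boundary, so distances and overlaps are
plain arithmetic. A transcript is its sorted, non-overlapping exon list; a
gene spans all its transcripts. Strand `.` (and any unrecognized symbol,
with a warning) means *unknown* — unknown-strand lncRNAs are legitimate
output of assembly and are kept, they simply cannot receive an orientation.
Interval queries run on per-scaffold interval trees and are property-tested
against linear scans.

Genome-wide density uses non-overlapping 1 Mb tiles over the scaffolds
concatenated longest-to-shortest (the convention of circular density plots);
a gene belongs to the tile containing its span midpoint. Midpoint assignment
is a choice — the straddling-gene case is otherwise ambiguous — and an
any-overlap mode exists (under which counts are no longer conserved).

## Coding potential

External predictors are first-class inputs: score tables are thresholded
exactly as the tools prescribe (CPC-style: non-coding iff score < 0;
CPAT-style: non-coding iff probability < 0.38, both strict), and verdict
columns (e.g. FEELnc, whose cutoff is data-derived from its own ROC curve
and not reproducible externally) are taken verbatim.

The built-in intrinsic classifier exists so the pipeline runs with no
external binaries. Features per transcript: longest-ORF length, ORF
coverage (length / transcript length), ORF integrity (start and in-frame
stop both present), the Fickett TESTCODE statistic from the published
position/composition lookup tables, and a hexamer log-likelihood ratio
(mean over in-frame hexamers of log coding/non-coding frequency, tables
trained with a +1 pseudocount over the 4^6 alphabet). A standardized
logistic regression combines them. ORF scanning considers forward-strand
frames only (transcripts are already stranded); when no ATG has an in-frame
stop, the longest open ATG→frame-end stretch is reported with
`integrity=False`; ties break toward the smaller start, complete beating
incomplete at equal length.

Gene-level consensus: a gene is non-coding under a tool iff **every**
transcript is (a transcript with no call counts as coding — conservative,
configurable); the gene enters the lncRNA set with ≥ `m_votes` (default 2)
tool votes. Whether multi-tool agreement should instead be intersected per
transcript first is genuinely ambiguous; both modes are implemented
(`level="gene"` default, `level="transcript"` alternative).

## Positional classification

Overlap is judged transcript-span against coding-gene span (exon-level mode
available); any overlap makes the gene *genic*, which takes precedence. The
nearest coding gene is by edge-to-edge distance on the same scaffold, any
strand, ties to the smaller gene id for deterministic output. Within the
100 kb window the gene is *intergenic* (a lincRNA); beyond it,
*non-neighboring* — defined strictly as "no coding gene within the window
and no overlap". Orientation needs both strands known: sense = equal
strands, antisense = opposite. Antisense subtype is per transcript from
5′/3′ geometry — divergent when the 5′ ends face each other (a transcript
left of its neighbor is divergent iff it runs leftward), convergent when
the 3′ ends do — and the gene is labelled *both* when its transcripts
disagree. Categories are monotone in the window size by construction.

## Expression filtering

Cascade order: prevalence filter on raw counts (> 0 in ≥ ⌈0.75·n⌉ samples;
ceiling makes 75% of 226 exactly 170) → median-of-ratios normalization
(reference = geometric mean over features positive in all samples; optional
half-count pseudo-reference when none exists; even-length medians average
the middle two) → abundance filter (normalized ≥ 1 in ≥ ⌈0.90·n⌉) →
highly-expressed flag (mean normalized count strictly > 500; "mean across
samples" is a choice, median/all-samples modes exist). Inequalities are
deliberately asymmetric — "> 0", "≥ 1", "> 500" — matching how the
thresholds are conventionally stated. Counts may be non-integer
(fractional multi-mapper counting upstream). Note that median-of-ratios
factors are defined only up to a common scale: rescaling one sample's
column by c multiplies its factor by c^(1−1/m) and the others by c^(−1/m),
so only factor *ratios* are scale-equivariant.

## Differential expression

The decision rule is: BH-adjusted p ≤ 0.05 AND basemean (mean normalized
count over **all** samples, the DESeq2 convention) ≥ 10 AND |log₂FC| ≥ 0.3
— the fold-change bound is two-sided since both directions of regulation
matter. The rule is always recomputed when a table is imported, regardless
of upstream flags.

Three statistic sources, one table format:

- `standin_test` — per-feature two-sample Wilcoxon rank-sum
  (tie-corrected normal approximation) on normalized counts, log₂FC =
  log₂((mean₊0.5)/(mean₊0.5)), BH over all tested features. It is
  explicitly **not** a negative-binomial model: its type-I error is nominal
  (measured ≈ 0.05 under the NB null) but at small group sizes it is more
  conservative than NB models — in the planted 4-fold simulation
  (NB mean 50, size 5, 100/2000 features, 7–11 per group) it recovers
  ~80–90% of planted features where the NB model recovers ~99%.
- `deseq2_test` — the Wald test of the DESeq2 model via the installed
  pydeseq2, mapped into the same table; this is the recommended route and
  the one used for the planted-DE recovery checks.
- `import_de` — any external table with a column mapping.

The expression-change contrast (are DE coding genes with a neighboring
lincRNA more often strongly changed, |log₂FC| > 2?) uses Pearson's
chi-squared **without** continuity correction, df = 1. This is pinned by
arithmetic: the reference 2×2 (7/198 vs 23/3233) yields X² = 17.166,
p = 3.425e-05 uncorrected, while the Yates-corrected statistic gives
p ≈ 1.8e-4 — only the uncorrected test matches the reported value. A
corrected variant sits behind a flag.

## Co-expression network

Input is log₂(normalized + 1) (the same transform as the PCA). Signed
adjacency a_ij = ((1 + cor_ij)/2)^β preserves correlation sign; β defaults
to 10 and `pick_power` selects the smallest candidate whose scale-free fit
R² ≥ 0.8 (log₁₀ frequency vs log₁₀ mean connectivity over 10 equal-width
bins, R² sign-adjusted by the slope; < 3 occupied bins is an error; if no
candidate qualifies the best fit is returned with a warning). TOM is the
unsigned Zhang–Horvath formula applied to the signed adjacency
(TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), sums excluding
i and j); a signed-TOM pairing would differ only through negative
adjacencies, which the signed adjacency never produces.

Module detection is deliberately simple: average-linkage clustering of
1 − TOM with a **static** cut (default height 0.99, minimum size 30,
sub-minimum clusters pooled as "grey", surviving modules colored by
decreasing size in the WGCNA convention). This is a declared approximation
to dynamic tree cut: module counts from real data will not match a dynamic
cut, and with few samples (n ≈ 18) background noise compresses the upper
dendrogram — unrelated feature groups can merge below 0.99, so planted-block
analyses cut at 0.95, inside the wide gap between within-block (~0.35) and
between-block (~0.97) merge heights. The module eigengene is the first
right singular vector of the feature-standardized module matrix (unit norm,
sign oriented to correlate positively with the module). Module–trait
association is Pearson r of eigengene vs condition (control = 0, CO₂ = 1)
with p from t = r√(n−2)/√(1−r²); modules are significant at p < 0.01.

## Regulatory candidates

Cis routes only ever pair a lincRNA with its assigned neighbor: (a) the
lincRNA is highly expressed; (b) lincRNA and neighbor both DE; (c) both in
the same significant module. One pair may carry several modes. Trans routes
screen (d) DE lincRNA × DE coding gene and (e) same-significant-module
pairs, after removing every lincRNA that has an assigned neighbor (full
exclusion; a flag keeps them). Spearman ρ uses average ranks and the
t-approximation for p (adequate at n = 18; exact permutation enumeration is
available for n ≤ 8); correlations are computed on normalized counts, not
log-transformed, and no multiple-testing correction is applied to the
screen (|ρ| ≥ 0.9, raw p ≤ 0.01) — an optional BH flag exists but is off to
match the stated rule.

## Orthology

Hits are outfmt-6 rows; multiple HSPs per query–subject pair collapse to
the minimum e-value first. Best hit per query = minimum e-value ≤ 1e-3,
ties by higher bit score then lexicographic subject id (deterministic). A
pair is orthologous iff the two directions' best hits are mutual; the
output is symmetric under swapping directions. Raising the cutoff can in
principle change which hit is best, so monotonicity in e_max holds only
when best hits are unchanged (tested on fixtures). Neighbor congruence
compares case-normalized gene symbols of the two lincRNAs' nearest coding
genes; a missing annotation yields *unknown*, excluded from congruent
counts. Species-specificity percentages are rounded to 2 decimals.

## Synthetic fixtures

The generators emulate the study design at desk scale and are deterministic
under (spec, seed), emitting machine-readable truth alongside the data:

- **Annotation**: one planted unit per 250 kb block over two 5 Mb
  scaffolds (genic = linc overlapping its block's coding gene; intergenic =
  5–80 kb away with the planted orientation/subtype realized by strand/side
  geometry; non-neighboring = coding-free block, > 150 kb to any coding
  gene). Category truth is exact by construction.
- **Counts**: negative-binomial, default mean 50 and size 5, 11 control +
  7 CO₂ samples. DE features multiply the CO₂ mean by 2^effect (default
  |effect| = 2, alternating sign — both directions of regulation occur in
  real contrasts and measured detection power is the same either way).
  Module blocks share a per-sample latent factor with log₂ loading 2 at low
  dispersion (size 50), giving within-block log-scale correlation ≈ 0.9;
  trait-linked blocks tie the factor to the condition. Highly-expressed
  features are planted at mean 10,000.
- **BLAST**: planted reciprocal pairs are mutual e-value minima; one-way
  pairs have a reverse best pointing elsewhere; decoys fail the cutoff.
- **Sequences**: coding-like transcripts carry a planted ORF (default 60%
  of a 500 nt transcript) built from GC-biased codons; every other ATG in
  the sequence is mutated (G→C, which can create neither a new ATG nor a
  stop), so the planted ORF is provably the longest — the construction
  oracle for the ORF scanner. Non-coding-like sequences are uniform random.
  At bias strength 0 the two classes are generated identically (the null
  for the classifier).

What passing these tests shows — and does not. The fixtures have clean
block structure, independent features outside planted structure, no library
composition artifacts, no GC/length biases, no isoform ambiguity and no
mapping noise. Perfect category/RBH recovery and AUC = 1 on the separable
benchmark verify the *logic*, not performance on real data; the honest
indicators of statistical behavior are the calibrated type-I error and the
DE power figures above.

## Problem sizes and runtime

Default analyses are sized for a single CPU: 2,000-feature count matrices,
18 samples, ≤ a few hundred network features, 100-instance oracle sweeps.
The full test suite runs in well under a minute apart from the
pydeseq2-backed recovery check (~10 s); `scripts/acceptance.py` completes in
under a minute.
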
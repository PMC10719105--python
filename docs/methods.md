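# Methods

This note documents the statistical models implemented in `ccre_atlas`,
the parameter defaults and why they were chosen, the design decisions made
where the published procedures leave details open, and the limits of what
the synthetic atlas shows.

## Fragment QC

Aligned pairs are corrected for the Tn5 transposase's 9-bp target-site
duplication: +4 bp on the plus-strand (left) end and −5 bp on the
minus-strand (right) end, applied once per fragment. Fragments shorter
than 9 bp after correction are kept as 1-bp stubs and flagged rather than
emitted as inverted intervals. MAPQ filtering is strict (`mapq > 30`);
duplicates are collapsed per (barcode, chrom, start, end).

TSS enrichment aggregates single-base cut sites (both fragment ends; the
right cut site is `end − 1` in half-open coordinates) in a ±2,000-bp
window per TSS, with minus-strand TSSs mirrored. The profile is divided by
the mean count over the |offset| ∈ [1900, 2000] flanks and smoothed with a
centred 11-bp moving average, truncated (not padded) at the window edges;
TSSe is the maximum of the smoothed profile. Numerical choices:

- A zero flank receives one pseudocount spread over the flank (202
  positions), so sparse nuclei yield finite TSSe and are flagged
  `low_coverage` instead of producing infinities.
- Per-barcode TSSe uses the same 11-bp smoothing as the sample-level
  metric (the published description does not distinguish them).
- Because TSSe is the *maximum* of a noisy profile, it is biased upward at
  low coverage: a barcode with a few thousand fragments over a flat
  insertion stream typically measures TSSe ≈ 1.2–1.5 rather than 1.0, and
  the bias shrinks with coverage. Tests and the acceptance script measure
  planted enrichments on dense streams (4 × 10⁵ fragments), where a
  planted 20× enrichment is recovered within a few percent.

The nucleus gate is inclusive on both thresholds (≥ 1,000 deduplicated
fragments AND TSSe ≥ 10), resolving the published "above 10" vs "≥ 10"
wording in favour of the Methods formulation.

## Peak filtering

Summits are extended ±250 bp to fixed 501-bp elements (clipped intervals
are flagged). Caller scores (−log₁₀ q) are converted to score-per-million
within each cluster's pooled set, SPMᵢ = scoreᵢ/(Σscore/10⁶); the SPM sums
to 10⁶ per cluster by construction and a single cut-off (default 5,
inclusive) applies across clusters of different depth. The exact SPM
formula is isolated behind `spm_transform` for easy substitution.

The reproducibility rule retains a pooled peak iff it overlaps at least
50 % *of its own length* with some peak in both replicates, or in both
pseudoreplicates. A call set that is absent (e.g. the caller was skipped
for a replicate with too few cells) automatically passes its branch —
mirroring the published intent of avoiding false negatives in
depth-limited replicates — and the decision is flagged in the output.

Merging per-cluster catalogues by coordinate union would break the fixed
501-bp width, so the union keeps, iteratively, the highest-SPM element and
removes everything overlapping it (ties broken by coordinate for
determinism). Each catalogue entry records the clusters whose peaks it
absorbed. This greedy selection is oracle-tested against a brute-force
implementation.

The cell-fraction filter models background fractions as a zero-inflated
beta: a point mass π at zero plus Beta(α, β) on (0, 1). π̂ is the zero
proportion; (α̂, β̂) are scipy's numerical MLE on the nonzero part, with
values exactly 1 shrunk by (x(n−1)+0.5)/n to keep the likelihood finite.
The per-entry p-value is the mixed upper tail P(X ≥ x) = (1−π)(1−F(x)) for
x > 0 and 1 at x = 0 — a valid p-value (P(p ≤ t) = t under the null).
BH adjustment is applied within each cluster (matching the "in at least
one of the clusters" retention phrasing); the null is fitted globally by
default with a per-cluster option. Calibration on a null-only table of
10⁵ draws keeps the false-discovery proportion at or below nominal.

## Cis-regulatory modules

NMF uses Lee–Seung multiplicative updates on the Frobenius objective from
a seeded nonnegative random initialization; the per-iteration error
trajectory is exposed and asserted non-increasing in tests. sklearn's NMF
(same objective, independent implementation) serves as a cross-check, and
the rank-1 factorization agrees with the truncated SVD (Perron–Frobenius)
to 1e−6. Input normalization for **V** is column-wise CPM of per-subclass
aggregated accessibility — the published "normalized chromatin
accessibility" without further specifics, isolated in `cpm_normalize`.

Rank metrics: Hoyer sparseness (√n − ‖x‖₁/‖x‖₂)/(√n − 1) of the rows of
**H**, and normalized Shannon entropy of column-normalized **H** averaged
over columns (0 = each subclass loads on one module, 1 = uniform), each
averaged over five seeded runs per rank. Both formulas are standard
definitions from the literature the published pipeline cites by name only,
and both are isolated behind single functions. Module–subclass association
min-max scales each column of **H** and associates at scaled value > 0.1;
constant columns are flagged rather than scaled. The feature score is the
Kim–Park definition (one minus normalized row entropy of **W**), with the
two published retention criteria (score > median + 3 s.d. and max basis
entry > median of **W**). Rank choice is left to the metrics table plus
configuration; the package does not hard-code a selected rank.

## Linking

Candidate pairs are all same-contig peak pairs with summit distance
≤ 500 kb; a member is proximal iff its summit lies within ±1 kb of a TSS
(the genomic-annotation preset "1.5 kb upstream / 500 bp downstream" is
retained as an alternative constant but the ±1-kb rule governs linking).
Distances are measured summit-to-TSS.

Co-accessibility is scored as the Pearson correlation of metacell
aggregates (seeded random groups of 10 cells within subclass; remainders
dropped). The published pipeline's graphical-lasso scorer is deliberately
replaced by this simpler scorer: the contribution implemented faithfully
here is the *null calibration* — scores are recomputed after permuting the
peak columns of the cell-by-peak matrix, a normal distribution is fitted
to the shuffled scores by MLE, one-sided upper-tail p-values are
BH-adjusted and pairs are retained at FDR < 0.001. The calibration is
scorer-agnostic. On the synthetic atlas, cells are conditionally
independent given their subclass, so within-subclass co-accessibility is
genuinely null and the calibrated pair count is honestly near zero; the
pipeline therefore feeds *all* distal–proximal pairs to the linking stage
and reports the co-accessibility calibration separately.

Enhancer–gene links correlate log1p-CPM peak accessibility with log1p-CPM
expression of the gene whose promoter hosts the proximal member, across
subclasses. The empirical FDR compares the observed PCC tail with the
tail of randomly re-paired peak–gene correlations:
FDR⁺(t) = #{shuffled ≥ t}/#{real ≥ t}, with the shuffled count scaled by
len(real)/len(shuffled) when the sets differ in size; the positive
threshold is the smallest t with FDR⁺(t) < 0.01, the negative tail is
symmetric, and thresholds are global (not per-distance-bin).

## GRNs

Per target, standardized expression is regressed on the standardized
candidate TFs with bagged ridge regression (20 bags, penalty 1.0, seeded
resampling). The edge weight is the mean coefficient across bags. For the
p-value, the bag coefficients estimate the sampling distribution of the
coefficient itself, so the standard error is their s.d. — *not* s.d./√B;
the statistic t = mean/sd(bags) with B−1 degrees of freedom calibrates
correctly (≈ 0.1 % of null edges pass p < 0.001), whereas the naive
one-sample t-test over bags is anticonservative by √B. The p < 0.001
filter applies before the top-10,000-|weight| cap. Candidate regulator
sets are an explicit input (the upstream motif scan is out of scope),
which also makes the regression core testable in isolation. Regression on
co-expression cannot resolve TF–TF edge direction, so reciprocal TF pairs
are common in inferred networks — visible in the motif census, where
one-way feed-forward templates rarely match.

The motif census counts node triples whose *induced* signed subgraph
equals a template up to label permutation: specified edges must match in
presence and sign, unspecified ordered pairs must be absent. Matching
against the template's full permutation orbit makes automorphism
deduplication implicit. The library ships the regulated double-positive
and double-negative motifs and both feed-forward sign variants; the full
17-motif catalogue is user-extensible via `MotifPattern`. Counts are
verified against brute-force ordered-triple enumeration.

Eigenvector centrality runs power iteration (tolerance 1e−10, max-score
normalization) on |weight| symmetrized by max(|wᵢⱼ|, |wⱼᵢ|) — the
published procedure does not state sign/direction handling, and this
choice is documented and swappable. The iteration uses the spectrally
shifted matrix A + max(A)·I, which has the same eigenvectors but breaks
the ±λ eigenvalue pairs of near-bipartite TF→target graphs that make raw
power iteration oscillate.

The degree power-law check is a discrete maximum-likelihood fit with an
xmin scan minimizing the Kolmogorov–Smirnov distance, plus a parametric
bootstrap (default 50 replicates; fitted tail + empirical body) whose
goodness-of-fit p-value sets the `plausible` flag at p > 0.1. Degenerate
(all-equal) degree sequences are flagged not-fittable.

## TE and conservation

TE overlap is a peak-level indicator at ≥ 1 bp (a peak hit by several TEs
counts once). The highTE classifier is a hand-rolled 1-D two-component
Gaussian EM (two-means initialization, variance floor 1e−8, exposed
log-likelihood trajectory, components ordered by mean), cross-checked
against sklearn's `GaussianMixture`. A subclass is highTE when its
posterior for the upper component exceeds 0.5; p-values are upper tails
under the lower (null) component and are reported for transparency.
Differential accessibility uses the two-sided Wilcoxon rank-sum test
(exact for small untied samples) with BH across peaks; constant rows get
p = 1. Family enrichment is the two-sided Fisher exact test per family
with BH; zero-margin tables give p = 1 and an undefined odds ratio.

The interval permutation test re-places each query uniformly on its own
contig (lengths and contig assignment preserved — keeping the analytic
expectation tractable and matching common shuffle semantics), with the
plus-one-corrected p-value (1 + #{null ≥ obs})/(n + 1), never zero.

Orthology classes: mapped fraction strictly > 0.5 and accessible in the
target species → CA-conserved; mappable but not accessible →
CA-divergent; otherwise mouse-specific.

## Weighted Poisson loss

With **C** the covariance matrix between cell-type rows of the true
signal matrix, the default (prose) reading gives per-type weights
wᵢ = (Σⱼ Cᵢⱼ)/n; the alternative reading of the printed equations — a
single scalar, the mean diagonal variance — is available as
`mode="scalar"`; neither is asserted as ground truth since the source
notation is internally inconsistent. The loss is
L = Σᵢ wᵢ · meanⱼ(ŷᵢⱼ − yᵢⱼ ln ŷᵢⱼ); the bin reduction is the mean by
default (scale-stable in sequence length) and configurable to the sum.
Negative weights (anticorrelated types) are passed through with a warning,
unclipped. The per-entry gradient 1 − y/ŷ and convexity in ŷ are verified
numerically.

## Synthetic atlas: what it emulates, and what it does not

Each peak belongs to one module and each subclass is assigned to one
module; base rates are `foreground_rate` = 0.30 where peak and subclass
share a module and `background_rate` = 0.02 elsewhere — matching the
sparse per-cell detection of snATAC-seq. On top of the module base, every
(peak, subclass) rate receives logit-normal jitter with s.d. 1.5
(`rate_jitter_sd`). This jitter is essential, not cosmetic: real cCREs
show graded, element-specific accessibility, and enhancer–gene linking
relies on exactly that peak-specific structure. Without it, every peak of
a module shares one pattern, so a random same-module peak–gene pair
correlates as strongly as a planted link and no empirical-FDR threshold
can separate them. With it, planted links (genes coupled to the planted
peak's realized log-rate pattern through a shared latent subclass factor
at loading `link_effect` = 0.8) are recovered at ≥ 99 % recall with < 1 %
false positives, while module NMF recovery remains at ARI ≈ 0.97, under
one set of defaults: 40 subclasses × 500 cells × 5,000 peaks × 1,000
genes × 8 modules × 300 links.

Expression is Poisson with log-mean log(200) + 0.7·latent − 0.245; genes'
TSSs sit at the summits of randomly chosen "promoter" peaks on a synthetic
genome of 4 contigs with 10-kb summit spacing, and planted distal partners
lie within the 500-kb pairing window. Fragment streams draw cut sites from
a mixture of uniform background and ±150-bp TSS windows whose density
ratio equals the planted enrichment; sites are sorted and paired into
fragments so both ends follow the planted profile. GRN expression follows
x = Bx + ε with a signed acyclic B (TF→TF edges only forward), exogenous
noise s.d. 1.0 for root TFs and 0.3 for regulated genes; matrices with
spectral radius ≥ 1 are rejected. A single root seed drives one child RNG
stream per artifact, so stages regenerate independently and bit-identically.

Known limitations of the emulation — and hence of what green tests show
about real data:

- Cells are conditionally independent given their subclass: there is no
  within-cluster covariation, doublets, batch structure, sequencing error
  or chimera formation. Co-accessibility methods that exploit
  within-cluster covariance see a true null here.
- A random permutation of cell labels does not fully destroy module
  signal in pseudobulk: finite groups sample subclass composition
  multinomially and that fluctuation is shared across same-module peaks,
  leaving residual recovery (ARI ≈ 0.25) at any group size. Chance-level
  recovery is demonstrated with the generator's no-signal condition
  instead.
- TSS enrichment of the fragment stream is planted as a density ratio;
  fragment lengths are a byproduct of site pairing, not a nucleosomal
  model.
- TE labels, orthology fractions and methylation/RNA tracks are sampled
  summaries with planted structure, not genome-derived annotations.

## Problem sizes

Default test and acceptance scales were chosen so the whole suite runs in
a few minutes on one core: ZIB calibration at 10⁵ draws, module recovery
at 2,000 peaks × 40 subclasses, link recovery at 300 planted links among
3,000 candidates over 40 × 500 cells, GRN sign accuracy at 20 TFs × 200
genes × 500 cells, TSSe recovery at 4 × 10⁵ fragments, and the mixture at
250 subclass fractions.
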
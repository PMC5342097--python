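# Methods

`pairomics` analyses matched tumor/control cohorts profiled on three omics
layers — miRNA, mRNA and protein — measured from the same tissue
specimens. This note describes the statistical procedures, the
stoichiometric miRNA-influence model at the package's core, the synthetic
cohort generator used to validate every stage against known ground truth,
and the numerical and design choices that were genuinely open.

## Paired differential statistics

Each patient contributes one tumor and one control sample; all hypothesis
tests exploit this pairing. Abundances are linear-scale and nonnegative.
Tests run on `log2(x + 1)`; the pseudocount of 1 keeps zero intensities
finite and is negligible against typical intensities (hundreds). Per
feature we report:

- **Paired t-test** on within-patient log2 differences (two-sided).
  Features whose differences are all identical have an undefined t; they
  are flagged `zero_variance`, assigned p = 1, and kept so feature counts
  stay stable across layers.
- **Wilcoxon–Mann–Whitney** as a two-sample rank-sum test between the
  tumor and control groups, using the tie-corrected normal approximation.
  Running a two-sample test in a paired design discards the pairing; it is
  kept as a distribution-free cross-check of the t-test, and their p-value
  rank correlation is asserted ≥ 0.7 on deregulated synthetic cohorts.
- **AUC**: the probability that a random tumor value exceeds a random
  control value, ties counting ½. It equals the rank-sum statistic U
  divided by n₁·n₂, which is asserted as a property test.
- **log2 fold change**: the mean within-patient log2 difference; its sign
  defines the measured direction of deregulation.
- **Effect size**: t divided by √(number of pairs).
- **Shapiro–Wilk** p-value on the paired differences, as a normality
  diagnostic for the t-test's assumptions.

Quantile normalization (per layer, before testing) forces each sample onto
the mean empirical distribution: each sample's sorted vector is replaced
by the across-sample mean of sorted vectors; ties within a sample receive
the mean of the reference quantiles they span.

Multiple testing is controlled by Benjamini–Hochberg (FDR) and Bonferroni
(FWER); Bonferroni at α = 0.05 is the default significance notion
downstream, with BH selectable everywhere. Adjustment preserves input
order and is elementwise monotone: Bonferroni ≥ BH ≥ raw.

Multivariate views: PCA on feature-centered log2 values (numpy SVD, sign
fixed so each component's largest-magnitude loading is positive, variance
fractions summing to 1) and average-linkage hierarchical clustering of
samples on Euclidean log2 distances, with samples pre-sorted by id so tied
merges resolve deterministically.

## Genomic co-enrichment scan

Features of all three layers are projected onto one axis by concatenating
chromosomes 1..22, X, Y and placing each feature at
`floor((start + end) / 2)` within its chromosome. BED input (0-based,
half-open) is converted once at the I/O boundary to internal 1-based
inclusive coordinates. A 1-Mb window slides along the axis (default step
500 kb — the step is a free parameter; 50% overlap balances resolution
against window count, and step = window gives non-overlapping tiles) and
counts Bonferroni-significant features per layer. Windows are half-open on
the right. Windows holding ≥ 1 significant miRNA, ≥ 1 gene, ≥ 1 protein
and more than 10 significant features in total qualify; overlapping or
touching qualifying windows merge into maximal regions. Merged spans are
cut at chromosome boundaries, members and counts recomputed per piece, and
pieces no longer meeting the criteria dropped — a region on a
concatenated-axis seam is not biologically meaningful. The windowed
counting is exactly equivalent to a naive per-window recount (asserted on
random layouts). A Manhattan-style table (−log10 adjusted p against global
position, adjusted p of 0 clamped to the smallest positive float) supports
plotting.

## Ab-initio correlation network

All C(N, 2) feature pairs across the pooled layers are tested for Pearson
correlation on log2 values over all samples (tumor + control pooled; a
per-condition run is possible by subsetting samples). With N = 43,419
features the Bonferroni-adjusted per-test threshold is
0.05 / C(43419, 2) = 0.05 / 942,583,071 ≈ 5.3×10⁻¹¹. P-values come from
the two-sided t transform of r with n − 2 degrees of freedom. The pair
matrix is evaluated in blocks so it is never materialized; blockwise and
all-pairs brute-force edge sets are asserted identical. Constant features
are excluded with a logged count, and the family size used for any
reporting is the number of pairs actually tested. Observed edge counts per
pair type (six unordered layer combinations) are compared with the
expected fractions n_A·n_B / C(N,2) (A ≠ B) and C(n_A, 2) / C(N,2)
(A = B).

## Stoichiometric miRNA influence model

The model is a bipartite miRNA → target-gene network with edge weights

    w_ij = e(g_j) / Σ_k e(g_k),

the sum running over all l targets of miRNA m_i, so each miRNA's weights
sum to 1 and a highly expressed competing target dilutes the miRNA's
influence on the others. The joint influence on gene g_j is

    s(g_j) = Σ_k w_kj · e(m_k)

over its z targeting miRNAs. Weights are fitted once from **control**
gene expression; evaluating s with control and tumor miRNA abundances
gives s^N and s^C. Rising influence predicts repression: Δ = s^C − s^N > 0
→ predicted down, Δ < 0 → predicted up, Δ = 0 → no call (excluded from
accuracy denominators; exact zeros occur only in degenerate inputs).

Expression summaries enter on the **linear** scale as arithmetic condition
means — the weights are abundance shares, and a log transform would
destroy their stoichiometric meaning. A miRNA whose targets all have zero
mean receives uniform weights 1/l with a warning. The interaction table
can be restricted to the functionally validated subset
(`support=functional_strong`) or used in full; degree z is counted after
filtering to measured features, since unmeasured miRNAs cannot contribute
to s.

Predictions are scored against the measured fold-change direction of
genes significant at Bonferroni-adjusted p < 0.05 (configurable),
stratified by minimum degree z ≥ d. Each stratum reports n_evaluated,
n_correct, the accuracy percentage and a one-sided exact binomial tail
P(X ≥ n_correct) against chance 0.5. Note that for 12 correct of 13 this
tail is 14/8192 ≈ 0.0017; published analyses of such networks have quoted
other values for the same stratum without documenting the computation, so
both counts are always reported alongside the percentage.

Model invariants asserted in tests: weight conservation per miRNA;
invariance of weights under rescaling of all gene means; linear scaling of
every Δ (and invariance of all predictions) under joint rescaling of
miRNA means; for a single-target gene, the prediction is exactly the
opposite of its miRNA's change; vectorized scoring equals a per-edge loop.

## Synthetic cohorts with known ground truth

The generator emulates the study design end to end: 18 patients by
default, each with one tumor and one control sample, and feature counts
defaulting to a tractable 100 miRNAs / 800 genes / 300 proteins that
preserve the ordering of the real layer sizes (2,549 / 34,687 / 6,183).
Natural-log abundance of a feature is

    mu_f + beta_{f,p} + delta_f·1[tumor] + eps,

with per-feature baseline mu_f ~ N(5, 1) (abundances around e⁵ ≈ 150),
per-feature-per-patient effect beta ~ N(0, 0.5²) shared by the patient's
two samples (the inter-individual variation that pairing removes),
intrinsic shifts delta = ±(effect_size_log2 = 1.5)·ln2 for a deregulated
fraction (miRNA 30%, untargeted genes 5%, proteins 5%; up/down 50/50), and
measurement noise eps ~ N(0, 0.3²). All abundances are strictly positive
by construction.

miRNA-driven repression is injected **through the model itself**: edge
weights and per-condition influence scores are computed from the
noise-free condition means, and each targeted gene's tumor abundance is
multiplied by `exp(−kappa·(s^C − s^N)/max(s^N, 10⁻⁶))` — the relative
influence change, floored so near-zero baselines are not blown up; the
model is descriptive, so this generative inversion is the package's own.
kappa defaults to 1. Intrinsic gene effects are placed only on untargeted
genes, keeping the two mechanisms disjoint. Proteins track their coding
gene's per-sample abundance plus a protein-specific offset ~ N(0, 1),
intrinsic shifts, and extra noise ~ N(0, 0.5²). The interaction network
draws each miRNA's target count as 1 + Poisson(mean − 1) (mean 8 targets
by default) with targets sampled without replacement, and flags 30% of
edges as functionally validated.

Coordinates tile real-sized chromosomes (~3.1 Gb total), so features are
Mb-scale apart and no spurious window enrichment arises; an opt-in hotspot
mode instead places every deregulated feature inside a 0.5-Mb span of a
designated 1-Mb region so window-scan recovery can be checked exactly.

What the generator does **not** emulate: microarray probe effects,
mass-spectrometry missingness, batch effects, library-size biases, or
correlated co-regulation beyond the miRNA coupling. Because the synthetic
matrices carry no technical bias, model-recovery tests evaluate the
influence model on the raw matrices: at strong coupling (kappa ≥ 5) the
generative multipliers are large enough that quantile normalization —
whose assumption of comparable distributions is then violated — would
redistribute them onto unshifted genes and contaminate the evaluation set.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the generative model, not performance on real
microarray/MS data.

Calibration and recovery properties asserted on the generator: with all
effects off, raw paired-t p-values are uniform (fraction < 0.05 within 3
binomial SEs at 2,000 features); with fixed seed, increasing kappa
monotonically increases coupled genes' fold-change magnitudes; at kappa 5
and low noise, direction accuracy at minimum degree 1 exceeds 90% (in
practice ~99%). One caveat found during validation: predictions do not
depend on kappa (miRNA data and control means are kappa-free), so raising
kappa only adds borderline genes — those with the smallest true influence
changes — to the significant set, and accuracy at kappa 5 can sit a
fraction of a point below the saturated 100% of kappa 1. Accuracy is
therefore not strictly monotone in kappa once saturated; the tests
document this honestly rather than asserting it away.

## Gene–protein concordance

Proteins are mapped to coding genes (many-to-many; unmapped proteins
dropped with a log line). Pairs where both layers have raw paired-t
p < 0.05 are compared by AUC: a pair is concordant when both AUCs sit on
the same side of 0.5. AUCs of exactly 0.5 are direction-neutral and
excluded from the percentage denominator. The pair-level gene and protein
AUC vectors are summarized by Pearson correlation (NaN below 3 pairs or
for constant vectors). On synthetic cohorts, concordance approaches 100%
as protein noise vanishes and falls toward chance when the protein layer
is decoupled.

## Numerical conventions and degenerate inputs

- Coordinates: BED is 0-based half-open; everything internal is 1-based
  inclusive; windows are half-open right; midpoints floor.
- p-values of exactly 0 are clamped to the smallest positive double
  before −log10.
- Correlation r is clipped to [−1, 1] before the t transform; 1 − r² is
  floored at the smallest positive double (p underflows to 0 for exact
  duplicates).
- Fewer than 3 pairs (differential), fewer than 3 samples (correlation),
  fewer than 2 samples (PCA/clustering/normalization) and constant
  matrices (PCA) raise; a single-sample normalization warns and returns
  the input.
- All result tables are written sorted by identifier, making repeated
  runs byte-identical.

## Problem sizes

Default test and validation runs use the scaled-down cohort (18 pairs,
100/800/300 features, ~1,200 features for the correlation network); the
null-calibration run uses 2,000 genes; oracle-equivalence suites use up to
300 features (correlation), 1,000 random p-vectors (BH) and 1,000 random
networks (weight conservation). These sizes were chosen so the complete
validation runs in well under a minute while keeping every Monte-Carlo
assertion's standard error far below its tolerance.
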
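# Methods

## Model and procedure

`setcorr` infers candidate gene function by correlating each gene's
expression with summary statistics of *a priori* gene sets across a
compendium of samples. The working assumption is that functionally
related genes are transcriptionally co-regulated, and that a compendium
with large between-sample variability (e.g. tumors standardized against
tissue-matched normals) carries enough signal for those co-regulation
patterns to dominate noise.

**Fold-change standardization.** Inputs are log2 expression values. Each
case sample is standardized by subtracting, per gene, the median log2
value of that gene across the control samples of the same tissue group.
The subtraction is done in log2 space: the upstream summaries (e.g. RMA)
are already logarithmic, and log-space medians keep the operation
translation-honest (adding a constant to a sample shifts its fold-changes
by exactly that constant — a tested invariant). The result is a log2
fold-change matrix, the substrate of everything downstream.

**Single-sample enrichment.** For one sample with fold-change vector *x*
over all measured genes, and a gene set with *m* members present in the
matrix, the parametric Z-score is

    Z = (S_m − μ) · √m / δ

with μ = mean(*x*), δ = SD(*x*), and S_m the mean over set members. μ and
δ are whole-vector statistics, never member statistics — conflating the
two is the classic implementation error, and the scalar definition is the
bit-for-bit contract for the vectorized matrix routine. Consequences that
serve as free sanity checks: the whole-universe set has Z = 0 in every
sample; Z is invariant under positive affine transforms of the sample
vector; negating a sample negates its Z-scores.

δ uses the n−1 (sample) denominator by default, matching the PGSEA
lineage; a `ddof=0` switch exposes the population version. A constant
sample vector (δ = 0) is an error, not a NaN.

**Set preparation.** Sets are intersected with the measured gene universe
and kept iff 22 ≤ m ≤ 800 (inclusive bounds; removal is strict-below /
strict-above). Both bounds are configurable. Very small sets make Z
noisy; very large sets drag S_m toward μ by construction.

**Correlation and relative ranks.** Spearman correlation (Pearson on
midranks, average ranks for ties) compares each gene's profile with each
set's Z profile. Coefficients are undefined (NaN) for constant profiles
and excluded from all rank computations rather than imputed as zero,
which would bias the center. The full distribution of finite coefficients
is translated to mean 0; coefficients are ranked by |rho − center|
descending with average ranks for ties, and divided by the count of
finite coefficients. Average-rank tie handling matches the midrank
convention used for Spearman itself and makes the ranks stable under
permutation of the matrix.

Within-gene ranking uses the relative rank (equivalently |rho − center|);
ties anywhere are broken lexicographically by name so all orderings are
deterministic.

**Leave-one-out (LOO).** When ranking genes against one set, a member
gene's own fold-change contributes 1/m of S_m, which induces a spurious
correlation of roughly 1/(m·SD(S_m)) — material for small sets. Member
genes are therefore correlated against scores recomputed on the set minus
that gene (μ and δ are unchanged: they are whole-sample statistics).
Removal below m − 1 = 2 is refused.

**Directional sets.** Sets whose names match the configurable
case-insensitive pattern `_DN$` are flagged "down"; their correlations
are reported sign-flipped (`reported_rho = −rho`, `flipped = true`).
Magnitude-based relative ranks are unaffected.

**Overrepresentation.** Gene lists from external tools are scored per set
with the upper-tail hypergeometric probability P[X ≥ overlap], observed
overlap included (the standard overrepresentation convention). Set sizes
are counted inside the user-supplied universe, because universe mismatch
is the dominant source of irreproducible enrichment p-values. No
multiple-testing correction is applied; results are an ordering aid.

## Synthetic data generator

The generator emulates the minimal structure under which the method's
claims are provable: per module *k*, a latent per-sample activity
a<sub>k,t</sub> ~ N(0, latent_sd²) drives member and hidden genes as
x<sub>g,t</sub> = β<sub>g</sub>·a<sub>k,t</sub> + ε with β uniform on a
loading range and ε ~ N(0, noise_sd²); background genes are pure noise;
decoy sets are random background draws. The closed form
corr(gene, latent) = β·σ_a/√(β²σ_a² + σ_ε²) anchors a Monte-Carlo test.
Randomness is split into named substreams (module structure, noise,
decoys) derived from the master seed, so changing the decoy count never
perturbs module values.

Default conditions — 2,000 genes × 300 samples, one module of 60 members
plus 30 hidden genes, β ∈ [0.8, 1.2], latent_sd = noise_sd = 1, 30 decoy
sets of 25–100 genes — give per-gene signal-to-noise (corr ≈ 0.7 with the
latent) comparable to strongly co-regulated pathways in tumor compendia,
at a size that runs in seconds. Decoy sizes span the small end of the
kept-set range, where enrichment scores are noisiest.

What the generator does **not** emulate: tissue-block structure,
heteroskedastic or heavy-tailed noise, overlapping sets, correlated
modules, and the ~18,000-gene universe of a real array. Two consequences
matter when reading test results. First, recovery numbers here are upper
bounds on real-data performance. Second, with only ~5% of genes in
modules, the module signal leaks into each sample's background mean μ, so
decoy-set Z-scores pick up a mild anticorrelation with module genes; on a
genome-scale universe this dilution artifact shrinks by an order of
magnitude. The relative-rank machinery orders associations correctly
despite it, which is itself part of what the recovery test demonstrates.

## Numerical choices

- The scalar Z and Spearman definitions are the contracts; vectorized
  paths must match them to ~1e-12.
- The correlation matrix is computed in gene blocks (default 1024 rows)
  with one matrix-vector product per gene, which makes results
  bit-identical across block sizes (batched GEMM kernels may round
  differently per shape). Expression arrays are forced C-contiguous for
  the same reason.
- Serialized tables are written at 17 significant digits so round trips
  are exact for finite doubles; missing values round-trip as empty cells.
- Undefined correlations stay NaN end to end and are excluded from
  n_finite.

## Problem sizes used in tests

Unit tests use fixtures of ≤ 50 genes checked against scalar oracles
(hand evaluation, exhaustive enumeration, independent midrank-Pearson).
The end-to-end recovery test and the acceptance script use the default
generator conditions above; the autocorrelation check uses a 25-member
pure-noise set over 500 samples, where theory predicts a naive
correlation of ≈ 1/√25 = 0.2 collapsing to ≈ 0 under LOO.

## Known limitations

- Overlapping gene sets make associations non-independent; relative ranks
  order them but carry no error rate.
- The enrichment score assumes an approximately symmetric fold-change
  distribution per sample; heavy skew inflates |Z| for all sets at once.
- Standardization requires at least one control per tissue group and does
  not attempt batch correction.
- The exclusion list for uninterpretable sets (e.g. unnamed cancer
  modules) is user-supplied, not curated here.
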
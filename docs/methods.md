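# Methods

This note records the models behind each module, the defaults and why,
and the choices made where the design was genuinely open.

## Synthetic data

**Soil tables.** Each replicate plot draws every variable from a normal
with the per-treatment mean and SD, truncated at zero by whole-row
resampling (never clipping), which keeps the marginals continuous —
important because the downstream ANOVA assumes continuous responses.
The bundled parameters (`data/sros2_soil_params.tsv`) are the published
group means ± SD of the four-stage rotation experiment: pH, EC (μS/cm),
SOC (%), TN (%), AP and AK (mg/kg) and the five enzyme activities
(μmol product g⁻¹ soil d⁻¹), for treatments B1–B4 with three replicate
plots. Variables are drawn independently by default because only group
means ± SD are published, not covariances; a Gaussian-copula correlation
matrix can be injected for testing the correlation stage. Micronutrient
parameters (`data/sros2_micronutrients_synthetic.tsv`) are **synthetic**:
only relative changes of Ca, Mn, S and Zn were reported, so baselines
typical of a yellow-brown facility soil were fixed once and scaled to
match those relative changes. The generator treats the plot as the
experimental unit and does not model within-plot subsample pooling.

**Count matrices.** Per sample, basis abundances are log-normal with a
configurable mean vector and covariance (treatment effects enter as log
fold-changes), closed to proportions and sampled multinomially at a
fixed read depth (default 60,000 reads/sample, the target depth of the
emulated sequencing design). Column sums therefore equal the read depth
exactly. This is precisely the generative model SparCC assumes, which
makes network recovery a fair test: the implied basis correlation matrix
is returned alongside the counts as the oracle. What this model does
*not* emulate: overdispersion beyond multinomial noise, taxa appearing
or vanishing between treatments discontinuously, chimeras/contaminants,
or phylogenetic structure — so passing recovery tests demonstrates
correctness of the estimator under its own assumptions, not performance
on arbitrary real communities.

**Latent datasets.** Exogenous latent scores are standard normal; each
endogenous score is the true-coefficient combination of its predecessors
plus normal noise. The default structural residual SD is
√max(1 − Σβ², 0.05), chosen so scores have unit variance when
predecessors are independent; it is configurable per latent. Indicators
are reflective: loading × latent + N(0, √(1 − λ²)), then standardized.
Acyclicity is enforced structurally (predictors must precede responses
in the latent order).

**Seeding.** One master seed expands into named substreams by hashing
the stream name (CRC-32) into the spawn key of a `SeedSequence`. Adding
a generator never perturbs another generator's stream, and every
pipeline stage is reproducible from the config seed alone.

## Treatment statistics

Percent change is 100·(treatment − control)/control on group means,
displayed to one decimal. One-way ANOVA uses the classical between/within
decomposition; perfect separation (zero pooled within-group variance,
differing means) is reported as F = ∞ with p = 0 rather than an error.
The letter display implements *protected* LSD: pairwise t tests (pooled
MSE, within-group df) run only when the omnibus F is significant at α,
matching standard LSD practice. Letters are assembled with the
insert-and-absorb algorithm, so two groups share a letter exactly when
their comparison is non-significant, and letters follow descending
means. Correlation p-values are raw (no multiplicity correction), as is
conventional for starred correlation heatmaps.

One published inconsistency is deliberately not smoothed over: the
narrative pH increase (+0.57 units) does not equal the tabulated group
difference (8.05 − 7.68 = 0.37); the package reproduces the tabulated
arithmetic.

## Enzyme stoichiometry

The vector formulas operate on raw log activities (the literal
formulation): L = √([ln BG]² + [ln(NAG+LAP)]²),
A = arctan(ln(NAG+LAP)/ln BG) in degrees, with the limit convention
A = 90° when ln BG = 0 and ln(NAG+LAP) > 0. Activities ≤ 1 make a
logarithm non-positive and break the first-quadrant interpretation;
such inputs are flagged with a warning (never clipped) and the
limitation classification refuses flagged angles. The classification is
nitrogen below 45°, phosphorus above, balanced at exactly 45°.

Applied to the published control-stage group means, the literal formula
gives A ≈ 39.8°, which does not match the published per-sample angle
range (27.2°–30.9°); the printed angles are evidently not derivable from
group means with this formula (likely per-replicate computation on
unpublished data or a different normalization). The package therefore
treats the formula, not the printed range, as the contract. A
relative-proportion variant (x = BG/(BG+ALP), y = BG/(BG+NAG+LAP),
angle = atan2(x, y)) is available behind `mode="relative"` for
sensitivity analysis; the literal formula stays the default.

## Community analysis

Chao1 is the bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)),
defined even when doubletons are absent — the right choice for sparse
synthetic data. "Simpson" defaults to Gini–Simpson (1 − Σp²), with the
classical dominance D behind a flag, because the bare name is ambiguous
in the literature. Bray–Curtis is computed on raw counts by default (the
generated matrices share one read depth, so proportion-normalization is
a no-op there); `relative=True` enables proportion input for unequal
depths.

PCoA Gower-centers the squared distances and eigendecomposes; when the
most negative eigenvalue's magnitude exceeds 1e-8 the Cailliez additive
constant is applied (the standard remedy for non-Euclidean Bray–Curtis
matrices) and tagged in the result. Explained proportions are over
positive eigenvalues only.

PERMANOVA uses the distance-based decomposition (total minus
within-group sums of squared distances), free permutation of labels (no
strata — the design gives no reason to restrict), and
p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1). Permutations are evaluated
vectorized over one-hot group membership, which keeps the 500-simulation
type-I calibration in the test suite around seconds. Note that with very
small groups a permutation can recreate the observed partition, so the
attainable minimum p is slightly above 1/(n_perm+1) there; calibration
tests use group sizes where this is negligible.

## Co-occurrence networks

SparCC is implemented in full: fractions → log-ratio variation matrix
T_ij = var(log x_i/x_j) → basis variances from the sparsity
approximation (t_i = (D−2)ω_i² + Σω_j²) → ρ_ij clipped to [−1, 1], with
iterative exclusion of the strongest pair above 0.8 (at most ⌊D/3⌋
pairs, the reference defaults), re-solving the system with the excluded
pair's contribution removed. At least 4 taxa are required (the basis
system is underdetermined below that) and at least 5 samples. Zeros are
handled by a pseudocount of 1 by default — deterministic and adequate at
the read depths generated here; Dirichlet resampling (α = count+1,
median over 20 inner iterations) is available by flag.

Edge significance: each taxon's counts are permuted independently across
samples, SparCC re-estimated (pseudocount mode, no exclusions — under
the null there are no strong pairs to exclude), and two-sided p-values
formed per pair; Benjamini–Hochberg over the upper triangle gives q. The
retention rule is |ρ| > 0.6 and q < 0.01 (the published cutoffs);
isolated nodes are dropped from the reported network by default, as is
typical in co-occurrence reporting, with a keep-isolates flag.

Worth knowing: at very small sample numbers (e.g. 12 samples over 15
taxa) the null basis-variance solve frequently degenerates and null
|ρ| reaches 1, so permutation q-values cannot clear 0.01 regardless of
signal. The demo therefore sequences 10 samples per treatment for the
community matrices, and builds networks on the 15 most abundant taxa —
mirroring the common practice of inferring coarse networks on the top
phyla. A lineage-aggregation helper (`aggregate_taxa`) supports true
phylum-level networks when taxonomy strings are available. Topology
metrics come from networkx; modularity is that of the greedy
agglomerative partition on the unweighted edge set.

Published method descriptions of this stage sometimes mix incompatible
tools (a neighborhood-selection package alongside SparCC ρ thresholds);
this package implements SparCC because the retention rule it targets is
expressed in SparCC's ρ.

## PLS path modeling

Mode A (reflective) throughout — the indicator lists are published
without a mode, and reflective is the conventional default. All three
inner weighting schemes are implemented; the default is `path` (the
scheme is not published; path weighting is the usual choice for
directed structural models, and on well-conditioned data the schemes
agree — asserted within 0.05 in the tests). Convergence is max absolute
outer-weight change < 1e-6 (weights compared after unit-norm scaling)
with a 300-iteration cap; non-convergence raises with the last delta.
Latent scores are re-standardized at every step, so unit variance is
exact. The global sign indeterminacy is fixed by requiring each latent's
largest-|loading| indicator to load positively — necessary for
aggregating bootstrap draws. The rotation treatment enters the bundled
six-latent model as a single ordinal indicator 1–4 (the stages form a
temporal sequence); users can substitute one-hot dummies in a custom
model file.

Structural coefficients are OLS on the converged scores; R² per
endogenous latent; communality = loading²; AVE = mean squared loading
per block; GoF = √(mean communality × mean R²), recomputable from the
stored parts to machine precision, with the conventional
GoF > 0.6 = excellent-fit reading exposed as a flag. The bootstrap
resamples rows with replacement, refits, and reports mean, SE,
percentile 95% CI and a smoothed two-sided sign-count p-value
(2·min(#{β* ≤ 0}, #{β* ≥ 0}) + 1)/(n+1); the reference R implementation
reports only bootstrap SEs, so the p-value construction is this
package's own. More than 10% failed resamples aborts with diagnostics.

The published path coefficients (β = 0.92, −0.501, 0.53) and GoF = 0.748
would require the original replicate-level data (n = 12 for six latents)
and are not reproduction targets; correctness is instead established by
the single-indicator reduction to OLS path analysis (exact to 1e-8) and
by parameter recovery on the latent generator (β = 0.8 recovered within
±0.1 at n = 500, zero paths covered by 95% bootstrap CIs at the nominal
rate).

## Problem sizes and calibration checks

The test suite and acceptance script size their simulations as follows:
ANOVA type-I, 1,000 simulations at the 4×3 design; PERMANOVA type-I,
500 (suite) / 300 (script) simulations at 999 permutations; SparCC
recovery, 40 taxa × 200 samples with one planted basis correlation of
0.9 (top-ranked with ρ > 0.6, shuffled-null 95th percentile < 0.4);
bootstrap coverage, 200 replications at n = 100 with n_boot = 200.
These sizes give stable pass/fail behavior under the seeded streams
while keeping a full run to a few minutes.

## Known limitations

* SparCC permutation p-values are unreliable below ~20 samples (null
  degeneracy described above); the package does not hide this — it
  simply returns the honest large p-values.
* The soil-table generator draws variables independently unless a
  correlation is supplied; published cross-variable correlations (e.g.
  EC–pH r = −0.87) are not reproduced by default.
* PLS-PM assumes linear relations among scores and listwise-deletes
  missing rows.
* No figure rendering, rarefaction, phylogenetic diversity, RDA, or
  differential-abundance methods — out of scope.
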
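# Methods

This note records the statistical models the package implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Data model and pre-processing

The central object is a samples × taxa matrix of nonnegative wet-weight
biomass concentrations (µg L⁻¹ equivalent). Proportions are unit-free, so
biovolume-calibrated biomass works identically provided units are
consistent across taxa. Missing biomass entries are treated as structural
zeros (absence); "present" always means biomass strictly > 0.

*Season/layer filter.* Summer windows are basin-specific: July–September
in the Baltic Proper, August–September in the Gulfs of Finland and Riga.
Community analyses default to the 1994–2004 year window, inside which the
summer community composition is regime-stable. An unknown basin label is
an error that lists the permitted labels, rather than a silent drop.

*Diazotroph partition.* The heterocystous genera *Aphanizomenon*,
*Nodularia*, *Dolichospermum* and *Anabaenopsis* are matched
case-insensitively against the leading genus token of the taxon id (or the
genus rank of the taxonomy when present). Bloom intensity is diazotroph
biomass over total biomass per sample; zero-biomass samples get proportion
0 with a warning. The ambient matrix excludes every matched taxon.

*Rare-taxon filter.* Taxa occurring in three or fewer samples are excluded
before ordination (`min_samples = 4`); the local-similarity screen requires
at least 10 occurrences per basin.

*Transformations.* Ordination input is square-root transformed then
Wisconsin double standardized (taxon ÷ taxon maximum, then sample ÷ sample
total), so every nonempty row sums to one; the chain is idempotent only in
the single-taxon case. LSA input is rank normal scores: average ranks for
ties mapped through the standard normal quantile at r/(n+1) (the van der
Waerden variant — the rank-to-quantile rule is not uniquely determined by
convention, and this is the common default), then rescaled to unit sample
variance. The unit-variance rescaling is what makes the |LS| ≤ 1 bound
exact (Cauchy–Schwarz over any subinterval). Constant inputs give all-zero
scores with a degeneracy warning.

## Resource use efficiency

RUE_P = ln(Chl a / TP) and RUE_N = ln(Chl a / TN), each computed over its
own complete positive chlorophyll–nutrient pair and z-scored (sample sd)
over its non-missing rows, which is why the two responses can have
different n. z-scoring makes slopes of the two responses directly
comparable and removes the additive constant from any joint unit change.

The regression is `z(RUE) ~ s(lat, lon) + β · asin(√p)`. The smooth is a
thin-plate-type radial basis, φ(r) = r² log r, on standardized
coordinates with up to 30 knots spread deterministically over the observed
locations, ridge-penalized with the penalty chosen by generalized
cross-validation, GCV(λ) = n·RSS/(n − edf)², over a log-spaced grid
(10⁻⁴–10⁵). The parametric part (intercept, linear lat/lon, the
proportion term) is unpenalized. The slope's standard error comes from the
sandwich covariance (XᵀX + λS)⁻¹XᵀX(XᵀX + λS)⁻¹·σ̂² with σ̂² =
RSS/(n − edf); the p-value is a two-sided normal test. With the smooth
disabled the model collapses to OLS with linear lat/lon adjustment and the
slope equals the closed-form least-squares coefficient (used as the oracle
in tests). A constant proportion is a rank-deficient design and an error;
fewer than 30 complete cases is an error.

Slope comparisons use the independent-SE Wald statistic
z = (β_a − β_b)/√(se_a² + se_b²). When both slopes are estimated from the
same samples this ignores their covariance and is only approximate; the
approximation is documented rather than hidden behind a joint fit.

## Ordination and variance partitioning

*Bray–Curtis* comes from scipy; an all-zero row pair has undefined
dissimilarity and is set to 0 with a warning.

*NMDS* delegates the isotonic-MDS inner loop to scikit-learn (metric=False,
best stress over `n_restarts` random starts, normalized stress-1). The
contribution here is the permutation assessment around the ordination, not
the SMACOF iteration. Dimensionality defaults to k = 2 with 4 restarts;
both are logged parameters, not constants.

*Vector fitting.* R² of the least-squares regression of the external
variable on the ordination coordinates; direction is the normalized
coefficient vector; p by permuting the variable across samples, 999
permutations by default.

*CCA.* The community matrix is chi-square standardized,
Q = (P − rcᵀ)/√(rcᵀ); total inertia is ‖Q‖²_F. Constraints are
row-weight centred, scaled by √r and the constrained inertia is the squared
norm of the least-squares projection of Q onto that space. Conditions are
partialled out first by the same weighted projection (conditioned inertia),
and the constraints are residualized on the conditions so the permutation
test permutes residualized constraint rows. The Pythagorean decomposition
constrained + conditioned + residual = total is checked to 1e−8 in tests
with the residual computed from the residual matrix itself. The default
199 permutations match the granularity of a p = 0.005 report; the count is
configurable.

*PERMANOVA.* Gower-centred inner product G = −½·J D² J; for a covariate
design X (continuous columns or dummy-coded categories) with hat matrix H
of the centred design, SS_model = tr(HG), SS_total = tr(G), pseudo-F =
(SS_model/df_m)/(SS_resid/df_r); p by permuting covariate rows. The
4-point line instance (SS_total 101, SS_model 100, F 200, exact
enumeration p = 1/3) is kept as a frozen hand oracle.

All permutation p-values use (1 + hits)/(1 + n_perm) and can never be 0.

## Local similarity analysis

For score series x, y the LS statistic is the maximal-magnitude sum of
products over a contiguous subinterval, signed and divided by n, computed
by a two-direction Kadane dynamic program and verified exhaustively in
tests for n ≤ 12. `max_delay` defaults to 0: the order-randomization
wrapper deliberately destroys serial structure, which makes time lags
meaningless; the parameter remains available for genuinely regular series.

The wrapper applies one shared random sample order per shuffle to all taxa
and the target (preserving cross-taxon comparability within a shuffle),
1000 shuffles by default, and reports the per-taxon mean and sd of LS with
a significance flag that requires every shuffle to agree in sign.

A caution established by simulation in the test suite: a shared
permutation leaves Σxᵢyᵢ unchanged, so the shuffle distribution is
concentrated around a data-dependent centre, and the all-same-sign rule
fires for ~40% of completely independent series pairs at n = 60. The flag
therefore separates clearly coupled taxa (which are flagged essentially
always, with large |mean LS|) from weakly associated ones, but it is not a
size-α test and should not be read as one. The positive/negative balance
among flagged taxa is tested against 0.5 with the continuity-corrected
1-sample proportion statistic z = (|k − n/2| − 0.5)/√(n/4), two-sided.

## Trait and phylogenetic convergence

Gower distances average, over each pair's non-missing traits, the binary
mismatch and |Δ log size|/range(log size), giving distances in [0, 1];
pairs with no shared trait are missing with a warning. Taxonomic distances
use topology only: d = (index of the lowest shared rank)/(number of
ranks), index 0 being the same terminal taxon, so two congeneric species
are at 1/6 with the six-rank default and taxa sharing nothing are at 1.
The optional Newick export writes the matching equal-height dendrogram.

Weighted MPD is Σ_{i<j} wᵢwⱼdᵢⱼ / Σ_{i<j} wᵢwⱼ with per-taxon weights
wᵢ = LSᵢ + 1 (+10⁻⁹ positivity guard) — the rescaling constant is fixed at
1 because LS ∈ [−1, 1]. The null shuffles the LS labels across the taxa in
the analysis set (9999 draws by default); SES = (obs − null mean)/null sd,
flagged undefined when the null sd vanishes (constant LS). One-tailed
proportions are reported in both directions; negative SES means trait or
clade convergence among positively associated taxa.

## Niche separation

The niche position of a species along temperature, salinity, distance to
shore or day of year is the variable's weighted mean with the species'
per-sample biomass proportions (or biomasses) as weights. The test
statistic is the difference of the two species' weighted means; the null
swaps the pair of weights within each sample independently with
probability ½ — the literal within-sample shuffle — rather than permuting
weights across samples, which would confound the niche contrast with the
marginal distribution of bloom intensity. Two-sided by default, one-sided
via `alternative="greater"`.

## Synthetic generator

`generate_dataset` emulates the statistical structure the analyses assume;
its defaults are the study conditions the pipeline targets:

- total diazotroph proportion ~ Beta(0.6, 3.0) (mean 1/6, strongly
  right-skewed, matching a 0.17 ± 0.19 / median 0.10 regime), *Nodularia*
  ~ Beta(0.25, 6.0) truncated at the total (far more skewed), the
  remainder split 95/5 between *Aphanizomenon* and *Dolichospermum*;
- per-basin sampling (GOF/GOR/BP round-robin) with basin-specific summer
  months, years 1994–2004, jittered basin-centre coordinates;
- planted niche offsets delta_t = 1.0 °C, delta_s = 0.08, delta_d = 7 km:
  each variable receives c·v with v the normalized *Nodularia*-minus-
  *Aphanizomenon* proportion contrast and c calibrated against the
  realized proportions so the deterministic part contributes exactly the
  planted weighted-mean difference, while the noise part stays mean-zero
  (so delta = 0 yields an honest null, not a degenerate one);
- RUE structure: log TP lognormal, Chl a built so z(RUE_P) carries slope
  beta_p = 0.31 on asin(√p) plus a low-order polynomial spatial surface
  (which a correctly specified smooth can absorb) plus Gaussian noise
  (sd 0.45); TN constructed so z(RUE_N) carries beta_n = 0.15. The raw
  slope is rescaled analytically so the planted value is on the z-score
  scale; infeasible combinations (β²·var(g) ≥ 1) warn and fall back;
- ambient taxa: log-normal biomasses, per-taxon occupancy in [0.55, 1],
  30% of taxa tilted positively and 30% negatively against the
  standardized proportion with strengths U(0.4, 0.9) — mixed positive and
  negative associations of realistic magnitude;
- optional convergence: the top quartile of positively associated taxa
  share a clade (class/order/family) and a three-trait block.

What the generator does **not** emulate: bloom phenology and succession,
N-fixation biogeochemistry, spatially autocorrelated sampling effort,
taxonomic mis-identification, or detection limits. Passing recovery tests
therefore demonstrate that each estimator finds the effects it is designed
for under its own assumptions — not that monitoring data satisfy those
assumptions.

`make_worked_fixture` is a 10-sample × 8-taxon hand-entered dataset whose
partition proportions, filter outcomes and standardization chain are
verified against hand arithmetic in the unit tests.

## Problem sizes and reproducibility

The acceptance script generates 600 samples × 60 ambient taxa, runs the
per-basin community statistics on one 200-sample basin (the per-basin
scale of the emulated design), LSA with the full 1000 shuffles, and
SES-MPD with 9999 nulls. Recovery tests in the suite use 50 replicates at
n = 500 for slope and niche power, 200 runs for type-I calibration, and
800 independent runs for SES null calibration (keeping the Monte-Carlo
error of the estimated mean well inside the ±0.1 acceptance band). Every
stochastic component takes an explicit seed; identical seed + parameters
reproduce bit-identical datasets and results.

## Known limitations

- The GCV ridge penalty on a radial basis is a close cousin of, but not
  identical to, a full thin-plate spline fit; smooth effective df are
  reported so fits can be compared across engines.
- `compare_slopes` assumes independent fits (see above).
- The sign-consistency LSA flag is descriptive, not a calibrated test
  (see the simulation note above).
- Gower distances treat all binary traits as equally informative; no
  trait weighting is implemented.
- The taxonomy distance uses a fixed rank ladder; unequal taxonomic depth
  across lineages (common in polyphyletic "phytoplankton") compresses
  some clades.
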
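# Methods

This note records the models, the numerical choices, and what the
synthetic data generator does and does not emulate. It is the package's
own account; every empirical claim below is computed by the test suite
or by `scripts/acceptance.py`.

## Data model

A survey yields a sites × species incidence (0/1) matrix, a per-site
environment table, planar site coordinates, and an ecological-status
label per lake (high / good / moderate / poor). Abundance values are
only reduced to presence/absence behind an explicit flag — silent
coercion would hide unit mistakes. The packaged species catalogue lists
104 boreal-lake macrophyte taxa (hybrids and subspecies are distinct
taxa) in four life-form groups: 26 shore plants, 19 helophytes, 49
rhizophytes, 10 free-floating species. Because only two lakes carry the
"poor" label in the emulated design, "poor" is pooled into "moderate"
for all analyses; the two pooled lakes are additionally dropped from
PERMANOVA and dispersion tests, which are sensitive to unequal group
sizes. Lakes with zero richness of a life-form group stay in the
richness models (the response becomes log10(n+1)) and leave only the
dissimilarity stages — exclusion is stage-local and logged.

## Derived environmental quantities

* **SDF** = shoreline length / (2√(π·area)); 1 for a circle.
* **PAC** = first principal component of pH, alkalinity and
  conductivity, computed on the correlation matrix so the three
  differently-scaled variables are commensurable; the result is
  invariant to affine rescaling of any input. The sign is fixed so the
  pH loading is positive — orientation affects only coefficient signs.
  The variance fraction is the leading eigenvalue over 3 and, with the
  printed pairwise correlations (0.740, 0.936, 0.806), equals 88.58 % —
  denominator conventions (n vs n−1) do not change it.
* **Levene tests** default to center = mean (the classical Levene
  statistic); Brown–Forsythe (median) is an option.
* Group summaries report t-based 95 % CIs and the conservative
  "CIs do not overlap" difference flags.

## The null model and dissimilarity deviation

Observed pairwise dissimilarity is incidence-based Sørensen,
d = (b+c)/(2a+b+c). The null hypothesis is random assembly holding each
site's richness and each species' occurrence frequency fixed, with no
dispersal limitation. Per pair, SES = (D_obs − mean_null)/sd_null, with
sd from the n−1 estimator (immaterial at 999 iterations but fixed for
bit-reproducibility). Pairs whose null SD is zero (e.g. a saturated
matrix) are masked undefined. One null matrix is drawn per iteration —
all pairs share the iteration's draw — and each iteration's RNG
substream is spawned from the seed by iteration index, so changing the
iteration count never reshuffles earlier draws.

**Sampler choice (a deliberate design decision).** Two readings of a
"fixed–fixed" null coexist in the literature. The *weighted pool*
reading draws, per site, exactly its richness by successive weighted
sampling without replacement with rates tied to occupancy. The
*margin-exact* reading (curveball trades) randomizes with both margins
held exactly. We measured the centring of both on data assembled by the
null process itself at study scale (66 × 104, richness 16–45): the
weighted sampler with rates literally proportional to occupancy counts
gives mean SES ≈ −0.36 (inclusion probabilities saturate and flatten the
null occupancy profile); recalibrating the rates so expected occupancy
matches observed counts (a Poissonized margin fit, available as
`calibrate_pool_rates`) overshoots to ≈ +0.14 because the realized
counts are one noisy draw; the curveball sampler is centred (≈ +0.01)
with no tuning. The curveball is therefore the default; the weighted
sampler (either rate convention) remains available for sensitivity
analysis. Each curveball draw restarts from the observed matrix and
performs 5n trades, the standard mixing recommendation.

**Non-negativity shift.** SES values can be negative, but the
distance-matrix tests need non-negative dissimilarities, so the
deviation matrix is translated by −min(SES) before testing and the shift
constant is recorded in the run record. The permutation statistics are
not strictly shift-invariant (Gower centering is quadratic in the
entries); a sensitivity test in the suite confirms statistics change
smoothly with the constant, which is why the constant is reported.

## Distance-matrix tests

All three tests build on G = J(−½ D∘D)J (Gower centering; J the
centering projector).

* **PERMANOVA**: pseudo-F from between/within sums of squared
  distances, one-way design, whole-row label permutation. Reduces
  exactly to the classical ANOVA F for Euclidean distances on
  univariate data.
* **Dispersion homogeneity**: PCoA retaining real and imaginary axes;
  distance of a site to its group centroid uses
  z² = d²_real − d²_imag truncated at 0 (the standard correction for
  non-Euclidean dissimilarities — verified to 1e-9 against the
  reference R implementation on a Sørensen matrix with negative
  eigenvalues); F is a one-way ANOVA on z, with p by permuting the
  least-squares residuals of z.
* **MDMR**: omnibus statistic tr(HGH)/tr(QGQ) and pseudo-R² =
  tr(HGH)/tr(G); per-predictor conditional effects are drops in
  explained trace when the predictor's columns leave the design,
  with Freedman–Lane permutation under the reduced model
  (G* = B G Bᵀ, B = H_r + P(I−H_r)). Categorical predictors are
  treatment-coded. Analytic quadratic-form p-values are deliberately out
  of scope: permutation p-values agree to Monte-Carlo error and keep the
  module self-contained; the conditional permutation scheme's type-I
  error is verified at 0.05 ± 0.02.
* p-values use (1 + #{stat* ≥ stat})/(1 + n_perm); ties count as ≥
  (conservative); all results are bit-reproducible given the seed.

## Spatial eigenfunctions and forward selection

PCNM: pairwise Euclidean distances, truncation at the longest minimum-
spanning-tree edge (configurable), distances beyond the threshold
replaced by 4× the threshold, PCoA, keep positive-eigenvalue
eigenvectors (unit norm). Output matches the reference R implementation
to 1e-8 on a fixture. On an equidistant transect the eigenvectors are
sinusoids; note the *leading* axis under this truncation rule is a
roughly one-period sinusoid, not the broadest half-cosine.

Forward selection by db-RDA operates directly on G (McArdle–Anderson)
rather than PCoA-then-RDA — mathematically equivalent and free of
axis-truncation choices. At each step the candidate adding the most
explained trace enters if its conditional permutation p ≤ α (default
0.05); an optional adjusted-R² double-stopping rule is off by default.
Because the tested candidate is the best of many, the step-wise test is
anti-conservative under the null (the suite measures the empirical
family-wise selection rate rather than pretending it is α); the planted-
signal recovery rate is the meaningful operating characteristic and is
≥ 90 % at the default settings.

## Richness models

Candidate set: all 2⁵ − 1 = 31 non-empty subsets of
{Secchi, SDF, TP, PAC, status}, each plus total transect length (the
sampling-effort control; the effort-only model is not a candidate).
Responses and continuous predictors are log10-transformed by default
(PAC excluded; log10(n+1) for responses containing zeros). Status is
treatment-coded with "high" as reference. Fits are ML (not REML — AICc
comparisons across fixed-effects structures require ML) via GLS with a
fixed correlation matrix; the spatial range r in
ρ(h) = 1/(1+(h/r)²) (rational quadratic) or exp(−(h/r)²) (gaussian) is
profiled on a 25-point log grid spanning [1e-6, 10] × max inter-site
distance, refined by bounded scalar minimization; no nugget. k counts
intercept + slopes + residual variance + range parameter, a convention
fixed so AICc is internally consistent. Structure choice fits the full
model under all three structures and keeps the smallest AICc; measured
specificity on independent residuals is ≈ 0.89 and sensitivity under
strong spatial correlation ≈ 1.0.

## Synthetic lake generator

The generator emulates the study design the analyses assume: 21/22/23
lakes in high/good/moderate status, 104 species in the four life-form
groups, planar coordinates uniform on a square (a clustered mode exists
to exercise PCNM selection). Group-level environmental means are the
printed study means; SDs are recovered from the printed 95 % CI
half-widths (sd = hw·√n/t₀.₉₇₅,ₙ₋₁). TP, alkalinity, conductivity and
transect length are log-normal (moment-matched); Secchi and pH normal;
SDF is 1 + a moment-matched log-normal so SDF ≥ 1. pH, alkalinity and
conductivity share a latent factor (ρ = 0.9) so a PAC-style PC1 captures
most of their joint variance (≈ 0.85 in simulation vs 0.886 printed).
The distributional forms are module defaults, not claims about the real
lakes (only means/CIs are published).

Assembly is cell-independent Bernoulli with no dispersal limitation.
Filtered mode: logit P(s,i) = a_s + b_s·z_i + c·effort_i with
a_s ~ N(−1.2, 0.8), b_s ~ N(0.35, 1.0), c = 0.75, z a standardized
score of the realized trophic/water-quality environment and effort the
standardized log10 transect length. The positive mean of b_s plants the
richness gradient (moderate lakes more species-rich); the SD of b_s
spreads species optima so composition turns over along the gradient.
Neutral mode: effort sets each lake's richness through the same
logistic cells with b_s = 0, and species identities are then drawn from
the relative frequencies by the weighted sampler — the null model's own
generative process, so dissimilarity deviations are centred at zero by
construction.

What the generator does **not** emulate: spatial autocorrelation of the
environment (coordinates are independent of chemistry unless the
clustered mode is used), species interactions, abundance structure,
temporal dynamics, and detection error. Passing tests therefore show the
statistical machinery is correct and calibrated under the stated
assembly models — not that real lake data satisfy those assumptions.

A noteworthy emulated artifact: under neutral assembly the status groups
still differ slightly in richness (effort differs by group), which
inflates PERMANOVA and dispersion tests on the *observed* Sørensen
matrix. On the *deviation* matrix both return to nominal behaviour
(false-positive rate ≈ 0.05; dispersion not rejected in ≈ 95 % of
replicates) — precisely the richness confound the null-model correction
exists to remove.

## Problem sizes used by tests and the acceptance script

Type-I suites use 500–2000 replicates with small per-replicate n
(12–60 sites) and 99 permutations, an exact-level decision rule under
exchangeability. Power and recovery suites use the generator's default
study-scale datasets (66 × 104) with 100–199 permutations and 199–999
null iterations, and 100–200 replicates; GLS coverage uses n = 200 with
150–200 replicates. These sizes were chosen to make Monte-Carlo error
small relative to the tolerance bands while keeping the whole suite
runnable on one CPU in a few minutes.

## Known limitations

* The weighted-pool null sampler is not exactly centred (see above);
  the curveball default is, but conditions on both observed margins.
* MDMR reports permutation p-values only.
* One-way designs only (the status comparison); no stratified or
  multi-factor PERMANOVA.
* Forward selection p-values are selection-biased by construction, as
  in the standard implementations of this procedure.
* Geographic coordinates are treated as planar; no geodesic correction.
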
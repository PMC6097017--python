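# limnodiv

Statistical workflow for aquatic macrophyte diversity in lakes surveyed
along a human-impact (ecological status) gradient: null-model-corrected
beta diversity, distance-matrix hypothesis tests with spatial covariates,
and AICc-ranked species-richness regressions — plus a synthetic lake
generator so the entire chain is testable without field data.

## Who this is for

Community ecologists (and microbiome/metagenomics researchers with
analogous incidence data) who want to ask, for a set of sites grouped by
an impact label:

1. Which environmental variables drive **species richness**?
2. Do the same variables drive **community composition**, independently
   of richness?
3. Do impact groups differ in **mean composition** and/or in
   **beta diversity** (dispersion of composition within a group)?

## The statistics at the core

**Dissimilarity deviation (SES).** For each pair of sites with observed
incidence-based Sørensen dissimilarity `D_obs = (b+c)/(2a+b+c)`, a
fixed–fixed null model shuffles species identities while holding each
site's richness and each species' occurrence frequency fixed. From 999
null matrices,

```
SES = (D_obs − mean(D_null)) / sd(D_null)
```

SES < 0 means the two communities are more similar than random assembly
predicts (deterministic, niche-based assembly); SES ≈ 0 means richness
and occupancy alone explain the observed dissimilarity. The default null
sampler is the margin-exact curveball algorithm; a Raup–Crick-style
weighted pool sampler is available as an option.

**Distance-matrix tests** (all permutation-based, built on the
Gower-centered matrix `G = J(−½D∘D)J`): one-way PERMANOVA for mean
composition differences; the distance-based homogeneity-of-dispersions
test (multivariate Levene analogue, with the real/imaginary-axis
correction for non-Euclidean dissimilarities) for beta diversity; and
multivariate distance matrix regression (MDMR) giving omnibus and
per-predictor conditional effects via hat-matrix traces, with
Freedman–Lane residual permutation.

**Spatial covariates.** PCNM eigenfunctions (principal coordinates of the
truncated neighbour matrix; positive-eigenvalue vectors only) plus raw
coordinates, forward-selected by distance-based redundancy analysis.

**Richness models.** Generalized least squares with all 31 non-empty
subsets of {Secchi, SDF, TP, PAC, status}, every model carrying total
transect length to control sampling effort; optional rational-quadratic
or gaussian spatial residual correlation (range profiled by ML); models
ranked by `AICc = −2L + 2k + 2k(k+1)/(n−k−1)` with Akaike weights.
PAC is the first principal component of pH, alkalinity and conductivity
(correlation-matrix PCA).

## Worked example

```python
import numpy as np
import limnodiv as lv

ds = lv.simulate_lakes(lv.SimulationConfig(seed=42))   # 66 lakes, 104 species
cm = ds.community.drop_empty_sites()

ses = lv.ses_dissimilarity(cm, lv.NullModelConfig(iterations=999, seed=0))
lab = ds.labels.for_sites(ses.site_ids)
iu = np.triu_indices(len(lab), 1)
within = lab[iu[0]] == lab[iu[1]]
print(f"mean within-group dissimilarity deviation: {ses.ses[iu][within].mean():.3f}")

D_dev, shift = lv.shift_nonnegative(ses)
pr = lv.permanova(D_dev, lab, permutations=999, seed=0)
dr = lv.dispersion_homogeneity(D_dev, lab, permutations=999, seed=0)
print(f"PERMANOVA: F = {pr.statistic:.2f} (df {pr.df1},{pr.df2}), p = {pr.pvalue:.3f}")
print(f"dispersion: F = {dr.statistic:.2f} (df {dr.df1},{dr.df2}), p = {dr.pvalue:.3f}")
```

prints

```
mean within-group dissimilarity deviation: -0.836
PERMANOVA: F = 17.05 (df 2,63), p = 0.001
dispersion: F = 6.82 (df 2,63), p = 0.002
```

Read: within a status group, lakes share far more species than the null
model predicts (SES ≪ 0 — environmental filtering, not random sampling);
the three status groups differ strongly in mean composition; and in this
filtered-mode simulation the moderate group's wider environmental spread
also produces a dispersion difference. The full pipeline
(`limnodiv run-all`, or `limnodiv.run_all(...)`) repeats this per
life-form group on both the observed Sørensen matrix and the shifted
deviation matrix, adds the MDMR tables with forward-selected spatial
covariates, the richness model-selection tables, Levene variance tests
and group summaries, and writes everything as CSV plus a JSON run record
that makes every number reproducible from config + seeds.

The command line mirrors the library:

```
limnodiv simulate --seed 42 --out data/
limnodiv run-all --community data/community.csv --environment data/environment.csv \
    --labels data/labels.csv --catalogue data/catalogue.csv --seed 42 --out results/
```

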
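"""Species-richness regressions with AICc model selection.

The candidate set consists of every non-empty subset of five focal
predictors (Secchi depth, SDF, TP, PAC, status), each model additionally
carrying total transect length to control for sampling effort — 2^5 - 1 =
31 models per response.  Models are generalized least squares fits by
maximum likelihood, optionally with a spatial residual correlation
structure (rational quadratic or gaussian, range profiled), ranked by
AICc with Akaike weights.  One-way ANOVA plus the disjoint-CI rule covers
the direct group comparison of richness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .environment import GroupSummary, group_summary

FOCAL_PREDICTORS = ("Secchi", "SDF", "TP", "PAC", "status")
CORRELATION_STRUCTURES = ("none", "rational_quadratic", "gaussian")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: focal predictors plus the always-on effort term."""

    response: str
    predictors: tuple[str, ...]
    correlation: str = "none"
    effort_term: str = "transect_length"

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictor names")
        if self.correlation not in CORRELATION_STRUCTURES:
            raise ValueError(f"unknown correlation structure {self.correlation!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return (self.effort_term,) + self.predictors

    def label(self) -> str:
        return " + ".join(self.terms)


@dataclass(frozen=True)
class GlsFit:
    params: pd.Series
    bse: pd.Series
    loglik: float
    n: int
    k: int                       # intercept + slopes + residual variance (+ range)
    correlation: str
    corr_range: float | None
    aicc: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "aicc", aicc(self.loglik, self.k, self.n))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.n - (self.k - 1))
        return pd.DataFrame({"low": self.params - q * self.bse,
                             "high": self.params + q * self.bse})


def build_model_set(focal_predictors: Sequence[str] = FOCAL_PREDICTORS,
                    response: str = "richness",
                    correlation: str = "none") -> list[ModelSpec]:
    """All non-empty focal-predictor subsets, effort term always included.

    Five focal predictors give 31 candidate models; the effort-only model
    is not part of the set.  Order is deterministic: by subset size, then
    lexicographic.
    """
    focal = tuple(focal_predictors)
    if len(set(focal)) != len(focal):
        raise ValueError("duplicate predictor names")
    specs = []
    for r in range(1, len(focal) + 1):
        for combo in itertools.combinations(sorted(focal), r):
            specs.append(ModelSpec(response, combo, correlation))
    return specs


def aicc(L: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2L + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * L + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _correlation_matrix(structure: str, dists: np.ndarray, r: float) -> np.ndarray:
    if structure == "rational_quadratic":
        V = 1.0 / (1.0 + (dists / r) ** 2)
    elif structure == "gaussian":
        V = np.exp(-((dists / r) ** 2))
    else:
        raise ValueError(structure)
    np.fill_diagonal(V, 1.0)
    return V


def _gls_loglik(y, X, V) -> tuple[float, object]:
    """Profiled ML log-likelihood of a GLS fit with fixed correlation V."""
    model = sm.GLS(y, X, sigma=V)
    res = model.fit()
    return float(res.llf), res


def fit_gls(y, X: pd.DataFrame, correlation: str = "none",
            coordinates=None) -> GlsFit:
    """Maximum-likelihood GLS fit, optionally with spatial correlation.

    Residual correlation decays with inter-site distance h as
    rho(h) = 1/(1+(h/r)^2) (rational quadratic) or exp(-(h/r)^2)
    (gaussian); the range r is profiled on a log grid over
    [1e-6, 10] x max distance and refined locally.  ``correlation="none"``
    reduces exactly to OLS.  The parameter count k includes intercept,
    slopes, residual variance, and the range when present.
    """
    y = np.asarray(y, dtype=float)
    # treatment-code categoricals (status reference level = first category)
    Xd = sm.add_constant(pd.get_dummies(X, drop_first=True).astype(float),
                         has_constant="add")
    n, p = Xd.shape
    if n <= p + 2:
        raise ValueError(f"too few observations (n={n}) for {p} design columns")
    if correlation == "none":
        res = sm.OLS(y, Xd).fit()
        return GlsFit(res.params, res.bse, float(res.llf), n, p + 1, "none", None)
    if coordinates is None:
        raise ValueError("coordinates required for a spatial correlation structure")
    coords = np.asarray(coordinates, dtype=float)
    dists = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    dmax = dists.max()
    if dmax == 0:
        raise ValueError("all coordinates identical")

    def neg_ll(log_r: float) -> float:
        V = _correlation_matrix(correlation, dists, np.exp(log_r))
        V = V + 1e-10 * np.eye(n)
        try:
            ll, _ = _gls_loglik(y, Xd, V)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    grid = np.log(np.geomspace(1e-6 * dmax, 10 * dmax, 25))
    vals = np.array([neg_ll(g) for g in grid])
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo < hi:
        opt = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
        log_r = opt.x if opt.fun <= vals[best] else grid[best]
    else:
        log_r = grid[best]
    r_hat = float(np.exp(log_r))
    V = _correlation_matrix(correlation, dists, r_hat) + 1e-10 * np.eye(n)
    ll, res = _gls_loglik(y, Xd, V)
    return GlsFit(res.params, res.bse, ll, n, p + 2, correlation, r_hat)


def select_models(fits: Sequence[tuple[ModelSpec, GlsFit]]) -> pd.DataFrame:
    """Rank candidate fits by AICc with delta and Akaike weights.

    Returns a table sorted ascending by AICc with columns model, df, L,
    AICc, d (= AICc - min AICc) and w (= normalized exp(-d/2)), plus one
    coefficient column per predictor and a status-inclusion flag.
    """
    if not fits:
        raise ValueError("no candidate fits")
    responses = {spec.response for spec, _ in fits}
    ns = {fit.n for _, fit in fits}
    if len(responses) > 1:
        raise ValueError(f"mixed responses in one selection: {sorted(responses)}")
    if len(ns) > 1:
        raise ValueError("candidate fits use different sample sizes")
    rows = []
    coef_names: list[str] = []
    for spec, fit in fits:
        row = {"model": spec.label(), "df": fit.k, "L": fit.loglik, "AICc": fit.aicc,
               "correlation": fit.correlation,
               "status": "x" if "status" in spec.predictors else ""}
        for name, value in fit.params.items():
            if name.startswith("status"):
                continue
            key = "Intercept" if name == "const" else name
            row[key] = value
            if key not in coef_names:
                coef_names.append(key)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["d"] = table["AICc"] - table["AICc"].min()
    table["w"] = np.exp(-table["d"] / 2.0)
    table["w"] /= table["w"].sum()
    order = ["model", "df", "L", "AICc", "d", "w"] + coef_names + ["status", "correlation"]
    return table[order].sort_values("AICc", kind="stable").reset_index(drop=True)


def fit_model_set(y, env: pd.DataFrame, specs: Sequence[ModelSpec],
                  coordinates=None) -> pd.DataFrame:
    """Fit every spec against an environment table and rank by AICc."""
    fits = []
    for spec in specs:
        X = env[list(spec.terms)]
        fits.append((spec, fit_gls(y, X, spec.correlation, coordinates)))
    return select_models(fits)


def choose_correlation_structure(y, X: pd.DataFrame, coordinates) -> tuple[str, pd.Series]:
    """Pick the residual correlation structure by AICc on the full model.

    Fits the same fixed effects under no correlation, rational quadratic
    and gaussian structures; returns the winning label and the AICc of
    each structure (deltas to "none" are the reported diagnostic).
    """
    aiccs = {}
    for structure in CORRELATION_STRUCTURES:
        try:
            fit = fit_gls(y, X, structure, coordinates if structure != "none" else None)
            aiccs[structure] = fit.aicc
        except (ValueError, np.linalg.LinAlgError):
            aiccs[structure] = np.inf
    series = pd.Series(aiccs)
    return str(series.idxmin()), series


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df1: int
    df2: int
    pvalue: float
    summary: GroupSummary


def anova_group_comparison(richness, groups) -> AnovaResult:
    """One-way ANOVA of richness across status groups, with CI flags.

    Groups are additionally "interpreted to differ" only when their 95%
    confidence intervals do not overlap (the conservative rule used for
    reporting).
    """
    richness = np.asarray(richness, dtype=float)
    groups = np.asarray(groups)
    keys = pd.unique(groups)
    samples = [richness[groups == k] for k in keys]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = stats.f_oneway(*samples)
    return AnovaResult(float(f), len(keys) - 1, len(richness) - len(keys), float(p),
                       group_summary(richness, groups))
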
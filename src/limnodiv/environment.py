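"""Derived environmental quantities and group-variance tests.

Covers the shoreline development factor (SDF), the compound water-quality
axis PAC (first principal component of pH, alkalinity and conductivity),
log10 transforms, Levene-style homogeneity-of-variance tests, and per-group
mean / 95% CI summaries with the "CIs do not cross" comparison rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PacResult:
    """First-principal-component summary of pH / alkalinity / conductivity.

    scores
        Per-site PC1 score (correlation-matrix PCA, pH loading forced
        positive so higher PAC means harder, more electrolyte-rich water).
    variance_fraction
        Leading eigenvalue / 3, the share of total standardized variance.
    loadings
        Unit-norm loadings in the order (pH, alkalinity, conductivity).
    """

    scores: np.ndarray
    variance_fraction: float
    loadings: np.ndarray


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    df_num: int
    df_den: int
    pvalue: float
    group_mean_abs_dev: dict


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean with t-based confidence interval, plus overlap flags."""

    table: pd.DataFrame          # index: group; columns: n, mean, ci_low, ci_high
    differing_pairs: tuple       # pairs of groups whose CIs do not overlap

    def differ(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.differing_pairs


def shoreline_development_factor(shoreline_length, lake_area):
    """SDF = shoreline length / (2 * sqrt(pi * lake area)).

    Equals 1 for a perfect circle and grows with shoreline convolution;
    used as a habitat-heterogeneity proxy.  Units: length in m, area in m2.
    """
    length = np.asarray(shoreline_length, dtype=float)
    area = np.asarray(lake_area, dtype=float)
    if (length <= 0).any() or (area <= 0).any():
        raise ValueError("shoreline length and lake area must be positive")
    return length / (2.0 * np.sqrt(np.pi * area))


def extract_pac(ph, alkalinity, conductivity) -> PacResult:
    """Compound PAC axis: PC1 of the correlation matrix of the three inputs.

    Correlation-matrix PCA makes the differently-scaled variables
    commensurable; the result is invariant to affine rescaling of any
    input.  The PC1 sign is fixed so the pH loading is positive.
    """
    X = np.column_stack([np.asarray(v, float) for v in (ph, alkalinity, conductivity)])
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sites for PCA")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant variable: PCA on the correlation matrix undefined")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    lead = eigvals[-1]
    loading = eigvecs[:, -1]
    if loading[0] < 0:
        loading = -loading
    return PacResult(
        scores=Z @ loading,
        variance_fraction=float(lead / 3.0),
        loadings=loading,
    )


def pac_variance_fraction_from_correlations(r_cond_ph, r_cond_alk, r_ph_alk) -> float:
    """Variance fraction of PC1 from the three pairwise Pearson correlations.

    Convenience for checking a PCA against published pairwise correlations
    without the underlying site data.
    """
    R = np.array(
        [
            [1.0, r_cond_ph, r_cond_alk],
            [r_cond_ph, 1.0, r_ph_alk],
            [r_cond_alk, r_ph_alk, 1.0],
        ]
    )
    return float(np.linalg.eigvalsh(R)[-1] / 3.0)


def levene_test(values, groups, center: str = "mean") -> LeveneResult:
    """Levene's homogeneity-of-variance test (one-way F on absolute deviations).

    ``center="mean"`` is the classical Levene statistic; ``"median"`` gives
    the Brown-Forsythe variant.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    keys = pd.unique(groups)
    samples = [values[groups == k] for k in keys]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for k, s in zip(keys, samples):
        if len(s) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    stat, p = stats.levene(*samples, center=center)
    centers = {k: (np.mean(s) if center == "mean" else np.median(s)) for k, s in zip(keys, samples)}
    mad = {k: float(np.mean(np.abs(s - centers[k]))) for k, s in zip(keys, samples)}
    return LeveneResult(
        statistic=float(stat),
        df_num=len(samples) - 1,
        df_den=int(len(values) - len(samples)),
        pvalue=float(p),
        group_mean_abs_dev=mad,
    )


def log_transform(values, plus_one: bool = False) -> np.ndarray:
    """Elementwise log10(x), or log10(x+1) with ``plus_one``.

    log10(n+1) is the convention for counts that can be zero (free-floating
    species richness); plain log10 rejects non-positive input.
    """
    values = np.asarray(values, float)
    if plus_one:
        if (values < 0).any():
            raise ValueError("negative value under log10(x+1)")
        return np.log10(values + 1.0)
    if (values <= 0).any():
        raise ValueError("non-positive value under log10 (use plus_one for counts)")
    return np.log10(values)


def group_summary(values, groups, confidence: float = 0.95) -> GroupSummary:
    """Per-group mean and t-based CI, with pairwise disjoint-CI flags.

    Two groups are flagged as differing when their confidence intervals do
    not overlap — the conservative graphical rule used alongside one-way
    ANOVA for richness comparisons.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    keys = list(pd.unique(groups))
    rows = []
    for k in keys:
        s = values[groups == k]
        if len(s) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
        m = s.mean()
        half = stats.t.ppf(0.5 + confidence / 2, len(s) - 1) * s.std(ddof=1) / np.sqrt(len(s))
        rows.append((k, len(s), m, m - half, m + half))
    table = pd.DataFrame(rows, columns=["group", "n", "mean", "ci_low", "ci_high"]).set_index("group")
    differing = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            ra, rb = table.loc[a], table.loc[b]
            if ra["ci_low"] > rb["ci_high"] or rb["ci_low"] > ra["ci_high"]:
                differing.append(tuple(sorted((str(a), str(b)))))
    return GroupSummary(table=table, differing_pairs=tuple(differing))
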
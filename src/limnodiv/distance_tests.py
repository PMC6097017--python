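"""Permutation tests on distance matrices.

All three tests share the McArdle–Anderson construction: a dissimilarity
matrix D is turned into the Gower-centered inner-product matrix

    G = (I - 11'/n) (-1/2 D∘D) (I - 11'/n),

whose trace partitions like a multivariate sum of squares.  PERMANOVA
partitions tr(G) between and within groups; the dispersion test compares
distances to group centroids in principal-coordinate space (the
multivariate analogue of Levene's test); MDMR regresses G on an arbitrary
design matrix via hat-matrix traces, with omnibus and per-predictor
conditional effects.  All p-values are permutation-based with the
(1 + #{stat* >= stat}) / (1 + n_perm) convention, ties counted as >=.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nullmodels import DistanceMatrix


@dataclass(frozen=True)
class GowerCentered:
    site_ids: tuple[str, ...]
    G: np.ndarray


@dataclass(frozen=True)
class PermanovaResult:
    statistic: float        # pseudo-F
    df1: int
    df2: int
    r_squared: float
    pvalue: float
    permutations: int
    seed: int


@dataclass(frozen=True)
class DispersionResult:
    distances: np.ndarray           # per-site distance to its group centroid
    group_means: dict
    statistic: float                # one-way ANOVA F on the distances
    df1: int
    df2: int
    pvalue: float
    permutations: int
    seed: int
    n_negative_eigenvalues: int
    min_eigenvalue: float


@dataclass(frozen=True)
class MdmrResult:
    """Omnibus and per-predictor (conditional) distance-matrix regression."""

    omnibus: pd.Series              # statistic, df, pseudo_r2, pvalue
    per_predictor: pd.DataFrame     # index: predictor; same columns
    permutations: int
    seed: int


def gower_center(D: DistanceMatrix) -> GowerCentered:
    """Double-centered -D²/2 matrix (the PCoA inner-product matrix)."""
    d = D.values
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    A = -0.5 * d * d
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    return GowerCentered(D.site_ids, (G + G.T) / 2.0)


def _group_masks(groups) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    keys = pd.unique(groups)
    masks = np.stack([groups == k for k in keys])
    return keys, masks


def _check_groups(groups, n):
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("label length does not match distance matrix")
    keys, masks = _group_masks(groups)
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    sizes = masks.sum(axis=1)
    if (sizes < 2).any():
        small = [str(k) for k, s in zip(keys, sizes) if s < 2]
        raise ValueError(f"group(s) of size < 2: {small}")
    return keys, masks


def permanova(D: DistanceMatrix, groups, permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_between/df1) / (SS_within/df2) with sums of squares
    computed directly from squared inter-point distances; significance by
    whole-row permutation of the group labels.
    """
    n = D.n
    keys, masks = _check_groups(groups, n)
    d2 = D.values**2
    if np.isnan(d2).any():
        raise ValueError("distance matrix contains undefined entries")
    ss_total = d2.sum() / (2.0 * n)
    sizes = masks.sum(axis=1)

    def ss_within(mask_mat):
        # mask_mat: (g, n) boolean; SS_W = sum_g (1' D2 1)_g / (2 n_g)
        within = np.einsum("gi,ij,gj->g", mask_mat.astype(float), d2, mask_mat.astype(float))
        return float((within / (2.0 * sizes)).sum())

    df1 = len(keys) - 1
    df2 = n - len(keys)
    ssw = ss_within(masks)
    ssb = ss_total - ssw
    f_obs = (ssb / df1) / (ssw / df2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        ssw_p = ss_within(masks[:, perm])
        f_p = ((ss_total - ssw_p) / df1) / (ssw_p / df2)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    return PermanovaResult(float(f_obs), df1, df2, float(ssb / ss_total), float(p),
                           permutations, seed)


def _pcoa_coordinates(G: np.ndarray, tol: float = 1e-9):
    """Real and imaginary PCoA axes from a Gower-centered matrix."""
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = tol * max(abs(eigvals[0]), 1.0)
    pos = eigvals > scale
    neg = eigvals < -scale
    C_real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    C_imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return C_real, C_imag, eigvals


def dispersion_homogeneity(D: DistanceMatrix, groups, permutations: int = 999,
                           seed: int = 0) -> DispersionResult:
    """Distance-based homogeneity of multivariate dispersions.

    Sites are embedded by PCoA keeping both real and imaginary axes; the
    distance of a site to its group centroid is
    z² = d²(real axes) − d²(imaginary axes), truncated at 0 when negative
    (the correction for non-Euclidean dissimilarities).  The F statistic is
    a one-way ANOVA on the z values, with significance by permutation of
    the least-squares residuals of z.
    """
    n = D.n
    keys, masks = _check_groups(groups, n)
    G = gower_center(D).G
    C_real, C_imag, eigvals = _pcoa_coordinates(G)
    z = np.empty(n)
    for mask in masks:
        cent_r = C_real[mask].mean(axis=0)
        d2_r = ((C_real[mask] - cent_r) ** 2).sum(axis=1)
        if C_imag.shape[1]:
            cent_i = C_imag[mask].mean(axis=0)
            d2_i = ((C_imag[mask] - cent_i) ** 2).sum(axis=1)
        else:
            d2_i = 0.0
        z[mask] = np.sqrt(np.maximum(d2_r - d2_i, 0.0))

    def anova_f(values):
        grand = values.mean()
        ssb = sum(m.sum() * (values[m].mean() - grand) ** 2 for m in masks)
        ssw = sum(((values[m] - values[m].mean()) ** 2).sum() for m in masks)
        df1, df2 = len(keys) - 1, n - len(keys)
        if ssw <= 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / df1) / (ssw / df2)

    f_obs = anova_f(z)
    # permute residuals about group means under the fitted one-way model
    fitted = np.empty(n)
    for mask in masks:
        fitted[mask] = z[mask].mean()
    resid = z - fitted
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        z_p = resid[rng.permutation(n)]
        if anova_f(z_p) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + permutations)
    group_means = {str(k): float(z[m].mean()) for k, m in zip(keys, masks)}
    return DispersionResult(z, group_means, float(f_obs), len(keys) - 1, n - len(keys),
                            float(p), permutations, seed,
                            int((eigvals < -1e-9 * max(abs(eigvals[0]), 1.0)).sum()),
                            float(eigvals.min()))


# ---------------------------------------------------------------------------
# MDMR


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    rank = int((np.abs(np.diag(R)) > 1e-10 * max(abs(np.diag(R)).max(), 1.0)).sum())
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return Q @ Q.T


def build_design(X: pd.DataFrame) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Design matrix with intercept; categoricals treatment-coded.

    Returns the matrix and, per predictor, the column indices it owns
    (a categorical owns one column per non-reference level).
    """
    cols = [np.ones(len(X))]
    owners: dict[str, list[int]] = {}
    j = 1
    for name in X.columns:
        col = X[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            owners[name] = list(range(j, j + dummies.shape[1]))
            cols.extend(dummies.to_numpy(dtype=float).T)
            j += dummies.shape[1]
        else:
            owners[name] = [j]
            cols.append(col.to_numpy(dtype=float))
            j += 1
    return np.column_stack(cols), owners


def mdmr(D: DistanceMatrix, X: pd.DataFrame, permutations: int = 999, seed: int = 0) -> MdmrResult:
    """Multivariate distance matrix regression.

    Omnibus statistic tr(H G H) / tr(Q G Q) with H the hat matrix of the
    full design (intercept added) and Q = I - H; pseudo-R² = tr(H G H)/tr(G).
    Each predictor's conditional effect is the drop in explained trace when
    its columns are removed, tested by Freedman–Lane permutation of the
    reduced-model residual structure:  G* = B G B' with
    B = H_reduced + P (I - H_reduced).
    """
    n = D.n
    if len(X) != n:
        raise ValueError("predictor table length does not match distance matrix")
    G = gower_center(D).G
    Xmat, owners = build_design(X)
    if Xmat.shape[1] >= n:
        raise ValueError("more design columns than sites")
    H = _hat(Xmat)
    Q = np.eye(n) - H
    tr_G = np.trace(G)
    tr_HGH = float(np.sum(H * G))   # tr(HGH) = tr(HG) for idempotent symmetric H
    tr_QGQ = float(np.sum(Q * G))
    omnibus_stat = tr_HGH / tr_QGQ
    omnibus_r2 = tr_HGH / tr_G
    rng = np.random.default_rng(seed)

    # omnibus: permute G rows/columns (intercept-only reduced model; G is
    # already centered, so raw permutation is the Freedman-Lane scheme)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        stat_p = np.sum(H * Gp) / np.sum(Q * Gp)
        if stat_p >= omnibus_stat - 1e-12:
            count += 1
    omnibus_p = (1 + count) / (1 + permutations)
    omnibus = pd.Series({
        "statistic": omnibus_stat, "df": Xmat.shape[1] - 1,
        "pseudo_r2": omnibus_r2, "pvalue": omnibus_p,
    })

    rows = []
    for j_pred, (name, cols) in enumerate(owners.items()):
        keep = [j for j in range(Xmat.shape[1]) if j not in cols]
        Hr = _hat(Xmat[:, keep])
        Qr = np.eye(n) - Hr
        tr_HrGHr = float(np.sum(Hr * G))
        stat_obs = (tr_HGH - tr_HrGHr) / tr_QGQ
        r2 = (tr_HGH - tr_HrGHr) / tr_G
        rng_j = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j_pred + 1,)))
        count = 0
        for _ in range(permutations):
            perm = rng_j.permutation(n)
            B = Hr + Qr[perm]
            Gp = B @ G @ B.T
            stat_p = (np.sum(H * Gp) - np.sum(Hr * Gp)) / np.sum(Q * Gp)
            if stat_p >= stat_obs - 1e-12:
                count += 1
        rows.append((name, stat_obs, len(cols), r2, (1 + count) / (1 + permutations)))
    per_pred = pd.DataFrame(rows, columns=["predictor", "statistic", "df", "pseudo_r2", "pvalue"]
                            ).set_index("predictor")
    return MdmrResult(omnibus, per_pred, permutations, seed)
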
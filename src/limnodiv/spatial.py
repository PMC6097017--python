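"""Spatial eigenfunction covariates.

PCNM (principal coordinates of neighbour matrices) builds spatial
eigenfunctions from site coordinates: pairwise Euclidean distances are
truncated (distances beyond the threshold replaced by four times the
threshold), the truncated matrix is run through PCoA, and the
positive-eigenvalue eigenvectors — the positively spatially
autocorrelated patterns, broad-scale first — are kept as candidate
covariates.  Forward selection by distance-based redundancy analysis
(db-RDA, McArdle–Anderson form) then picks the spatial variables that
best explain a community distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .distance_tests import gower_center, _hat
from .nullmodels import DistanceMatrix


@dataclass(frozen=True)
class SpatialEigenvectors:
    site_ids: tuple[str, ...]
    vectors: pd.DataFrame       # columns PCNM1, PCNM2, ... (unit norm)
    eigenvalues: np.ndarray
    truncation: float


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    steps: pd.DataFrame          # per accepted step: variable, pseudo_f, pvalue, cum_r2
    stopping_reason: str
    alpha: float
    permutations: int
    seed: int


def pcnm(coordinates, truncation: float | None = None,
         site_ids: tuple[str, ...] | None = None) -> SpatialEigenvectors:
    """Spatial eigenfunctions from planar coordinates.

    ``truncation`` defaults to the longest edge of the minimum spanning
    tree of the inter-site distances (the standard rule keeping the graph
    of "neighbour" distances connected).
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 coordinate points")
    n = coords.shape[0]
    if site_ids is None:
        site_ids = tuple(f"site_{i}" for i in range(n))
    d = squareform(pdist(coords))
    if d.max() == 0:
        raise ValueError("all points identical")
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("truncation distance must be positive")
    d_trunc = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(d_trunc, 0.0)
    G = gower_center(DistanceMatrix(site_ids, d_trunc, "other")).G
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-9 * max(abs(eigvals[0]), 1.0)
    vectors = pd.DataFrame(
        eigvecs[:, pos],
        index=pd.Index(site_ids, name="site"),
        columns=[f"PCNM{i + 1}" for i in range(int(pos.sum()))],
    )
    return SpatialEigenvectors(tuple(site_ids), vectors, eigvals[pos], truncation)


def _dbrda_f(G: np.ndarray, X: np.ndarray, X_reduced: np.ndarray | None):
    """Pseudo-F for the columns of X beyond X_reduced, McArdle–Anderson."""
    n = G.shape[0]
    H = _hat(X)
    tr_H = float(np.sum(H * G))
    tr_res = float(np.trace(G)) - tr_H
    if X_reduced is None:
        tr_added = tr_H
        df_added = X.shape[1] - 1
    else:
        Hr = _hat(X_reduced)
        tr_added = tr_H - float(np.sum(Hr * G))
        df_added = X.shape[1] - X_reduced.shape[1]
    df_res = n - X.shape[1]
    return (tr_added / df_added) / (tr_res / df_res), tr_added


def forward_select_dbrda(D: DistanceMatrix, candidates: pd.DataFrame,
                         alpha: float = 0.05, permutations: int = 999,
                         seed: int = 0,
                         use_adjusted_r2_stop: bool = False) -> SelectionResult:
    """Greedy forward selection of spatial covariates by db-RDA.

    At each step the candidate adding the most explained trace of the
    Gower-centered D enters, and stays if its conditional permutation
    p-value (Freedman–Lane under the model selected so far) is <= alpha.
    ``use_adjusted_r2_stop`` additionally stops once the cumulative R²
    exceeds the adjusted R² of the full candidate model (the
    double-stopping rule); off by default.
    """
    n = D.n
    G = gower_center(D).G
    tr_G = float(np.trace(G))
    names = list(candidates.columns)
    if not names:
        return SelectionResult((), pd.DataFrame(
            columns=["variable", "pseudo_f", "pvalue", "cum_r2"]), "no candidates",
            alpha, permutations, seed)
    Xc = candidates.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    intercept = np.ones((n, 1))

    r2_stop = np.inf
    if use_adjusted_r2_stop and n > len(names) + 1:
        X_full = np.hstack([intercept, Xc])
        H_full = _hat(X_full)
        r2_full = float(np.sum(H_full * G)) / tr_G
        r2_stop = 1 - (1 - r2_full) * (n - 1) / (n - len(names) - 1)

    selected: list[int] = []
    steps = []
    cum_r2 = 0.0
    reason = "candidates exhausted"
    rng_master = np.random.SeedSequence(seed)
    step = 0
    while len(selected) < len(names):
        X_red = np.hstack([intercept] + ([Xc[:, selected]] if selected else []))
        if X_red.shape[1] + 1 >= n:
            reason = "design saturated"
            break
        best, best_gain = None, -np.inf
        for j in range(len(names)):
            if j in selected:
                continue
            X_try = np.hstack([X_red, Xc[:, [j]]])
            try:
                _, gain = _dbrda_f(G, X_try, X_red)
            except ValueError:   # collinear candidate
                continue
            if gain > best_gain:
                best, best_gain = j, gain
        if best is None:
            reason = "no admissible candidate"
            break
        X_try = np.hstack([X_red, Xc[:, [best]]])
        f_obs, _ = _dbrda_f(G, X_try, X_red)
        # Freedman-Lane: permute the residual structure under the reduced model
        Hr = _hat(X_red)
        Qr = np.eye(n) - Hr
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(step,)))
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            B = Hr + Qr[perm]
            Gp = B @ G @ B.T
            f_p, _ = _dbrda_f(Gp, X_try, X_red)
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + permutations)
        if p > alpha:
            reason = "no candidate passed alpha"
            break
        selected.append(best)
        cum_r2 += best_gain / tr_G
        steps.append((names[best], float(f_obs), float(p), float(cum_r2)))
        step += 1
        if cum_r2 > r2_stop:
            reason = "adjusted-R2 stop"
            break
    else:
        reason = "candidates exhausted"
    return SelectionResult(
        tuple(names[j] for j in selected),
        pd.DataFrame(steps, columns=["variable", "pseudo_f", "pvalue", "cum_r2"]),
        reason, alpha, permutations, seed,
    )
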
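"""Synthetic lake datasets with the statistical structure the analyses assume.

The generator emulates a survey of boreal lakes in three ecological-status
groups (high / good / moderate).  Group-level environmental distributions
follow the study system's direction: moderate-status lakes have higher and
more variable total phosphorus, alkalinity and conductivity, higher pH,
and lower, less variable Secchi depth.  pH, alkalinity and conductivity
share a latent water-quality factor so that a PAC-style first principal
component captures most of their joint variance.

Species assembly assumes no dispersal limitation.  In ``filtered`` mode
occurrence is cell-independent Bernoulli with

    P(s, i) = inverse-logit(a_s + b_s * z_i + c * effort_i),

where z_i is a standardized site score built from the realized trophic /
water-quality environment, so lakes with similar chemistry share species
— the deterministic-assembly signal every downstream test should detect.
In ``neutral`` mode species identities carry no environmental signal:
sampling effort sets each lake's richness (via the same logistic cell
probabilities with b_s = 0) and species identities are then drawn from
the relative species frequencies by weighted sampling without
replacement — the null model's own generative process, so dissimilarity
deviations are centred at zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CommunityMatrix, GroupLabels, OccupancyWeights
from .nullmodels import null_draw, weighted_incidence

#: Group-level environmental means and SDs.  Means are the study system's
#: printed group means; SDs are recovered once from the printed 95% CI
#: half-widths (sd = hw * sqrt(n) / t_{0.975, n-1} with n = 21/22/23).
DEFAULT_ENV_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "transect_length": {"high": (869.0, 452.6), "good": (748.0, 477.0), "moderate": (882.0, 442.8)},
    "sdf": {"high": (2.8, 1.10), "good": (3.6, 1.47), "moderate": (3.0, 1.39)},
    "secchi": {"high": (2.91, 1.417), "good": (2.02, 0.677), "moderate": (1.32, 0.451)},
    "tp": {"high": (11.91, 7.98), "good": (18.93, 7.64), "moderate": (41.78, 25.32)},
    "ph": {"high": (6.9, 0.44), "good": (6.8, 0.45), "moderate": (7.5, 1.40)},
    "alkalinity": {"high": (0.110, 0.0615), "good": (0.119, 0.0677), "moderate": (0.334, 0.1746)},
    "conductivity": {"high": (3.139, 1.566), "good": (3.498, 1.421), "moderate": (7.165, 3.576)},
}

#: Variables drawn log-normally (moment-matched); the rest are normal.
LOGNORMAL_VARS = ("transect_length", "tp", "alkalinity", "conductivity")

DEFAULT_N_SITES = {"high": 21, "good": 22, "moderate": 23}
DEFAULT_N_SPECIES = {"shore plant": 26, "helophyte": 19, "rhizophyte": 49, "free-floating": 10}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic lake generator.

    ``niche_mean`` and ``niche_sd`` set the distribution of the
    per-species environmental slope b_s in filtered mode: the positive
    mean plants the system's richness gradient (more species in
    nutrient-richer, harder-water lakes), while the SD spreads species
    optima so composition turns over along the gradient.
    ``effort_slope`` is the common slope on standardized log10 transect
    length; ``occupancy_intercept_mean/sd`` set the spread of baseline
    occupancy logits a_s.
    """

    n_sites: dict = field(default_factory=lambda: dict(DEFAULT_N_SITES))
    n_species: dict = field(default_factory=lambda: dict(DEFAULT_N_SPECIES))
    env_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ENV_PARAMS.items()})
    assembly: str = "filtered"
    niche_mean: float = 0.35
    niche_sd: float = 1.0
    effort_slope: float = 0.75
    occupancy_intercept_mean: float = -1.2
    occupancy_intercept_sd: float = 0.8
    latent_correlation: float = 0.9       # pH/alkalinity/conductivity shared factor
    coordinate_mode: str = "uniform"      # or "clustered"
    extent: float = 100.0                 # side of the square study region
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assembly not in ("neutral", "filtered"):
            raise ValueError("assembly must be 'neutral' or 'filtered'")
        if any(n < 2 for n in self.n_sites.values()):
            raise ValueError("each status group needs at least 2 lakes")
        if any(n < 1 for n in self.n_species.values()) or not self.n_species:
            raise ValueError("each life-form group needs at least 1 species")
        for var, groups in self.env_params.items():
            for g, (m, s) in groups.items():
                if s < 0:
                    raise ValueError(f"negative SD for {var}/{g}")


@dataclass(frozen=True)
class SyntheticDataset:
    community: CommunityMatrix
    environment: pd.DataFrame      # per-site covariates incl. x, y, status
    labels: GroupLabels
    catalogue: pd.DataFrame        # species -> life_form_group
    config: SimulationConfig

    @property
    def coordinates(self) -> np.ndarray:
        return self.environment[["x", "y"]].to_numpy(dtype=float)

    def write_csvs(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.community.to_frame().to_csv(out / "community.csv")
        self.environment.to_csv(out / "environment.csv")
        self.labels.labels.to_frame().to_csv(out / "labels.csv")
        self.catalogue.to_csv(out / "catalogue.csv", index=False)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=0)
    return (x - x.mean()) / (s if s > 0 else 1.0)


def simulate_lakes(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Draw one synthetic dataset (community + environment + coordinates).

    Regeneration from the same config and seed is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    groups, sizes = zip(*config.n_sites.items())
    n = int(sum(sizes))
    status = np.repeat(groups, sizes)
    site_ids = tuple(f"lake_{i + 1:03d}" for i in range(n))

    # latent shared water-quality factor drives pH/alkalinity/conductivity
    w = rng.standard_normal(n)
    rho = config.latent_correlation
    env = {}
    for var, by_group in config.env_params.items():
        shared = var in ("ph", "alkalinity", "conductivity")
        eps = rng.standard_normal(n)
        latent = rho * w + np.sqrt(1 - rho**2) * eps if shared else eps
        values = np.empty(n)
        for g in groups:
            m, s = by_group[g]
            mask = status == g
            if var in LOGNORMAL_VARS:
                mu, sigma = _lognormal_params(m, s)
                values[mask] = np.exp(mu + sigma * latent[mask])
            elif var == "sdf":
                # SDF >= 1 physically: 1 + moment-matched log-normal
                mu, sigma = _lognormal_params(m - 1.0, s)
                values[mask] = 1.0 + np.exp(mu + sigma * latent[mask])
            else:
                values[mask] = np.maximum(m + s * latent[mask], 0.05)
        env[var] = values

    if config.coordinate_mode == "clustered":
        centers = rng.uniform(0, config.extent, size=(len(groups), 2))
        coords = np.vstack([
            centers[gi] + rng.normal(scale=config.extent / 10, size=(sz, 2))
            for gi, sz in enumerate(sizes)
        ])
    else:
        coords = rng.uniform(0, config.extent, size=(n, 2))

    # site environmental score: realized trophic state + water-quality axis
    z = _standardize(
        0.5 * _standardize(np.log10(env["tp"]))
        + 0.5 * _standardize(env["ph"] + _standardize(np.log10(env["alkalinity"]))
                             + _standardize(np.log10(env["conductivity"])))
    )
    effort = _standardize(np.log10(env["transect_length"]))

    species_ids, lf_groups = [], []
    for g, count in config.n_species.items():
        tag = g.replace(" ", "_").replace("-", "_")
        for i in range(count):
            species_ids.append(f"{tag}_{i + 1:02d}")
            lf_groups.append(g)
    S = len(species_ids)
    a = rng.normal(config.occupancy_intercept_mean, config.occupancy_intercept_sd, size=S)
    if config.assembly == "filtered":
        b = rng.normal(config.niche_mean, config.niche_sd, size=S)
        logit = a[None, :] + b[None, :] * z[:, None] + config.effort_slope * effort[:, None]
        prob = 1.0 / (1.0 + np.exp(-logit))
        incidence = (rng.random((n, S)) < prob).astype(np.int8)
    else:
        # neutral: effort sets richness, frequency sets identity
        logit = a[None, :] + config.effort_slope * effort[:, None]
        prob = 1.0 / (1.0 + np.exp(-logit))
        richness_draw = (rng.random((n, S)) < prob).sum(axis=1)
        frequency = prob.mean(axis=0)
        incidence = weighted_incidence(richness_draw, frequency, rng)

    community = CommunityMatrix(site_ids, tuple(species_ids), incidence)
    environment = pd.DataFrame(env, index=pd.Index(site_ids, name="site"))
    environment["x"] = coords[:, 0]
    environment["y"] = coords[:, 1]
    environment["status"] = status
    labels = GroupLabels(pd.Series(status, index=pd.Index(site_ids, name="site")))
    catalogue = pd.DataFrame({"species": species_ids, "life_form_group": lf_groups})
    return SyntheticDataset(community, environment, labels, catalogue, config)


def simulate_null_communities(richness, weights: OccupancyWeights, seed: int = 0) -> CommunityMatrix:
    """Null communities from the fixed-richness occupancy-weighted sampler.

    Exposes the null model's generative process as a standalone data
    source (delegates to :func:`limnodiv.nullmodels.null_draw`).
    """
    rng = np.random.default_rng(seed)
    return null_draw(richness, weights, rng)
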
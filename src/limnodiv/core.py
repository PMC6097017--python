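"""Core data model for lake macrophyte community analyses.

A survey of lakes yields a sites x species presence/absence table, a
catalogue assigning each species to one of four macrophyte life-form
groups (shore plant, helophyte, rhizophyte, free-floating), and an
ecological-status label per lake (high / good / moderate / poor under the
EU Water Framework Directive).  This module holds those containers, their
validation, CSV round-tripping, and the small derived quantities
(occupancy weights, status pooling) the downstream statistics consume.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LIFE_FORM_GROUPS = ("shore plant", "helophyte", "rhizophyte", "free-floating")
STATUS_LEVELS = ("high", "good", "moderate", "poor")
POOLED_STATUS_LEVELS = ("high", "good", "moderate")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Sites x species incidence (0/1) matrix with identifier labels."""

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2 or inc.shape != (len(self.site_ids), len(self.species_ids)):
            raise DataValidationError(
                f"incidence shape {inc.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise DataValidationError("duplicate site identifiers")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise DataValidationError("duplicate species identifiers")
        if not np.isin(inc, (0, 1)).all():
            raise DataValidationError("incidence entries must be 0 or 1")
        object.__setattr__(self, "incidence", inc.astype(np.int8))

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> np.ndarray:
        """Per-site species richness (row sums)."""
        return self.incidence.sum(axis=1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=pd.Index(self.site_ids, name="site"),
            columns=list(self.species_ids),
        )

    def drop_empty_sites(self) -> "CommunityMatrix":
        """Remove zero-richness sites (stage-local; load keeps them)."""
        keep = self.richness() > 0
        return CommunityMatrix(
            tuple(s for s, k in zip(self.site_ids, keep) if k),
            self.species_ids,
            self.incidence[keep],
        )

    def select_sites(self, site_ids: Iterable[str]) -> "CommunityMatrix":
        wanted = list(site_ids)
        pos = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise DataValidationError(f"unknown site identifiers: {missing}")
        idx = [pos[s] for s in wanted]
        return CommunityMatrix(tuple(wanted), self.species_ids, self.incidence[idx])


@dataclass(frozen=True)
class LifeFormCatalogue:
    """Species -> (growth form, life-form group) lookup with a closed group set."""

    table: pd.DataFrame  # columns: species, growth_form (optional), life_form_group

    def __post_init__(self) -> None:
        t = self.table
        if "species" not in t.columns or "life_form_group" not in t.columns:
            raise DataValidationError("catalogue needs 'species' and 'life_form_group' columns")
        if t["species"].duplicated().any():
            dups = t.loc[t["species"].duplicated(), "species"].tolist()
            raise DataValidationError(f"duplicate species in catalogue: {dups}")
        unknown = set(t["life_form_group"]) - set(LIFE_FORM_GROUPS)
        if unknown:
            raise DataValidationError(f"unknown life-form group(s): {sorted(unknown)}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.table["species"])

    def group_of(self) -> Mapping[str, str]:
        return dict(zip(self.table["species"], self.table["life_form_group"]))

    def members(self, group: str) -> tuple[str, ...]:
        if group not in LIFE_FORM_GROUPS:
            raise DataValidationError(f"unknown life-form group: {group!r}")
        mask = self.table["life_form_group"] == group
        return tuple(self.table.loc[mask, "species"])

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.table["life_form_group"] == g).sum()) for g in LIFE_FORM_GROUPS}


@dataclass(frozen=True)
class GroupLabels:
    """Per-site ecological status labels."""

    labels: pd.Series  # index: site, values in STATUS_LEVELS

    def __post_init__(self) -> None:
        unknown = set(self.labels) - set(STATUS_LEVELS)
        if unknown:
            raise DataValidationError(f"unknown status label(s): {sorted(unknown)}")
        if self.labels.index.duplicated().any():
            raise DataValidationError("duplicate site identifiers in labels")
        object.__setattr__(self, "labels", self.labels.rename_axis("site").rename("status"))

    def counts(self) -> dict[str, int]:
        return {k: int((self.labels == k).sum()) for k in STATUS_LEVELS if (self.labels == k).any()}

    def for_sites(self, site_ids: Iterable[str]) -> np.ndarray:
        return self.labels.loc[list(site_ids)].to_numpy()


@dataclass(frozen=True)
class OccupancyWeights:
    """Species occurrence counts and normalized occupancy weights.

    Weights are proportional to occurrence counts, normalized over species
    observed at least once; never-observed species carry zero weight and can
    never be drawn by the null sampler.
    """

    species_ids: tuple[str, ...]
    counts: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.species_ids),):
            raise DataValidationError("counts shape mismatch")
        if (counts < 0).any():
            raise DataValidationError("negative occurrence count")
        total = counts.sum()
        if total == 0:
            raise DataValidationError("no species observed (all-zero matrix)")
        object.__setattr__(self, "counts", counts.astype(int))
        object.__setattr__(self, "weights", counts / total)

    @property
    def n_positive(self) -> int:
        return int((self.counts > 0).sum())


# ---------------------------------------------------------------------------
# I/O


def load_community_matrix(source, *, coerce_abundance: bool = False) -> CommunityMatrix:
    """Load a wide-format sites x species CSV (first column = site id).

    Positive non-binary entries are rejected unless ``coerce_abundance`` is
    set, in which case any value > 0 becomes a presence.  Silent coercion is
    deliberately forbidden: abundance tables fed in by mistake should fail.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise DataValidationError("empty community table")
    site_col = df.columns[0]
    sites = df[site_col].astype(str)
    if sites.duplicated().any():
        raise DataValidationError(f"duplicate site identifiers: {sites[sites.duplicated()].tolist()}")
    values = df.drop(columns=[site_col]).to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataValidationError("missing values in community table")
    if coerce_abundance:
        if (values < 0).any():
            raise DataValidationError("negative abundance")
        values = (values > 0).astype(int)
    elif not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))][:5]
        raise DataValidationError(
            f"non-binary entries {bad.tolist()} (pass coerce_abundance=True to reduce to incidence)"
        )
    return CommunityMatrix(tuple(sites), tuple(map(str, df.columns[1:])), values.astype(int))


def write_community_matrix(cm: CommunityMatrix, path) -> None:
    cm.to_frame().to_csv(path)


def load_lifeform_catalogue(source=None) -> LifeFormCatalogue:
    """Load a species catalogue CSV; with no argument, the packaged catalogue.

    The packaged file transcribes the study's species list: 104 boreal lake
    macrophytes partitioned into 26 shore plants, 19 helophytes,
    49 rhizophytes and 10 free-floating species.
    """
    if source is None:
        resource = importlib.resources.files("limnodiv") / "data" / "lifeform_catalogue.csv"
        with importlib.resources.as_file(resource) as path:
            df = pd.read_csv(path)
    elif isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    return LifeFormCatalogue(df)


def load_group_labels(source) -> GroupLabels:
    """Load a two-column (site, status) CSV."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    if df.shape[1] < 2:
        raise DataValidationError("labels table needs (site, status) columns")
    return GroupLabels(pd.Series(
        df.iloc[:, 1].astype(str).str.lower().to_numpy(),
        index=pd.Index(df.iloc[:, 0].astype(str)),
    ))


def load_environment_table(source) -> pd.DataFrame:
    """Load a per-site environment CSV indexed by site identifier."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    first = df.columns[0]
    if first.lower() in ("site", "site_id", "lake"):
        df = df.set_index(first)
    df.index = df.index.astype(str)
    df = df.rename_axis("site")
    if df.index.duplicated().any():
        raise DataValidationError("duplicate site identifiers in environment table")
    return df


# ---------------------------------------------------------------------------
# Derived operations


def subset_by_lifeform(
    cm: CommunityMatrix,
    catalogue: LifeFormCatalogue,
    group: str,
    *,
    drop_unknown: bool = False,
) -> CommunityMatrix:
    """Restrict columns to one life-form group (or ``"all"`` = identity).

    Sites whose richness drops to zero are retained: exclusion is decided
    per analysis stage (richness models keep them; dissimilarity stages
    drop them).
    """
    if group == "all":
        return cm
    mapping = catalogue.group_of()
    missing = [s for s in cm.species_ids if s not in mapping]
    if missing and not drop_unknown:
        raise DataValidationError(
            f"species missing from catalogue: {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''} (pass drop_unknown=True to drop)"
        )
    keep = [i for i, s in enumerate(cm.species_ids) if mapping.get(s) == group]
    if group not in LIFE_FORM_GROUPS:
        raise DataValidationError(f"unknown life-form group: {group!r}")
    return CommunityMatrix(
        cm.site_ids,
        tuple(cm.species_ids[i] for i in keep),
        cm.incidence[:, keep],
    )


def pool_status(labels: GroupLabels) -> GroupLabels:
    """Relabel 'poor' sites as 'moderate' (the pooled three-level view)."""
    pooled = labels.labels.replace("poor", "moderate")
    return GroupLabels(pooled)


def occupancy(cm: CommunityMatrix) -> OccupancyWeights:
    """Occurrence counts (column sums) and normalized occupancy weights."""
    counts = cm.incidence.sum(axis=0)
    return OccupancyWeights(cm.species_ids, counts)
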
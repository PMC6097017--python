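"""End-to-end orchestration of the lake-diversity analysis.

Given a community matrix, an environment table, status labels and a
life-form catalogue (real data or output of :mod:`limnodiv.simulate`),
``run_all`` produces, per life-form group:

* an AICc-ranked richness model-selection table (GLS, 31 candidates);
* observed Sørensen and shifted dissimilarity-deviation matrices;
* forward-selected spatial covariates (lat/lon + PCNM eigenfunctions);
* MDMR omnibus + per-predictor tables on both matrices;
* PERMANOVA and dispersion-homogeneity results on both matrices
  (poor-status lakes dropped: those tests are sensitive to unequal
  group sizes);

plus dataset-level outputs: the PAC axis, Levene variance tests, and
per-group environmental summaries.  Every random stage derives its seed
from the run seed, and a run record captures config, seeds, shift
constants and dropped sites so any number in any table is reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (CommunityMatrix, GroupLabels, LifeFormCatalogue,
                   pool_status, subset_by_lifeform)
from .distance_tests import dispersion_homogeneity, mdmr, permanova
from .environment import extract_pac, group_summary, levene_test, log_transform
from .nullmodels import NullModelConfig, ses_dissimilarity, shift_nonnegative, sorensen_matrix
from .richness import (anova_group_comparison, build_model_set,
                       choose_correlation_structure, fit_model_set)
from .spatial import forward_select_dbrda, pcnm

ANALYSIS_GROUPS = ("all", "shore plant", "helophyte", "rhizophyte", "free-floating")
LEVENE_VARIABLES = ("secchi", "tp", "pac", "transect_length", "sdf")


@dataclass(frozen=True)
class RunConfig:
    groups: tuple[str, ...] = ANALYSIS_GROUPS
    null_iterations: int = 999
    permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    select_correlation: bool = True     # AICc-choose the GLS spatial structure
    log_transform: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.null_iterations < 2:
            raise ValueError("null_iterations must be >= 2")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        unknown = set(self.groups) - set(ANALYSIS_GROUPS)
        if unknown:
            raise ValueError(f"unknown analysis group(s): {sorted(unknown)}")


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    record: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv")
        with open(out / "run_record.json", "w") as fh:
            json.dump(self.record, fh, indent=2, default=str)


def _transformed_predictors(env: pd.DataFrame, pac_scores: np.ndarray,
                            transform: bool) -> pd.DataFrame:
    """Predictor table in model scale: log10 continuous variables, raw PAC."""
    X = pd.DataFrame(index=env.index)
    if transform:
        X["transect_length"] = log_transform(env["transect_length"])
        X["Secchi"] = log_transform(env["secchi"])
        X["SDF"] = log_transform(env["sdf"])
        X["TP"] = log_transform(env["tp"])
    else:
        X["transect_length"] = env["transect_length"]
        X["Secchi"] = env["secchi"]
        X["SDF"] = env["sdf"]
        X["TP"] = env["tp"]
    X["PAC"] = pac_scores
    X["status"] = pd.Categorical(env["status"],
                                 categories=["high", "good", "moderate"])
    return X


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % 2**31)


def run_all(community: CommunityMatrix, environment: pd.DataFrame,
            labels: GroupLabels, catalogue: LifeFormCatalogue,
            config: RunConfig = RunConfig()) -> PipelineResult:
    t0 = time.time()
    tables: dict[str, pd.DataFrame] = {}
    record: dict = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "seeds": {}, "warnings": [], "timings": {}, "shift_constants": {},
        "dropped_sites": {}, "spatial_selection": {}, "correlation_structures": {},
    }

    sites = list(community.site_ids)
    env = environment.loc[sites]
    pooled = pool_status(labels)
    status_pooled = pooled.for_sites(sites)
    original_status = labels.for_sites(sites)

    # --- PAC axis ------------------------------------------------------
    pac = extract_pac(env["ph"], env["alkalinity"], env["conductivity"])
    record["pac"] = {
        "variance_fraction": pac.variance_fraction,
        "loadings": dict(zip(("ph", "alkalinity", "conductivity"), pac.loadings)),
    }
    env = env.assign(pac=pac.scores, status=status_pooled)
    X_env = _transformed_predictors(env, pac.scores, config.log_transform)
    coords = env[["x", "y"]].to_numpy(dtype=float)

    # sites retained for the group-size-sensitive tests (drop poor lakes)
    not_poor = original_status != "poor"
    if (~not_poor).any():
        record["dropped_sites"]["poor_status"] = [s for s, k in zip(sites, not_poor) if not k]

    # --- environment summaries and variance tests ----------------------
    summaries = []
    for var in ("transect_length", "sdf", "secchi", "tp", "ph", "alkalinity",
                "conductivity", "pac"):
        gs = group_summary(env[var].to_numpy(), status_pooled)
        t = gs.table.reset_index()
        t.insert(0, "variable", var)
        t["differing"] = [";".join("|".join(p) for p in gs.differing_pairs)] * len(t)
        summaries.append(t)
    tables["environment_summary"] = pd.concat(summaries, ignore_index=True)

    lev_rows = []
    for var in LEVENE_VARIABLES:
        res = levene_test(env.loc[not_poor, var].to_numpy(), status_pooled[not_poor])
        lev_rows.append((var, res.statistic, res.df_num, res.df_den, res.pvalue))
    tables["levene_tests"] = pd.DataFrame(
        lev_rows, columns=["variable", "statistic", "df_num", "df_den", "pvalue"]
    ).set_index("variable")

    # --- per life-form group -------------------------------------------
    perm_rows, mdmr_frames, richness_frames, anova_rows = [], [], [], []
    for gi, group in enumerate(config.groups):
        t_group = time.time()
        cm_g = subset_by_lifeform(community, catalogue, group)
        richness = cm_g.richness()

        # richness models (all sites kept; zeros handled by log10(n+1))
        plus_one = group == "free-floating" or (richness == 0).any()
        if plus_one and group != "free-floating":
            record["warnings"].append(
                f"{group}: zero-richness sites present; response uses log10(n+1)")
        y = (log_transform(richness, plus_one=plus_one)
             if config.log_transform else richness.astype(float))
        corr = "none"
        if config.select_correlation:
            corr, aiccs = choose_correlation_structure(y, X_env, coords)
            record["correlation_structures"][group] = {
                "chosen": corr, "aicc": aiccs.to_dict()}
        sel_table = fit_model_set(y, X_env, build_model_set(correlation=corr),
                                  coords if corr != "none" else None)
        sel_table.insert(0, "life_form_group", group)
        richness_frames.append(sel_table)

        av = anova_group_comparison(richness[not_poor], status_pooled[not_poor])
        anova_rows.append((group, av.statistic, av.df1, av.df2, av.pvalue,
                           ";".join("|".join(p) for p in av.summary.differing_pairs)))

        # dissimilarity stages (empty sites dropped, logged)
        cm_beta = cm_g.drop_empty_sites()
        dropped = sorted(set(cm_g.site_ids) - set(cm_beta.site_ids))
        if dropped:
            record["dropped_sites"][f"{group}_empty"] = dropped
        d_obs = sorensen_matrix(cm_beta)
        ses = ses_dissimilarity(cm_beta, NullModelConfig(
            iterations=config.null_iterations, seed=_subseed(config.seed, 1, gi)))
        # drop sites with undefined (zero null SD) pairs before shifting
        n_b = len(ses.site_ids)
        undef = ~ses.defined & ~np.eye(n_b, dtype=bool)
        if undef.any():
            keep = np.ones(n_b, dtype=bool)
            while undef[np.ix_(keep, keep)].any():
                counts = (undef & keep[None, :]).sum(axis=1)
                counts[~keep] = -1
                keep[int(np.argmax(counts))] = False
            dropped_undef = [s for s, k in zip(ses.site_ids, keep) if not k]
            record["dropped_sites"][f"{group}_undefined_ses"] = dropped_undef
            cm_beta = cm_beta.select_sites(
                [s for s, k in zip(ses.site_ids, keep) if k])
            d_obs = sorensen_matrix(cm_beta)
            ses = ses_dissimilarity(cm_beta, NullModelConfig(
                iterations=config.null_iterations, seed=_subseed(config.seed, 1, gi)))
        d_dev, shift = shift_nonnegative(ses)
        record["shift_constants"][group] = shift
        record.setdefault("mean_ses", {})[group] = ses.mean_ses()

        beta_sites = list(cm_beta.site_ids)
        env_b = env.loc[beta_sites]
        keep_b = labels.for_sites(beta_sites) != "poor"
        eig = pcnm(env_b[["x", "y"]].to_numpy(dtype=float), site_ids=tuple(beta_sites))
        candidates = pd.concat(
            [env_b[["x", "y"]].rename(columns={"x": "longitude", "y": "latitude"}),
             eig.vectors], axis=1)

        for kind, D in (("observed", d_obs), ("deviation", d_dev)):
            sel = forward_select_dbrda(
                D, candidates, alpha=config.alpha,
                permutations=config.permutations,
                seed=_subseed(config.seed, 2, gi, 0 if kind == "observed" else 1))
            record["spatial_selection"][f"{group}/{kind}"] = list(sel.selected)
            X_m = pd.concat([X_env.loc[beta_sites],
                             candidates[list(sel.selected)]], axis=1)
            m = mdmr(D, X_m, permutations=config.permutations,
                     seed=_subseed(config.seed, 3, gi, 0 if kind == "observed" else 1))
            frame = pd.concat(
                [m.omnibus.to_frame("Omnibus").T, m.per_predictor])
            frame.insert(0, "matrix", kind)
            frame.insert(0, "life_form_group", group)
            mdmr_frames.append(frame)

            D_np = D.select_sites([s for s, k in zip(beta_sites, keep_b) if k])
            g_np = pooled.for_sites(D_np.site_ids)
            pr = permanova(D_np, g_np, permutations=config.permutations,
                           seed=_subseed(config.seed, 4, gi))
            dr = dispersion_homogeneity(D_np, g_np, permutations=config.permutations,
                                        seed=_subseed(config.seed, 5, gi))
            perm_rows.append((group, kind, pr.statistic, pr.df1, pr.df2, pr.pvalue,
                              dr.statistic, dr.df1, dr.df2, dr.pvalue))
        record["timings"][group] = round(time.time() - t_group, 2)

    tables["richness_models"] = pd.concat(richness_frames, ignore_index=True)
    tables["richness_anova"] = pd.DataFrame(
        anova_rows, columns=["life_form_group", "F", "df1", "df2", "pvalue",
                             "differing_cis"]).set_index("life_form_group")
    tables["mdmr"] = pd.concat(mdmr_frames)
    tables["group_tests"] = pd.DataFrame(
        perm_rows, columns=["life_form_group", "matrix",
                            "permanova_F", "permanova_df1", "permanova_df2", "permanova_p",
                            "dispersion_F", "dispersion_df1", "dispersion_df2", "dispersion_p"])
    record["seeds"]["root"] = config.seed
    record["timings"]["total"] = round(time.time() - t0, 2)
    result = PipelineResult(tables, record)
    if config.outdir:
        result.write(config.outdir)
    return result


def grouping_sensitivity(community: CommunityMatrix, environment: pd.DataFrame,
                         labels: GroupLabels, alternative: GroupLabels,
                         catalogue: LifeFormCatalogue,
                         config: RunConfig = RunConfig(groups=("all",))) -> pd.DataFrame:
    """Re-run PERMANOVA and dispersion under an alternative grouping.

    Typical use: groups formed from total-phosphorus tertiles instead of
    ecological status, to check that the no-difference-in-dispersion
    conclusion does not hinge on the status classification.
    """
    if set(alternative.labels.index) < set(community.site_ids):
        raise ValueError("alternative labels must cover all sites")
    rows = []
    for name, lab in (("original", labels), ("alternative", alternative)):
        cm = subset_by_lifeform(community, catalogue, "all").drop_empty_sites()
        pooled = pool_status(lab)
        g = pooled.for_sites(cm.site_ids)
        counts = pd.Series(g).value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"grouping {name!r} has singleton group(s): {bad}")
        D = sorensen_matrix(cm)
        pr = permanova(D, g, permutations=config.permutations, seed=config.seed)
        dr = dispersion_homogeneity(D, g, permutations=config.permutations,
                                    seed=config.seed)
        rows.append((name, pr.statistic, pr.pvalue, dr.statistic, dr.pvalue))
    return pd.DataFrame(rows, columns=["grouping", "permanova_F", "permanova_p",
                                       "dispersion_F", "dispersion_p"]).set_index("grouping")


def tp_tertile_labels(environment: pd.DataFrame) -> GroupLabels:
    """Alternative grouping: total-phosphorus tertiles mapped to status names."""
    tp = environment["tp"]
    tert = pd.qcut(tp, 3, labels=["high", "good", "moderate"])
    return GroupLabels(pd.Series(tert.astype(str).to_numpy(),
                                 index=environment.index))
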
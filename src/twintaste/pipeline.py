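"""End-to-end analysis: QC -> metrics -> variance partition -> twin models.

``run_pipeline`` drives the full analysis from a single configuration
(simulation-backed or from a rating CSV) and returns a machine-readable
report: QC counts, per-domain aesthetic metrics, the pair-class agreement
ANOVA, rating variance partitioning, the univariate model ladder per trait
(saturated -> ACE/ADE -> AE/CE -> E with likelihood-ratio tests), the
multivariate models across domains, and an optional sensitivity
re-analysis on residualized scores.

The ACE-vs-ADE choice follows the twin-correlation pattern: ADE when
``r_DZ < r_MZ / 2``, else ACE; the final model is the most parsimonious
submodel whose LRT against the full model is non-significant at 0.05.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as me
from . import qc as qcmod
from . import simulate as sim
from .multivariate import (MultivariateTwinModel, make_multitrait_pairs,
                           saturated_minus2ll)
from .univariate import (SaturatedTwinModel, UnivariateTwinModel,
                         compare_models, make_pair_table)
from .varcomp import CrossedVarianceModel

__all__ = ["PipelineConfig", "residualize", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full analysis run."""

    simulation: sim.SimulationConfig | None = None
    ratings_path: str | None = None
    rating_scale: tuple[float, float] | None = None
    r_intra_min: float = 0.5
    iqr_mult: float = 3.0
    seed: int = 0
    vpc_max_individuals: int = 120   # REML cost grows fast with raters
    profile_cis: bool = False
    sensitivity_loading: float | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if (self.simulation is None) == (self.ratings_path is None):
            raise ValueError("provide exactly one of simulation or ratings_path")


def residualize(scores, covariates: pd.DataFrame | np.ndarray | None):
    """OLS residuals of ``scores`` on an intercept plus ``covariates``.

    With no covariates this is a centred passthrough.  Residuals are
    orthogonal to every covariate column; a rank-deficient covariate
    matrix raises an error naming the collinear columns.
    """
    y = np.asarray(scores, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        return y - y.mean()
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(covariates, dtype=float))
        if x.shape[0] != len(y):
            x = x.T
        names = [f"x{i}" for i in range(x.shape[1])]
    xd = np.column_stack([np.ones(len(y)), x])
    rank = np.linalg.matrix_rank(xd)
    if rank < xd.shape[1]:
        # identify offending columns via incremental rank
        collinear = []
        cur = xd[:, :1]
        for i in range(x.shape[1]):
            trial = np.column_stack([cur, x[:, i]])
            if np.linalg.matrix_rank(trial) == cur.shape[1]:
                collinear.append(names[i])
            else:
                cur = trial
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    return y - xd @ beta


def _sex_age_design(meta: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "sex": (meta["sex"] == "F").astype(float),
        "age": meta["age"].astype(float) - meta["age"].mean(),
    }, index=meta.index)


def _univariate_ladder(pairs: pd.DataFrame, seed: int, profile_cis: bool) -> dict:
    """Saturated model, full ACE/ADE and nested submodels with LRTs."""
    sat = SaturatedTwinModel(pairs, covariates=("sex", "age")).fit()
    r_mz = sat.twin_correlations["MZ"]
    r_dz = sat.twin_correlations["DZ"]
    full_spec = "ADE" if r_dz < r_mz / 2 else "ACE"
    ladder = [full_spec, "AE" if "A" in full_spec else "CE", "E"]
    if full_spec == "ACE":
        ladder.insert(2, "CE")
    fits = {}
    for spec_name in ladder:
        fits[spec_name] = UnivariateTwinModel(
            pairs, spec_name, covariates=("sex", "age")).fit(seed=seed)
    full = fits[full_spec]
    tests = {"saturated_vs_full": compare_models(sat, full)}
    final_name = full_spec
    for name in ladder[1:]:
        lrt = compare_models(full, fits[name])
        tests[f"full_vs_{name}"] = lrt
        if lrt["p"] >= 0.05:
            final_name = name
    final = fits[final_name]
    shares = final.standardized_shares()
    out = {
        "twin_correlations": {z: {"r": sat.twin_correlations[z],
                                  "ci": list(sat.correlation_ci[z])}
                              for z in ("MZ", "DZ")},
        "full_model": full_spec,
        "final_model": final_name,
        "models": {name: {"minus2ll": f.minus2ll, "aic": f.aic,
                          "n_params": f.n_params,
                          "components": f.components,
                          "shares": f.standardized_shares()}
                   for name, f in fits.items()},
        "lrt": tests,
        "h2": final.heritability,
        "shares": shares,
    }
    if profile_cis:
        out["share_ci"] = {k: list(final.profile_ci(f"{k}_share"))
                           for k in final.components}
    return out, final_name


def _metric_stage(matrix: qcmod.RatingMatrix, iqr_mult: float, seed: int) -> dict:
    """Individual metrics, twin/UR pair records and outlier masks for one domain."""
    ind = me.individual_metrics(matrix)
    twin_recs = me.twin_pair_records(matrix)
    ur_recs, unpaired = me.make_unrelated_pairs(matrix, seed=seed)
    pair_df = pd.DataFrame([vars(r) for r in twin_recs + ur_recs])

    keep_pairs = qcmod.metric_outlier_filter(pair_df["z_inter"], iqr_mult)
    keep_t = qcmod.metric_outlier_filter(ind["taste_typicality_z"], iqr_mult)
    keep_b = qcmod.metric_outlier_filter(ind["evaluation_bias"], iqr_mult)
    return {
        "individual": ind[keep_t & keep_b],
        "pairs": pair_df[keep_pairs],
        "n_outlier_individuals": int((~(keep_t & keep_b)).sum()),
        "n_outlier_pairs": int((~keep_pairs).sum()),
        "n_unpaired_ur": len(unpaired),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report as a nested dict.

    With ``output_dir`` set, the report (JSON), per-stage CSVs and a log
    are also written there.  Every random step derives from
    ``config.seed``, so reruns are reproducible.
    """
    log = []

    def note(stage, **info):
        log.append({"stage": stage, **info})

    report: dict = {"seed": config.seed}

    # -- input ---------------------------------------------------------------
    if config.simulation is not None:
        traits = sim.simulate_twin_traits(config.simulation)
        ratings = sim.simulate_ratings(config.simulation, traits)
        report["input"] = {"kind": "simulation",
                           "ground_truth": config.simulation.ground_truth()}
    else:
        ratings = qcmod.read_ratings(config.ratings_path, scale=config.rating_scale)
        traits = None
        report["input"] = {"kind": "file", "path": str(config.ratings_path)}
    note("input", n_rows=len(ratings), domains=sorted(ratings["domain"].unique()))

    # -- QC ------------------------------------------------------------------
    ratings = qcmod.validate_ratings(ratings)
    clean, qc_report = qcmod.apply_exclusions(ratings, r_intra_min=config.r_intra_min)
    report["qc"] = json.loads(qc_report.to_json())
    note("qc", retained=qc_report.retained_counts)

    matrices = qcmod.rating_matrices(clean)
    domains = sorted(matrices)

    # -- metrics & agreement -------------------------------------------------
    metric_tables: dict[str, dict] = {}
    all_pairs = []
    report["metrics"] = {}
    for dom in domains:
        stage = _metric_stage(matrices[dom], config.iqr_mult, config.seed)
        metric_tables[dom] = stage
        all_pairs.append(stage["pairs"])
        pa = me.principal_axes(
            matrices[dom].first_members(), n_axes=2,
            align_bias=stage["individual"].reindex(
                matrices[dom].first_members().individuals)["evaluation_bias"].to_numpy(),
        )
        fm = matrices[dom].first_members().individuals
        ind_fm = stage["individual"].reindex(fm)
        ok = ind_fm["taste_typicality_z"].notna().to_numpy()
        r_pc1 = np.corrcoef(pa.scores["PC1"], ind_fm["evaluation_bias"])[0, 1]
        r_pc2 = np.corrcoef(pa.scores["PC2"][ok],
                            ind_fm["taste_typicality_z"][ok])[0, 1]
        report["metrics"][dom] = {
            "n_individuals": len(stage["individual"]),
            "n_pairs": len(stage["pairs"]),
            "n_outlier_individuals": stage["n_outlier_individuals"],
            "n_outlier_pairs": stage["n_outlier_pairs"],
            "pca_explained": pa.explained_variance_ratio.tolist(),
            "corr_pc1_bias": float(abs(r_pc1)),
            "corr_pc2_typicality": float(abs(r_pc2)),
        }
        note("metrics", domain=dom, individuals=len(stage["individual"]))

    pair_all = pd.concat(all_pairs, ignore_index=True)
    if pair_all["domain"].nunique() >= 1 and pair_all["pair_class"].nunique() == 3:
        anova = me.agreement_anova(pair_all)
        report["agreement_anova"] = {
            "marginal_r": anova.marginal_means.loc["pair_class"]["r"].to_dict(),
            "effects": anova.effect_sizes.to_dict(orient="index"),
            "contrasts": anova.contrasts[["estimate_z", "p_bonferroni", "cohens_d"]]
            .to_dict(orient="index"),
        }
        note("agreement_anova", n_pairs=len(pair_all))

    # -- variance partitioning ------------------------------------------------
    report["vpc"] = {}
    for dom in domains:
        first = clean[(clean["domain"] == dom) & (clean["twin_order"] == 1)]
        ids = first["individual_id"].unique()
        if len(ids) > config.vpc_max_individuals:
            rng = np.random.default_rng([config.seed, 3])
            ids = rng.choice(ids, size=config.vpc_max_individuals, replace=False)
            first = first[first["individual_id"].isin(ids)]
        res = CrossedVarianceModel(
            first[["individual_id", "image_id", "presentation", "rating"]]).fit()
        shares = res.vpc()
        report["vpc"][dom] = {
            "components": res.components, "vpc": shares,
            "individual_level_share": shares["sigma2_ind"]
            + shares["sigma2_img_ind"] + shares["sigma2_ind_exp"],
            "n_individuals": int(len(ids)), "converged": res.converged,
        }
        note("vpc", domain=dom, n_individuals=int(len(ids)))

    # -- univariate twin models -----------------------------------------------
    report["univariate"] = {}
    trait_cols = {"taste_typicality": "taste_typicality_z",
                  "evaluation_bias": "evaluation_bias"}
    final_specs: dict[tuple[str, str], str] = {}
    for dom in domains:
        ind = metric_tables[dom]["individual"]
        report["univariate"][dom] = {}
        for label, col in trait_cols.items():
            pairs = make_pair_table(ind, col)
            ladder, final_name = _univariate_ladder(pairs, config.seed,
                                                    config.profile_cis)
            report["univariate"][dom][label] = ladder
            final_specs[(dom, label)] = final_name
            note("univariate", domain=dom, trait=label, final=final_name)

    # -- multivariate twin models ---------------------------------------------
    report["multivariate"] = {}
    if len(domains) >= 2:
        for label, col in trait_cols.items():
            meta_all, values = None, {}
            for dom in domains:
                ind = metric_tables[dom]["individual"]
                values[dom] = ind[col]
                meta_d = ind[["family_id", "twin_order", "zygosity", "sex", "age"]]
                meta_all = meta_d if meta_all is None else meta_all.combine_first(meta_d)
            merged = meta_all.join(pd.DataFrame(values))
            pairs_mv = make_multitrait_pairs(merged, domains)
            include = {"A": [d for d in domains
                             if "A" in final_specs[(d, label)]] or None,
                       "C": [d for d in domains
                             if "C" in final_specs[(d, label)]],
                       "E": None}
            if not include["C"]:
                del include["C"]
            if include["A"] is None and "A" not in "".join(
                    final_specs[(d, label)] for d in domains):
                del include["A"]
            mv_model = MultivariateTwinModel(pairs_mv, domains, include)
            mv = mv_model.fit(seed=config.seed)
            full = MultivariateTwinModel(
                pairs_mv, domains, {"A": None, "C": None, "E": None}).fit(
                seed=config.seed)
            try:
                sat = saturated_minus2ll(pairs_mv, domains)
                chain = {"saturated_vs_full": compare_models(sat, full),
                         "full_vs_specified": compare_models(full, mv)}
            except ValueError as err:
                chain = {"error": str(err)}
            entry = {
                "include": {k: (v if v is not None else list(domains))
                            for k, v in include.items()},
                "sigma": {c: m.to_numpy().tolist() for c, m in mv.sigma.items()},
                "minus2ll": mv.minus2ll, "aic": mv.aic, "chain": chain,
                "rhoE": mv.correlation_matrix("E").to_numpy().tolist(),
            }
            if "A" in mv.sigma:
                sa = mv.sigma["A"]
                rho_a, h2b = {}, {}
                for i, di in enumerate(domains):
                    for dj in domains[i + 1:]:
                        if sa.loc[di, di] > 0 and sa.loc[dj, dj] > 0:
                            rho_a[f"{di}~{dj}"] = mv.genetic_correlation(di, dj)
                            h2b[f"{di}~{dj}"] = mv.bivariate_heritability(
                                di, dj, clip=False)
                entry["rhoA"] = rho_a
                entry["h2_b"] = h2b
            report["multivariate"][label] = entry
            note("multivariate", trait=label)

    # -- sensitivity ----------------------------------------------------------
    if config.sensitivity_loading is not None and traits is not None:
        dom0 = config.simulation.domains[-1].name
        tname = [t for t in config.simulation.trait_names if t.endswith(dom0)]
        controls = sim.simulate_control_scores(
            traits, config.sensitivity_loading,
            typicality_col=tname[0], bias_col=tname[1], seed=config.seed)
        ind = metric_tables[dom0]["individual"].join(
            controls.set_index("individual_id"))
        ind = ind.dropna(subset=["taste_typicality_z", "evaluation_bias",
                                 "control_typicality", "control_bias"])
        design = _sex_age_design(ind)
        report["sensitivity"] = {"domain": dom0, "loading": config.sensitivity_loading}
        for label, col, ctrl in (("taste_typicality", "taste_typicality_z",
                                  "control_typicality"),
                                 ("evaluation_bias", "evaluation_bias",
                                  "control_bias")):
            covs = design.assign(control=ind[ctrl].to_numpy())
            resid = residualize(ind[col].to_numpy(), covs)
            ind2 = ind.copy()
            ind2[col] = resid
            pairs = make_pair_table(ind2, col)
            spec_name = final_specs[(dom0, label)]
            fit = UnivariateTwinModel(pairs, spec_name).fit(seed=config.seed)
            report["sensitivity"][label] = {
                "final_model": spec_name,
                "shares": fit.standardized_shares(),
                "h2": fit.heritability,
            }
        note("sensitivity", domain=dom0)

    report["log"] = log

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        for dom in domains:
            metric_tables[dom]["individual"].to_csv(out / f"metrics_{dom}.csv")
            metric_tables[dom]["pairs"].to_csv(out / f"pairs_{dom}.csv", index=False)
        with open(out / "pipeline.log", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry, default=float) + "\n")
    return report
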
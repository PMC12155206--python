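"""End-to-end pipeline: generate/ingest -> QC -> harmonize -> PLS per
modality -> leave-one-site-out -> outcome prediction -> report.

A single master seed deterministically derives per-stage seeds (via
``numpy.random.SeedSequence`` spawning), so a rerun with the same config and
seed reproduces every numeric output byte-for-byte. All intermediate tables
are written as delimited text; the run manifest records the configuration,
package version, and derived stage seeds.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import neuropls
from neuropls import io as npio
from neuropls.datatypes import CognitionMatrix, FeatureMatrix
from neuropls.generalize import LosoConfig, leave_one_site_out
from neuropls.harmonize import harmonize
from neuropls.pls import (
    association_with_covariate,
    bootstrap_loadings,
    fit_pls,
    latent_test_correlations,
    permutation_test,
    select_n_components,
)
from neuropls.predict import (
    evaluate_parsimonious,
    nested_elasticnet,
    pls_madrs_change,
    stability_select,
)
from neuropls.prep import (
    filter_by_motion,
    filter_by_surface_holes,
    filter_tracts,
    impute_cognition_mean,
    transform_wmh,
    zscore_columns,
)
from neuropls.synthetic import GeneratorConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    fd_threshold: float = 0.7
    max_holes: int = 380
    max_unusable: float = 0.03
    impute_before_qc: bool = True  # mean-impute cognition on the full sample


@dataclass
class HarmonizationConfig:
    modalities: tuple = ("FC", "WM")  # GM harmonization is optional, default off
    protect_covariates: bool = True
    covariates: tuple = ("age", "sex")
    fc_motion_covariate: bool = True  # add mean FD for functional data only


@dataclass
class ModalityPLSConfig:
    n_components: int | str = "auto"
    max_components: int = 5
    n_perm: int = 1000
    n_boot: int = 1000
    z_threshold: float = 3.0
    alpha: float = 0.05
    n_perm_select: int = 200


@dataclass
class LOSOSettings:
    modalities: tuple = ("FC",)
    n_components: int | str = "auto"
    max_components: int = 3
    n_perm_select: int = 200
    alpha: float = 0.05


@dataclass
class PredictionConfig:
    blocks: tuple = ("demo", "clinical", "cognitive", "gm")
    n_iter: int = 100
    test_n: int = 20
    inner_folds: int = 10
    stability_threshold: float = 0.95
    k_folds: int = 8
    run_madrs_change: bool = True
    madrs_n_components: int = 1
    madrs_n_perm: int = 500


@dataclass
class PipelineConfig:
    mode: str = "generate"  # or "ingest"
    input_dir: str | None = None
    outdir: str = "neuropls_run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    pls: ModalityPLSConfig = field(default_factory=ModalityPLSConfig)
    loso: LOSOSettings = field(default_factory=LOSOSettings)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        kwargs = {}
        for name, sub in [("generator", GeneratorConfig), ("qc", QCConfig),
                          ("harmonization", HarmonizationConfig),
                          ("pls", ModalityPLSConfig), ("loso", LOSOSettings),
                          ("prediction", PredictionConfig)]:
            if name in doc:
                section = dict(doc.pop(name))
                kwargs[name] = sub(**section)
        kwargs.update(doc)
        cfg = cls(**kwargs)
        if cfg.mode == "ingest" and not cfg.input_dir:
            raise ValueError("ingest mode requires input_dir")
        if cfg.mode not in ("generate", "ingest"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def _pls_stage(Xdf: pd.DataFrame, cognition: CognitionMatrix, cohort: pd.DataFrame,
               cfg: ModalityPLSConfig, seed: int) -> dict:
    """Full single-modality PLS analysis on an aligned sample."""
    rng = np.random.default_rng(seed)
    Y = cognition.data.loc[Xdf.index]
    Xz, _ = zscore_columns(Xdf)
    Yz, _ = zscore_columns(Y)
    if cfg.n_components == "auto":
        n_sig = select_n_components(Xz, Yz, cfg.max_components,
                                    n_perm=cfg.n_perm_select, alpha=cfg.alpha,
                                    seed=int(rng.integers(2 ** 31)))
        ncomp = max(1, n_sig)
    else:
        ncomp = int(cfg.n_components)
        n_sig = ncomp
    fit = fit_pls(Xz, Yz, ncomp)
    perm = permutation_test(Xz, Yz, ncomp, n_perm=cfg.n_perm,
                            seed=int(rng.integers(2 ** 31)))
    boot = bootstrap_loadings(Xz, Yz, ncomp, n_boot=cfg.n_boot,
                              z_threshold=cfg.z_threshold,
                              seed=int(rng.integers(2 ** 31)))
    assoc = latent_test_correlations(fit, Y, alpha=cfg.alpha)

    sub = cohort.set_index("participant_id").loc[Xdf.index]
    wmh = transform_wmh(sub["wmh_volume"], sub["icv"])
    covars = {"education": sub["education"].to_numpy(),
              "centile": sub["centile"].to_numpy(),
              "athf": sub["athf"].to_numpy(),
              "wmh_sqrt_icv": np.asarray(wmh)}
    cog_score = fit.y_scores[:, 0]
    covar_assoc = {name: association_with_covariate(cog_score, v)
                   for name, v in covars.items()}
    return {
        "n": len(Xdf), "n_features": Xdf.shape[1],
        "n_components": ncomp, "n_significant_components": n_sig,
        "variance_explained": fit.total_variance_explained_y,
        "variance_explained_debiased": perm.debiased_statistic,
        "permutation_p": perm.p_value,
        "significant": bool(perm.p_value < cfg.alpha),
        "n_robust_features": [int(boot.significant_mask[:, a].sum())
                              for a in range(ncomp)],
        "significant_tests": sorted(assoc.loc[assoc["significant"], "test"].unique()),
        "covariate_associations": {k: {"r": r, "p": p}
                                   for k, (r, p) in covar_assoc.items()},
        "fit": fit, "permutation": perm, "bootstrap": boot, "associations": assoc,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write tables, a manifest, and a report.

    Returns a nested dict with every headline quantity (also serialized to
    ``results/summary.yaml`` in the output directory).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["generate", "pls_FC", "pls_WM", "pls_GM",
                                       "loso", "predict", "madrs"])

    # --- stage 1: data ----------------------------------------------------
    stage = "generate/ingest"
    try:
        if config.mode == "generate":
            gen_cfg = dataclasses.replace(config.generator, seed=seeds["generate"])
            cohort, cognition, features, truth = generate_cohort(gen_cfg)
        else:
            cohort, cognition, features, truth = npio.read_dataset(config.input_dir)
        npio.write_dataset(outdir / "dataset", cohort, cognition, features, truth)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    results: dict = {"seed": config.seed, "n_input": len(cohort)}

    # --- stage 2: prep ----------------------------------------------------
    stage = "prep"
    try:
        if config.qc.impute_before_qc:
            cognition = impute_cognition_mean(cognition)
        fc_cohort = filter_by_motion(cohort, config.qc.fd_threshold)
        gm_cohort = filter_by_surface_holes(cohort, config.qc.max_holes)
        samples = {"FC": fc_cohort, "WM": cohort, "GM": gm_cohort}
        if "WM" in features:
            features["WM"] = filter_tracts(features["WM"], config.qc.max_unusable)
        if not config.qc.impute_before_qc:
            cognition = impute_cognition_mean(cognition)
        results["qc"] = {
            "n_after_fd_filter": len(fc_cohort),
            "n_after_holes_filter": len(gm_cohort),
            "n_tracts_retained": features["WM"].n_features if "WM" in features else 0,
            "n_cognition_imputed": int(cognition.missing_mask.to_numpy().sum()),
        }
        _ensure(outdir / "prep")
        for m in features:
            ids = samples[m]["participant_id"]
            features[m] = features[m].subset_participants(ids)
            npio.write_features(features[m], outdir / "prep" / f"features_{m}.csv")
        npio.write_cognition(cognition, outdir / "prep" / "cognition.csv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- stage 3: harmonization ------------------------------------------
    stage = "harmonization"
    try:
        harmonized: dict[str, FeatureMatrix] = {}
        n_sites = cohort["site"].nunique()
        for m, fm in features.items():
            if m in config.harmonization.modalities and n_sites > 1:
                covs = list(config.harmonization.covariates)
                if m == "FC" and config.harmonization.fc_motion_covariate:
                    covs = covs + ["mean_fd"]
                sub_cohort = samples[m].reset_index(drop=True)
                adjusted, model = harmonize(
                    fm, sub_cohort, covs,
                    protect_covariates=config.harmonization.protect_covariates)
                harmonized[m] = adjusted
                model.to_yaml(outdir / "prep" / f"harmonization_{m}.yaml")
            else:
                harmonized[m] = fm
        results["harmonization"] = {"modalities": sorted(
            m for m in features if m in config.harmonization.modalities and n_sites > 1)}
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- stage 4: PLS per modality ---------------------------------------
    stage = "pls"
    try:
        _ensure(outdir / "results")
        pls_results = {}
        for m, fm in harmonized.items():
            res = _pls_stage(fm.data, cognition, samples[m], config.pls, seeds[f"pls_{m}"])
            pls_results[m] = res
            res["associations"].to_csv(
                outdir / "results" / f"pls_{m}_test_correlations.csv", index=False)
            pd.DataFrame(res["bootstrap"].z_ratio, index=fm.feature_names,
                         columns=[f"LV{a+1}" for a in range(res["n_components"])]
                         ).rename_axis("feature").to_csv(
                outdir / "results" / f"pls_{m}_bootstrap_z.csv")
        results["pls"] = {m: {k: v for k, v in r.items()
                              if k not in ("fit", "permutation", "bootstrap", "associations")}
                          for m, r in pls_results.items()}
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- stage 5: leave-one-site-out -------------------------------------
    stage = "loso"
    try:
        loso_results = {}
        if n_sites >= 2:
            for m in config.loso.modalities:
                if m not in harmonized:
                    continue
                fm = harmonized[m]
                sub = samples[m].set_index("participant_id").loc[fm.data.index]
                loso_cfg = LosoConfig(
                    n_components=config.loso.n_components,
                    max_components=config.loso.max_components,
                    n_perm_select=config.loso.n_perm_select,
                    alpha=config.loso.alpha, seed=seeds["loso"])
                holdout = leave_one_site_out(
                    fm.data, cognition.data.loc[fm.data.index], sub["site"], loso_cfg)
                holdout.per_site.to_csv(outdir / "results" / f"loso_{m}.csv", index=False)
                loso_results[m] = {
                    "mean_r": holdout.mean_r,
                    "per_site": holdout.per_site.set_index("site")["r"].to_dict(),
                }
        results["loso"] = loso_results
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- stage 6: outcome prediction -------------------------------------
    stage = "prediction"
    try:
        results["prediction"] = _prediction_stage(
            config, cohort, samples, cognition, harmonized, seeds, outdir)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- report and manifest ---------------------------------------------
    _write_summary(results, outdir / "results" / "summary.yaml")
    _write_report(results, outdir / "report.txt")
    manifest = {"package_version": neuropls.__version__,
                "config": config.to_dict(), "stage_seeds": seeds}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return results


def _prediction_stage(config, cohort, samples, cognition, harmonized, seeds, outdir):
    pred_cfg = config.prediction
    blocks = []
    base = cohort.set_index("participant_id")
    labelled = base.loc[base["remission"].notna()]
    n_dropped = len(base) - len(labelled)
    if n_dropped:
        log.info("prediction: excluding %d participants without an endpoint label",
                 n_dropped)
    ids = labelled.index
    if "gm" in pred_cfg.blocks and "GM" in harmonized:
        ids = ids.intersection(harmonized["GM"].data.index)
    sub = labelled.loc[ids]
    if "demo" in pred_cfg.blocks:
        blocks.append(sub[["age", "sex", "education"]])
    if "clinical" in pred_cfg.blocks:
        blocks.append(sub[["madrs_baseline", "athf", "cirs_g"]])
    if "cognitive" in pred_cfg.blocks:
        blocks.append(cognition.data.loc[ids])
    for key, mod in (("gm", "GM"), ("fc", "FC"), ("wm", "WM")):
        if key in pred_cfg.blocks and mod in harmonized:
            blocks.append(harmonized[mod].data.reindex(ids).dropna())
    X = pd.concat(blocks, axis=1).dropna()
    y = sub.loc[X.index, "remission"].astype(int)

    run = nested_elasticnet(X, y, n_iter=pred_cfg.n_iter, test_n=pred_cfg.test_n,
                            inner_folds=pred_cfg.inner_folds, seed=seeds["predict"])
    run.stability_frequency.rename_axis("feature").to_csv(
        outdir / "results" / "stability_frequencies.csv")
    stable = stability_select(run, pred_cfg.stability_threshold)
    out = {"n": len(y), "n_features": X.shape[1], "n_remitters": int(y.sum()),
           "mean_auc": run.mean_auc, "auc_ci": list(run.auc_ci),
           "parsimonious_set": stable}
    if stable:
        auc, cm = evaluate_parsimonious(X[stable], y, k_folds=pred_cfg.k_folds,
                                        seed=seeds["predict"] + 1)
        out["parsimonious_auc"] = auc
        out["confusion"] = {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                            "sensitivity": cm.sensitivity,
                            "specificity": cm.specificity}
    if pred_cfg.run_madrs_change and sub["madrs_change"].notna().all():
        mres = pls_madrs_change(X, sub.loc[X.index, "madrs_change"],
                                n_components=pred_cfg.madrs_n_components,
                                n_perm=pred_cfg.madrs_n_perm, seed=seeds["madrs"])
        out["madrs_change"] = {
            "variance_explained": mres.variance_explained,
            "permutation_p": mres.permutation.p_value,
            "holdout_r": mres.holdout_r, "holdout_p": mres.holdout_p,
        }
    return out


def _ensure(path: Path) -> bool:
    path.mkdir(parents=True, exist_ok=True)
    return True


def _write_summary(results: dict, path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    with open(path, "w") as fh:
        yaml.safe_dump(clean(results), fh)


def _write_report(results: dict, path) -> None:
    lines = ["neuropls pipeline report", "=" * 40, ""]
    lines.append("[1] Sample")
    lines.append(f"  participants generated/ingested: {results['n_input']}")
    qc = results.get("qc", {})
    lines.append("")
    lines.append("[2] Quality control")
    lines.append(f"  after motion filter (FC sample):      {qc.get('n_after_fd_filter')}")
    lines.append(f"  after surface-hole filter (GM sample): {qc.get('n_after_holes_filter')}")
    lines.append(f"  tracts retained (WM):                  {qc.get('n_tracts_retained')}")
    lines.append(f"  cognition cells imputed:               {qc.get('n_cognition_imputed')}")
    lines.append("")
    lines.append("[3] Harmonization")
    lines.append(f"  modalities harmonized: {results.get('harmonization', {}).get('modalities')}")
    lines.append("")
    lines.append("[4] Brain-cognition PLS")
    for m, r in results.get("pls", {}).items():
        verdict = "significant" if r["significant"] else "not significant"
        lines.append(f"  {m}: n={r['n']}, {r['n_components']} LV(s), "
                     f"{100 * r['variance_explained']:.1f}% of cognition variance, "
                     f"permutation p={r['permutation_p']:.4g} ({verdict})")
        lines.append(f"      robust features per LV (|Z|>3): {r['n_robust_features']}")
        lines.append(f"      tests associated (Bonferroni): {r['significant_tests']}")
    lines.append("")
    lines.append("[5] Leave-one-site-out generalizability")
    for m, r in results.get("loso", {}).items():
        per_site = ", ".join(f"{s}: r={v:.3f}" for s, v in r["per_site"].items())
        lines.append(f"  {m}: mean held-out r={r['mean_r']:.3f} ({per_site})")
    lines.append("")
    lines.append("[6] Remission prediction")
    pred = results.get("prediction", {})
    if pred:
        lines.append(f"  n={pred['n']} ({pred['n_remitters']} remitters), "
                     f"{pred['n_features']} predictors")
        lines.append(f"  mean held-out AUC: {pred['mean_auc']:.3f} "
                     f"(95% band {pred['auc_ci'][0]:.3f}-{pred['auc_ci'][1]:.3f})")
        lines.append(f"  stable predictors (>95% of runs): {pred['parsimonious_set']}")
        if "parsimonious_auc" in pred:
            cm = pred["confusion"]
            lines.append(f"  parsimonious model: AUC={pred['parsimonious_auc']:.3f}, "
                         f"sens={cm['sensitivity']:.2f}, spec={cm['specificity']:.2f} "
                         f"(TP={cm['tp']}, FP={cm['fp']}, TN={cm['tn']}, FN={cm['fn']})")
        if "madrs_change" in pred:
            mc = pred["madrs_change"]
            lines.append(f"  MADRS-change PLS: {100 * mc['variance_explained']:.1f}% "
                         f"variance, permutation p={mc['permutation_p']:.4g}, "
                         f"held-out r={mc['holdout_r']:.3f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
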
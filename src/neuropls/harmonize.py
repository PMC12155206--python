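"""Empirical-Bayes site harmonization of brain-feature matrices.

Removes additive (location) and multiplicative (scale) site effects per
feature while preserving covariate effects (age, sex, and — for functional
data — head motion), in the location/scale batch-adjustment tradition used
throughout multi-site MRI work.

Model per feature g and participant j at site i::

    x_ijg = alpha_g + X_cov beta_g + gamma_ig + delta_ig * eps_ijg

Features are standardized by the pooled residual variance, per-site
location (gamma) and scale (delta^2) estimates are shrunk toward parametric
priors (normal for locations, inverse-gamma for scales) fitted across
features within each site by the method of moments, and the posterior
estimates are iterated to convergence. Adjusted data are reconstructed with
site effects removed and covariate effects restored (by default; a
``protect_covariates=False`` fit residualizes them instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from neuropls.datatypes import FeatureMatrix, SchemaError

log = logging.getLogger(__name__)

EB_CONVERGENCE = 1e-4
EB_MAX_ITER = 100


@dataclass
class HarmonizationModel:
    """Fitted harmonization parameters for one feature matrix."""

    sites: list
    covariates: list
    feature_names: list
    grand_mean: np.ndarray  # per feature
    beta_cov: np.ndarray  # covariates x features
    var_pooled: np.ndarray  # per feature
    gamma_star: np.ndarray  # sites x features, posterior location shifts
    delta2_star: np.ndarray  # sites x features, posterior squared scales
    cov_center: np.ndarray  # per covariate, training means (design centering)
    excluded_features: list = field(default_factory=list)
    protect_covariates: bool = True
    identity: bool = False  # single-site fallback

    def to_yaml(self, path) -> None:
        doc = {
            "sites": list(self.sites),
            "covariates": list(self.covariates),
            "feature_names": list(self.feature_names),
            "grand_mean": self.grand_mean.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "cov_center": self.cov_center.tolist(),
            "excluded_features": list(self.excluded_features),
            "protect_covariates": bool(self.protect_covariates),
            "identity": bool(self.identity),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "HarmonizationModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        arrays = {k: np.asarray(doc[k], dtype=float) for k in
                  ["grand_mean", "beta_cov", "var_pooled", "gamma_star",
                   "delta2_star", "cov_center"]}
        return cls(sites=doc["sites"], covariates=doc["covariates"],
                   feature_names=doc["feature_names"],
                   excluded_features=doc["excluded_features"],
                   protect_covariates=doc["protect_covariates"],
                   identity=doc["identity"], **arrays)


def _design(cohort: pd.DataFrame, covariates: list, center: np.ndarray | None = None):
    """Covariate design (n x c), centered on training means."""
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise SchemaError(f"covariates missing from cohort table: {missing}")
    M = cohort[list(covariates)].to_numpy(dtype=float)
    if np.isnan(M).any():
        raise SchemaError("covariates contain missing values")
    if center is None:
        center = M.mean(axis=0) if M.size else np.zeros(0)
    return M - center, center


def fit_harmonization(features: FeatureMatrix, cohort: pd.DataFrame,
                      covariates: list[str] | None = None, *,
                      protect_covariates: bool = True) -> HarmonizationModel:
    """Fit the empirical-Bayes site-adjustment model.

    ``cohort`` must be row-aligned with ``features`` and carry ``site`` plus
    the requested covariate columns. Features with zero within-site variance
    at any site are excluded from EB estimation and passed through unchanged
    by :func:`apply_harmonization`.
    """
    covariates = list(covariates) if covariates is not None else []
    X = features.values()
    if X.shape[0] != len(cohort):
        raise SchemaError("features and cohort are not row-aligned")
    if np.isnan(X).any():
        raise SchemaError("feature matrix contains missing values; impute first")
    site = cohort["site"].astype(str).to_numpy()
    sites = sorted(set(site))
    counts = pd.Series(site).value_counts()
    if (counts < 2).any():
        tiny = list(counts.index[counts < 2])
        raise ValueError(f"sites with a single participant cannot be harmonized: {tiny}")

    n, p = X.shape
    names = features.feature_names
    Mc, center = _design(cohort, covariates)
    if covariates:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Mc]))
        if rank < 1 + len(covariates):
            raise SchemaError("covariates are collinear")

    if len(sites) < 2:
        log.warning("fit_harmonization: single site; model is an identity adjustment")
        beta = (np.linalg.lstsq(Mc, X - X.mean(axis=0), rcond=None)[0]
                if covariates else np.zeros((0, p)))
        return HarmonizationModel(
            sites=sites, covariates=covariates, feature_names=names,
            grand_mean=X.mean(axis=0), beta_cov=beta,
            var_pooled=X.var(axis=0, ddof=1), gamma_star=np.zeros((1, p)),
            delta2_star=np.ones((1, p)), cov_center=center,
            protect_covariates=protect_covariates, identity=True)

    S = len(sites)
    site_idx = np.searchsorted(np.array(sites), site)
    onehot = np.zeros((n, S))
    onehot[np.arange(n), site_idx] = 1.0
    design = np.column_stack([onehot, Mc]) if covariates else onehot
    B = np.linalg.lstsq(design, X, rcond=None)[0]  # (S + c) x p
    site_means = B[:S]
    beta_cov = B[S:]
    n_per_site = onehot.sum(axis=0)
    grand_mean = (n_per_site / n) @ site_means
    resid = X - design @ B
    var_pooled = (resid ** 2).mean(axis=0)
    if (var_pooled <= 0).any():
        bad = [names[i] for i in np.flatnonzero(var_pooled <= 0)]
        raise ValueError(f"features with zero residual variance: {bad[:5]}")

    stand_mean = grand_mean[None, :] + (Mc @ beta_cov if covariates else 0.0)
    Z = (X - stand_mean) / np.sqrt(var_pooled)

    # per-site raw estimates, masking features with no within-site variance
    gamma_hat = np.zeros((S, p))
    delta2_hat = np.ones((S, p))
    usable = np.ones(p, dtype=bool)
    for i in range(S):
        Zi = Z[site_idx == i]
        gamma_hat[i] = Zi.mean(axis=0)
        d2 = Zi.var(axis=0, ddof=1)
        usable &= d2 > 0
        delta2_hat[i] = d2
    excluded = [names[i] for i in np.flatnonzero(~usable)]
    if excluded:
        log.warning("fit_harmonization: %d features have zero within-site "
                    "variance and are passed through: %s", len(excluded), excluded[:5])

    gamma_star = np.zeros((S, p))
    delta2_star = np.ones((S, p))
    u = usable
    for i in range(S):
        g_hat = gamma_hat[i, u]
        d2_hat = delta2_hat[i, u]
        g_bar = g_hat.mean()
        tau2 = g_hat.var(ddof=1)
        m = d2_hat.mean()
        s2 = d2_hat.var(ddof=1)
        # method-of-moments inverse-gamma hyperparameters
        aprior = (2.0 * s2 + m ** 2) / s2 if s2 > 0 else 100.0
        bprior = (m * s2 + m ** 3) / s2 if s2 > 0 else (99.0 * m)
        ni = float(n_per_site[i])
        g_post = g_hat.copy()
        d2_post = d2_hat.copy()
        Zi = Z[site_idx == i][:, u]
        for _ in range(EB_MAX_ITER):
            g_new = (ni * tau2 * g_hat + d2_post * g_bar) / (ni * tau2 + d2_post)
            sum2 = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (0.5 * sum2 + bprior) / (ni / 2.0 + aprior - 1.0)
            change = max(np.max(np.abs(g_new - g_post) / (np.abs(g_post) + 1e-12)),
                         np.max(np.abs(d2_new - d2_post) / d2_post))
            g_post, d2_post = g_new, d2_new
            if change < EB_CONVERGENCE:
                break
        gamma_star[i, u] = g_post
        delta2_star[i, u] = d2_post

    return HarmonizationModel(
        sites=sites, covariates=covariates, feature_names=names,
        grand_mean=grand_mean, beta_cov=beta_cov, var_pooled=var_pooled,
        gamma_star=gamma_star, delta2_star=delta2_star, cov_center=center,
        excluded_features=excluded, protect_covariates=protect_covariates)


def apply_harmonization(model: HarmonizationModel, features: FeatureMatrix,
                        cohort: pd.DataFrame) -> FeatureMatrix:
    """Apply a fitted model: remove site location/scale in standardized
    space, then restore the grand mean and (if protected) covariate effects.
    Deterministic; unseen site labels are an error."""
    if list(features.feature_names) != list(model.feature_names):
        raise SchemaError("feature names do not match the fitted model")
    X = features.values()
    site = cohort["site"].astype(str).to_numpy()
    unseen = sorted(set(site) - set(model.sites))
    if unseen:
        raise ValueError(f"sites not present in the fitted model: {unseen}")
    if model.identity:
        adj = X.copy()
        if not model.protect_covariates and model.covariates:
            Mc, _ = _design(cohort, model.covariates, model.cov_center)
            adj = adj - Mc @ model.beta_cov
        out = pd.DataFrame(adj, index=features.data.index, columns=model.feature_names)
        return FeatureMatrix(out, features.modality, features.unusable)

    site_idx = np.searchsorted(np.array(model.sites), site)
    Mc, _ = _design(cohort, model.covariates, model.cov_center)
    cov_part = Mc @ model.beta_cov if model.covariates else 0.0
    stand_mean = model.grand_mean[None, :] + cov_part
    Z = (X - stand_mean) / np.sqrt(model.var_pooled)
    Zadj = (Z - model.gamma_star[site_idx]) / np.sqrt(model.delta2_star[site_idx])
    restore = model.grand_mean[None, :]
    if model.protect_covariates and model.covariates:
        restore = restore + cov_part
    Xadj = Zadj * np.sqrt(model.var_pooled) + restore

    if model.excluded_features:
        keep = np.array([f in model.excluded_features for f in model.feature_names])
        Xadj[:, keep] = X[:, keep]
    out = pd.DataFrame(Xadj, index=features.data.index, columns=model.feature_names)
    return FeatureMatrix(out, features.modality, features.unusable)


def harmonize(features: FeatureMatrix, cohort: pd.DataFrame,
              covariates: list[str] | None = None, *,
              protect_covariates: bool = True) -> tuple[FeatureMatrix, HarmonizationModel]:
    """Fit and apply in one step (training-data harmonization)."""
    model = fit_harmonization(features, cohort, covariates,
                              protect_covariates=protect_covariates)
    return apply_harmonization(model, features, cohort), model
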
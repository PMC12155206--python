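"""Synthetic multi-site cohorts with known brain-cognition ground truth.

The generator emulates the structure of a multi-site late-life
treatment-resistant depression biomarker study: ~4 acquisition sites,
N in the low hundreds, three brain-feature blocks (functional-connectivity
edges, white-matter tract FA, gray-matter structure), a 12-test cognitive
battery over 6 domains, and a binary remission endpoint.

Data-generating model
---------------------
Shared latent factors ``F`` (participants x k, standard normal) drive both
blocks:

* each cognitive test loads on exactly one factor with loading
  ``sqrt(signal_strength)`` and unit total variance, so the fraction of Y
  variance carried by the factors equals ``signal_strength`` exactly;
* within each modality, a sparse subset of features loads on each factor
  with population feature-factor correlation ``x_loading_strength``;
* site effects are additive location shifts (normal across site x feature)
  and multiplicative scale factors (inverse-gamma across site x feature),
  the generating model assumed by empirical-Bayes harmonization;
* age, sex, and head motion enter every feature with known slopes;
* remission labels are drawn from a logistic model on a sparse set of
  informative gray-matter features, with the slope calibrated numerically so
  the true linear predictor attains a requested AUC.

Everything is reproducible: one seed fully determines the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from neuropls.datatypes import (
    DEFAULT_COGNITIVE_DOMAINS,
    CognitionMatrix,
    FeatureMatrix,
    fc_edge_names,
)

log = logging.getLogger(__name__)

DEFAULT_FEATURES = {"FC": 210, "WM": 62, "GM": 74}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the scale of the emulated study: ~230 participants with
    complete imaging across 4 sites, 210 FC edges (21 network components),
    62 FA tracts, 74 gray-matter variables, 12 cognitive tests, ~4% missing
    cognition, remission prevalence about one third.
    """

    n_participants: int = 230
    n_sites: int = 4
    features_per_modality: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    n_cognitive_tests: int = 12
    n_latent_factors: int = 2
    loading_sparsity: float = 0.10  # fraction of features carrying each factor
    signal_strength: float = 0.08  # fraction of Y variance explained by X factors
    x_loading_strength: float = 0.5  # feature-factor population correlation
    site_location_sd: float = 0.5
    site_scale_sd: float = 0.2
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.15, "sex": 0.1, "mean_fd": -0.2}
    )
    outcome_n_informative: int = 5
    outcome_auc_target: float = 0.70
    outcome_prevalence: float = 0.35
    outcome_modality: str = "GM"
    madrs_change_r2: float = 0.30
    missing_cognition_rate: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_sites": self.n_sites,
            "n_cognitive_tests": self.n_cognitive_tests,
            **{f"features[{m}]": p for m, p in self.features_per_modality.items()},
        }
        for name, v in counts.items():
            if int(v) <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_latent_factors < 0:
            raise ValueError("n_latent_factors must be >= 0")
        if not 0.0 <= self.signal_strength < 1.0:
            raise ValueError("signal_strength must be in [0, 1)")
        if not 0.0 <= self.missing_cognition_rate <= 0.2:
            raise ValueError("missing_cognition_rate must be in [0, 0.2]")
        if not 0.5 <= self.outcome_auc_target < 1.0:
            raise ValueError("outcome_auc_target must be in [0.5, 1)")

    def resolved_outcome_modality(self) -> str:
        """The modality driving the outcome; falls back to the first
        available one when the configured block is absent."""
        if self.outcome_modality in self.features_per_modality:
            return self.outcome_modality
        return next(iter(self.features_per_modality))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    factor_scores: np.ndarray  # n x k
    factor_loadings_X: dict  # modality -> p_m x k
    factor_loadings_Y: np.ndarray  # q x k
    informative_feature_ids: list
    outcome_coefficients: np.ndarray  # aligned with informative_feature_ids
    outcome_slope: float
    outcome_intercept: float
    site_location: dict  # modality -> sites x p_m
    site_scale: dict  # modality -> sites x p_m
    covariate_slopes: dict  # covariate -> slope (uniform across features)
    planted_variance_explained: float
    seed: int = 0


def _true_predictor_auc(slope: float, z: np.ndarray) -> float:
    """AUC of the true linear predictor when labels are Bernoulli with
    logit = intercept + slope*z; independent of the intercept."""
    p1 = special.expit(slope * z)  # z sorted ascending
    s0 = 1.0 - p1
    csum = np.concatenate(([0.0], np.cumsum(s0)))[:-1]
    numer = float((p1 * csum).sum())
    denom = float(p1.sum() * s0.sum() - (p1 * s0).sum())
    return numer / denom if denom > 0 else 0.5


def calibrate_outcome_model(auc_target: float, prevalence: float) -> tuple[float, float]:
    """Slope and intercept of the logistic outcome model such that the true
    standardized linear predictor attains ``auc_target`` with the requested
    label prevalence. Deterministic (quadrature grid, no RNG)."""
    m = 4001
    z = special.ndtri((np.arange(m) + 0.5) / m)  # sorted N(0,1) grid
    if auc_target <= 0.5:
        slope = 0.0
    else:
        slope = float(optimize.brentq(
            lambda c: _true_predictor_auc(c, z) - auc_target, 1e-9, 50.0, xtol=1e-10))
    intercept = float(optimize.brentq(
        lambda a: special.expit(a + slope * z).mean() - prevalence, -60.0, 60.0,
        xtol=1e-12))
    return slope, intercept


def _sparse_loadings(rng: np.random.Generator, p: int, k: int,
                     sparsity: float, strength: float) -> np.ndarray:
    """Loadings with disjoint sparse supports: each factor lands on
    ``round(sparsity*p)`` features; loaded features carry population
    feature-factor correlation ``strength``."""
    L = np.zeros((p, k))
    if k == 0 or strength == 0:
        return L
    per_factor = max(1, int(round(sparsity * p)))
    order = rng.permutation(p)
    for a in range(k):
        block = order[a * per_factor:(a + 1) * per_factor]
        if block.size == 0:  # more factors than disjoint blocks: wrap around
            block = order[(a * per_factor) % p:(a * per_factor) % p + per_factor]
        signs = rng.choice([-1.0, 1.0], size=block.size)
        L[block, a] = strength * signs
    return L


def _site_effects(rng: np.random.Generator, n_sites: int, p: int,
                  location_sd: float, scale_sd: float) -> tuple[np.ndarray, np.ndarray]:
    gamma = rng.normal(0.0, location_sd, size=(n_sites, p)) if location_sd > 0 else np.zeros((n_sites, p))
    if scale_sd > 0:
        # inverse-gamma with mean 1 and sd scale_sd across site x feature
        a = 2.0 + 1.0 / scale_sd ** 2
        b = a - 1.0
        delta2 = b / rng.gamma(a, 1.0, size=(n_sites, p))
        delta = np.sqrt(delta2)
    else:
        delta = np.ones((n_sites, p))
    return gamma, delta


def generate_cohort(config: GeneratorConfig):
    """Generate one synthetic multi-site cohort.

    Returns
    -------
    (cohort, cognition, features, truth)
        ``cohort`` is the participant table, ``cognition`` a
        :class:`CognitionMatrix`, ``features`` a dict modality ->
        :class:`FeatureMatrix`, and ``truth`` the :class:`SyntheticTruth`
        needed for parameter-recovery tests.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ["cohort", "factors", "loadings", "site", "noise", "outcome", "missing"],
        root.spawn(7))}

    n = config.n_participants
    k = config.n_latent_factors
    q = config.n_cognitive_tests
    v = config.signal_strength

    # --- participant table ------------------------------------------------
    rc = streams["cohort"]
    sites = np.array([f"site{1 + i % config.n_sites}" for i in range(n)])
    rc.shuffle(sites)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    age = np.clip(rc.normal(68.0, 6.0, n), 60.0, 90.0)
    sex = (rc.random(n) < 0.68).astype(int)  # 1 = female, ~68%
    education = np.clip(rc.normal(14.8, 2.5, n), 8.0, 22.0)
    madrs_baseline = np.clip(rc.normal(19.5, 9.0, n), 6.0, 50.0).round(0)
    athf = np.clip(rc.normal(8.0, 2.8, n), 2.0, 20.0).round(0)
    cirs_g = np.clip(rc.normal(8.5, 4.4, n), 0.0, 30.0).round(0)
    mean_fd = np.exp(rc.normal(np.log(0.18), 0.65, n))
    icv = rc.normal(1.45e6, 1.4e5, n)
    wmh_volume = np.exp(rc.normal(7.5, 1.0, n))
    centile = rc.beta(2.0, 2.0, n)
    surface_holes = np.exp(rc.normal(np.log(100.0), 0.55, n)).round(0).astype(int)

    # --- latent factors and cognition ------------------------------------
    F = streams["factors"].standard_normal((n, k)) if k else np.zeros((n, 0))
    Ly = np.zeros((q, k))
    if k and v > 0:
        for j in range(q):
            Ly[j, j % k] = np.sqrt(v)
    rn = streams["noise"]
    y_noise_sd = np.sqrt(1.0 - (Ly ** 2).sum(axis=1))
    Y = F @ Ly.T + rn.standard_normal((n, q)) * y_noise_sd
    test_names = list(DEFAULT_COGNITIVE_DOMAINS)[:q] if q <= 12 else (
        list(DEFAULT_COGNITIVE_DOMAINS) + [f"test_{j}" for j in range(13, q + 1)])
    domains = {t: DEFAULT_COGNITIVE_DOMAINS.get(t, "extra") for t in test_names}

    # --- brain features ---------------------------------------------------
    rl = streams["loadings"]
    rs = streams["site"]
    site_codes = pd.Categorical(sites, categories=[f"site{i+1}" for i in range(config.n_sites)]).codes
    age_z = (age - age.mean()) / age.std()
    fd_z = (np.log(mean_fd) - np.log(mean_fd).mean()) / np.log(mean_fd).std()
    sex_c = sex - sex.mean()
    cov_design = {"age": age_z, "sex": sex_c, "mean_fd": fd_z}
    slopes = dict(config.covariate_effects)

    loadings_X: dict[str, np.ndarray] = {}
    site_loc: dict[str, np.ndarray] = {}
    site_scl: dict[str, np.ndarray] = {}
    features: dict[str, FeatureMatrix] = {}
    for modality, p in config.features_per_modality.items():
        Lx = _sparse_loadings(rl, p, k, config.loading_sparsity, config.x_loading_strength)
        noise_sd = np.sqrt(np.clip(1.0 - (Lx ** 2).sum(axis=1), 1e-12, None))
        signal = F @ Lx.T + rn.standard_normal((n, p)) * noise_sd
        cov_part = np.zeros((n, p))
        for c, b in slopes.items():
            if c == "mean_fd" and modality != "FC":
                continue  # head motion only perturbs functional data
            cov_part += np.outer(cov_design[c], np.full(p, b))
        gamma, delta = _site_effects(rs, config.n_sites, p,
                                     config.site_location_sd, config.site_scale_sd)
        Xm = cov_part + signal * delta[site_codes] + gamma[site_codes]
        if modality == "FC":
            names = fc_edge_names(_fc_components_for(p))[:p]
        elif modality == "WM":
            names = [f"tract_{i + 1:02d}" for i in range(p)]
        else:
            names = ([f"thickness_{i + 1:02d}" for i in range(min(p, 60))]
                     + [f"volume_{i + 1:02d}" for i in range(max(0, p - 60))])
        df = pd.DataFrame(Xm, index=pd.Index(ids, name="participant_id"), columns=names)
        unusable = None
        if modality == "WM":
            unusable = pd.Series(rs.beta(0.4, 40.0, p), index=names, name="unusable")
            miss = rs.random((n, p)) < unusable.to_numpy()
            df = df.mask(pd.DataFrame(miss, index=df.index, columns=df.columns))
        features[modality] = FeatureMatrix(df, modality, unusable)
        loadings_X[modality] = Lx
        site_loc[modality] = gamma
        site_scl[modality] = delta

    # --- outcome ----------------------------------------------------------
    ro = streams["outcome"]
    out_mod = features[config.resolved_outcome_modality()]
    n_inf = min(config.outcome_n_informative, out_mod.n_features)
    inf_idx = ro.choice(out_mod.n_features, size=n_inf, replace=False)
    inf_names = [out_mod.feature_names[i] for i in inf_idx]
    coefs = ro.choice([-1.0, 1.0], size=n_inf)
    slope, intercept = calibrate_outcome_model(config.outcome_auc_target,
                                               config.outcome_prevalence)
    truth = SyntheticTruth(
        factor_scores=F, factor_loadings_X=loadings_X, factor_loadings_Y=Ly,
        informative_feature_ids=inf_names, outcome_coefficients=coefs,
        outcome_slope=slope, outcome_intercept=intercept,
        site_location=site_loc, site_scale=site_scl,
        covariate_slopes=slopes, planted_variance_explained=v, seed=config.seed,
    )
    remission = generate_outcome_labels(out_mod, truth, config, rng=ro)

    rm = streams["missing"]
    eta = true_linear_predictor(out_mod, truth)
    change_noise = rm.standard_normal(n)
    r2 = config.madrs_change_r2
    change_std = np.sqrt(r2) * (-eta) + np.sqrt(1 - r2) * change_noise
    madrs_change = np.round(8.0 * change_std - 9.0, 0)

    cohort = pd.DataFrame({
        "participant_id": ids, "site": sites, "age": age.round(1), "sex": sex,
        "education": education.round(1), "madrs_baseline": madrs_baseline,
        "madrs_change": madrs_change, "remission": remission, "athf": athf,
        "cirs_g": cirs_g, "mean_fd": mean_fd.round(4), "icv": icv.round(0),
        "wmh_volume": wmh_volume.round(1), "centile": centile.round(4),
        "surface_holes": surface_holes,
    })

    Ydf = pd.DataFrame(Y, index=pd.Index(ids, name="participant_id"), columns=test_names)
    if config.missing_cognition_rate > 0:
        holes = rm.random(Ydf.shape) < config.missing_cognition_rate
        Ydf = Ydf.mask(pd.DataFrame(holes, index=Ydf.index, columns=Ydf.columns))
    cognition = CognitionMatrix(Ydf, domains)
    return cohort, cognition, features, truth


def _fc_components_for(n_edges: int) -> int:
    """Smallest component count whose edge set covers n_edges."""
    c = 2
    while c * (c - 1) // 2 < n_edges:
        c += 1
    return c


def true_linear_predictor(features: FeatureMatrix, truth: SyntheticTruth) -> np.ndarray:
    """Standardized true linear predictor of the outcome model (unit variance
    in population terms) for the given feature rows."""
    if len(truth.informative_feature_ids) == 0:
        return np.zeros(len(features.data))  # null outcome: labels independent of X
    missing = [f for f in truth.informative_feature_ids if f not in features.data.columns]
    if missing:
        raise ValueError(f"informative features absent from matrix: {missing}")
    sub = features.data[truth.informative_feature_ids].to_numpy(dtype=float)
    if np.isnan(sub).any():
        col_mean = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), col_mean, sub)
    sub = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    eta = sub @ truth.outcome_coefficients
    return eta / np.sqrt(len(truth.outcome_coefficients))


def generate_outcome_labels(features: FeatureMatrix, truth: SyntheticTruth,
                            config: GeneratorConfig, rng=None,
                            max_retries: int = 10) -> np.ndarray:
    """Draw binary remission labels from the calibrated logistic model on the
    informative features. Degenerate all-one/all-zero draws are regenerated
    (bounded retries)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    eta = true_linear_predictor(features, truth)
    prob = special.expit(truth.outcome_intercept + truth.outcome_slope * eta)
    for attempt in range(max_retries):
        labels = (rng.random(len(prob)) < prob).astype(int)
        if 0 < labels.sum() < len(labels):
            return labels
        log.warning("generate_outcome_labels: degenerate draw (attempt %d), retrying",
                    attempt + 1)
    raise RuntimeError("could not draw non-degenerate outcome labels; "
                       "check outcome_prevalence and intercept")
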
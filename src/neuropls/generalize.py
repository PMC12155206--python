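"""Leave-one-site-out (LOSO) generalizability of PLS brain-cognition models.

For each acquisition site, a PLS model is trained on the remaining sites,
cognitive tests significantly associated with the training latent variables
are summarized into a composite (first principal component), and held-out
participants' cognition is predicted by pushing their standardized brain
features through the training beta coefficients. The held-out correlation
between predicted and observed composites quantifies between-site
generalizability. Every trainable quantity — standardization parameters,
the PLS fit, the test selection, and the composite weights — comes from the
training sites only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from neuropls.pls import fit_pls, latent_test_correlations, select_n_components
from neuropls.prep import zscore_columns

log = logging.getLogger(__name__)

MIN_SITE_N = 3


def composite_cognition(Y: pd.DataFrame, selected_tests: list[str]):
    """First-principal-component composite of the selected (standardized)
    cognitive tests.

    Returns ``(scores, weights)``; the sign is fixed so the composite
    correlates positively with the mean of the selected tests. A single
    selected test is returned standardized, with a warning.
    """
    if len(selected_tests) == 0:
        raise ValueError("no tests selected for the composite")
    sub = Y[list(selected_tests)].to_numpy(dtype=float)
    if len(selected_tests) == 1:
        log.warning("composite_cognition: single test selected; composite is "
                    "that test standardized")
        s = sub[:, 0]
        s = (s - s.mean()) / s.std(ddof=1)
        return s, np.array([1.0])
    centered = sub - sub.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    weights = Vt[0]
    scores = centered @ weights
    if np.corrcoef(scores, sub.mean(axis=1))[0, 1] < 0:
        weights = -weights
        scores = -scores
    return scores, weights


@dataclass
class LosoConfig:
    """Settings for the leave-one-site-out evaluation."""

    n_components: int | str = "auto"  # "auto" = sequential permutation rule
    max_components: int = 5
    n_perm_select: int = 200
    alpha: float = 0.05
    min_site_n: int = MIN_SITE_N
    fixed_test_list: list[str] | None = None  # bypass in-fold test selection
    seed: int = 0


@dataclass
class SiteHoldoutResult:
    """Per-site held-out performance of the PLS model."""

    per_site: pd.DataFrame  # site, n_test, r, p, n_components, n_selected_tests
    composite_tests: dict = field(default_factory=dict)  # site -> training test list

    @property
    def mean_r(self) -> float:
        return float(self.per_site["r"].mean())


def leave_one_site_out(X: pd.DataFrame, Y: pd.DataFrame, sites: pd.Series,
                       config: LosoConfig | None = None) -> SiteHoldoutResult:
    """Evaluate PLS generalizability across sites.

    ``X`` (brain features) and ``Y`` (cognition) are raw, row-aligned
    frames; standardization happens inside each training fold. Sites smaller
    than ``config.min_site_n`` are skipped with a warning.
    """
    config = config or LosoConfig()
    if not (len(X) == len(Y) == len(sites)):
        raise ValueError("X, Y, and sites must be row-aligned")
    site_labels = sites.astype(str).to_numpy()
    unique_sites = sorted(set(site_labels))
    if len(unique_sites) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")
    rng = np.random.default_rng(config.seed)

    rows = []
    composite_tests: dict[str, list[str]] = {}
    for site in unique_sites:
        test_mask = site_labels == site
        n_test = int(test_mask.sum())
        if n_test < config.min_site_n:
            log.warning("leave_one_site_out: site %s has %d participants; skipped",
                        site, n_test)
            continue
        Xtr, x_scaler = zscore_columns(X.loc[~test_mask])
        Ytr, y_scaler = zscore_columns(Y.loc[~test_mask])
        if config.n_components == "auto":
            ncomp = select_n_components(
                Xtr, Ytr, config.max_components, n_perm=config.n_perm_select,
                alpha=config.alpha, seed=int(rng.integers(2 ** 31)))
            ncomp = max(1, ncomp)  # always evaluate at least one LV
        else:
            ncomp = int(config.n_components)
        fit = fit_pls(Xtr, Ytr, ncomp)

        if config.fixed_test_list is not None:
            selected = list(config.fixed_test_list)
        else:
            assoc = latent_test_correlations(fit, Ytr, alpha=config.alpha)
            selected = sorted(assoc.loc[assoc["significant"], "test"].unique())
            if not selected:
                log.warning("leave_one_site_out: no significant tests for held-out "
                            "site %s; falling back to all tests", site)
                selected = list(Y.columns)
        composite_tests[site] = selected
        _, weights = composite_cognition(Ytr, selected)

        Xte = x_scaler.transform(X.loc[test_mask]).to_numpy(dtype=float)
        Yte = y_scaler.transform(Y.loc[test_mask])
        Yhat = pd.DataFrame(Xte @ fit.beta, columns=Y.columns)
        sel_means = Ytr[selected].to_numpy().mean(axis=0)  # ~0; composite centering
        pred_comp = (Yhat[selected].to_numpy() - sel_means) @ weights
        obs_comp = (Yte[selected].to_numpy() - sel_means) @ weights
        if np.std(pred_comp) == 0 or np.std(obs_comp) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(pred_comp, obs_comp)
        rows.append((site, n_test, float(r), float(p), ncomp, len(selected)))

    per_site = pd.DataFrame(rows, columns=["site", "n_test", "r", "p",
                                           "n_components", "n_selected_tests"])
    return SiteHoldoutResult(per_site=per_site, composite_tests=composite_tests)
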
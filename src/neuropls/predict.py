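"""Treatment-outcome prediction: stability-selected elastic-net remission
models and a PLS model of continuous depression-score change.

The remission classifier follows an iterated nested scheme: on each of
``n_iter`` iterations the cohort is split into a training set and a small
held-out test set (default 20 participants, stratified by outcome); an
elastic-net logistic regression is tuned by inner stratified 10-fold
cross-validation over a penalty grid (maximizing inner AUC), refit on the
full training split, and scored on the held-out set. Features whose
coefficients survive regularization in more than 95% of iterations form the
parsimonious model, which is then evaluated with plain stratified k-fold
cross-validation and a confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from neuropls.pls import PermutationResult, PLSFit, fit_pls, permutation_test
from neuropls.prep import zscore_columns

log = logging.getLogger(__name__)

DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)
DEFAULT_CS = tuple(np.logspace(-2, 2, 20))
STABILITY_THRESHOLD = 0.95
COEF_TOL = 1e-8


@dataclass
class ConfusionMatrix:
    """2x2 confusion counts with derived operating characteristics."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float = float("nan")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


@dataclass
class PredictionRun:
    """Result of the iterated nested elastic-net procedure."""

    feature_names: list
    n_iter: int
    test_n: int
    aucs: np.ndarray  # held-out AUC per usable iteration (NaN = excluded)
    selected_sets: list  # per-iteration lists of nonzero-coefficient features
    chosen_params: list  # per-iteration (C, l1_ratio)
    stability_frequency: pd.Series
    seed: int | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.aucs))

    @property
    def auc_ci(self) -> tuple[float, float]:
        """Percentile 95% interval of the held-out AUCs across iterations."""
        ok = self.aucs[~np.isnan(self.aucs)]
        return (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))

    @property
    def parsimonious_set(self) -> list:
        return stability_select(self)


def _one_se_choice(scores: np.ndarray, Cs: np.ndarray,
                   l1_ratios: np.ndarray) -> tuple[float, float]:
    """One-standard-error penalty selection from inner-CV scores.

    ``scores`` has shape (folds, l1_ratios, Cs). Among grid points whose mean
    inner AUC is within one standard error of the maximum, choose the most
    parsimonious: the smallest C (strongest shrinkage), breaking ties toward
    the largest l1 mixing (sparsest penalty). Under a flat score surface
    (uninformative features) this collapses to the strongest penalty, so no
    feature "survives regularization" by accident of tie-breaking.
    """
    n_folds = scores.shape[0]
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_best = np.unravel_index(int(np.argmax(mean)), mean.shape)
    threshold = mean[i_best] - se[i_best]
    order_C = np.argsort(Cs)  # ascending: strongest penalty first
    order_l1 = np.argsort(-l1_ratios)  # sparsest mixing first
    for ic in order_C:
        for il in order_l1:
            if mean[il, ic] >= threshold:
                return float(Cs[ic]), float(l1_ratios[il])
    return float(Cs[order_C[0]]), float(l1_ratios[order_l1[0]])


def _stratified_split(rng: np.random.Generator, labels: np.ndarray, test_n: int):
    """Random test indices of size test_n, stratified by label (proportional
    allocation with largest-remainder rounding)."""
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    quota = test_n * counts / n
    base = np.floor(quota).astype(int)
    rem = test_n - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    base = np.minimum(np.maximum(base, 1), counts - 1)  # keep both classes everywhere
    test_idx = []
    for cls, k in zip(classes, base):
        pool = np.flatnonzero(labels == cls)
        test_idx.append(rng.choice(pool, size=k, replace=False))
    return np.sort(np.concatenate(test_idx))


def nested_elasticnet(features: pd.DataFrame, labels, n_iter: int = 100,
                      test_n: int = 20, inner_folds: int = 10,
                      l1_ratios=DEFAULT_L1_RATIOS, Cs=DEFAULT_CS,
                      seed=None, max_iter: int = 2000, tol: float = 1e-3) -> PredictionRun:
    """Iterated nested cross-validated elastic-net logistic regression.

    Standardization, penalty selection (inner stratified CV scored by AUC,
    with the one-standard-error rule picking the most parsimonious penalty
    whose inner AUC is within 1 SE of the best), and the final refit all
    happen strictly inside each training split; the held-out AUC is computed
    on the ``test_n`` left-out participants.
    Iterations whose test split ends up single-class are excluded from the
    AUC mean (stratified splitting makes this rare by construction).
    """
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("both outcome classes must be present (>=2 each)")
    if len(features) != len(y):
        raise ValueError("features and labels must be row-aligned")
    rng = np.random.default_rng(seed)
    names = list(features.columns)
    Xall = features.to_numpy(dtype=float)
    n = len(y)

    aucs = np.full(n_iter, np.nan)
    selected_sets: list[list] = []
    chosen: list[tuple[float, float]] = []
    nonzero_counts = np.zeros(len(names))
    for it in range(n_iter):
        test_idx = _stratified_split(rng, y, test_n)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = Xall[train_mask], y[train_mask]
        Xte, yte = Xall[test_idx], y[test_idx]
        scaler = StandardScaler().fit(Xtr)
        Xtr_s = scaler.transform(Xtr)
        Xte_s = scaler.transform(Xte)
        inner_cv = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                   random_state=int(rng.integers(2 ** 31)))
        model = LogisticRegressionCV(
            Cs=list(Cs), l1_ratios=list(l1_ratios), solver="saga",
            cv=inner_cv, scoring="roc_auc", max_iter=max_iter, tol=tol,
            random_state=int(rng.integers(2 ** 31)), n_jobs=None,
            use_legacy_attributes=False,
        ).fit(Xtr_s, ytr)
        C_sel, l1_sel = _one_se_choice(model.scores_, np.asarray(model.Cs_),
                                       np.asarray(model.l1_ratios_))
        final = LogisticRegression(
            C=C_sel, l1_ratio=l1_sel, solver="saga", max_iter=max_iter,
            tol=tol, random_state=int(rng.integers(2 ** 31))).fit(Xtr_s, ytr)
        coef = final.coef_.ravel()
        nz = np.abs(coef) > COEF_TOL
        nonzero_counts += nz
        selected_sets.append([names[i] for i in np.flatnonzero(nz)])
        chosen.append((C_sel, l1_sel))
        model = final
        if len(np.unique(yte)) < 2:
            log.warning("nested_elasticnet: single-class test split at iteration "
                        "%d; AUC undefined, excluded", it)
            continue
        aucs[it] = roc_auc_score(yte, model.predict_proba(Xte_s)[:, 1])

    freq = pd.Series(nonzero_counts / n_iter, index=names, name="stability_frequency")
    return PredictionRun(feature_names=names, n_iter=n_iter, test_n=test_n,
                         aucs=aucs, selected_sets=selected_sets,
                         chosen_params=chosen, stability_frequency=freq,
                         seed=seed if isinstance(seed, int) else None)


def stability_select(run: PredictionRun, threshold: float = STABILITY_THRESHOLD) -> list:
    """Features surviving regularization in strictly more than
    ``threshold`` of iterations, sorted by decreasing frequency."""
    freq = run.stability_frequency
    keep = freq[freq > threshold].sort_values(ascending=False)
    if keep.empty:
        log.warning("stability_select: no feature exceeds the %.0f%% threshold",
                    100 * threshold)
    return list(keep.index)


def evaluate_parsimonious(features: pd.DataFrame, labels, k_folds: int = 8,
                          seed=None, prob_threshold: float = 0.5,
                          threshold_rule: str = "fixed") -> tuple[float, ConfusionMatrix]:
    """Stratified k-fold evaluation of the parsimonious feature subset with a
    lightly ridge-stabilized (effectively unpenalized) logistic model.

    Out-of-fold probabilities are pooled into a single AUC; classes are
    assigned at ``prob_threshold`` (``threshold_rule="youden"`` instead picks
    the pooled-ROC Youden-optimal point) to build the confusion matrix.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature subset")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(labels, dtype=int)
    X = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True,
                         random_state=int(rng.integers(2 ** 31)))
    prob = np.empty(len(y))
    for tr, te in cv.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        clf = LogisticRegression(C=1e3, max_iter=5000)
        clf.fit(scaler.transform(X[tr]), y[tr])
        prob[te] = clf.predict_proba(scaler.transform(X[te]))[:, 1]
    auc = float(roc_auc_score(y, prob))
    if threshold_rule == "youden":
        from sklearn.metrics import roc_curve
        fpr, tpr, thr = roc_curve(y, prob)
        prob_threshold = float(thr[int(np.argmax(tpr - fpr))])
    pred = (prob >= prob_threshold).astype(int)
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        auc=auc,
    )
    return auc, cm


@dataclass
class MadrsChangeResult:
    """PLS model of continuous depression-score change."""

    fit: PLSFit
    permutation: PermutationResult
    holdout_r: float
    holdout_p: float
    n_holdout: int

    @property
    def variance_explained(self) -> float:
        return self.fit.total_variance_explained_y


def pls_madrs_change(features: pd.DataFrame, madrs_change, n_components: int = 1,
                     n_perm: int = 1000, holdout_fraction: float = 0.2,
                     seed=None) -> MadrsChangeResult:
    """PLS regression of depression-score change on a combined
    clinical/demographic/cognitive/brain feature block.

    Reports in-sample variance explained, a permutation p-value, and the
    predicted-vs-observed correlation on a random held-out split.
    """
    y = np.asarray(madrs_change, dtype=float)
    if len(features) != len(y):
        raise ValueError("features and outcome must be row-aligned")
    if np.std(y) == 0:
        raise ValueError("outcome is constant")
    rng = np.random.default_rng(seed)
    n = len(y)
    Xz, _ = zscore_columns(features)
    yz = (y - y.mean()) / y.std(ddof=1)
    fit = fit_pls(Xz, yz[:, None], n_components)
    perm = permutation_test(Xz, yz[:, None], n_components, n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))

    n_test = max(3, int(round(holdout_fraction * n)))
    test_idx = rng.choice(n, size=n_test, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[test_idx] = True
    Xtr, x_scaler = zscore_columns(features.loc[~mask])
    ytr = y[~mask]
    ytr_z = (ytr - ytr.mean()) / ytr.std(ddof=1)
    hfit = fit_pls(Xtr, ytr_z[:, None], n_components)
    Xte = x_scaler.transform(features.loc[mask]).to_numpy(dtype=float)
    pred = (Xte @ hfit.beta).ravel()
    r, p = stats.pearsonr(pred, y[mask])
    return MadrsChangeResult(fit=fit, permutation=perm, holdout_r=float(r),
                             holdout_p=float(p), n_holdout=n_test)
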
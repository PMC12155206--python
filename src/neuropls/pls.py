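"""Partial least squares (PLS) regression with resampling inference.

The engine links a standardized brain-feature block X (participants x
features) to a standardized cognition block Y (participants x tests) through
paired latent variables that maximize cross-block covariance. Inference
follows the resampling conventions of the brain-behavior PLS literature:

* model significance by permuting participants' Y rows and refitting
  (statistic: total fraction of Y variance explained);
* loading robustness by bootstrap over participants, with each replicate's
  components re-aligned (order and sign) to the original fit before the
  bootstrap ratio Z = mean / SE is accumulated; |Z| > 3 flags robust features;
* latent-score / cognitive-test correlations with Bonferroni correction over
  the components x tests family.

The fit itself is NIPALS in regression mode: only X is deflated, so the
Y-side loading of each component is computed against the original Y and the
per-component variance-explained contributions are additive (X-scores are
mutually orthogonal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

Z_THRESHOLD = 3.0
_STANDARDIZATION_ATOL = 1e-6


def _as_array(m) -> np.ndarray:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float)
    a = np.asarray(m, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _check_standardized(a: np.ndarray, name: str) -> None:
    if np.abs(a.mean(axis=0)).max() > _STANDARDIZATION_ATOL:
        raise ValueError(f"{name} is not column-centered; z-score it first")


@dataclass
class PLSFit:
    """A fitted PLS regression model.

    ``beta`` maps standardized X to standardized fitted Y; ``x_scores`` (XS)
    are participants' projections onto each latent brain direction.
    """

    n_components: int
    x_weights: np.ndarray  # p x A, unit-norm weight vectors on deflated X
    x_rotations: np.ndarray  # p x A, project original X directly onto scores
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # q x A
    x_scores: np.ndarray  # n x A
    y_scores: np.ndarray  # n x A
    beta: np.ndarray  # p x q
    variance_explained_y: np.ndarray  # per-component fractions, additive
    feature_names: list[str] | None = None
    test_names: list[str] | None = None

    @property
    def total_variance_explained_y(self) -> float:
        return float(self.variance_explained_y.sum())

    def transform(self, X) -> np.ndarray:
        """Latent brain scores for (standardized) feature rows."""
        return _as_array(X) @ self.x_rotations

    def predict(self, X) -> np.ndarray:
        """Predicted standardized Y for (standardized) feature rows."""
        return _as_array(X) @ self.beta


def fit_pls(X, Y, n_components: int, *, max_iter: int = 500, tol: float = 1e-12,
            check_standardized: bool = True) -> PLSFit:
    """Fit a NIPALS PLS regression of Y on X.

    Parameters
    ----------
    X, Y
        Row-aligned, column-standardized matrices (participants x features
        and participants x tests).
    n_components
        Number of latent variables; must not exceed ``min(n-1, p)``.

    Notes
    -----
    Per component the weight vector converges to the dominant direction of
    the X'Y cross-covariance (power iteration); X is deflated by the rank-one
    score/loading outer product, Y is left intact (regression mode). The sign
    of each component is fixed so its largest-magnitude X-weight is positive.
    """
    Xa = _as_array(X).copy()
    Ya = _as_array(Y)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = Xa.shape
    q = Ya.shape[1]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound min(n-1, p)={max_rank}"
        )
    if check_standardized:
        _check_standardized(Xa, "X")
        _check_standardized(Ya, "Y")

    total_ss_y = float((Ya ** 2).sum())
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    Q = np.empty((q, n_components))
    T = np.empty((n, n_components))
    U = np.empty((n, n_components))
    var_exp = np.empty(n_components)

    Xd = Xa
    for a in range(n_components):
        C = Xd.T @ Ya  # p x q cross-covariance of deflated X with Y
        # NIPALS inner loop == power iteration for the dominant singular
        # direction of C; iterate in the cheaper of the two dimensions
        nrm = np.linalg.norm(C)
        if nrm == 0:
            raise ValueError(f"X deflated to rank {a}; reduce n_components")
        if p <= q:
            M = C @ C.T  # p x p
            w = C[:, int(np.argmax((C ** 2).sum(axis=0)))].copy()
            w /= np.linalg.norm(w)
            for _ in range(max_iter):
                w_new = M @ w
                w_new /= np.linalg.norm(w_new)
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w = w_new
        else:
            M = C.T @ C  # q x q
            v = M[:, int(np.argmax(np.diag(M)))].copy()
            v /= np.linalg.norm(v)
            for _ in range(max_iter):
                v_new = M @ v
                v_new /= np.linalg.norm(v_new)
                if np.linalg.norm(v_new - v) < tol:
                    v = v_new
                    break
                v = v_new
            w = C @ v
            w /= np.linalg.norm(w)
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0 or not np.isfinite(tt):
            raise ValueError(f"degenerate component {a + 1}; reduce n_components")
        p_load = Xd.T @ t / tt
        q_load = Ya.T @ t / tt  # vs original Y: scores orthogonal => additive
        # sign convention: largest-magnitude X-weight positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w, t, p_load, q_load = -w, -t, -p_load, -q_load
        qq = float(q_load @ q_load)
        u = Ya @ q_load / qq if qq > 0 else np.zeros(n)
        W[:, a], P[:, a], Q[:, a], T[:, a], U[:, a] = w, p_load, q_load, t, u
        var_exp[a] = tt * float(q_load @ q_load) / total_ss_y
        Xd = Xd - np.outer(t, p_load)

    # rotations map the *original* X to scores: R = W (P'W)^{-1}
    R = W @ np.linalg.inv(P.T @ W)
    beta = R @ Q.T

    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    test_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    return PLSFit(
        n_components=n_components, x_weights=W, x_rotations=R, x_loadings=P,
        y_loadings=Q, x_scores=T, y_scores=U, beta=beta,
        variance_explained_y=var_exp,
        feature_names=feature_names, test_names=test_names,
    )


@dataclass
class PermutationResult:
    """Permutation null for the fraction of Y variance explained."""

    observed_statistic: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(self.null_distribution.mean())

    @property
    def debiased_statistic(self) -> float:
        """Observed variance explained minus the permutation-null mean.

        In-sample PLS variance explained is optimistically biased (the weight
        vector is chosen on the same sample); subtracting the null mean gives
        an approximately unbiased estimate of the planted effect size.
        """
        return self.observed_statistic - self.null_mean


def permutation_test(X, Y, n_components: int, n_perm: int = 5000,
                     seed=None) -> PermutationResult:
    """Test model significance by permuting participants' Y rows.

    Each replicate refits the PLS with the same number of components on
    (X, Y[perm]) and records the total fraction of Y variance explained.
    The p-value uses the add-one correction
    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` and is therefore
    conservative and never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Xa = _as_array(X)
    Ya = _as_array(Y)
    observed = fit_pls(Xa, Ya, n_components).total_variance_explained_y
    null = np.empty(n_perm)
    for b in range(n_perm):
        Yp = Ya[rng.permutation(Ya.shape[0])]
        null[b] = fit_pls(Xa, Yp, n_components,
                          check_standardized=False).total_variance_explained_y
    p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return PermutationResult(observed, null, p, n_perm,
                             seed if isinstance(seed, int) else None)


def select_n_components(X, Y, max_components: int, n_perm: int = 200,
                        alpha: float = 0.05, seed=None) -> int:
    """Sequential permutation rule for the number of latent variables.

    Components are retained one at a time: at each step the dominant
    singular value of the residual cross-covariance X_res' Y_res is compared
    with its permutation null (Y_res rows shuffled); the step is accepted if
    p <= alpha, then both blocks are deflated and the test repeats. Returns
    the number of accepted components (possibly 0).
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    rng = np.random.default_rng(seed)
    Xd = _as_array(X).copy()
    Yd = _as_array(Y).copy()
    n = Xd.shape[0]
    kept = 0
    for _ in range(max_components):
        C = Xd.T @ Yd
        observed = float(np.linalg.svd(C, compute_uv=False)[0])
        exceed = 0
        for _b in range(n_perm):
            Cp = Xd.T @ Yd[rng.permutation(n)]
            if np.linalg.svd(Cp, compute_uv=False)[0] >= observed:
                exceed += 1
        p = (1.0 + exceed) / (n_perm + 1.0)
        if p > alpha:
            break
        kept += 1
        if kept >= min(Xd.shape[1], n - 1):
            break
        comp = fit_pls(Xd, Yd, 1, check_standardized=False)
        t = comp.x_scores[:, 0]
        tt = float(t @ t)
        Xd = Xd - np.outer(t, Xd.T @ t / tt)
        Yd = Yd - np.outer(t, Yd.T @ t / tt)
    return kept


@dataclass
class BootstrapResult:
    """Bootstrap ratios (Z) for X-loadings, with the |Z| > 3 robustness mask."""

    z_ratio: np.ndarray  # features x components
    significant_mask: np.ndarray  # |z_ratio| > z_threshold
    loading_mean: np.ndarray
    loading_se: np.ndarray
    n_boot: int
    z_threshold: float = Z_THRESHOLD
    seed: int | None = None
    feature_names: list[str] | None = None

    def significant_features(self, component: int) -> list:
        idx = np.flatnonzero(self.significant_mask[:, component])
        if self.feature_names is not None:
            return [self.feature_names[i] for i in idx]
        return list(idx)


def _align_components(T_ref: np.ndarray, T_boot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match bootstrap components to the reference fit by maximal absolute
    score correlation; returns (order, signs)."""
    A = T_ref.shape[1]
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(T_ref, T_boot, rowvar=False)[:A, A:]
    C = np.nan_to_num(C)
    order = np.full(A, -1, dtype=int)
    signs = np.ones(A)
    absC = np.abs(C).copy()
    for _ in range(A):
        i, j = np.unravel_index(int(np.argmax(absC)), absC.shape)
        order[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        absC[i, :] = -1.0
        absC[:, j] = -1.0
    return order, signs


def bootstrap_loadings(X, Y, n_components: int, n_boot: int = 5000, seed=None,
                       z_threshold: float = Z_THRESHOLD,
                       ratio: str = "bootstrap_mean", max_redraws: int = 100) -> BootstrapResult:
    """Bootstrap the X-loadings to find features contributing robustly to
    each latent variable.

    Participants are resampled with replacement, each replicate is
    re-standardized and refit, and its components are aligned (order and
    sign) to the original fit by maximal absolute correlation between the
    replicate's X-scores and the original scores of the same resampled rows.
    ``z_ratio`` is the bootstrap mean loading over its bootstrap SE
    (``ratio="original"`` uses the original loading over the bootstrap SE).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if ratio not in ("bootstrap_mean", "original"):
        raise ValueError("ratio must be 'bootstrap_mean' or 'original'")
    rng = np.random.default_rng(seed)
    Xa = _as_array(X)
    Ya = _as_array(Y)
    n, p = Xa.shape
    ref = fit_pls(Xa, Ya, n_components)
    sums = np.zeros((p, n_components))
    sumsq = np.zeros((p, n_components))
    done = 0
    redraws = 0
    while done < n_boot:
        idx = rng.integers(0, n, n)
        Xb = Xa[idx]
        Yb = Ya[idx]
        sx = Xb.std(axis=0, ddof=1)
        sy = Yb.std(axis=0, ddof=1)
        if (sx == 0).any() or (sy == 0).any():
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap draws")
            continue
        Xb = (Xb - Xb.mean(axis=0)) / sx
        Yb = (Yb - Yb.mean(axis=0)) / sy
        try:
            bfit = fit_pls(Xb, Yb, n_components, check_standardized=False)
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap draws")
            continue
        order, signs = _align_components(ref.x_scores[idx], bfit.x_scores)
        L = bfit.x_loadings[:, order] * signs
        sums += L
        sumsq += L ** 2
        done += 1
    mean = sums / n_boot
    var = (sumsq - n_boot * mean ** 2) / (n_boot - 1)
    se = np.sqrt(np.clip(var, 0.0, None))
    numer = mean if ratio == "bootstrap_mean" else ref.x_loadings
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, numer / se, 0.0)
    return BootstrapResult(
        z_ratio=z, significant_mask=np.abs(z) > z_threshold,
        loading_mean=mean, loading_se=se, n_boot=n_boot,
        z_threshold=z_threshold, seed=seed if isinstance(seed, int) else None,
        feature_names=ref.feature_names,
    )


def latent_test_correlations(fit: PLSFit, Y_raw: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each latent brain score (XS column) with each cognitive
    test, Bonferroni-corrected over the components x tests family.

    Returns a tidy frame with columns ``component``, ``test``, ``r``,
    ``p_raw``, ``p_bonferroni``, ``significant``. A constant test column
    yields an undefined correlation and is flagged not-significant.
    """
    XS = fit.x_scores
    n, A = XS.shape
    tests = list(Y_raw.columns)
    m = A * len(tests)
    rows = []
    for a in range(A):
        for test in tests:
            y = Y_raw[test].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(XS[:, a]) == 0:
                log.warning("latent_test_correlations: constant column %r; "
                            "correlation undefined", test)
                rows.append((a + 1, test, np.nan, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(XS[:, a], y)
            p_adj = min(1.0, p * m)
            rows.append((a + 1, test, r, p, p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=["component", "test", "r", "p_raw",
                                       "p_bonferroni", "significant"])


def association_with_covariate(latent_scores, covariate) -> tuple[float, float]:
    """Pearson correlation (with two-sided p) between a latent-score vector
    and a participant-level covariate such as education, brain-structure
    centile, ATHF, or WMH burden."""
    x = np.asarray(latent_scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("latent_scores and covariate must be aligned 1-d vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
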
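"""Out-of-sample prediction of psychopathology dimensions.

Repeated k-fold cross-validated ridge regression predicts each orthogonal
psychopathology dimension from multivariate patterns of regional brain
features (deviation z-scores or raw volume). Within every training fold,
nuisance covariates (age, sex by default) are regressed out of the target
and a PCA retains components explaining at least a configured share of
variance; both transforms are fit on the training fold only and applied to
the held-out fold, so no information leaks. Error metrics carry a negative
sign so that higher is always better. Significance comes from a
permutation null over shuffled targets; feature kinds are compared with a
paired sign-flip exact test over the repeat-level scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PredictionConfig",
    "ScoreDistribution",
    "PCRidge",
    "nuisance_residualize",
    "pca_reduce",
    "repeated_cv_predict",
    "permutation_test",
    "attach_permutation_pvalues",
    "fdr_correct",
    "exact_test_of_differences",
]

METRICS = ("neg_rmse", "neg_mae", "corr_true_pred")


@dataclass(frozen=True)
class PredictionConfig:
    """Settings of the prediction pipeline.

    Defaults follow the reference analysis (ridge penalty 1, 100 repeats
    of 10-fold CV, PCs with >= 1% explained variance, age/sex nuisance
    regression) except ``n_permutations``, which defaults to a desk-scale
    1,000 (configurable up to the full 100,000).
    """

    ridge_penalty: float = 1.0
    n_repeats: int = 100
    k_folds: int = 10
    pc_variance_threshold: float = 1.0  # percent
    n_components_override: int | None = None
    n_permutations: int = 1000
    perm_fold_layouts: int = 1  # fold layouts reused across permutations
    nuisance_covariates: tuple[str, ...] = ("age", "sex")
    seed: int = 0

    def __post_init__(self):
        for name in ("n_repeats", "k_folds", "n_permutations", "perm_fold_layouts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.pc_variance_threshold <= 100.0:
            raise ValueError("pc_variance_threshold must be in (0, 100]")


@dataclass
class ScoreDistribution:
    """Per-repeat CV scores for one (dimension, feature kind, metric)."""

    dimension: str
    feature_kind: str
    metric: str
    values: np.ndarray
    permutation_p: float | None = None
    fdr_significant: bool | None = None

    @property
    def point_estimate(self) -> float:
        return float(np.mean(self.values))


def _with_intercept(covars: np.ndarray) -> np.ndarray:
    return np.c_[np.ones(len(covars)), covars]


def nuisance_residualize(
    y_train: np.ndarray,
    y_test: np.ndarray,
    covars_train,
    covars_test,
) -> tuple[np.ndarray, np.ndarray]:
    """OLS-residualize a target on covariates, fit on training rows only.

    The regression (with intercept) is estimated from the training rows
    and its predictions subtracted from both sets, preventing test-set
    leakage into the nuisance fit.
    """
    names = (
        list(covars_train.columns)
        if isinstance(covars_train, pd.DataFrame)
        else [f"covar_{i}" for i in range(np.shape(covars_train)[1])]
    )
    Ctr = _with_intercept(np.asarray(covars_train, dtype=float))
    Cte = _with_intercept(np.asarray(covars_test, dtype=float))
    if np.linalg.matrix_rank(Ctr) < Ctr.shape[1]:
        _, _, piv = qr(Ctr, pivoting=True)
        rank = np.linalg.matrix_rank(Ctr)
        bad = sorted(piv[rank:])
        bad_names = [("intercept" if i == 0 else names[i - 1]) for i in bad]
        raise ValueError(f"collinear nuisance covariates: {bad_names}")
    beta, *_ = np.linalg.lstsq(Ctr, np.asarray(y_train, dtype=float), rcond=None)
    return (
        np.asarray(y_train, dtype=float) - Ctr @ beta,
        np.asarray(y_test, dtype=float) - Cte @ beta,
    )


def pca_reduce(
    train_features: np.ndarray,
    test_features: np.ndarray,
    threshold: float = 1.0,
    n_override: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project onto training-set principal components.

    Retains every component whose individual explained-variance share is
    at least ``threshold`` percent, unless ``n_override`` fixes the count
    (used to give raw-volume models the same input dimensionality as
    deviation models). Centering uses training statistics only.
    """
    Xtr = np.asarray(train_features, dtype=float)
    Xte = np.asarray(test_features, dtype=float)
    pca = PCA(svd_solver="full").fit(Xtr)
    if n_override is not None:
        n = int(n_override)
        if not 1 <= n <= pca.n_components_:
            raise ValueError(f"n_override={n} outside [1, {pca.n_components_}]")
    else:
        n = int(np.sum(pca.explained_variance_ratio_ >= threshold / 100.0))
        if n == 0:
            raise ValueError(
                "no principal component reaches the variance threshold; "
                "set n_override to fix the component count"
            )
    return pca.transform(Xtr)[:, :n], pca.transform(Xte)[:, :n], n


class PCRidge(BaseEstimator, RegressorMixin):
    """Ridge regression on leading principal components of the features.

    scikit-learn estimator: ``fit`` learns the PCA basis (training rows
    only) and the ridge coefficients; ``predict`` projects new rows onto
    the learned basis. ``n_components=None`` selects components by the
    explained-variance threshold (percent).
    """

    def __init__(self, alpha: float = 1.0, var_threshold: float = 1.0,
                 n_components: int | None = None):
        self.alpha = alpha
        self.var_threshold = var_threshold
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        S, _, n = pca_reduce(X, X[:1], self.var_threshold, self.n_components)
        self.n_components_ = n
        self.pca_ = PCA(n_components=n, svd_solver="full").fit(X)
        S = self.pca_.transform(X)
        self.y_mean_ = float(y.mean())
        A = S.T @ S + self.alpha * np.eye(n)
        self.coef_ = np.linalg.solve(A, S.T @ (y - self.y_mean_))
        return self

    def predict(self, X):
        S = self.pca_.transform(np.asarray(X, dtype=float))
        return S @ self.coef_ + self.y_mean_


# ---------------------------------------------------------------------------
# Repeated cross-validation core
# ---------------------------------------------------------------------------


class _FoldPipeline:
    """Per-fold deterministic intermediates for one fold layout.

    PCA bases, nuisance projectors, and the ridge solve matrix depend only
    on the features, covariates, and fold assignment — not on the target —
    so they are computed once and reused for every (possibly permuted)
    target scored under this layout.
    """

    def __init__(self, X: np.ndarray, C: np.ndarray, folds, alpha: float,
                 threshold: float, n_override: int | None):
        self.folds = []
        for tr, te in folds:
            if len(te) < 3:
                raise ValueError("fold with fewer than 3 test subjects")
            Ctr, Cte = _with_intercept(C[tr]), _with_intercept(C[te])
            pinv = np.linalg.pinv(Ctr)
            Str, Ste, n = pca_reduce(X[tr], X[te], threshold, n_override)
            M = np.linalg.solve(Str.T @ Str + alpha * np.eye(n), Str.T)
            self.folds.append((tr, te, Ctr, Cte, pinv, Str, Ste, M))
        self.n_components_ = n

    def score(self, y: np.ndarray) -> dict[str, float]:
        """Fold-averaged metrics for one target vector."""
        out = {m: 0.0 for m in METRICS}
        for tr, te, Ctr, Cte, pinv, Str, Ste, M in self.folds:
            beta = pinv @ y[tr]
            ytr = y[tr] - Ctr @ beta
            yte = y[te] - Cte @ beta
            mu = ytr.mean()
            pred = Ste @ (M @ (ytr - mu)) + mu
            err = yte - pred
            out["neg_rmse"] -= float(np.sqrt(np.mean(err**2)))
            out["neg_mae"] -= float(np.mean(np.abs(err)))
            ps, ys = pred.std(), yte.std()
            corr = 0.0 if ps == 0 or ys == 0 else float(np.corrcoef(yte, pred)[0, 1])
            out["corr_true_pred"] += corr
        k = len(self.folds)
        return {m: v / k for m, v in out.items()}


def _layout(n: int, k: int, seed: int):
    return list(KFold(n_splits=k, shuffle=True, random_state=seed % 2**32).split(
        np.arange(n)))


def repeated_cv_predict(
    features: pd.DataFrame,
    y: np.ndarray | pd.Series,
    cohort: pd.DataFrame,
    config: PredictionConfig,
    dimension: str = "y",
    feature_kind: str = "deviation_z",
) -> dict[str, ScoreDistribution]:
    """Repeated k-fold CV scores for one dimension and one feature kind.

    Fold assignment is reshuffled per repeat with a seed derived from the
    repeat index, so runs on different feature kinds under the same config
    share fold structure and their repeat-level scores are paired.
    """
    X = np.asarray(features, dtype=float)
    yv = np.asarray(y, dtype=float)
    if not np.isfinite(yv).all():
        raise ValueError("non-finite target values")
    C = cohort[list(config.nuisance_covariates)].to_numpy(dtype=float)
    if len(X) != len(yv) or len(X) != len(C):
        raise ValueError("features, target, and cohort are not aligned")

    per_repeat = {m: np.empty(config.n_repeats) for m in METRICS}
    for r in range(config.n_repeats):
        pipe = _FoldPipeline(
            X, C, _layout(len(X), config.k_folds, config.seed + r),
            config.ridge_penalty, config.pc_variance_threshold,
            config.n_components_override,
        )
        scores = pipe.score(yv)
        for m in METRICS:
            per_repeat[m][r] = scores[m]
    return {
        m: ScoreDistribution(dimension, feature_kind, m, per_repeat[m])
        for m in METRICS
    }


def _null_scores(
    features: pd.DataFrame,
    y: np.ndarray,
    cohort: pd.DataFrame,
    config: PredictionConfig,
) -> dict[str, np.ndarray]:
    """Permutation null: shuffle the target, rerun the CV pipeline.

    Each permutation is scored under ``perm_fold_layouts`` fold layouts
    (averaged), reusing the target-independent intermediates of each
    layout across permutations.
    """
    if config.n_permutations < 100:
        warnings.warn(
            f"{config.n_permutations} permutations give a coarse p-value "
            f"granularity of {1 / config.n_permutations:.3g}", stacklevel=2
        )
    X = np.asarray(features, dtype=float)
    yv = np.asarray(y, dtype=float)
    C = cohort[list(config.nuisance_covariates)].to_numpy(dtype=float)
    pipes = [
        _FoldPipeline(
            X, C, _layout(len(X), config.k_folds, config.seed + r),
            config.ridge_penalty, config.pc_variance_threshold,
            config.n_components_override,
        )
        for r in range(config.perm_fold_layouts)
    ]
    rng = np.random.default_rng(config.seed)
    null = {m: np.empty(config.n_permutations) for m in METRICS}
    for b in range(config.n_permutations):
        yp = rng.permutation(yv)
        acc = {m: 0.0 for m in METRICS}
        for pipe in pipes:
            s = pipe.score(yp)
            for m in METRICS:
                acc[m] += s[m]
        for m in METRICS:
            null[m][b] = acc[m] / len(pipes)
    return null


def permutation_test(
    observed: ScoreDistribution,
    features: pd.DataFrame,
    y: np.ndarray,
    cohort: pd.DataFrame,
    config: PredictionConfig,
) -> float:
    """One-sided permutation p: proportion of permuted scores that are
    greater than or equal to the observed point estimate (plain
    proportion, no smoothing; the granularity floor is 1/n_permutations)."""
    null = _null_scores(features, y, cohort, config)[observed.metric]
    return float(np.mean(null >= observed.point_estimate))


def attach_permutation_pvalues(
    observed: dict[str, ScoreDistribution],
    features: pd.DataFrame,
    y: np.ndarray,
    cohort: pd.DataFrame,
    config: PredictionConfig,
) -> dict[str, ScoreDistribution]:
    """Permutation p-values for all three metrics from one null sweep."""
    null = _null_scores(features, y, cohort, config)
    for m, sd in observed.items():
        sd.permutation_p = float(np.mean(null[m] >= sd.point_estimate))
    return observed


def fdr_correct(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at rate ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def exact_test_of_differences(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_mc: int = 10000,
    seed: int = 0,
    method: str = "auto",
) -> tuple[float, float]:
    """Paired sign-flip permutation test on per-repeat score differences.

    The statistic is the mean paired difference. All 2^n sign patterns are
    enumerated when n <= 20; otherwise a Monte-Carlo sample of ``n_mc``
    random sign flips is used (with add-one smoothing, so the smallest
    attainable p is 1/(n_mc+1)). Two-sided. ``method`` forces
    ``"enumerate"`` or ``"monte_carlo"`` instead of the size-based choice.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1-d and equal length")
    d = a - b
    stat = float(d.mean())
    if np.all(d == 0):
        return 0.0, 1.0
    n = d.size
    tol = 1e-12 * max(1.0, float(np.abs(d).max()))
    if method not in ("auto", "enumerate", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    enumerate_all = n <= 20 if method == "auto" else method == "enumerate"
    if enumerate_all and n > 26:
        raise ValueError("full enumeration is limited to n <= 26")
    if enumerate_all:
        # enumerate all 2^n sign patterns via half-split subset sums
        def subset_sums(v: np.ndarray) -> np.ndarray:
            s = np.zeros(1)
            for x in v:
                s = np.concatenate([s, s + x])
            return s

        half = subset_sums(d[: n // 2])
        rest = subset_sums(d[n // 2 :])
        pos = (half[:, None] + rest[None, :]).ravel()  # sum over +1 positions
        perm = (2.0 * pos - d.sum()) / n
        p = float(np.mean(np.abs(perm) >= abs(stat) - tol))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_mc, n))
        perm = flips @ d / n
        p = (1.0 + np.sum(np.abs(perm) >= abs(stat) - tol)) / (n_mc + 1.0)
    return stat, float(p)
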
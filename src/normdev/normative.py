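"""Per-region normative models of a brain feature and deviation z-scores.

A normative model regresses a regional feature (here cortical volume) on
age and sex in healthy subjects with Gaussian-process regression, learning
both the expected developmental trajectory and the normative variance
around it. Every scored subject then receives, per region, a deviation
z-score

    z_ij = (y_ij - yhat_ij) / sqrt(sigma_ij^2 + sigma_nj^2)

where ``yhat_ij`` is the predicted feature, ``sigma_ij`` the predictive
uncertainty at that subject's covariates, and ``sigma_nj`` the normative
(noise) standard deviation learned for region j. Negative z means lower
than normatively expected volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    Hyperparameter,
    Kernel,
    WhiteKernel,
)
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SplitSpec",
    "MaskedKernel",
    "NormativeModel",
    "split_cohort",
    "fit_normative",
    "deviation_scores",
    "crossval_deviations",
]


def deviation_z(
    y: np.ndarray, yhat: np.ndarray, sigma: np.ndarray, sigma_n: np.ndarray
) -> np.ndarray:
    """z_ij = (y_ij - yhat_ij) / sqrt(sigma_ij^2 + sigma_nj^2)."""
    return (np.asarray(y) - np.asarray(yhat)) / np.sqrt(
        np.asarray(sigma) ** 2 + np.asarray(sigma_n) ** 2
    )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: training is healthy-only, test holds all clinical
    subjects plus a random healthy subsample."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    n_healthy_in_test: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subjects overlap")


def split_cohort(
    cohort: pd.DataFrame, n_healthy_to_test: int, seed: int
) -> SplitSpec:
    """Assign all clinical subjects plus ``n_healthy_to_test`` randomly
    drawn healthy subjects to the test set; remaining healthy subjects
    form the normative training set."""
    healthy = cohort.loc[cohort["group"] == "healthy", "subject_id"].to_numpy()
    clinical = cohort.loc[cohort["group"] != "healthy", "subject_id"].to_numpy()
    if n_healthy_to_test >= len(healthy):
        raise ValueError(
            f"n_healthy_to_test={n_healthy_to_test} >= {len(healthy)} healthy subjects"
        )
    rng = np.random.default_rng(seed)
    to_test = set(rng.choice(healthy, size=n_healthy_to_test, replace=False))
    test_mask = cohort["subject_id"].isin(to_test) | cohort["subject_id"].isin(clinical)
    return SplitSpec(
        train_ids=tuple(cohort.loc[~test_mask, "subject_id"]),
        test_ids=tuple(cohort.loc[test_mask, "subject_id"]),
        n_healthy_in_test=n_healthy_to_test,
    )


class MaskedKernel(Kernel):
    """Evaluate a base kernel on a subset of input columns.

    Lets a sum kernel combine a radial-basis term over age with a linear
    term over the full (age, sex) covariate block.
    """

    def __init__(self, kernel: Kernel, dims: tuple[int, ...]):
        self.kernel = kernel
        self.dims = tuple(dims)

    def get_params(self, deep=True):
        params = dict(kernel=self.kernel, dims=self.dims)
        if deep:
            params.update(
                ("kernel__" + k, v) for k, v in self.kernel.get_params().items()
            )
        return params

    @property
    def hyperparameters(self):
        return [
            Hyperparameter(
                "kernel__" + h.name, h.value_type, h.bounds, h.n_elements
            )
            for h in self.kernel.hyperparameters
        ]

    @property
    def theta(self):
        return self.kernel.theta

    @theta.setter
    def theta(self, theta):
        self.kernel.theta = theta

    @property
    def bounds(self):
        return self.kernel.bounds

    def __call__(self, X, Y=None, eval_gradient=False):
        Xs = np.asarray(X)[:, self.dims]
        Ys = None if Y is None else np.asarray(Y)[:, self.dims]
        return self.kernel(Xs, Ys, eval_gradient=eval_gradient)

    def diag(self, X):
        return self.kernel.diag(np.asarray(X)[:, self.dims])

    def is_stationary(self):
        return self.kernel.is_stationary()

    def __eq__(self, other):
        return (
            type(self) is type(other)
            and self.kernel == other.kernel
            and self.dims == other.dims
        )

    def __repr__(self):
        return f"Masked({self.kernel!r}, dims={self.dims})"


def _default_kernel() -> Kernel:
    """RBF over standardized age + linear over (age, sex) + white noise.

    The white-noise level supplies the normative variance; the remaining
    terms supply the smooth mean function and its predictive uncertainty.
    """
    return (
        MaskedKernel(ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e2)), (0,))
        + MaskedKernel(
            ConstantKernel(0.1, (1e-4, 1e3)) * DotProduct(1.0, (1e-3, 1e3)), (0, 1)
        )
        + WhiteKernel(0.5, (1e-6, 1e1))
    )


def _noise_level(kernel: Kernel) -> float:
    if isinstance(kernel, WhiteKernel):
        return float(kernel.noise_level)
    for attr in ("k1", "k2", "kernel"):
        sub = getattr(kernel, attr, None)
        if isinstance(sub, Kernel):
            lvl = _noise_level(sub)
            if lvl is not None:
                return lvl
    return None


class NormativeModel(BaseEstimator):
    """Set of per-region Gaussian-process normative models.

    Parameters
    ----------
    n_restarts : int
        Random restarts of the marginal-likelihood optimizer (on top of
        the initial hyperparameter values).
    kernel : sklearn kernel or None
        Covariance function over the (standardized age, sex) inputs.
        ``None`` uses an RBF-over-age + linear + white-noise sum whose
        learned noise level supplies the normative variance.
    random_state : int
        Seed for the restart draws; shared across regions so identical
        feature columns yield identical fitted models.

    Attributes
    ----------
    region_ids_ : list of str
    models_ : dict mapping region id -> fitted GaussianProcessRegressor
    sigma_n_ : pandas.Series
        Learned normative standard deviation per region (feature units).
    train_ids_ : list of str
    """

    def __init__(self, n_restarts: int = 5, kernel: Kernel | None = None,
                 random_state: int = 0):
        self.n_restarts = n_restarts
        self.kernel = kernel
        self.random_state = random_state

    # -- covariate handling -------------------------------------------------
    def _design(self, cohort: pd.DataFrame) -> np.ndarray:
        age = cohort["age"].to_numpy(dtype=float)
        sex = cohort["sex"].to_numpy(dtype=float)
        return np.c_[(age - self.age_center_) / self.age_scale_, sex]

    def fit(self, cohort: pd.DataFrame, features: pd.DataFrame) -> "NormativeModel":
        """Fit one GP per region on the (healthy) training subjects."""
        if len(cohort) != len(features):
            raise ValueError("cohort and features have different numbers of rows")
        if len(cohort) < 20:
            raise ValueError("need at least 20 training subjects")
        if "group" in cohort.columns and (cohort["group"] != "healthy").any():
            raise ValueError("normative training subjects must all be healthy")
        vals = features.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite feature values in training data")

        age = cohort["age"].to_numpy(dtype=float)
        self.age_center_ = float(age.mean())
        self.age_scale_ = float(age.std(ddof=0)) or 1.0
        X = self._design(cohort)

        self.region_ids_ = list(features.columns)
        self.train_ids_ = list(cohort["subject_id"]) if "subject_id" in cohort else None
        self.centers_ = vals.mean(axis=0)
        scales = vals.std(ddof=0, axis=0)
        self.scales_ = np.where(scales > 0, scales, 1.0)

        base = self.kernel if self.kernel is not None else _default_kernel()
        self.models_ = {}
        sig_n = {}
        for j, rid in enumerate(self.region_ids_):
            y = (vals[:, j] - self.centers_[j]) / self.scales_[j]
            gp = GaussianProcessRegressor(
                kernel=clone(base),
                n_restarts_optimizer=self.n_restarts,
                normalize_y=False,
                random_state=self.random_state,
            ).fit(X, y)
            noise = _noise_level(gp.kernel_)
            if noise is None:
                raise ValueError("kernel must contain a WhiteKernel noise term")
            self.models_[rid] = gp
            sig_n[rid] = float(np.sqrt(noise)) * self.scales_[j]
        self.sigma_n_ = pd.Series(sig_n, name="sigma_n")
        return self

    def predict(
        self, cohort: pd.DataFrame, return_uncertainty: bool = False
    ) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
        """Expected feature values (and optionally the per-point predictive
        uncertainty sigma_ij, noise excluded), in feature units."""
        check_is_fitted(self, "models_")
        X = self._design(cohort)
        idx = cohort["subject_id"] if "subject_id" in cohort else cohort.index
        yhat = np.empty((len(cohort), len(self.region_ids_)))
        sig = np.empty_like(yhat)
        for j, rid in enumerate(self.region_ids_):
            m, s = self.models_[rid].predict(X, return_std=True)
            # s includes the white-noise term; remove it to isolate sigma_ij
            noise = _noise_level(self.models_[rid].kernel_)
            yhat[:, j] = m * self.scales_[j] + self.centers_[j]
            sig[:, j] = np.sqrt(np.clip(s**2 - noise, 0.0, None)) * self.scales_[j]
        yhat = pd.DataFrame(yhat, index=idx, columns=self.region_ids_)
        if return_uncertainty:
            return yhat, pd.DataFrame(sig, index=idx, columns=self.region_ids_)
        return yhat

    def transform(self, cohort: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
        """Deviation z-scores for every (subject, region)."""
        check_is_fitted(self, "models_")
        if list(features.columns) != self.region_ids_:
            raise ValueError("region mismatch between fitted models and features")
        if len(cohort) != len(features):
            raise ValueError("cohort and features have different numbers of rows")
        yhat, sigma = self.predict(cohort, return_uncertainty=True)
        y = features.to_numpy(dtype=float)
        sig_n = self.sigma_n_.reindex(self.region_ids_).to_numpy()
        z = deviation_z(y, yhat.to_numpy(), sigma.to_numpy(), sig_n)
        return pd.DataFrame(z, index=yhat.index, columns=self.region_ids_)


def fit_normative(
    train_features: pd.DataFrame, train_cohort: pd.DataFrame, **kwargs
) -> NormativeModel:
    """Fit per-region normative models; see :class:`NormativeModel`."""
    return NormativeModel(**kwargs).fit(train_cohort, train_features)


def deviation_scores(
    models: NormativeModel, features: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Score subjects against fitted normative models (z-score matrix Z)."""
    return models.transform(cohort, features)


def crossval_deviations(
    train_features: pd.DataFrame,
    train_cohort: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Deviation z-scores for the training subjects themselves (Z_cv).

    Splits the training subset into ``k`` shuffled folds; each fold is
    scored by models refit on the remaining folds, so every subject is
    scored exactly once by a model not trained on them. Fold membership
    is derived from the seed and the sorted subject ids, so the result is
    invariant to the input row order.
    """
    n = len(train_cohort)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} training subjects")
    order = np.argsort(train_cohort["subject_id"].to_numpy())
    cohort = train_cohort.iloc[order].reset_index(drop=True)
    feats = train_features.iloc[order].reset_index(drop=True)
    out = np.full((n, train_features.shape[1]), np.nan)
    for tr, te in KFold(n_splits=k, shuffle=True, random_state=seed).split(cohort):
        model = NormativeModel(**kwargs).fit(cohort.iloc[tr], feats.iloc[tr])
        z = model.transform(cohort.iloc[te], feats.iloc[te])
        out[te] = z.to_numpy()
    z_sorted = pd.DataFrame(
        out, index=pd.Index(cohort["subject_id"], name="subject_id"),
        columns=train_features.columns,
    )
    return z_sorted.loc[train_cohort["subject_id"]]
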
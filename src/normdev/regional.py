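"""Regional associations between psychopathology dimensions and deviations.

Two complementary analyses: (i) a priori ROI analysis — deviations are
averaged over the parcels of each named ROI, correlated with each
dimension after residualizing both for image-quality covariates, and the
absolute effect size of every specific dimension is compared against that
of overall psychopathology with a bootstrap of the difference in absolute
correlations; (ii) whole-brain mass-univariate correlation over every
(parcel, dimension) pair with a single Benjamini-Hochberg family across
all tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prediction import fdr_correct
from .simulate import FACTOR_NAMES

__all__ = [
    "BootstrapDeltaResult",
    "roi_average",
    "residualized_correlation",
    "bootstrap_delta_r",
    "mass_univariate",
]


@dataclass
class BootstrapDeltaResult:
    """Bootstrap distribution of |r_overall| - |r_specific| for one ROI.

    ``significant`` means the lower CI bound exceeds zero, i.e. overall
    psychopathology yields a reliably stronger absolute effect than the
    specific dimension.
    """

    roi_name: str
    specific_dimension: str
    overall_dimension: str
    r_overall: float
    r_specific: float
    delta_r: np.ndarray
    ci: tuple[float, float]
    ci_level: float
    significant: bool
    n_redraws: int = 0


def roi_average(deviations: pd.DataFrame, roi_map: dict[str, list[str]]) -> pd.DataFrame:
    """Average deviation columns over the member parcels of each ROI."""
    known = set(deviations.columns)
    out = {}
    for roi, members in roi_map.items():
        if len(members) == 0:
            raise ValueError(f"ROI {roi!r} has no member parcels")
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ValueError(f"ROI {roi!r} references unknown regions: {unknown}")
        out[roi] = deviations[list(members)].mean(axis=1)
    return pd.DataFrame(out, index=deviations.index)


def _residuals(v: np.ndarray, covars: np.ndarray | None) -> np.ndarray:
    if covars is None:
        return v - v.mean()
    C = np.c_[np.ones(len(v)), np.asarray(covars, dtype=float)]
    beta, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ beta


def residualized_correlation(
    x: np.ndarray, y: np.ndarray, covars: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation between the OLS residuals of ``x`` and ``y`` on
    the covariates, with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d vectors")
    rx, ry = _residuals(x, covars), _residuals(y, covars)
    # relative floor: an exact linear match leaves only rounding noise
    if rx.std() <= 1e-12 * max(1.0, np.abs(x).max()) or ry.std() <= 1e-12 * max(
        1.0, np.abs(y).max()
    ):
        raise ValueError("constant residual vector: correlation undefined")
    r, p = stats.pearsonr(rx, ry)
    return float(r), float(p)


def _batch_residualize(V: np.ndarray, C: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Residualize columns of V on design C within each bootstrap draw."""
    Cb = C[idx]                                  # B x n x q
    Vb = V[idx]                                  # B x n x m
    G = Cb.transpose(0, 2, 1) @ Cb
    beta = np.linalg.solve(G, Cb.transpose(0, 2, 1) @ Vb)
    return Vb - Cb @ beta


def _batch_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-batch Pearson correlation of zero-mean vectors (B x n each)."""
    num = np.einsum("bn,bn->b", a, b)
    den = np.sqrt(np.einsum("bn,bn->b", a, a) * np.einsum("bn,bn->b", b, b))
    return num / den


def bootstrap_delta_r(
    deviation_roi: np.ndarray,
    cohort: pd.DataFrame,
    specific_dim: str,
    covars: np.ndarray | None = None,
    n_boot: int = 10000,
    ci_level: float = 99.0,
    seed: int = 0,
    overall_dim: str = "p",
    chunk: int = 500,
) -> BootstrapDeltaResult:
    """Bootstrap the difference in absolute residualized correlations.

    In each of ``n_boot`` resamples of subjects with replacement, the ROI
    deviation is correlated (after within-resample residualization on the
    covariates) with overall psychopathology and with the specific
    dimension; the distribution of |r_overall| - |r_specific| yields a
    percentile CI at ``ci_level``. Resamples in which the ROI deviation is
    constant are redrawn and counted.
    """
    x = np.asarray(deviation_roi, dtype=float)
    n = x.size
    f_all = cohort[overall_dim].to_numpy(dtype=float)
    f_spec = cohort[specific_dim].to_numpy(dtype=float)
    C = np.c_[np.ones(n)] if covars is None else np.c_[
        np.ones(n), np.asarray(covars, dtype=float)
    ]
    V = np.c_[x, f_all, f_spec]

    r_overall, _ = residualized_correlation(x, f_all, covars)
    r_specific, _ = residualized_correlation(x, f_spec, covars)

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    filled = 0
    n_redraws = 0
    while filled < n_boot:
        b = min(chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(b, n))
        const = x[idx].std(axis=1) == 0
        while const.any():  # vanishingly rare unless the ROI is degenerate
            n_redraws += int(const.sum())
            idx[const] = rng.integers(0, n, size=(int(const.sum()), n))
            const = x[idx].std(axis=1) == 0
        R = _batch_residualize(V, C, idx)
        r_p = _batch_corr(R[:, :, 0], R[:, :, 1])
        r_s = _batch_corr(R[:, :, 0], R[:, :, 2])
        deltas[filled : filled + b] = np.abs(r_p) - np.abs(r_s)
        filled += b
    if n_redraws:
        warnings.warn(
            f"redrew {n_redraws} bootstrap samples with constant ROI values",
            stacklevel=2,
        )
    tail = (100.0 - ci_level) / 2.0
    lo, hi = np.percentile(deltas, [tail, 100.0 - tail])
    return BootstrapDeltaResult(
        roi_name="roi",
        specific_dimension=specific_dim,
        overall_dimension=overall_dim,
        r_overall=r_overall,
        r_specific=r_specific,
        delta_r=deltas,
        ci=(float(lo), float(hi)),
        ci_level=ci_level,
        significant=bool(lo > 0),
        n_redraws=n_redraws,
    )


def mass_univariate(
    deviations: pd.DataFrame,
    cohort: pd.DataFrame,
    covars: np.ndarray | None = None,
    q: float = 0.05,
    dimensions: tuple[str, ...] = FACTOR_NAMES,
) -> pd.DataFrame:
    """Whole-brain mass-univariate correlation map.

    Pearson correlation of every parcel's deviations with every
    psychopathology dimension (both residualized on the covariates when
    given), corrected in a single BH-FDR family across all parcels x
    dimensions. Returns a long table (region_id, dimension, r, p,
    significant).
    """
    missing = [d for d in dimensions if d not in cohort.columns]
    if missing:
        raise ValueError(f"missing psychopathology dimensions: {missing}")
    n = len(deviations)
    D = np.asarray(deviations, dtype=float)
    F = cohort[list(dimensions)].to_numpy(dtype=float)
    D = np.apply_along_axis(lambda v: _residuals(v, covars), 0, D) if covars is not None else D - D.mean(axis=0)
    F = np.apply_along_axis(lambda v: _residuals(v, covars), 0, F) if covars is not None else F - F.mean(axis=0)
    Dn = D / np.linalg.norm(D, axis=0)
    Fn = F / np.linalg.norm(F, axis=0)
    R = Dn.T @ Fn                                  # regions x dimensions
    t = R * np.sqrt((n - 2) / np.clip(1.0 - R**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame(
        {
            "region_id": np.repeat(deviations.columns.to_numpy(), len(dimensions)),
            "dimension": np.tile(np.asarray(dimensions, dtype=object), D.shape[1]),
            "r": R.ravel(),
            "p": p.ravel(),
        }
    )
    table["significant"] = fdr_correct(table["p"].to_numpy(), q=q)
    return table
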
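"""Matched case-control comparison of deviations from normative models.

For each disorder group, healthy controls are matched 1:1 on age, sex, and
image-quality covariates; group-level abnormality is summarized as a map
of regional Cohen's d values. The spatial Pearson correlation between two
disorders' d maps quantifies how much of their case-control signal
overlaps, and re-estimating the maps after residualizing deviations on
overall psychopathology (separately within each patient-group-plus-
controls set) shows how much of that overlap the general factor carries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MatchSpec",
    "match_controls",
    "cohens_d_map",
    "control_for_factor",
    "spatial_correlation",
    "d_shift_test",
]

MATCH_COVARIATES = ("age", "sex", "t1_qa", "t1_snr")


@dataclass(frozen=True)
class MatchSpec:
    """1:1 matched case/control sets with covariate balance diagnostics.

    ``balance`` holds the post-match standardized mean difference (SMD)
    per matching covariate: (mean_case - mean_control) / pooled sd.
    """

    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    covariates: tuple[str, ...]
    balance: dict[str, float]


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def match_controls(
    cases: pd.DataFrame,
    healthy_pool: pd.DataFrame,
    covariates: tuple[str, ...] = MATCH_COVARIATES,
    seed: int = 0,
) -> MatchSpec:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Sex is matched exactly; the remaining covariates enter a standardized
    Euclidean distance (scales from the pooled case+pool sample). Cases
    are visited in a seed-shuffled order; each takes its nearest unused
    control. Raises when the pool cannot supply a control for every case.
    """
    if "group" in healthy_pool.columns and (healthy_pool["group"] != "healthy").any():
        raise ValueError("control pool must contain only healthy subjects")
    if len(healthy_pool) <= len(cases):
        raise ValueError(
            f"control pool ({len(healthy_pool)}) not larger than case group ({len(cases)})"
        )
    cont = [c for c in covariates if c != "sex"]
    both = pd.concat([cases[list(cont)], healthy_pool[list(cont)]])
    scale = both.to_numpy(dtype=float).std(axis=0, ddof=0)
    scale[scale == 0] = 1.0

    Xc = cases[list(cont)].to_numpy(dtype=float) / scale
    Xp = healthy_pool[list(cont)].to_numpy(dtype=float) / scale
    sex_c = cases["sex"].to_numpy() if "sex" in covariates else None
    sex_p = healthy_pool["sex"].to_numpy() if "sex" in covariates else None

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    used = np.zeros(len(healthy_pool), dtype=bool)
    pick = np.empty(len(cases), dtype=int)
    deficit = 0
    for i in order:
        dist = np.sqrt(((Xp - Xc[i]) ** 2).sum(axis=1))
        ok = ~used
        if sex_c is not None:
            ok &= sex_p == sex_c[i]
        if not ok.any():
            deficit += 1
            continue
        j = int(np.flatnonzero(ok)[np.argmin(dist[ok])])
        used[j] = True
        pick[i] = j
    if deficit:
        raise ValueError(f"control pool exhausted: {deficit} cases unmatched")

    matched = healthy_pool.iloc[pick]
    balance = {
        c: _smd(
            cases[c].to_numpy(dtype=float), matched[c].to_numpy(dtype=float)
        )
        for c in covariates
    }
    return MatchSpec(
        case_ids=tuple(cases["subject_id"]),
        control_ids=tuple(matched["subject_id"]),
        covariates=tuple(covariates),
        balance=balance,
    )


def cohens_d_map(
    deviations: pd.DataFrame,
    group_a_ids,
    group_b_ids,
) -> pd.Series:
    """Regional Cohen's d between two groups of subjects.

    d_j = (mean_a - mean_b) / pooled sd with (n-1)-weighted pooling.
    Rows of ``deviations`` are indexed by subject id.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups overlap")
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs at least 3 subjects")
    A = deviations.loc[a_ids].to_numpy(dtype=float)
    B = deviations.loc[b_ids].to_numpy(dtype=float)
    na, nb = len(A), len(B)
    pooled = np.sqrt(
        ((na - 1) * A.var(axis=0, ddof=1) + (nb - 1) * B.var(axis=0, ddof=1))
        / (na + nb - 2)
    )
    if (pooled == 0).any():
        bad = deviations.columns[pooled == 0].tolist()
        raise ValueError(f"zero pooled standard deviation in regions {bad}")
    return pd.Series(
        (A.mean(axis=0) - B.mean(axis=0)) / pooled, index=deviations.columns,
        name="cohens_d",
    )


def control_for_factor(
    deviations: pd.DataFrame,
    cohort: pd.DataFrame,
    factor: str,
    scope_ids,
) -> pd.DataFrame:
    """Residualize deviations on one factor within a subject scope.

    The OLS fit uses only the scoped subjects (one patient group plus its
    matched controls), so control of the factor is independent for each
    case-control analysis.
    """
    ids = list(scope_ids)
    f = (
        cohort.set_index("subject_id")[factor]
        .loc[ids]
        .to_numpy(dtype=float)
    )
    if f.std() == 0:
        raise ValueError(f"factor {factor!r} is constant within the scope")
    D = deviations.loc[ids].to_numpy(dtype=float)
    C = np.c_[np.ones(len(f)), f]
    beta, *_ = np.linalg.lstsq(C, D, rcond=None)
    return pd.DataFrame(D - C @ beta, index=pd.Index(ids, name="subject_id"),
                        columns=deviations.columns)


def spatial_correlation(map_a: pd.Series, map_b: pd.Series) -> tuple[float, float]:
    """Pearson correlation across regions between two effect-size maps."""
    if list(map_a.index) != list(map_b.index):
        raise ValueError("effect-size maps cover different regions")
    r, p = stats.pearsonr(map_a.to_numpy(dtype=float), map_b.to_numpy(dtype=float))
    return float(r), float(p)


def d_shift_test(map_before: pd.Series, map_after: pd.Series) -> tuple[float, float]:
    """Paired test of whether a d distribution shifted towards zero.

    Paired t test over regions on |d_before| - |d_after|; positive t means
    the map after control sits closer to zero. Returns (t, two-sided p);
    degenerate identical maps give (0, 1).
    """
    if list(map_before.index) != list(map_after.index):
        raise ValueError("effect-size maps cover different regions")
    if len(map_before) < 10:
        warnings.warn("fewer than 10 regions: shift test is underpowered",
                      stacklevel=2)
    diff = np.abs(map_before.to_numpy(dtype=float)) - np.abs(
        map_after.to_numpy(dtype=float)
    )
    if np.allclose(diff, 0):
        return 0.0, 1.0
    t, p = stats.ttest_1samp(diff, 0.0)
    return float(t), float(p)
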
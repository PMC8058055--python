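"""Synthetic cohort generation.

Generates cohorts with the statistical structure the downstream analyses
assume: nonlinear, sex-dependent age trajectories of regional cortical
volume; mutually orthogonal psychopathology dimensions (one general factor
plus five specific factors); negative deviation effects concentrated in
designated region sets and tied to chosen dimensions at chosen effect
sizes; and diagnostic group labels driven by factor-score thresholds.

The generator is the test bed for every other module: the latent deviation
component it plants is exactly the quantity the normative model is supposed
to recover, so parameter-recovery tests can compare against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import rankdata

__all__ = [
    "FACTOR_NAMES",
    "GROUPS",
    "TrajectoryPriors",
    "Effect",
    "GeneratorConfig",
    "SyntheticTruth",
    "default_roi_map",
    "default_effect_map",
    "default_diagnosis_rules",
    "generate_cohort",
    "assign_groups",
    "inverse_normal_transform",
]

#: Psychopathology dimensions, general factor first.
FACTOR_NAMES = (
    "p",
    "anxious_misery",
    "externalizing",
    "fear",
    "psychosis_positive",
    "psychosis_negative",
)

GROUPS = ("healthy", "depression", "adhd", "other_clinical")

#: Required cohort columns besides the factor scores.
COHORT_COLUMNS = ("subject_id", "age", "sex", "t1_qa", "t1_snr", "group")


@dataclass(frozen=True)
class TrajectoryPriors:
    """Distributions from which per-region age-curve parameters are drawn.

    The curve is a logistic decline superimposed on a linear decline::

        f(age, sex) = baseline + amplitude * sigmoid(-(age - midpoint)/width)
                      - slope * (age - age_mid) + sex_offset * [sex == male]

    Units are mm^3 (volume of one parcel) and years.
    """

    baseline: tuple[float, float] = (3000.0, 500.0)
    amplitude: tuple[float, float] = (350.0, 100.0)
    midpoint: tuple[float, float] = (14.0, 1.5)
    width: tuple[float, float] = (1.8, 0.4)
    slope: tuple[float, float] = (12.0, 4.0)
    sex_offset: tuple[float, float] = (150.0, 50.0)


@dataclass(frozen=True)
class Effect:
    """Planted association between one factor and a set of regions.

    ``r`` is the population correlation between the factor score and the
    latent deviation component in each listed region.
    """

    regions: tuple[int, ...]
    factor: str
    r: float

    def __post_init__(self):
        if self.factor not in FACTOR_NAMES:
            raise ValueError(f"unknown factor {self.factor!r}")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"effect size {self.r} outside [-1, 1]")


def default_roi_map(n_regions: int) -> dict[str, list[int]]:
    """Default 4-ROI parcel membership (indices into the region axis)."""
    blocks = {
        "vmPFC_mOFC": range(0, 10),
        "inferior_temporal": range(10, 22),
        "daCC": range(22, 28),
        "insula": range(28, 38),
    }
    if n_regions < 38:
        raise ValueError("default ROI map requires at least 38 regions")
    return {name: list(ix) for name, ix in blocks.items()}


def default_effect_map(n_regions: int) -> list[Effect]:
    """Study-condition effect map.

    The general factor carries a negative deviation effect in all four
    a-priori ROIs; fear and psychosis-positive carry weaker effects in
    subsets; anxious-misery and externalizing carry disorder-specific
    effects in region blocks disjoint from the ROIs, giving the
    case-control analyses a shared (general-factor) pattern plus
    disorder-specific patterns.
    """
    rois = default_roi_map(n_regions)
    if n_regions < 80:
        raise ValueError("default effect map requires at least 80 regions")
    t = tuple
    return [
        Effect(t(rois["vmPFC_mOFC"]), "p", -0.15),
        Effect(t(rois["inferior_temporal"]), "p", -0.15),
        Effect(t(rois["daCC"]), "p", -0.12),
        Effect(t(rois["insula"]), "p", -0.11),
        Effect(t(rois["vmPFC_mOFC"]), "fear", -0.07),
        Effect(t(rois["inferior_temporal"]), "fear", -0.11),
        Effect(t(rois["insula"]), "fear", -0.13),
        Effect(t(rois["inferior_temporal"]), "psychosis_positive", -0.08),
        Effect(t(rois["daCC"]), "psychosis_positive", -0.07),
        Effect(t(range(40, 60)), "anxious_misery", -0.12),
        Effect(t(range(60, 80)), "externalizing", -0.12),
    ]


def default_diagnosis_rules() -> dict[str, dict[str, float]]:
    """Threshold rules: a subject is in a group when every listed factor
    exceeds its threshold. Comorbid depression+ADHD subjects are moved to
    ``other_clinical``; subjects matching no rule are healthy when all
    factor scores stay below ``healthy``'s single ``max`` threshold."""
    return {
        "depression": {"anxious_misery": 0.75, "p": 0.25},
        "adhd": {"externalizing": 0.75, "p": 0.25},
        "healthy": {"max": 0.9},
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Defaults mirror the study conditions: 1271 subjects aged 8-22 (47%
    male), 400 cortical parcels, nonlinear sex-dependent volume decline,
    negative general-factor deviation effects in the four a-priori ROIs,
    and threshold-defined depression / ADHD / healthy groups.
    """

    n_subjects: int = 1271
    n_regions: int = 400
    age_range: tuple[float, float] = (8.0, 22.0)
    sex_ratio: float = 0.47
    trajectory_priors: TrajectoryPriors = field(default_factory=TrajectoryPriors)
    normative_sd: tuple[float, float] = (200.0, 40.0)
    hetero_slope: float = 0.0
    effect_map: list[Effect] | None = None
    qa_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"t1_qa": (0.0, 1.0), "t1_snr": (0.0, 1.0)}
    )
    diagnosis_rules: dict[str, dict[str, float]] = field(
        default_factory=default_diagnosis_rules
    )
    seed: int = 0

    def resolved_effects(self) -> list[Effect]:
        if self.effect_map is not None:
            return list(self.effect_map)
        if self.n_regions >= 80:
            return default_effect_map(self.n_regions)
        return []

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range min must be below max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be a proportion")
        if self.normative_sd[0] <= 0:
            raise ValueError("normative_sd mean must be strictly positive")
        effects = self.resolved_effects()
        seen: dict[tuple[int, str], float] = {}
        load: dict[int, float] = {}
        for e in effects:
            for j in e.regions:
                if not 0 <= j < self.n_regions:
                    raise ValueError(f"effect region index {j} out of range")
                key = (j, e.factor)
                if key in seen and seen[key] != e.r:
                    raise ValueError(
                        f"conflicting effects on region {j}, factor {e.factor!r}"
                    )
                seen[key] = e.r
                load[j] = load.get(j, 0.0) + e.r**2
        for j, s in load.items():
            if s > 1.0:
                raise ValueError(
                    f"total squared effect loading {s:.3f} > 1 on region {j}"
                )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated cohort, for parameter-recovery checks.

    ``trajectory`` is the noiseless expected volume per (subject, region);
    ``deviation`` is the latent standardized deviation component (the
    quantity a perfectly calibrated normative model would recover);
    ``region_sd`` is the per-region normative standard deviation.
    """

    trajectory: np.ndarray
    deviation: np.ndarray
    region_sd: np.ndarray
    trajectory_params: pd.DataFrame
    effects: list[Effect]


def _orthogonal_factors(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly orthogonal, zero-mean, unit-sd factor scores (n x k)."""
    g = rng.standard_normal((n, k))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    q -= q.mean(axis=0)  # columns stay in the centered span; re-center for safety
    return q / q.std(axis=0, ddof=0)


def generate_cohort(
    config: GeneratorConfig, return_truth: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a cohort table and a subjects x regions raw-volume matrix.

    Volumes follow ``trajectory(age, sex) + sd_j * deviation`` where the
    deviation component correlates with the configured factors at the
    configured effect sizes in the configured region sets and is pure
    noise elsewhere. Reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_regions

    subject_ids = [f"sub-{i:05d}" for i in range(n)]
    region_ids = [f"ROI_{j + 1:03d}" for j in range(p)]

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    sex = (rng.random(n) < config.sex_ratio).astype(int)  # 1 = male
    qa = {
        k: rng.normal(m, s, n) for k, (m, s) in sorted(config.qa_params.items())
    }

    factors = _orthogonal_factors(n, len(FACTOR_NAMES), rng)

    # Per-region trajectory parameters, drawn once.
    pri = config.trajectory_priors
    params = pd.DataFrame(
        {
            name: rng.normal(*getattr(pri, name), p)
            for name in ("baseline", "amplitude", "midpoint", "width", "slope", "sex_offset")
        },
        index=region_ids,
    )
    params["width"] = np.clip(params["width"], 0.3, None)

    age_mid = 0.5 * (lo + hi)
    logistic = expit(
        -(age[:, None] - params["midpoint"].to_numpy()) / params["width"].to_numpy()
    )
    trajectory = (
        params["baseline"].to_numpy()
        + params["amplitude"].to_numpy() * logistic
        - params["slope"].to_numpy() * (age[:, None] - age_mid)
        + params["sex_offset"].to_numpy() * sex[:, None]
    )

    # Latent deviation: loaded on factors where configured, noise elsewhere.
    effects = config.resolved_effects()
    loading = np.zeros((len(FACTOR_NAMES), p))
    for e in effects:
        k = FACTOR_NAMES.index(e.factor)
        for j in e.regions:
            loading[k, j] = e.r
    resid_scale = np.sqrt(np.clip(1.0 - (loading**2).sum(axis=0), 0.0, 1.0))
    deviation = factors @ loading + resid_scale * rng.standard_normal((n, p))

    region_sd = np.clip(rng.normal(*config.normative_sd, p), 1e-3, None)
    if config.hetero_slope != 0.0:
        # sd grows (or shrinks) linearly in age, relative to the age midpoint
        rel = 1.0 + config.hetero_slope * (age - age_mid) / (hi - lo)
        scale = region_sd * np.clip(rel, 0.05, None)[:, None]
    else:
        scale = region_sd
    values = trajectory + scale * deviation

    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            "t1_qa": qa.get("t1_qa", np.zeros(n)),
            "t1_snr": qa.get("t1_snr", np.zeros(n)),
        }
    )
    for k, name in enumerate(FACTOR_NAMES):
        cohort[name] = factors[:, k]
    cohort = assign_groups(cohort, config.diagnosis_rules)

    features = pd.DataFrame(values, index=pd.Index(subject_ids, name="subject_id"),
                            columns=region_ids)
    if not return_truth:
        return cohort, features
    truth = SyntheticTruth(
        trajectory=trajectory,
        deviation=deviation,
        region_sd=region_sd,
        trajectory_params=params,
        effects=effects,
    )
    return cohort, features, truth


def assign_groups(
    cohort: pd.DataFrame, rules: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Assign one diagnostic group label per subject from threshold rules.

    A subject belongs to ``depression`` / ``adhd`` when every factor listed
    in that rule exceeds its threshold; subjects meeting both are comorbid
    and assigned ``other_clinical`` (the two case groups are mutually
    exclusive). Remaining subjects are ``healthy`` when all factor scores
    fall below the healthy rule's ``max`` threshold, else ``other_clinical``.
    """
    missing = [f for f in FACTOR_NAMES if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks factor scores: {missing}")
    scores = cohort[list(FACTOR_NAMES)].to_numpy()

    def meets(rule: dict[str, float]) -> np.ndarray:
        mask = np.ones(len(cohort), dtype=bool)
        for fac, thr in rule.items():
            mask &= scores[:, FACTOR_NAMES.index(fac)] > thr
        return mask

    dep = meets(rules.get("depression", {"anxious_misery": np.inf}))
    adhd = meets(rules.get("adhd", {"externalizing": np.inf}))
    comorbid = dep & adhd
    healthy_max = rules.get("healthy", {"max": 0.9})["max"]
    healthy = (scores < healthy_max).all(axis=1) & ~dep & ~adhd

    group = np.full(len(cohort), "other_clinical", dtype=object)
    group[healthy] = "healthy"
    group[dep & ~comorbid] = "depression"
    group[adhd & ~comorbid] = "adhd"

    for g in ("depression", "adhd", "healthy"):
        if not (group == g).any():
            warnings.warn(f"diagnosis rules produced an empty {g!r} group",
                          stacklevel=2)
    out = cohort.copy()
    out["group"] = group
    return out


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transformation (Blom offset).

    Maps values to normal quantiles of ``(rank - 3/8) / (n + 1/4)`` with
    average ranks for ties, so the output is monotone in the input and
    tied inputs receive equal outputs.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant input: transform undefined")
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 3.0 / 8.0) / (x.size + 0.25))
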
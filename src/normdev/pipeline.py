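"""End-to-end pipeline driver with hashed stage caching and a run manifest.

Sequences simulate -> split -> fit-normative -> deviations (+ cross-
validated training deviations) -> prediction (both feature kinds) ->
regional -> case-control. Every stage records the hash of its inputs; a
stage is skipped on rerun when its outputs exist and the recorded input
hash is unchanged, so deleting one intermediate file reruns only the
stages downstream of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, case_control, io, normative, prediction, regional
from .simulate import FACTOR_NAMES, GeneratorConfig, default_roi_map, generate_cohort

__all__ = ["RunConfig", "RunManifest", "load_run_config", "run_pipeline"]

SPECIFIC_DIMS = tuple(f for f in FACTOR_NAMES if f != "p")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    The ``full`` preset encodes the full analysis settings (10-fold
    normative CV, ridge penalty 1, 100 repeats, 1% PC threshold, q=0.05,
    10,000 bootstraps, 99% CI); the ``desk`` preset scales cohort size,
    permutations, and bootstraps down for interactive use.
    """

    out_dir: str = "normdev_run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_healthy_to_test: int = 100
    n_restarts: int = 5
    cv_folds: int = 10
    prediction: prediction.PredictionConfig = field(
        default_factory=prediction.PredictionConfig
    )
    predict_dimensions: tuple[str, ...] = FACTOR_NAMES
    fdr_q: float = 0.05
    n_boot: int = 10000
    ci_level: float = 99.0
    case_groups: tuple[str, ...] = ("depression", "adhd")
    control_factor: str = "p"

    # Paths to pre-existing inputs; when set, the simulate stage is skipped.
    cohort_path: str | None = None
    features_path: str | None = None
    roimap_path: str | None = None


PRESETS: dict[str, dict] = {
    "full": {},
    "desk": {
        "generator": {"n_subjects": 600, "n_regions": 100},
        "n_restarts": 1,
        "prediction": {"n_repeats": 20, "n_permutations": 200},
        "n_boot": 1000,
    },
}


def load_run_config(path: str | Path | None = None, preset: str = "full",
                    **overrides) -> RunConfig:
    """Build a RunConfig from a preset, an optional YAML file, and keyword
    overrides (applied in that order)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    data: dict = json.loads(json.dumps(PRESETS[preset]))
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        for k, v in loaded.items():
            if isinstance(v, dict) and isinstance(data.get(k), dict):
                data[k].update(v)
            else:
                data[k] = v
    data.update(overrides)
    gen = data.pop("generator", {})
    pred = data.pop("prediction", {})
    cfg = RunConfig(**data)
    if gen:
        cfg.generator = dataclasses.replace(cfg.generator, **gen)
    if pred:
        cfg.prediction = dataclasses.replace(cfg.prediction, **pred)
    return cfg


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, per-stage input/output
    hashes, software version, timestamps, and seeds."""

    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _hash_obj(obj) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Runner:
    def __init__(self, out: Path, manifest: RunManifest, old_stages: dict):
        self.out = out
        self.manifest = manifest
        self.old = old_stages

    def run(self, name: str, inputs_hash: str, outputs: list[str], fn):
        paths = [self.out / o for o in outputs]
        prev = self.old.get(name)
        if prev and prev["inputs_hash"] == inputs_hash and all(
            p.exists() for p in paths
        ):
            self.manifest.stages[name] = prev | {"cached": True}
            return
        t0 = time.time()
        try:
            fn()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        self.manifest.stages[name] = {
            "inputs_hash": inputs_hash,
            "outputs": {str(o): _hash_file(p) for o, p in zip(outputs, paths)},
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "cached": False,
        }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis pipeline; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old_stages = {}
    if manifest_path.exists():
        old_stages = json.loads(manifest_path.read_text()).get("stages", {})
    manifest = RunManifest(
        config_hash=_hash_obj(config), version=__version__, seed=config.seed
    )
    runner = _Runner(out, manifest, old_stages)
    gen = dataclasses.replace(config.generator, seed=config.seed)

    # -- simulate ----------------------------------------------------------
    def do_simulate():
        cohort, features = generate_cohort(gen)
        io.write_cohort_table(cohort, out / "cohort.tsv")
        io.write_feature_matrix(features, out / "volume.tsv")
        rois = default_roi_map(gen.n_regions)
        io.write_roi_map(
            {k: [features.columns[j] for j in v] for k, v in rois.items()},
            out / "roimap.tsv",
        )

    if config.cohort_path is None:
        runner.run("simulate", _hash_obj(gen), ["cohort.tsv", "volume.tsv", "roimap.tsv"], do_simulate)
        cohort_path, features_path = out / "cohort.tsv", out / "volume.tsv"
        roimap_path = out / "roimap.tsv"
    else:
        cohort_path = Path(config.cohort_path)
        features_path = Path(config.features_path)
        roimap_path = Path(config.roimap_path)

    cohort = io.read_cohort_table(cohort_path)
    features = io.read_feature_matrix(features_path)
    roi_map = io.read_roi_map(roimap_path)
    data_hash = _hash_file(cohort_path) + _hash_file(features_path)

    # -- split -------------------------------------------------------------
    def do_split():
        spec = normative.split_cohort(cohort, config.n_healthy_to_test, config.seed)
        (out / "split.json").write_text(
            json.dumps({"train_ids": spec.train_ids, "test_ids": spec.test_ids})
        )

    runner.run(
        "split",
        _hash_obj([data_hash, config.n_healthy_to_test, config.seed]),
        ["split.json"],
        do_split,
    )
    split = json.loads((out / "split.json").read_text())
    train_mask = cohort["subject_id"].isin(split["train_ids"])
    test_mask = cohort["subject_id"].isin(split["test_ids"])
    train_cohort = cohort[train_mask].reset_index(drop=True)
    test_cohort = cohort[test_mask].reset_index(drop=True)
    train_feats = features.loc[train_cohort["subject_id"]]
    test_feats = features.loc[test_cohort["subject_id"]]

    # -- normative model and deviations ------------------------------------
    norm_hash = _hash_obj([data_hash, config.n_restarts, config.seed, "norm"])

    def do_normative():
        model = normative.fit_normative(
            train_feats, train_cohort, n_restarts=config.n_restarts,
            random_state=config.seed,
        )
        with open(out / "models.pkl", "wb") as fh:
            pickle.dump({"version": __version__, "model": model}, fh)
        (out / "models_manifest.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "region_ids": model.region_ids_,
                    "n_train": len(train_cohort),
                    "training_hash": data_hash,
                    "seed": config.seed,
                }
            )
        )
        z = model.transform(test_cohort, test_feats)
        io.write_feature_matrix(z, out / "deviations_test.tsv")

    runner.run(
        "normative", norm_hash,
        ["models.pkl", "models_manifest.json", "deviations_test.tsv"],
        do_normative,
    )

    def do_cv():
        z_cv = normative.crossval_deviations(
            train_feats, train_cohort, k=config.cv_folds, seed=config.seed,
            n_restarts=config.n_restarts, random_state=config.seed,
        )
        io.write_feature_matrix(z_cv, out / "deviations_cv.tsv")

    runner.run(
        "normative_cv", _hash_obj([norm_hash, config.cv_folds]),
        ["deviations_cv.tsv"], do_cv,
    )
    deviations = io.read_feature_matrix(out / "deviations_test.tsv")

    # -- prediction: deviations vs raw volume ------------------------------
    pcfg = dataclasses.replace(config.prediction, seed=config.seed)

    def do_predict():
        rows, summary = [], {}
        for dim in config.predict_dimensions:
            y = test_cohort[dim].to_numpy()
            n_comp = {}
            per_kind = {}
            for kind, feats in (
                ("deviation_z", deviations),
                ("raw_volume", test_feats),
            ):
                cfg_k = pcfg
                if kind == "raw_volume" and "deviation_z" in n_comp:
                    cfg_k = dataclasses.replace(
                        pcfg, n_components_override=n_comp["deviation_z"]
                    )
                scores = prediction.repeated_cv_predict(
                    feats, y, test_cohort, cfg_k, dimension=dim, feature_kind=kind
                )
                prediction.attach_permutation_pvalues(
                    scores, feats, y, test_cohort, cfg_k
                )
                _, _, n_comp[kind] = prediction.pca_reduce(
                    feats.to_numpy(), feats.to_numpy()[:1],
                    pcfg.pc_variance_threshold, cfg_k.n_components_override,
                )
                per_kind[kind] = scores
                for m, sd in scores.items():
                    rows.append(
                        {
                            "dimension": dim, "feature_kind": kind, "metric": m,
                            "mean_score": sd.point_estimate,
                            "permutation_p": sd.permutation_p,
                            **{f"rep_{i}": v for i, v in enumerate(sd.values)},
                        }
                    )
            summary[dim] = {
                m: {
                    "exact_test": prediction.exact_test_of_differences(
                        per_kind["deviation_z"][m].values,
                        per_kind["raw_volume"][m].values,
                        seed=config.seed,
                    )
                }
                for m in prediction.METRICS
            }
        table = pd.DataFrame(rows)
        # FDR across dimensions within each (feature kind, metric) family
        for (kind, m), grp in table.groupby(["feature_kind", "metric"]):
            rej = prediction.fdr_correct(
                grp["permutation_p"].to_numpy(), q=config.fdr_q
            )
            table.loc[grp.index, "fdr_significant"] = rej
        cols = ["dimension", "feature_kind", "metric", "mean_score",
                "permutation_p", "fdr_significant"]
        table[cols + [c for c in table.columns if c.startswith("rep_")]].to_csv(
            out / "prediction_scores.tsv", sep="\t", index=False
        )
        (out / "prediction_summary.json").write_text(
            json.dumps(summary, indent=2)
        )

    runner.run(
        "predict", _hash_obj([norm_hash, pcfg, config.predict_dimensions]),
        ["prediction_scores.tsv", "prediction_summary.json"], do_predict,
    )

    # -- regional ----------------------------------------------------------
    covars = test_cohort[["t1_qa", "t1_snr"]].to_numpy()

    def do_regional():
        roi_dev = regional.roi_average(deviations, roi_map)
        rows, drows = [], []
        for roi in roi_dev.columns:
            x = roi_dev[roi].to_numpy()
            r, p = regional.residualized_correlation(
                x, test_cohort["p"].to_numpy(), covars
            )
            rows.append({"roi": roi, "dimension": "p", "r": r, "p": p})
            for dim in SPECIFIC_DIMS:
                r, p = regional.residualized_correlation(
                    x, test_cohort[dim].to_numpy(), covars
                )
                rows.append({"roi": roi, "dimension": dim, "r": r, "p": p})
                res = regional.bootstrap_delta_r(
                    x, test_cohort, dim, covars, n_boot=config.n_boot,
                    ci_level=config.ci_level, seed=config.seed,
                )
                drows.append(
                    {
                        "roi": roi, "specific_dimension": dim,
                        "delta_r_mean": float(res.delta_r.mean()),
                        "ci_low": res.ci[0], "ci_high": res.ci[1],
                        "significant": res.significant,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "roi_correlations.tsv", sep="\t", index=False)
        pd.DataFrame(drows).to_csv(out / "roi_delta_r.tsv", sep="\t", index=False)
        regional.mass_univariate(
            deviations, test_cohort, covars, q=config.fdr_q
        ).to_csv(out / "mass_univariate.tsv", sep="\t", index=False)

    runner.run(
        "regional", _hash_obj([norm_hash, config.n_boot, config.ci_level]),
        ["roi_correlations.tsv", "roi_delta_r.tsv", "mass_univariate.tsv"],
        do_regional,
    )

    # -- case-control ------------------------------------------------------
    def do_casecontrol():
        # controls are drawn from the FULL healthy cohort: training subjects
        # carry cross-validated deviations, test subjects direct ones
        z_cv = io.read_feature_matrix(out / "deviations_cv.tsv")
        dev_all = pd.concat([deviations, z_cv])
        healthy_pool = cohort[cohort["group"] == "healthy"]
        summary: dict = {"groups": {}}
        d_maps, d_maps_ctl = {}, {}
        used: set[str] = set()
        for grp in config.case_groups:
            cases = test_cohort[test_cohort["group"] == grp]
            pool = healthy_pool[~healthy_pool["subject_id"].isin(used)]
            match = case_control.match_controls(cases, pool, seed=config.seed)
            used.update(match.control_ids)
            d = case_control.cohens_d_map(
                dev_all, match.case_ids, match.control_ids
            )
            scope = list(match.case_ids) + list(match.control_ids)
            resid = case_control.control_for_factor(
                dev_all, cohort, config.control_factor, scope
            )
            d_ctl = case_control.cohens_d_map(
                resid, match.case_ids, match.control_ids
            )
            t, p = case_control.d_shift_test(d, d_ctl)
            d_maps[grp], d_maps_ctl[grp] = d, d_ctl
            summary["groups"][grp] = {
                "n_cases": len(match.case_ids),
                "balance_smd": match.balance,
                "d_shift_t": t,
                "d_shift_p": p,
            }
            pd.DataFrame(
                {"cohens_d": d, "cohens_d_controlled": d_ctl}
            ).to_csv(out / f"cohens_d_{grp}.tsv", sep="\t")
        a, b = config.case_groups[:2]
        r0, p0 = case_control.spatial_correlation(d_maps[a], d_maps[b])
        r1, p1 = case_control.spatial_correlation(d_maps_ctl[a], d_maps_ctl[b])
        summary["spatial_r"] = {"before": [r0, p0], "after_control": [r1, p1]}
        (out / "casecontrol_summary.json").write_text(json.dumps(summary, indent=2))

    runner.run(
        "casecontrol",
        _hash_obj([norm_hash, config.cv_folds, config.case_groups,
                   config.control_factor]),
        ["casecontrol_summary.json"]
        + [f"cohens_d_{g}.tsv" for g in config.case_groups],
        do_casecontrol,
    )

    manifest.save(manifest_path)
    return manifest
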
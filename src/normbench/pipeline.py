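"""End-to-end benchmark suite: simulate -> fit -> deviations -> benchmarks -> compare.

The suite follows the benchmarking workflow: normative models are trained
on healthy controls from the training sites only; benchmark sites play
the role of unseen scanners, with half of each benchmark site's controls
used as the transfer adaptation sample and the other half (plus the
patients) entering the benchmarks. Deviation scores and nuisance-
residualized raw features for the same benchmark subjects feed the three
tasks on both arms, and each task's theta gets a shared-shuffle
permutation p-value. The whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmarks import (
    compare_extreme_counts,
    summarize_extreme_deviations,
)
from .features import connectome_feature_table, residualize_features
from .normative import NormativeModelSet
from .permutation import (
    make_task1_runner,
    make_task2_runner,
    make_task3_runner,
    run_permutation_test,
)
from .synthetic import CohortConfig, generate_cognition, generate_cohort, generate_connectome_runs

logger = logging.getLogger("normbench")

__all__ = ["RunConfig", "BenchmarkReport", "run_benchmark_suite", "write_report", "read_report"]

TASK_LABELS = {1: "Group Difference", 2: "Classification", 3: "Regression"}


@dataclass
class RunConfig:
    """Configuration of a full benchmark run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_training_sites: int = 2
    modalities: tuple = ("structural",)
    n_networks: int = 8
    n_runs: int = 2
    alpha: float = 0.05
    n_folds: int = 10
    bbs_k: int = 15
    z_threshold: float = 2.0
    n_permutations: int = 499
    seed: int = 0
    outdir: str = None

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        bad = set(self.modalities) - {"structural", "connectome"}
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        if not 1 <= self.n_training_sites < self.cohort.n_sites:
            raise ValueError("n_training_sites must leave at least one benchmark site")

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        missing = set(d) - {f.name for f in dataclasses.fields(cls)}
        if missing:
            raise ValueError(f"unknown config keys: {sorted(missing)}")
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class BenchmarkReport:
    """Theta rows per task x modality, fit metrics, and provenance."""

    rows: list
    fit_metrics: dict
    extreme_deviation_tests: dict
    provenance: dict

    def to_dict(self):
        # JSON-canonical (tuples become lists) so write/read round-trips equal
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    def comparable_dict(self):
        """Report content without timestamps/wall times, for equality checks."""
        d = self.to_dict()
        d["provenance"] = {
            k: v for k, v in d["provenance"].items() if k not in ("created", "stage_seconds")
        }
        return d


def _derived_seed(seed, *key):
    """A deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


def _split_benchmark_sites(cov, n_training_sites, seed):
    sites = sorted(cov["site"].unique())
    training_sites = sites[:n_training_sites]
    benchmark_sites = sites[n_training_sites:]
    rng = np.random.default_rng(_derived_seed(seed, 10))
    adaptation_ids, test_control_ids = [], []
    for site in benchmark_sites:
        ids = list(cov.index[(cov["site"] == site) & (cov["group"] == "control")])
        rng.shuffle(ids)
        half = len(ids) // 2
        adaptation_ids.append(ids[:half])
        test_control_ids.extend(ids[half:])
    patient_ids = list(cov.index[(cov["site"].isin(benchmark_sites)) & (cov["group"] == "patient")])
    return training_sites, benchmark_sites, adaptation_ids, test_control_ids, patient_ids


def _modality_tables(config, modality):
    if modality == "structural":
        cov, features, truth = generate_cohort(config.cohort)
    else:
        cov, runs, truth = generate_connectome_runs(
            config.cohort, n_networks=config.n_networks, n_runs=config.n_runs
        )
        features = connectome_feature_table(runs)
    cognition = generate_cognition(features, truth, seed=_derived_seed(config.seed, 20))
    cov = cov.assign(cognition=cognition)
    return cov, features, truth


def prepare_benchmark_arms(config, modality="structural"):
    """Simulate, fit, transfer, and build the two benchmark feature arms.

    Returns a dict with the deviation-score table ``z``, the residualized
    raw table ``raw``, the boolean patient ``labels``, the benchmark
    covariates, the fitted ``model_set``, the full cohort tables, and the
    test-control ids — everything the benchmark tasks need.
    """
    timings = {}
    t0 = time.perf_counter()
    cov, features, truth = _modality_tables(config, modality)
    timings["simulate"] = time.perf_counter() - t0
    logger.info("[%s] simulated %d subjects x %d features", modality, *features.shape)

    training_sites, benchmark_sites, adaptation_ids, test_control_ids, patient_ids = (
        _split_benchmark_sites(cov, config.n_training_sites, config.seed)
    )
    train_mask = cov["site"].isin(training_sites) & (cov["group"] == "control")
    t0 = time.perf_counter()
    model_set = NormativeModelSet.fit(cov[train_mask], features[train_mask])
    for ids in adaptation_ids:
        model_set = model_set.transfer(cov.loc[ids], features.loc[ids])
    timings["fit_normative"] = time.perf_counter() - t0
    logger.info(
        "[%s] fit %d normative models on %d training controls; %d transfer sites",
        modality,
        features.shape[1],
        int(train_mask.sum()),
        len(benchmark_sites),
    )

    bench_ids = test_control_ids + patient_ids
    bench_cov = cov.loc[bench_ids]
    bench_features = features.loc[bench_ids]
    t0 = time.perf_counter()
    z = model_set.deviation_scores(bench_cov, bench_features)
    raw = residualize_features(
        bench_features, bench_cov, include_motion=(modality == "connectome")
    )
    timings["deviations"] = time.perf_counter() - t0
    return {
        "z": z,
        "raw": raw,
        "labels": (bench_cov["group"] == "patient").to_numpy(),
        "bench_cov": bench_cov,
        "model_set": model_set,
        "cov": cov,
        "features": features,
        "truth": truth,
        "test_control_ids": test_control_ids,
        "timings": timings,
    }


def _run_modality(config, modality):
    arms = prepare_benchmark_arms(config, modality)
    z, raw, labels, bench_cov, model_set = (
        arms["z"],
        arms["raw"],
        arms["labels"],
        arms["bench_cov"],
        arms["model_set"],
    )
    cov, features, test_control_ids = arms["cov"], arms["features"], arms["test_control_ids"]
    timings = arms["timings"]

    control_metrics = model_set.metrics(cov.loc[test_control_ids], features.loc[test_control_ids])
    z_controls = z.loc[test_control_ids].to_numpy()
    fit_summary = {
        "mean_explained_variance": float(control_metrics["explained_variance"].mean()),
        "mean_msll": float(control_metrics["msll"].mean()),
        "mean_z_skew": float(control_metrics["z_skew"].mean()),
        "mean_z_kurtosis": float(control_metrics["z_kurtosis"].mean()),
        "control_z_mean": float(z_controls.mean()),
        "control_z_sd": float(z_controls.std()),
        "n_test_controls": len(test_control_ids),
    }

    rows = []
    extreme_tests = {}
    n_bench = len(bench_cov)

    # task 1: mass-univariate group differences
    t0 = time.perf_counter()
    try:
        runner = make_task1_runner(alpha=config.alpha)
        res = run_permutation_test(
            1, runner, z.to_numpy(), raw.to_numpy(), labels,
            n_permutations=config.n_permutations, seed=_derived_seed(config.seed, 31),
        )
        rows.append(_theta_row(1, modality, res, n_bench))
        summary = summarize_extreme_deviations(z.to_numpy(), labels, threshold=config.z_threshold)
        u_pos, p_pos = compare_extreme_counts(summary.positive_patient, summary.positive_control)
        u_neg, p_neg = compare_extreme_counts(summary.negative_patient, summary.negative_control)
        extreme_tests = {
            "positive": {"U": u_pos, "p": p_pos},
            "negative": {"U": u_neg, "p": p_neg},
            "threshold": config.z_threshold,
        }
    except ValueError as exc:
        rows.append(_error_row(1, modality, exc, n_bench))
    timings["task1"] = time.perf_counter() - t0

    # task 2: SVC classification
    t0 = time.perf_counter()
    try:
        runner = make_task2_runner(labels, n_folds=config.n_folds, seed=_derived_seed(config.seed, 32) % (2**31))
        res = run_permutation_test(
            2, runner, z.to_numpy(), raw.to_numpy(), labels,
            n_permutations=config.n_permutations, seed=_derived_seed(config.seed, 33),
        )
        rows.append(_theta_row(2, modality, res, n_bench))
    except ValueError as exc:
        rows.append(_error_row(2, modality, exc, n_bench))
    timings["task2"] = time.perf_counter() - t0

    # task 3: BBS regression on the healthy benchmark controls
    t0 = time.perf_counter()
    try:
        control_pos = np.flatnonzero(~labels)
        rng = np.random.default_rng(_derived_seed(config.seed, 34))
        rng.shuffle(control_pos)
        half = len(control_pos) // 2
        train_idx, test_idx = control_pos[:half], control_pos[half:]
        k = config.bbs_k
        if k > min(len(train_idx) - 1, z.shape[1]):
            raise ValueError(
                f"bbs_k={k} exceeds min(n_train - 1, n_features) = "
                f"{min(len(train_idx) - 1, z.shape[1])}"
            )
        cognition = bench_cov["cognition"].to_numpy(dtype=float)
        runner = make_task3_runner(train_idx, test_idx, k=k)
        res = run_permutation_test(
            3, runner, z.to_numpy(), raw.to_numpy(), cognition,
            n_permutations=config.n_permutations, seed=_derived_seed(config.seed, 35),
        )
        rows.append(_theta_row(3, modality, res, n_bench))
    except ValueError as exc:
        rows.append(_error_row(3, modality, exc, n_bench))
    timings["task3"] = time.perf_counter() - t0
    for stage, secs in timings.items():
        logger.info("[%s] %s: %.2fs", modality, stage, secs)
    return rows, fit_summary, extreme_tests, timings


def _theta_row(task, modality, res, n_subjects):
    return {
        "task": task,
        "benchmark": TASK_LABELS[task],
        "modality": modality,
        "status": "ok",
        "metric_z": res.metric_z,
        "metric_r": res.metric_r,
        "theta": res.theta_observed,
        "C": res.C,
        "n_permutations": res.n_permutations,
        "p_value": res.p_value,
        "seed": res.seed,
        "n_subjects": n_subjects,
        "null_digest": res.to_dict()["null_digest"],
    }


def _error_row(task, modality, exc, n_subjects):
    logger.warning("[%s] task %d not run: %s", modality, task, exc)
    return {
        "task": task,
        "benchmark": TASK_LABELS[task],
        "modality": modality,
        "status": f"error: {exc}",
        "metric_z": None,
        "metric_r": None,
        "theta": None,
        "C": None,
        "n_permutations": None,
        "p_value": None,
        "seed": None,
        "n_subjects": n_subjects,
        "null_digest": None,
    }


def run_benchmark_suite(config):
    """Run the full suite for every requested modality; returns a report
    (and writes it to ``config.outdir`` when set)."""
    all_rows, fit_metrics, extremes, stage_seconds = [], {}, {}, {}
    for modality in config.modalities:
        rows, fit_summary, extreme_tests, timings = _run_modality(config, modality)
        all_rows.extend(rows)
        fit_metrics[modality] = fit_summary
        extremes[modality] = extreme_tests
        stage_seconds[modality] = {k: round(v, 3) for k, v in timings.items()}
    report = BenchmarkReport(
        rows=all_rows,
        fit_metrics=fit_metrics,
        extreme_deviation_tests=extremes,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stage_seconds": stage_seconds,
        },
    )
    if config.outdir:
        write_report(report, config.outdir)
    return report


def write_report(report, outdir):
    """Write report.json and a Table-2-shaped report.csv; refuses to write
    any row whose p-value violates p = (C + 1)/(n_permutations + 1)."""
    import pathlib

    for row in report.rows:
        if row["status"] == "ok":
            expected = (row["C"] + 1) / (row["n_permutations"] + 1)
            if row["p_value"] != expected:
                raise ValueError(
                    f"refusing to write: row (task {row['task']}, {row['modality']}) has "
                    f"p={row['p_value']} but (C+1)/(n+1)={expected}"
                )
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    table = pd.DataFrame(
        [
            {
                "Benchmark": r["benchmark"],
                "Modality": r["modality"],
                "Deviation": r["metric_z"],
                "Raw": r["metric_r"],
                "Difference": r["theta"],
                "p": r["p_value"],
            }
            for r in report.rows
        ]
    )
    table.to_csv(out / "report.csv", index=False)
    logger.info("report written to %s", out)
    return out / "report.json", out / "report.csv"


def read_report(path):
    """Read back a report.json written by :func:`write_report`."""
    with open(path) as fh:
        return BenchmarkReport.from_dict(json.load(fh))
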
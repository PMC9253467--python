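"""End-to-end orchestration: simulate -> sweep -> tables -> train -> evaluate.

This module glues the simulator, dataset builders, network trainers and
evaluators into the reproducible study pipeline used by the command-line
interface and the acceptance machinery.  Sweeps are resumable: each
completed case is stored in an HDF5 trajectory container keyed by the
configuration hash, and already-stored cases are not recomputed.
"""

from __future__ import annotations

import statistics
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bpnn import SurrogateModel, train_surrogate
from .config import TARGET_NAMES, RunConfig
from .evaluation import EvaluationReport, evaluate_surrogate, fit_correlation
from .fsi_sim import Trajectory, TransitResult, run_transit
from .sweep_dataset import (
    CANONICAL_IMPACTION_PAIRS,
    MOTION_TEST_PAIRS,
    TIME_TEST_PAIRS,
    SampleTable,
    make_motion_table,
    make_time_table,
)

__all__ = [
    "simulate_case",
    "run_sweep",
    "sweep_summary",
    "retained",
    "build_table",
    "train_target",
    "evaluate_target",
    "StudyResult",
    "run_study",
    "save_sweep",
    "load_sweep",
]


def _log(msg: str, enabled: bool) -> None:
    if enabled:
        print(msg, file=sys.stderr, flush=True)


def simulate_case(cfg: RunConfig, Re: float, AR: float) -> TransitResult:
    """Run one scenario under a configuration's physical settings."""
    return run_transit(cfg.sim_params(Re, AR))


# ---------------------------------------------------------------------------
# trajectory store (HDF5, one group per case)
# ---------------------------------------------------------------------------


def _case_key(Re: float, AR: float) -> str:
    return f"re{Re:.4f}_ar{AR:.4f}"


def save_sweep(path, cfg: RunConfig, results: dict) -> None:
    """Persist sweep results; config hash recorded for provenance."""
    import h5py

    with h5py.File(path, "a") as f:
        f.attrs["config_hash"] = cfg.hash()
        f.attrs["seed"] = cfg.seed
        for (Re, AR), res in results.items():
            key = _case_key(Re, AR)
            if key in f:
                continue
            g = f.create_group(key)
            g.attrs.update(
                {
                    "Re": Re,
                    "AR": AR,
                    "outcome": res.outcome,
                    "transit_time": res.transit_time,
                    "n_steps": res.n_steps,
                    "dt": res.dt,
                    "area_drift": res.area_drift,
                    "max_dimensionless_divergence": res.max_dimensionless_divergence,
                }
            )
            for name in Trajectory._FIELDS:
                g.create_dataset(name, data=res.trajectory.series(name))


def load_sweep(path, cfg: RunConfig | None = None) -> dict:
    """Load stored cases; rejects a store from a different configuration."""
    import h5py

    results = {}
    with h5py.File(path, "r") as f:
        if cfg is not None and f.attrs.get("config_hash") != cfg.hash():
            raise ValueError(
                f"trajectory store {path} was produced by config "
                f"{f.attrs.get('config_hash')}, not {cfg.hash()}"
            )
        for key, g in f.items():
            Re, AR = float(g.attrs["Re"]), float(g.attrs["AR"])
            traj = Trajectory(
                Re=Re, AR=AR, **{name: g[name][...] for name in Trajectory._FIELDS}
            )
            params = None if cfg is None else cfg.sim_params(Re, AR)
            results[(Re, AR)] = TransitResult(
                params=params,
                outcome=str(g.attrs["outcome"]),
                transit_time=float(g.attrs["transit_time"]),
                trajectory=traj,
                n_steps=int(g.attrs["n_steps"]),
                dt=float(g.attrs["dt"]),
                area_drift=float(g.attrs["area_drift"]),
                max_dimensionless_divergence=float(
                    g.attrs["max_dimensionless_divergence"]
                ),
            )
    return results


def run_sweep(
    cfg: RunConfig,
    pairs=None,
    store_path=None,
    progress: bool = False,
) -> dict:
    """Simulate every (Re, AR) pair, resuming from a store if given.

    Returns ``{(Re, AR): TransitResult}``.  A case that fails is logged and
    skipped; the remaining cases still run, and the failures are listed at
    the end.
    """
    if pairs is None:
        pairs = cfg.grid().cases()
    results = {}
    if store_path is not None and Path(store_path).exists():
        stored = load_sweep(store_path, cfg)
        results.update({k: v for k, v in stored.items() if k in set(pairs)})
    failures = []
    for Re, AR in pairs:
        if (Re, AR) in results:
            _log(f"case {_case_key(Re, AR)}: cached", progress)
            continue
        try:
            res = simulate_case(cfg, Re, AR)
        except Exception as exc:  # noqa: BLE001 - batch robustness
            failures.append(((Re, AR), repr(exc)))
            _log(f"case {_case_key(Re, AR)}: FAILED {exc!r}", progress)
            continue
        results[(Re, AR)] = res
        _log(
            f"case {_case_key(Re, AR)}: outcome={res.outcome} "
            f"transit_time={res.transit_time:.5g}s steps={res.n_steps} "
            f"wall={res.wall_time:.1f}s",
            progress,
        )
        if store_path is not None:
            save_sweep(store_path, cfg, {(Re, AR): res})
    if failures:
        _log(f"{len(failures)} case(s) failed: {failures}", True)
    return results


def sweep_summary(results: dict) -> pd.DataFrame:
    """One row per case: Re, AR, outcome, transit_time."""
    rows = [
        {
            "Re": Re,
            "AR": AR,
            "outcome": r.outcome,
            "transit_time": r.transit_time,
            "n_samples": len(r.trajectory),
            "area_drift": r.area_drift,
            "max_dimensionless_divergence": r.max_dimensionless_divergence,
        }
        for (Re, AR), r in sorted(results.items())
    ]
    return pd.DataFrame(rows)


def retained(cfg: RunConfig, results: dict) -> dict:
    """Drop impaction/timeout cases per the configured exclusion mode."""
    if cfg.exclusion_mode == "canonical":
        excluded = set(CANONICAL_IMPACTION_PAIRS)
        return {k: v for k, v in results.items() if k not in excluded}
    return {k: v for k, v in results.items() if v.outcome == "transit"}


# ---------------------------------------------------------------------------
# tables / training / evaluation
# ---------------------------------------------------------------------------


def build_table(cfg: RunConfig, results: dict, target: str, seed: int) -> SampleTable:
    """SampleTable for one target from retained sweep results."""
    kept = retained(cfg, results)
    if target == "transit_time":
        return make_time_table(sweep_summary(kept), cfg.split_fractions, seed)
    return make_motion_table(
        [r.trajectory for _, r in sorted(kept.items())],
        target,
        cfg.split_fractions,
        seed,
    )


def train_target(cfg: RunConfig, results: dict, target_name: str, seed: int):
    """Build the table and train the surrogate for one named target.

    ``target_name`` is a short CLI name (time, rmax, vy, lift, drag).
    Returns ``(model, report, table)``.
    """
    column = TARGET_NAMES[target_name]
    table = build_table(cfg, results, column, seed)
    spec = cfg.network_spec(target_name, seed=seed)
    model, report = train_surrogate(table, spec, seed=seed)
    model.meta["config_hash"] = cfg.hash()
    model.meta["seed"] = seed
    return model, report, table


def evaluate_target(model: SurrogateModel, test_results: dict) -> EvaluationReport:
    """Score a surrogate against freshly simulated held-out cases."""
    cases = []
    for (Re, AR), res in sorted(test_results.items()):
        case = {"Re": Re, "AR": AR}
        if model.target_column == "transit_time":
            case["transit_time"] = res.transit_time
        else:
            case["displacement"] = res.trajectory.displacement
            case[model.target_column] = res.trajectory.series(model.target_column)
        cases.append(case)
    return evaluate_surrogate(model, cases)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    """Everything the full pipeline produces, across training seeds."""

    config: RunConfig
    summary: pd.DataFrame
    n_retained: int
    time_r2: dict = field(default_factory=dict)  # seed -> pooled held-out R^2
    motion_min_r2: dict = field(default_factory=dict)  # target -> {seed: min per-case R^2}
    motion_fit: dict = field(default_factory=dict)  # target -> {seed: full-table correlation}
    table_sizes: dict = field(default_factory=dict)

    def median_time_r2(self) -> float:
        return statistics.median(self.time_r2.values())

    def median_motion_min_r2(self, target: str) -> float:
        return statistics.median(self.motion_min_r2[target].values())

    def median_motion_fit(self, target: str) -> float:
        return statistics.median(self.motion_fit[target].values())


def run_study(
    cfg: RunConfig,
    seeds,
    time_test_pairs=TIME_TEST_PAIRS,
    motion_test_pairs=MOTION_TEST_PAIRS,
    targets=("time", "rmax", "vy", "lift", "drag"),
    progress: bool = False,
    store_path=None,
) -> StudyResult:
    """Run the complete study: sweep, held-out sims, training, scoring.

    The simulator is deterministic, so the sweep and the held-out
    simulations are computed once and shared across training seeds; the
    seeds control only split assignment and network initialization.
    """
    grid_pairs = cfg.grid().cases()
    test_pairs = sorted(set(tuple(p) for p in time_test_pairs) | set(tuple(p) for p in motion_test_pairs))
    _log(f"sweep: {len(grid_pairs)} grid cases + {len(test_pairs)} test cases", progress)
    results = run_sweep(cfg, grid_pairs, store_path=store_path, progress=progress)
    test_results = run_sweep(cfg, test_pairs, store_path=store_path, progress=progress)

    study = StudyResult(
        config=cfg,
        summary=sweep_summary(results),
        n_retained=len(retained(cfg, results)),
    )

    time_tests = {p: test_results[p] for p in map(tuple, time_test_pairs) if p in test_results}
    motion_tests = {p: test_results[p] for p in map(tuple, motion_test_pairs) if p in test_results}

    for target in targets:
        if target == "time":
            for seed in seeds:
                model, report, table = train_target(cfg, results, "time", seed)
                rep = evaluate_target(model, time_tests)
                study.time_r2[seed] = rep.pooled_r2
                study.table_sizes["time"] = len(table)
                _log(
                    f"time model seed={seed}: stop={report.stop_reason} "
                    f"epochs={report.n_epochs} pooled R2={rep.pooled_r2:.5f}",
                    progress,
                )
        else:
            column = TARGET_NAMES[target]
            study.motion_min_r2[column] = {}
            study.motion_fit[column] = {}
            for seed in seeds:
                model, report, table = train_target(cfg, results, target, seed)
                rep = evaluate_target(model, motion_tests)
                pred_all = model.predict(table.df[table.input_columns])
                fit = fit_correlation(pred_all, table.df[column].to_numpy())
                study.motion_min_r2[column][seed] = rep.min_case_r2
                study.motion_fit[column][seed] = fit
                study.table_sizes[column] = len(table)
                _log(
                    f"{target} model seed={seed}: stop={report.stop_reason} "
                    f"epochs={report.n_epochs} min case R2={rep.min_case_r2:.5f} "
                    f"fit R={fit:.6f}",
                    progress,
                )
    return study
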
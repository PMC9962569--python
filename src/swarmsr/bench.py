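"""Benchmark harness: independent runs, summary statistics, CSV reports.

The reference protocol mirrors the optimizer comparison study: population 40,
10,000 iterations per run, 20 independent runs per (function, algorithm)
pair on a fixed seeded instance, reporting best / worst / mean / sample std /
mean absolute error versus the known optimum, plus wall-clock time.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import objectives
from .swarm import SwarmConfig, minimize

__all__ = ["table1_config", "run_function", "run_benchmark"]

#: CSV columns of the benchmark report
REPORT_COLUMNS = ["function", "algorithm", "best", "worst", "mean", "std",
                  "mae", "time_s"]


def table1_config(algorithm: str, seed: int, n_particles: int = 40,
                  iterations: int = 10_000) -> SwarmConfig:
    """The optimizer-comparison protocol: N=40, 10,000 iterations."""
    return SwarmConfig(n_particles=n_particles, eval_budget=None,
                       max_iterations=iterations, algorithm=algorithm,
                       seed=seed)


def run_function(instance: objectives.ObjectiveInstance, algorithm: str,
                 n_runs: int = 20, seed: int = 0, n_particles: int = 40,
                 iterations: int = 10_000) -> np.ndarray:
    """Final best values of ``n_runs`` independent swarm runs.

    The instance is fixed; runs differ only in the swarm seed
    (``seed``, ``seed+1``, ...).
    """
    finals = []
    for r in range(n_runs):
        cfg = table1_config(algorithm, seed + r, n_particles, iterations)
        res = minimize(instance, instance.lower, instance.upper,
                       instance.dimension, cfg)
        finals.append(res.best_value)
    return np.asarray(finals)


def run_benchmark(function_ids, algorithms, dimension: int = 30,
                  n_runs: int = 20, seed: int = 0, n_particles: int = 40,
                  iterations: int = 10_000,
                  instance_seed: int = 1) -> pd.DataFrame:
    """One summary row per (function, algorithm), deterministic given seeds."""
    rows = []
    for fid in function_ids:
        inst = objectives.make_instance(fid, dimension, instance_seed)
        for alg in algorithms:
            t0 = time.perf_counter()
            finals = run_function(inst, alg, n_runs, seed, n_particles,
                                  iterations)
            elapsed = time.perf_counter() - t0
            stats = objectives.summarize_runs(finals, inst.bias)
            rows.append({
                "function": fid, "algorithm": alg,
                "best": stats.best, "worst": stats.worst,
                "mean": stats.mean, "std": stats.std, "mae": stats.mae,
                "time_s": elapsed})
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
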
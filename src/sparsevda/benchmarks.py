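"""Simulation benchmarks: run the nested-CV pipeline over replicates.

This is the driver behind the reproduction script and the heavier tests:
generate data under a :class:`~sparsevda.simulation.SimulationScenario`,
run nested cross validation on the training samples, and score the refit
model once on the independent test set, repeating over seeds.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model_selection import CVConfig, nested_cv
from .simulation import SimulationScenario, simulate_classification
from .solvers import AnnealingSchedule, SolverControls

# Desk-scale tuning grids: three insensitivity radii bracketing the default
# and model sizes log-spaced over half the feature space.
BENCH_EPS_GRID = (0.1, 0.3, 0.5)
BENCH_K_GRID_P1000 = (1, 3, 12, 43, 146, 500)


def run_simulation_benchmark(
        scenario: SimulationScenario,
        n_replicates: int,
        family: str = "row",
        seed: int = 0,
        eps_grid: Sequence[float] = BENCH_EPS_GRID,
        k_grid: Optional[Sequence[int]] = None,
        n_folds: int = 3,
        schedule: Optional[AnnealingSchedule] = None,
        controls: Optional[SolverControls] = None):
    """Per-replicate test errors (%) and support metrics for one scenario.

    Each replicate regenerates data with its own seed (derived from
    ``seed``), tunes epsilon and k by nested CV on the training samples,
    and evaluates the refit model on the scenario's independent test set.
    Returns a dict with arrays ``test_error_pct``, ``tpr``, ``ppv`` and the
    list of chosen model sizes.
    """
    from dataclasses import replace

    if k_grid is None:
        k_grid = BENCH_K_GRID_P1000 if scenario.p == 1000 else None
    errors, tprs, ppvs, sizes = [], [], [], []
    for r in range(n_replicates):
        rep_seed = (seed * 1000 + r) % (2**31 - 1)
        data = simulate_classification(replace(scenario, seed=rep_seed))
        cfg = CVConfig(n_folds=n_folds, eps_grid=tuple(eps_grid),
                       k_grid=k_grid, seed=rep_seed)
        result = nested_cv(data.X_train, data.y_train, cfg, family=family,
                           schedule=schedule, controls=controls,
                           X_test=data.X_test, y_test=data.y_test)
        errors.append(result.test_error_pct)
        truth = data.truth
        if family == "col" and truth.per_class_support is not None:
            from .simulation import per_class_support_metrics
            tpr, ppv = per_class_support_metrics(result.per_class_support,
                                                 truth.per_class_support)
        else:
            from .simulation import support_metrics
            tpr, ppv = support_metrics(result.support, truth.support)
        tprs.append(tpr)
        ppvs.append(ppv)
        sizes.append(result.chosen_k)
    return {"test_error_pct": np.array(errors), "tpr": np.array(tprs),
            "ppv": np.array(ppvs), "chosen_k": sizes}


def median_test_error(bench: dict) -> float:
    return float(np.median(bench["test_error_pct"]))
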
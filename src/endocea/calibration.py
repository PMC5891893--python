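"""Calibration of the unpublished self-care parameters to prevalence targets.

Four quantities in the model have no published value: the three annual
self-care remission probabilities (dysmenorrhea, ENDO I/II, ENDO III/IV) and
the base annual ENDO I/II -> III/IV progression.  They are fitted so that the
simulated self-care arm matches external prevalence targets: a cumulative
national endometriosis case count (about 210,000 cases when scaled by the
population denominator) and age-group-specific prevalences of endometriosis
and dysmenorrhea.  The shipped target values are a synthetic stand-in
generated to be consistent with the package's calibrated base case, since the
underlying survey tables are not reproduced anywhere; users can substitute
real survey values through the CSV interface.

The optimizer is derivative-free and reproducible: a coarse bounded grid
search followed by Nelder-Mead refinement.  Age-specific targets beyond age
34 default to weight 0 (the model is known to overpredict prevalence there,
a discrepancy that is reproduced, not fixed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import HealthState, Strategy, prevalence_counts, run_cohort
from .parameters import CALIBRATABLE, CostParameters, ModelParameters

__all__ = [
    "CalibrationTarget",
    "CalibrationResult",
    "calibration_objective",
    "calibrate",
    "default_targets",
    "default_bounds",
    "targets_to_csv",
    "targets_from_csv",
]

_KINDS = ("cumulative_count", "age_specific_prevalence", "age_specific_dys_prevalence")


@dataclass(frozen=True)
class CalibrationTarget:
    """One observed quantity the self-care model should reproduce."""

    name: str
    kind: str
    observed: float
    age_low: int | None = None
    age_high: int | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("target weight must be non-negative")
        if self.observed <= 0:
            raise ValueError("observed target value must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    fitted: dict
    objective: float
    residuals: pd.DataFrame
    converged: bool
    n_evaluations: int


def default_targets() -> list:
    """Synthetic calibration targets (stand-ins for the unpublished survey
    tables), self-consistent with the package's calibrated base case."""
    endo = {(12, 16): 0.154, (17, 21): 0.146, (22, 26): 0.137, (27, 31): 0.137, (32, 34): 0.137}
    dys = {(12, 16): 0.697, (17, 21): 0.456, (22, 26): 0.453, (27, 31): 0.453, (32, 34): 0.452}
    targets = [
        CalibrationTarget("cumulative_endometriosis_cases", "cumulative_count", 210_000.0, weight=2.0)
    ]
    for (lo, hi), v in endo.items():
        targets.append(
            CalibrationTarget(f"endo_prevalence_{lo}_{hi}", "age_specific_prevalence", v, lo, hi)
        )
    for (lo, hi), v in dys.items():
        targets.append(
            CalibrationTarget(f"dys_prevalence_{lo}_{hi}", "age_specific_dys_prevalence", v, lo, hi)
        )
    return targets


def default_bounds() -> dict:
    """Feasible boxes for the calibratable parameters."""
    return {
        "p_selfcare_remission_dys": (0.005, 0.5),
        "p_selfcare_remission_endo12": (0.05, 0.95),
        "p_selfcare_remission_endo34": (0.05, 0.95),
        "p_progress_endo12_to_34": (0.01, 0.5),
    }


def targets_to_csv(targets, path) -> None:
    pd.DataFrame(
        [
            {
                "name": t.name,
                "kind": t.kind,
                "age_low": t.age_low,
                "age_high": t.age_high,
                "observed": t.observed,
                "weight": t.weight,
            }
            for t in targets
        ]
    ).to_csv(path, index=False)


def targets_from_csv(path) -> list:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"targets file {path} contains no targets")
    out = []
    for row in df.itertuples(index=False):
        lo = None if pd.isna(row.age_low) else int(row.age_low)
        hi = None if pd.isna(row.age_high) else int(row.age_high)
        out.append(
            CalibrationTarget(row.name, row.kind, float(row.observed), lo, hi, float(row.weight))
        )
    return out


def _model_quantity(trace, pop, target: CalibrationTarget) -> float:
    if target.kind == "cumulative_count":
        _, total = prevalence_counts(trace, pop)
        return total
    ages = trace.ages[:-1].astype(int)
    mask = (ages >= target.age_low) & (ages <= target.age_high)
    if not mask.any():
        raise ValueError(f"target {target.name}: ages {target.age_low}-{target.age_high} outside horizon")
    if target.kind == "age_specific_prevalence":
        occ = trace.occupancy[:-1, [HealthState.ENDO_I_II, HealthState.ENDO_III_IV]].sum(axis=1)
    else:
        occ = trace.occupancy[:-1, HealthState.DYSMENORRHEA]
    return float(occ[mask].mean())


def calibration_objective(
    free_params,
    free_names,
    targets,
    mp: ModelParameters,
    cp: CostParameters,
    pop,
) -> float:
    """Weighted sum of squared relative residuals of the self-care run.

    ``free_params`` are substituted into ``mp`` under ``free_names`` before
    the cohort is propagated.
    """
    if not targets:
        raise ValueError("need at least one calibration target")
    if all(t.weight == 0 for t in targets):
        raise ValueError("all target weights are zero: no information to calibrate on")
    mp2 = replace(mp, **dict(zip(free_names, np.asarray(free_params, dtype=float))))
    trace = run_cohort(mp2, Strategy.SELF_CARE)
    obj = 0.0
    for t in targets:
        if t.weight == 0:
            continue
        model = _model_quantity(trace, pop, t)
        obj += t.weight * ((model - t.observed) / t.observed) ** 2
    return float(obj)


def calibrate(
    targets,
    bounds: dict,
    mp: ModelParameters,
    cp: CostParameters,
    pop,
    seed: int = 0,
    grid_points: int = 5,
) -> CalibrationResult:
    """Fit the calibratable parameters to the targets.

    A full factorial grid over ``bounds`` (``grid_points`` per axis) locates
    the basin; bounded Nelder-Mead then refines.  The procedure is
    deterministic (``seed`` is accepted for interface symmetry with the
    stochastic pipeline stages but no randomness is used).  Non-convergence
    of the refinement is reported honestly in ``converged``.
    """
    if not bounds:
        raise ValueError("no calibratable parameters given")
    for name, (lo, hi) in bounds.items():
        if not (0 <= lo < hi <= 1):
            raise ValueError(f"infeasible bounds for {name}: ({lo}, {hi})")
    free_names = list(bounds)
    n_eval = 0

    def obj(x):
        nonlocal n_eval
        n_eval += 1
        return calibration_objective(x, free_names, targets, mp, cp, pop)

    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds.values()]
    best_x, best_f = None, np.inf
    for point in itertools.product(*axes):
        f = obj(point)
        if f < best_f:
            best_x, best_f = np.asarray(point), f

    res = optimize.minimize(
        obj,
        best_x,
        method="Nelder-Mead",
        bounds=list(bounds.values()),
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 2000},
    )
    x = np.clip(res.x, [lo for lo, _ in bounds.values()], [hi for _, hi in bounds.values()])
    fitted = dict(zip(free_names, x.tolist()))

    mp_fit = replace(mp, **fitted)
    trace = run_cohort(mp_fit, Strategy.SELF_CARE)
    rows = []
    for t in targets:
        model = _model_quantity(trace, pop, t)
        rows.append(
            {
                "name": t.name,
                "kind": t.kind,
                "observed": t.observed,
                "model": model,
                "relative_residual": (model - t.observed) / t.observed,
                "weight": t.weight,
            }
        )
    return CalibrationResult(
        fitted=fitted,
        objective=float(res.fun),
        residuals=pd.DataFrame(rows),
        converged=bool(res.success),
        n_evaluations=n_eval,
    )
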
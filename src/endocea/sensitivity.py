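"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the full two-arm pipeline at the low and high end
of a parameter's published sensitivity range, holding everything else at
base case; entries sorted by outcome spread give the tornado diagram.  The
default range sets mirror the published payer-perspective (ICER) and
societal-perspective (SMV) diagrams.

The probabilistic analysis draws every parameter that carries a
distribution assignment independently from its family (beta / normal /
lognormal, see :class:`endocea.parameters.DistributionSpec`), evaluates the
pipeline per draw, and summarises incremental cost and effect and the
cost-effectiveness acceptability curve (fraction of draws with positive net
monetary benefit as a function of willingness to pay).  Each draw uses its
own child generator seeded by (seed, draw index), so results are
reproducible and independent of batching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Strategy
from .economics import DEFAULT_WTP, compare, evaluate_strategy, run_base_case
from .parameters import AgeSchedule, CostParameters, DistributionSpec, ModelParameters

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "set_parameter",
    "one_way",
    "tornado",
    "sample_parameters",
    "run_psa",
    "ceac",
    "psa_summary",
    "PAYER_TORNADO_RANGES",
    "SOCIETAL_TORNADO_RANGES",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20180410  # configurable; any int < 2**31 works

#: published payer-perspective one-way ranges (ICER outcome)
PAYER_TORNADO_RANGES = {
    "p_cure_dys": (0.643, 0.957),
    "or_develop_endo12": (0.2, 0.7),
    "u_endo34": (0.15, 0.557),
    "visit_prop_endo": (0.0, 0.07),
    "p_progress_dys_to_endo12": (0.179, 0.189),
    "discount_rate": (0.01, 0.05),
    "u_dys": (0.63, 0.644),
    "p_recurrence": (0.206, 0.239),
    "p_cure_endo12": (0.322, 0.478),
    "u_endo12": (0.63, 0.644),
}

#: published societal-perspective one-way ranges (SMV outcome)
SOCIETAL_TORNADO_RANGES = {
    "discount_rate": (0.01, 0.05),
    "p_recurrence": (0.206, 0.239),
    "p_cure_endo12": (0.322, 0.478),
    "or_develop_endo12": (0.2, 0.7),
    "p_progress_dys_to_endo12": (0.179, 0.189),
    "p_cure_dys": (0.643, 0.957),
    "visit_prop_endo": (0.0, 0.07),
}

_MODEL_FIELD_NAMES = set(ModelParameters.__dataclass_fields__)
_COST_FIELD_NAMES = set(CostParameters.__dataclass_fields__)
_SCHEDULE_NAMES = {"incidence_dysmenorrhea", "visit_prop_dys", "visit_prop_endo", "mortality"}


def set_parameter(mp: ModelParameters, cp: CostParameters, name: str, value):
    """Return copies of (mp, cp) with one named parameter replaced.

    Age-dependent schedules accept a scalar, which overrides the whole
    schedule with a flat value (this is how the published one-way ranges for
    the visit proportions are expressed).
    """
    if name in _SCHEDULE_NAMES and np.isscalar(value):
        value = AgeSchedule(((0.0, float(value)),))
    if name in _MODEL_FIELD_NAMES:
        return replace(mp, **{name: value}), cp
    if name in _COST_FIELD_NAMES:
        return mp, replace(cp, **{name: value})
    valid = sorted(_MODEL_FIELD_NAMES | _COST_FIELD_NAMES)
    raise KeyError(f"unknown parameter {name!r}; valid names: {', '.join(valid)}")


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a tornado diagram."""

    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float
    outcome_base: float
    outcome: str

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)

    @property
    def base_within_endpoints(self) -> bool:
        lo, hi = sorted((self.outcome_low, self.outcome_high))
        return lo <= self.outcome_base <= hi


def _outcome_value(ce, outcome: str) -> float:
    if outcome == "icer":
        if ce.icer is None:
            raise ValueError("ICER undefined (zero incremental effect)")
        return ce.icer
    if outcome == "inc_cost":
        return ce.inc_cost
    if outcome == "smv":
        return ce.smv
    raise ValueError(f"unknown outcome {outcome!r} (use 'icer', 'inc_cost' or 'smv')")


def _evaluate_at(mp, cp, wtp):
    out = run_base_case(mp, cp, wtp)
    return out["ce"]


def one_way(
    mp: ModelParameters,
    cp: CostParameters,
    name: str,
    low: float,
    high: float,
    outcome: str = "icer",
    wtp: float = DEFAULT_WTP,
) -> TornadoEntry:
    """Deterministic one-way sensitivity of an incremental outcome."""
    if low > high:
        raise ValueError(f"invalid range for {name}: low {low} > high {high}")
    base = _outcome_value(_evaluate_at(mp, cp, wtp), outcome)
    values = []
    for v in (low, high):
        mp2, cp2 = set_parameter(mp, cp, name, v)
        values.append(_outcome_value(_evaluate_at(mp2, cp2, wtp), outcome))
    return TornadoEntry(name, low, high, values[0], values[1], base, outcome)


def tornado(
    mp: ModelParameters,
    cp: CostParameters,
    ranges: dict | None = None,
    outcome: str = "icer",
    wtp: float = DEFAULT_WTP,
) -> list:
    """All one-way entries, sorted by spread (widest bar first).

    Sorting breaks ties by parameter name so the result does not depend on
    the order ranges are supplied.
    """
    if ranges is None:
        ranges = PAYER_TORNADO_RANGES if outcome == "icer" else SOCIETAL_TORNADO_RANGES
    entries = [one_way(mp, cp, n, lo, hi, outcome, wtp) for n, (lo, hi) in ranges.items()]
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "outcome": e.outcome,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "outcome_base": e.outcome_base,
                "spread": e.spread,
            }
            for e in entries
        ]
    )


def sample_parameters(
    mp: ModelParameters,
    cp: CostParameters,
    dists: dict,
    rng: np.random.Generator,
):
    """One joint independent draw of every distributed parameter."""
    sampled = {}
    mp2, cp2 = mp, cp
    for name, spec in dists.items():
        if not isinstance(spec, DistributionSpec):
            raise TypeError(f"{name}: expected a DistributionSpec")
        value = float(spec.sample(rng))
        sampled[name] = value
        mp2, cp2 = set_parameter(mp2, cp2, name, value)
    return mp2, cp2, sampled


@dataclass(frozen=True)
class PSAResult:
    """Per-draw sampled parameters and incremental outcomes."""

    draws: pd.DataFrame
    n: int
    seed: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("PSA needs at least one draw")


def run_psa(
    mp: ModelParameters,
    cp: CostParameters,
    dists: dict,
    n: int = 10_000,
    seed: int = DEFAULT_SEED,
    wtp: float = DEFAULT_WTP,
) -> PSAResult:
    """Monte-Carlo pipeline evaluation over ``n`` independent parameter draws.

    Draw ``i`` uses ``numpy.random.default_rng([seed, i])``, so the result is
    bit-reproducible for a given seed and unchanged by parallel or partial
    execution order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    records = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        mp_i, cp_i, sampled = sample_parameters(mp, cp, dists, rng)
        out = run_base_case(mp_i, cp_i, wtp)
        ce = out["ce"]
        rec = {"iteration": i, **sampled}
        rec["inc_cost"] = ce.inc_cost
        rec["inc_effect"] = ce.inc_effect
        rec["smv"] = ce.smv
        records.append(rec)
    return PSAResult(draws=pd.DataFrame(records), n=n, seed=seed)


@dataclass(frozen=True)
class CEACCurve:
    """Acceptance probability by willingness-to-pay threshold."""

    wtp_grid: np.ndarray
    acceptance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "acceptance": self.acceptance})

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if not np.isclose(self.wtp_grid[idx], wtp):
            raise KeyError(f"wtp {wtp} not on the grid")
        return float(self.acceptance[idx])


def default_wtp_grid() -> np.ndarray:
    """0 to 5,000,000 JPY/QALY in 50,000-JPY steps."""
    return np.arange(0.0, 5_000_001.0, 50_000.0)


def ceac(psa: PSAResult, wtp_grid=None) -> CEACCurve:
    """Fraction of draws with positive net monetary benefit at each WTP."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    cost = psa.draws["inc_cost"].to_numpy()
    eff = psa.draws["inc_effect"].to_numpy()
    nmb = wtp_grid[:, None] * eff[None, :] - cost[None, :]
    return CEACCurve(wtp_grid=wtp_grid, acceptance=(nmb > 0).mean(axis=1))


def psa_summary(psa: PSAResult) -> dict:
    """Means, empirical 95% intervals and normal-theory CIs of the draws."""
    if psa.n < 2:
        raise ValueError("need at least two draws to summarise")
    out = {"n": psa.n, "seed": psa.seed}
    for key in ("inc_cost", "inc_effect", "smv"):
        x = psa.draws[key].to_numpy()
        mean = float(x.mean())
        lo, hi = np.percentile(x, [2.5, 97.5])
        se = float(x.std(ddof=1) / np.sqrt(len(x)))
        out[key] = {
            "mean": mean,
            "percentile_ci": (float(lo), float(hi)),
            "normal_ci_of_mean": (mean - 1.959963984540054 * se, mean + 1.959963984540054 * se),
            "sd": float(x.std(ddof=1)),
        }
    curve = ceac(psa)
    out["acceptance_at_100k"] = curve.at(100_000.0)
    out["acceptance_at_5m"] = curve.at(5_000_000.0)
    return out
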
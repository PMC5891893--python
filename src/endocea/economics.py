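"""Cost and QALY accumulation, discounting, ICER and societal monetary value.

Two perspectives are supported.  The healthcare-payer perspective counts only
direct medical costs reimbursed by national health insurance (outpatient
visits inclusive of drugs, inpatient care, surgery).  The societal
perspective adds non-medical direct costs (OTC analgesics and
self-medication, weighted by the published OTC-use proportion) and
opportunity costs from productivity loss, printed per half-year and accrued
twice per applicable person-year: at the self-care rate on symptomatic
person-years, and at the (much smaller) intervention rate on all
on-treatment person-years.

Costs accrue on start-of-cycle occupancy; both costs and QALYs are
discounted at the same annual rate with cycle 0 undiscounted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTrace, HealthState, Strategy, run_cohort
from .parameters import CostParameters, ModelParameters

__all__ = [
    "Perspective",
    "EconResult",
    "CEResult",
    "discount_factor",
    "accumulate_costs",
    "accumulate_qalys",
    "evaluate_strategy",
    "compare",
    "run_base_case",
    "DEFAULT_WTP",
]

DEFAULT_WTP = 5_000_000.0  # JPY per QALY, the Japanese willingness-to-pay threshold


class Perspective(enum.Enum):
    PAYER = "payer"
    SOCIETAL = "societal"


def discount_factor(rate: float, cycle):
    """Present-value factor ``(1 + rate)^(-cycle)`` for a yearly cycle index."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    cycle = np.asarray(cycle)
    if np.any(cycle < 0):
        raise ValueError("cycle index must be non-negative")
    out = (1.0 + rate) ** (-cycle.astype(float))
    return out.item() if out.ndim == 0 else out


def _cost_components(trace: CohortTrace, cp: CostParameters, mp: ModelParameters, rate: float):
    """Discounted (medical, non-medical direct, opportunity) cost totals."""
    ev = trace.events
    H = len(ev)
    disc = discount_factor(rate, np.arange(H))
    intervention = trace.strategy is Strategy.INTERVENTION
    managed = intervention and mp.recurrence_managed_under_intervention

    visits = cp.visits_per_year
    medical = (
        ev["attended_dys"].to_numpy() * visits * cp.visit_cost_dys
        + ev["attended_endo"].to_numpy() * visits * cp.visit_cost_endo
        + ev["surgery"].to_numpy() * (cp.mean_surgery_cost + cp.inpatient_cost_annual)
    )
    if intervention:
        medical = medical + (
            ev["maintenance"].to_numpy()
            * mp.maintenance_visits_per_year
            * cp.visit_cost_dys
        )
        if managed:
            medical = medical + ev["recurrence"].to_numpy() * visits * cp.visit_cost_dys

    if intervention:
        nonmedical = np.zeros(H)
        # residual productivity loss persists while on treatment, i.e. for
        # symptomatic person-years and cured person-years under maintenance
        on_treatment = (
            ev["symptomatic"].to_numpy()
            + trace.occupancy[:H, HealthState.CURED]
        )
        opportunity = on_treatment * 2.0 * cp.productivity_loss_halfyear_intervention
    else:
        otc_mix = (
            mp.prop_otc_selfcare * cp.otc_cost_annual
            + (1.0 - mp.prop_otc_selfcare) * cp.selfmed_cost_annual
        )
        sympt = ev["symptomatic"].to_numpy()
        nonmedical = sympt * otc_mix
        opportunity = sympt * 2.0 * cp.productivity_loss_halfyear_selfcare

    return (
        float(np.sum(medical * disc)),
        float(np.sum(nonmedical * disc)),
        float(np.sum(opportunity * disc)),
    )


def accumulate_costs(
    trace: CohortTrace,
    cp: CostParameters,
    mp: ModelParameters,
    perspective: Perspective,
    rate: float | None = None,
) -> float:
    """Total discounted cost (JPY) of one strategy arm under a perspective."""
    rate = mp.discount_rate if rate is None else rate
    medical, nonmedical, opportunity = _cost_components(trace, cp, mp, rate)
    if perspective is Perspective.PAYER:
        return medical
    return medical + nonmedical + opportunity


def accumulate_qalys(trace: CohortTrace, mp: ModelParameters, rate: float | None = None) -> float:
    """Discounted quality-adjusted life-years over the horizon.

    Occupancy is utility-weighted per cycle (WELL and CURED at 1.0, DEAD at
    0).  Under intervention, cured person-years with a managed recurrence
    episode carry the dysmenorrhea utility for that cycle.
    """
    rate = mp.discount_rate if rate is None else rate
    H = len(trace.events)
    disc = discount_factor(rate, np.arange(H))
    utilities = np.zeros(len(HealthState))
    utilities[HealthState.WELL] = mp.u_well
    utilities[HealthState.DYSMENORRHEA] = mp.u_dys
    utilities[HealthState.ENDO_I_II] = mp.u_endo12
    utilities[HealthState.ENDO_III_IV] = mp.u_endo34
    utilities[HealthState.CURED] = mp.u_cured
    per_cycle = trace.occupancy[:H] @ utilities
    if trace.strategy is Strategy.INTERVENTION and mp.recurrence_managed_under_intervention:
        per_cycle = per_cycle + trace.events["recurrence"].to_numpy() * (mp.u_dys - mp.u_cured)
    return float(np.sum(per_cycle * disc))


@dataclass(frozen=True)
class EconResult:
    """Per-strategy discounted cost and effectiveness totals."""

    strategy: Strategy
    cost_payer: float
    cost_nonmedical: float
    cost_opportunity: float
    qalys: float
    cost_payer_undiscounted: float
    qalys_undiscounted: float

    @property
    def cost_societal(self) -> float:
        return self.cost_payer + self.cost_nonmedical + self.cost_opportunity


def evaluate_strategy(
    mp: ModelParameters,
    cp: CostParameters,
    strategy: Strategy,
    trace: CohortTrace | None = None,
) -> EconResult:
    """Run (or reuse) the cohort and accumulate all economic outcomes."""
    if trace is None:
        trace = run_cohort(mp, strategy)
    med, nonmed, opp = _cost_components(trace, cp, mp, mp.discount_rate)
    med0, _, _ = _cost_components(trace, cp, mp, 0.0)
    return EconResult(
        strategy=strategy,
        cost_payer=med,
        cost_nonmedical=nonmed,
        cost_opportunity=opp,
        qalys=accumulate_qalys(trace, mp),
        cost_payer_undiscounted=med0,
        qalys_undiscounted=accumulate_qalys(trace, mp, 0.0),
    )


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of intervention (a) vs comparator (b)."""

    inc_cost: float
    inc_effect: float
    icer: float | None
    smv: float
    opportunity_saved: float
    direct_cost_consumed: float
    wtp: float
    cost_effective: bool | None

    def icer_usd(self, jpy_per_usd: float = 120.0) -> float | None:
        return None if self.icer is None else self.icer / jpy_per_usd


def compare(a: EconResult, b: EconResult, wtp: float = DEFAULT_WTP) -> CEResult:
    """Incremental cost-effectiveness (payer) and cost-benefit (societal).

    ``a`` is the intervention, ``b`` the comparator.  The ICER is incremental
    payer cost per QALY gained; it is undefined (None) when the incremental
    effect is zero.  The societal monetary value is the opportunity cost
    saved minus the full direct cost consumed by adopting ``a``; a positive
    value favours the intervention.
    """
    inc_cost = a.cost_payer - b.cost_payer
    inc_effect = a.qalys - b.qalys
    icer = inc_cost / inc_effect if inc_effect != 0 else None
    opportunity_saved = b.cost_opportunity - a.cost_opportunity
    direct_consumed = (a.cost_payer + a.cost_nonmedical) - (b.cost_payer + b.cost_nonmedical)
    smv = opportunity_saved - direct_consumed
    return CEResult(
        inc_cost=inc_cost,
        inc_effect=inc_effect,
        icer=icer,
        smv=smv,
        opportunity_saved=opportunity_saved,
        direct_cost_consumed=direct_consumed,
        wtp=wtp,
        cost_effective=None if icer is None else bool(icer < wtp),
    )


def run_base_case(mp: ModelParameters, cp: CostParameters, wtp: float = DEFAULT_WTP) -> dict:
    """Full two-arm evaluation: per-arm totals, incremental row, ICER and SMV."""
    trace_int = run_cohort(mp, Strategy.INTERVENTION)
    trace_sc = run_cohort(mp, Strategy.SELF_CARE)
    res_int = evaluate_strategy(mp, cp, Strategy.INTERVENTION, trace_int)
    res_sc = evaluate_strategy(mp, cp, Strategy.SELF_CARE, trace_sc)
    ce = compare(res_int, res_sc, wtp)
    return {
        "intervention": res_int,
        "self_care": res_sc,
        "ce": ce,
        "traces": {Strategy.INTERVENTION: trace_int, Strategy.SELF_CARE: trace_sc},
    }
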
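"""Model and cost parameters for the dysmenorrhea/endometriosis cohort model.

The base case encodes the published Japanese decision-model inputs: annual
transition probabilities, treatment-effect odds ratios, VAS utilities, unit
costs in JPY, a 3% annual discount rate, and a 23-cycle horizon starting at
age 12 (mean age of first menstruation).  Age-dependent quantities (incidence
of dysmenorrhea, visit proportions, background mortality) are piecewise-linear
schedules anchored at the published range endpoints.

Three self-care remission probabilities and the base ENDO I/II -> III/IV
progression are not published anywhere; they carry calibrated defaults (see
:mod:`endocea.calibration` and docs/methods.md) and are flagged accordingly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .synthetic import make_life_table

log = logging.getLogger(__name__)

__all__ = [
    "AgeSchedule",
    "ModelParameters",
    "CostParameters",
    "DistributionSpec",
    "ParameterError",
    "ConfigError",
    "base_case_parameters",
    "default_distributions",
    "load_parameters",
    "load_config",
    "save_parameters",
    "schedule_value",
    "CALIBRATABLE",
]


class ParameterError(ValueError):
    """A parameter value lies outside its scientific domain."""


class ConfigError(ValueError):
    """A configuration file could not be interpreted."""


@dataclass(frozen=True)
class AgeSchedule:
    """Age-dependent annual probability, interpolated between anchor points.

    Evaluation clamps to the first/last anchor value outside the anchored
    range.  ``interpolation`` is ``"linear"`` or ``"step"`` (left-continuous).
    """

    anchors: tuple  # ((age, value), ...)
    interpolation: str = "linear"

    def __post_init__(self):
        anchors = tuple((float(a), float(v)) for a, v in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        ages = [a for a, _ in anchors]
        vals = [v for _, v in anchors]
        if len(anchors) == 0:
            raise ParameterError("AgeSchedule needs at least one anchor")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ParameterError("AgeSchedule anchor ages must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ParameterError("AgeSchedule values must lie in [0, 1]")
        if self.interpolation not in ("linear", "step"):
            raise ParameterError(f"unknown interpolation {self.interpolation!r}")

    def __call__(self, age):
        ages = np.array([a for a, _ in self.anchors])
        vals = np.array([v for _, v in self.anchors])
        if self.interpolation == "linear":
            return np.interp(age, ages, vals)
        idx = np.clip(np.searchsorted(ages, age, side="right") - 1, 0, len(ages) - 1)
        out = vals[idx]
        return out.item() if np.ndim(age) == 0 else out


def schedule_value(schedule: AgeSchedule, age) -> float:
    """Evaluate an :class:`AgeSchedule` at ``age`` (clamped outside anchors)."""
    if np.any(np.asarray(age) < 0):
        raise ParameterError("age must be non-negative")
    return schedule(age)


def _default_incidence() -> AgeSchedule:
    # published range 0.0008-0.007/yr, minimum at the starting age, maximum at
    # 30 where endometriosis incidence peaks, clamped after
    return AgeSchedule(((12, 0.0008), (30, 0.007)))


def _default_visit_prop_dys() -> AgeSchedule:
    return AgeSchedule(((12, 0.03), (30, 0.5)))


def _default_visit_prop_endo() -> AgeSchedule:
    return AgeSchedule(((12, 0.0124), (30, 0.0307)))


def _default_mortality() -> AgeSchedule:
    lt = make_life_table(0, 60)
    return AgeSchedule(tuple(zip(lt.ages, lt.qx)))


@dataclass(frozen=True)
class ModelParameters:
    """Epidemiological, effect and utility parameters, by strategy.

    ``p_cure_*`` are annual cure probabilities under guideline-based
    intervention; ``p_selfcare_remission_*`` are spontaneous annual remission
    probabilities under self-care (calibrated, not published).
    """

    start_age: int = 12
    horizon: int = 23
    discount_rate: float = 0.03

    incidence_dysmenorrhea: AgeSchedule = field(default_factory=_default_incidence)
    p_progress_dys_to_endo12: float = 0.184
    p_recurrence: float = 0.222
    p_surgery_endo: float = 0.06
    prop_otc_selfcare: float = 0.871

    # intervention-arm cure probabilities (tornado ranges centre on these)
    p_cure_dys: float = 0.80
    p_cure_endo12: float = 0.40
    p_cure_endo34: float = 0.80

    # self-care remission + base severe-progression: calibrated defaults
    p_selfcare_remission_dys: float = 0.02
    p_selfcare_remission_endo12: float = 0.65
    p_selfcare_remission_endo34: float = 0.40
    p_progress_endo12_to_34: float = 0.08

    # treatment effects on the hazard scale
    or_develop_endo12: float = 0.40
    or_progress_endo34: float = 0.10

    visit_prop_dys: AgeSchedule = field(default_factory=_default_visit_prop_dys)
    visit_prop_endo: AgeSchedule = field(default_factory=_default_visit_prop_endo)
    mortality: AgeSchedule = field(default_factory=_default_mortality)

    u_well: float = 1.0
    u_dys: float = 0.637
    u_endo12: float = 0.637
    u_endo34: float = 0.549
    u_cured: float = 1.0

    # structural switches
    start_state: str = "DYSMENORRHEA"
    maintenance_visits_per_year: float = 2.0
    recurrence_managed_under_intervention: bool = True
    surgery_cures: bool = True
    half_cycle_correction: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        probs = {
            "p_progress_dys_to_endo12": self.p_progress_dys_to_endo12,
            "p_recurrence": self.p_recurrence,
            "p_surgery_endo": self.p_surgery_endo,
            "prop_otc_selfcare": self.prop_otc_selfcare,
            "p_cure_dys": self.p_cure_dys,
            "p_cure_endo12": self.p_cure_endo12,
            "p_cure_endo34": self.p_cure_endo34,
            "p_selfcare_remission_dys": self.p_selfcare_remission_dys,
            "p_selfcare_remission_endo12": self.p_selfcare_remission_endo12,
            "p_selfcare_remission_endo34": self.p_selfcare_remission_endo34,
            "p_progress_endo12_to_34": self.p_progress_endo12_to_34,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in ("u_well", "u_dys", "u_endo12", "u_endo34", "u_cured"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.or_develop_endo12 <= 0 or self.or_progress_endo34 <= 0:
            raise ParameterError("odds ratios must be positive")
        if self.horizon < 1:
            raise ParameterError(f"horizon={self.horizon} must be >= 1")
        if self.discount_rate < 0:
            raise ParameterError("discount rate must be non-negative")
        if self.maintenance_visits_per_year < 0:
            raise ParameterError("maintenance visit frequency must be non-negative")
        if self.start_state not in ("WELL", "DYSMENORRHEA"):
            raise ParameterError(f"unsupported start_state {self.start_state!r}")


@dataclass(frozen=True)
class CostParameters:
    """Unit costs (JPY) and resource-use frequencies, split by perspective.

    Payer perspective uses visit, inpatient and surgery costs only; the
    societal perspective adds OTC/self-medication spending and productivity
    losses (printed per half-year, accrued twice per symptomatic year).
    Currency is JPY throughout; ``jpy_per_usd`` is display-only.
    """

    visit_cost_dys: float = 7_529.0
    visit_cost_endo: float = 11_291.0
    visits_per_year: float = 4.0
    inpatient_cost_annual: float = 207_661.0
    surgery_cost_mild: float = 288_080.0
    surgery_cost_complex: float = 456_667.0
    prop_complex: float = 0.452
    otc_cost_annual: float = 19_243.0
    selfmed_cost_annual: float = 13_715.0
    productivity_loss_halfyear_selfcare: float = 184_625.0
    productivity_loss_halfyear_intervention: float = 39_546.0
    jpy_per_usd: float = 120.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "prop_complex":
                if not 0.0 <= v <= 1.0:
                    raise ParameterError(f"prop_complex={v} outside [0, 1]")
            elif v < 0:
                raise ParameterError(f"{f.name}={v} must be non-negative")

    @property
    def mean_surgery_cost(self) -> float:
        return (
            self.prop_complex * self.surgery_cost_complex
            + (1.0 - self.prop_complex) * self.surgery_cost_mild
        )


#: parameters whose base values come from calibration, not a published source
CALIBRATABLE = (
    "p_selfcare_remission_dys",
    "p_selfcare_remission_endo12",
    "p_selfcare_remission_endo34",
    "p_progress_endo12_to_34",
)


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of one parameter for probabilistic analysis.

    ``family`` follows the published distribution assignments (beta for
    binomial-scale rates, lognormal for ratio-scale quantities, normal for
    interval-scale ones).  Dispersion is given either as an explicit ``(low,
    high)`` central 95% interval or as a coefficient of variation ``cv``
    about ``central``.  ``domain`` clips samples to the parameter's support.
    """

    family: str
    central: float
    low: float | None = None
    high: float | None = None
    cv: float | None = None
    domain: tuple = (0.0, np.inf)

    def __post_init__(self):
        if self.family not in ("beta", "normal", "lognormal", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family != "fixed" and self.low is None and self.cv is None:
            raise ParameterError("need a (low, high) interval or a cv")

    @property
    def sd(self) -> float:
        """Standard deviation on the natural scale implied by the dispersion."""
        if self.family == "fixed":
            return 0.0
        if self.family == "lognormal":
            s = self.log_sigma
            mean = self.central * np.exp(s**2 / 2)
            return float(mean * np.sqrt(np.expm1(s**2)))
        if self.low is not None:
            return float((self.high - self.low) / (2 * 1.959963984540054))
        return float(self.cv * self.central)

    @property
    def log_sigma(self) -> float:
        """Log-scale SD for the lognormal family."""
        if self.low is not None:
            return float(np.log(self.high / self.low) / (2 * 1.959963984540054))
        return float(np.sqrt(np.log1p(self.cv**2)))

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution, clipped to ``domain``."""
        lo, hi = self.domain
        if self.family == "fixed":
            out = np.full(size, self.central) if size else self.central
            return out
        if self.family == "beta":
            m = self.central
            v = self.sd**2
            if v <= 0 or v >= m * (1 - m):
                raise ParameterError(f"beta moments unmatchable: mean={m}, var={v}")
            k = m * (1 - m) / v - 1.0
            draw = rng.beta(m * k, (1 - m) * k, size=size)
        elif self.family == "normal":
            draw = rng.normal(self.central, self.sd, size=size)
        else:  # lognormal, median at the base-case value
            draw = rng.lognormal(np.log(self.central), self.log_sigma, size=size)
        return np.clip(draw, lo, hi)


def default_distributions() -> dict:
    """The published distribution assignment for every input parameter that
    carries one, with dispersions per the documented convention: a printed
    (low, high) sensitivity range is read as a central 95% interval; otherwise
    a coefficient of variation of 0.2 about the base value is assumed.
    """
    prob = (0.0, 1.0)
    pos = (0.0, np.inf)
    util = (0.0, 1.0)
    return {
        "p_progress_dys_to_endo12": DistributionSpec("beta", 0.184, 0.179, 0.189, domain=prob),
        "p_recurrence": DistributionSpec("beta", 0.222, 0.206, 0.239, domain=prob),
        "p_surgery_endo": DistributionSpec("normal", 0.06, cv=0.2, domain=prob),
        "prop_otc_selfcare": DistributionSpec("normal", 0.871, cv=0.2, domain=prob),
        "or_develop_endo12": DistributionSpec("lognormal", 0.40, 0.2, 0.7, domain=pos),
        # reciprocal of the published OR 10.00 (95% CI 3.21-31.17)
        "or_progress_endo34": DistributionSpec("lognormal", 0.10, 1 / 31.17, 1 / 3.21, domain=pos),
        "u_dys": DistributionSpec("lognormal", 0.637, 0.630, 0.644, domain=util),
        "u_endo12": DistributionSpec("lognormal", 0.637, 0.630, 0.644, domain=util),
        # the printed lower endpoint 0.15 is an explicit external worst case,
        # not a confidence bound; mirror the upper half-width instead
        "u_endo34": DistributionSpec("lognormal", 0.549, 0.541, 0.557, domain=util),
        "visit_cost_dys": DistributionSpec("lognormal", 7_529.0, cv=0.2, domain=pos),
        "visit_cost_endo": DistributionSpec("lognormal", 11_291.0, cv=0.2, domain=pos),
        "inpatient_cost_annual": DistributionSpec("lognormal", 207_661.0, cv=0.2, domain=pos),
        "surgery_cost_mild": DistributionSpec("lognormal", 288_080.0, cv=0.2, domain=pos),
        "surgery_cost_complex": DistributionSpec("lognormal", 456_667.0, cv=0.2, domain=pos),
        "prop_complex": DistributionSpec("lognormal", 0.452, cv=0.2, domain=prob),
        "otc_cost_annual": DistributionSpec("lognormal", 19_243.0, cv=0.2, domain=pos),
        "selfmed_cost_annual": DistributionSpec("lognormal", 13_715.0, cv=0.2, domain=pos),
        "productivity_loss_halfyear_selfcare": DistributionSpec("lognormal", 184_625.0, cv=0.2, domain=pos),
        "productivity_loss_halfyear_intervention": DistributionSpec("lognormal", 39_546.0, cv=0.2, domain=pos),
    }


def base_case_parameters():
    """The published base case.

    Returns
    -------
    (ModelParameters, CostParameters, dict[str, DistributionSpec])
    """
    return ModelParameters(), CostParameters(), default_distributions()


# --------------------------------------------------------------------------
# configuration file IO
# --------------------------------------------------------------------------

_SCHEDULE_FIELDS = {"incidence_dysmenorrhea", "visit_prop_dys", "visit_prop_endo", "mortality"}


def _schedule_to_dict(s: AgeSchedule) -> dict:
    return {"anchors": [[a, v] for a, v in s.anchors], "interpolation": s.interpolation}


def _schedule_from_dict(name: str, d) -> AgeSchedule:
    if not isinstance(d, dict) or "anchors" not in d:
        raise ConfigError(f"{name}: expected a mapping with an 'anchors' list")
    try:
        return AgeSchedule(
            tuple((a, v) for a, v in d["anchors"]),
            d.get("interpolation", "linear"),
        )
    except (TypeError, ParameterError) as e:
        raise ConfigError(f"{name}: {e}") from e


def save_parameters(path, mp: ModelParameters, cp: CostParameters, run: dict | None = None) -> None:
    """Write a full parameter configuration as YAML (sections model/costs/run)."""
    model = {}
    for f in dataclasses.fields(mp):
        v = getattr(mp, f.name)
        model[f.name] = _schedule_to_dict(v) if isinstance(v, AgeSchedule) else v
    costs = {f.name: getattr(cp, f.name) for f in dataclasses.fields(cp)}
    doc = {"model": model, "costs": costs}
    if run:
        doc["run"] = dict(run)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def _build_section(cls, section_name: str, overrides: dict, defaults):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section_name}': {', '.join(sorted(unknown))}")
    missing = known - set(overrides)
    if overrides and missing:
        log.warning(
            "config section '%s': %d key(s) not given, using base-case values (%s)",
            section_name,
            len(missing),
            ", ".join(sorted(missing)[:5]) + ("..." if len(missing) > 5 else ""),
        )
    kwargs = {}
    for name, value in overrides.items():
        if name in _SCHEDULE_FIELDS and not isinstance(value, AgeSchedule):
            value = _schedule_from_dict(name, value)
        kwargs[name] = value
    try:
        return replace(defaults, **kwargs)
    except (ParameterError, TypeError) as e:
        raise ConfigError(f"section '{section_name}': {e}") from e


def load_config(path):
    """Parse a YAML configuration; returns (ModelParameters, CostParameters, run dict)."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse {path}: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(doc) - {"model", "costs", "distributions", "run"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(sorted(unknown))}")
    mp = _build_section(ModelParameters, "model", doc.get("model") or {}, ModelParameters())
    cp = _build_section(CostParameters, "costs", doc.get("costs") or {}, CostParameters())
    run = doc.get("run") or {}
    if not isinstance(run, dict):
        raise ConfigError("'run' section must be a mapping")
    return mp, cp, run


def load_parameters(path):
    """Load (ModelParameters, CostParameters) from a YAML configuration file.

    Unknown keys are rejected with the offending name; missing keys fall back
    to the base case with a logged warning; out-of-domain values raise
    :class:`ConfigError`.
    """
    mp, cp, _ = load_config(path)
    return mp, cp
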
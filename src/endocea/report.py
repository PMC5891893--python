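"""Report artifacts: per-arm base-case summaries, calibration results,
tornado and PSA exports, and run manifests.

Every report function writes machine-readable CSV/JSON (unrounded) plus, for
the sensitivity analyses, a static PNG figure, and returns the in-memory
result.  A ``RunManifest`` accompanies each run: it records a digest of the
exact configuration, the seed and the produced files, so reruns are
attributable and identical configurations yield identical digests.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import __version__
from .calibration import calibrate, default_bounds, default_targets, targets_to_csv
from .cohort import Strategy, cumulative_endometriosis, run_cohort
from .economics import DEFAULT_WTP, run_base_case
from .parameters import CostParameters, ModelParameters, save_parameters
from .sensitivity import (
    DEFAULT_SEED,
    PAYER_TORNADO_RANGES,
    SOCIETAL_TORNADO_RANGES,
    ceac,
    psa_summary,
    run_psa,
    tornado,
    tornado_frame,
)
from .synthetic import make_life_table, make_population, simulate_vas_survey

__all__ = [
    "RunManifest",
    "config_digest",
    "base_case_report",
    "calibrate_report",
    "psa_report",
    "tornado_report",
    "fixtures_report",
]


def config_digest(mp: ModelParameters, cp: CostParameters) -> str:
    """Stable SHA-256 digest of the full parameter configuration."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [encode(x) for x in obj]
        return obj

    blob = yaml.safe_dump({"model": encode(mp), "costs": encode(cp)}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    command: str
    digest: str
    seed: int | None = None
    version: str = __version__
    timestamp: str = ""
    outputs: list = field(default_factory=list)

    def add(self, path) -> Path:
        self.outputs.append(str(path))
        return Path(path)

    def write(self, out_dir) -> Path:
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path = Path(out_dir) / f"manifest_{self.command.replace('-', '_')}.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def _mkdir(out_dir) -> Path:
    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _econ_dict(res) -> dict:
    return {
        "expected_cost_payer_jpy": res.cost_payer,
        "expected_cost_societal_jpy": res.cost_societal,
        "expected_effectiveness_qalys": res.qalys,
        "cost_nonmedical_jpy": res.cost_nonmedical,
        "cost_opportunity_jpy": res.cost_opportunity,
        "undiscounted_cost_payer_jpy": res.cost_payer_undiscounted,
        "undiscounted_qalys": res.qalys_undiscounted,
    }


def base_case_report(mp, cp, out_dir, wtp: float = DEFAULT_WTP) -> dict:
    """Two-arm base case: per-arm expected cost/QALYs (both perspectives),
    incremental row, ICER, SMV and the cost-effectiveness verdict."""
    out_dir = _mkdir(out_dir)
    manifest = RunManifest("base-case", config_digest(mp, cp))
    out = run_base_case(mp, cp, wtp)
    ce = out["ce"]
    tr_int = out["traces"][Strategy.INTERVENTION]
    tr_sc = out["traces"][Strategy.SELF_CARE]

    reduction = 100.0 * (1.0 - cumulative_endometriosis(tr_int) / cumulative_endometriosis(tr_sc))
    doc = {
        "intervention": _econ_dict(out["intervention"]),
        "self_care": _econ_dict(out["self_care"]),
        "incremental": {
            "cost_payer_jpy": ce.inc_cost,
            "effect_qalys": ce.inc_effect,
            "icer_jpy_per_qaly": ce.icer,
            "icer_usd_per_qaly": ce.icer_usd(cp.jpy_per_usd),
        },
        "societal": {
            "smv_jpy": ce.smv,
            "opportunity_cost_saved_jpy": ce.opportunity_saved,
            "full_direct_cost_consumed_jpy": ce.direct_cost_consumed,
        },
        "wtp_jpy_per_qaly": wtp,
        "cost_effective": ce.cost_effective,
        "endometriosis_reduction_pct": reduction,
    }
    manifest.add(out_dir / "base_case.json").write_text(json.dumps(doc, indent=2) + "\n")
    for strategy, trace in ((Strategy.INTERVENTION, tr_int), (Strategy.SELF_CARE, tr_sc)):
        p = manifest.add(out_dir / f"trace_{strategy.value}.csv")
        trace.to_frame().to_csv(p, index=False)
    manifest.write(out_dir)
    return {"report": doc, **out}


def calibrate_report(mp, cp, pop=None, targets=None, bounds=None, out_dir="results", seed: int = 0):
    """Calibrate the unpublished self-care parameters and write the fit."""
    out_dir = _mkdir(out_dir)
    pop = pop if pop is not None else make_population()
    targets = targets if targets is not None else default_targets()
    bounds = bounds if bounds is not None else default_bounds()
    manifest = RunManifest("calibrate", config_digest(mp, cp), seed)
    result = calibrate(targets, bounds, mp, cp, pop, seed=seed)
    doc = {
        "fitted": result.fitted,
        "objective": result.objective,
        "converged": result.converged,
        "n_evaluations": result.n_evaluations,
    }
    manifest.add(out_dir / "calibration.json").write_text(json.dumps(doc, indent=2) + "\n")
    result.residuals.to_csv(manifest.add(out_dir / "calibration_residuals.csv"), index=False)
    mp_fit = dataclasses.replace(mp, **result.fitted)
    save_parameters(manifest.add(out_dir / "calibrated_parameters.yaml"), mp_fit, cp)
    manifest.write(out_dir)
    return result


def psa_report(mp, cp, dists, n: int = 10_000, seed: int = DEFAULT_SEED, out_dir="results",
               wtp: float = DEFAULT_WTP):
    """Probabilistic sensitivity analysis: draws, CEAC, summary, figure."""
    out_dir = _mkdir(out_dir)
    manifest = RunManifest("psa", config_digest(mp, cp), seed)
    psa = run_psa(mp, cp, dists, n=n, seed=seed, wtp=wtp)
    curve = ceac(psa)
    summary = psa_summary(psa)

    psa.draws.to_csv(manifest.add(out_dir / "psa_draws.csv"), index=False)
    curve.to_frame().to_csv(manifest.add(out_dir / "ceac.csv"), index=False)
    manifest.add(out_dir / "psa_summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n"
    )

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp_grid / 1e6, curve.acceptance)
    ax.set_xlabel("willingness to pay (million JPY per QALY)")
    ax.set_ylabel("probability intervention is cost-effective")
    ax.set_ylim(0, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(manifest.add(out_dir / "ceac.png"), dpi=150)
    plt.close(fig)
    manifest.write(out_dir)
    return psa, curve, summary


def tornado_report(mp, cp, out_dir="results", wtp: float = DEFAULT_WTP,
                   payer_ranges=None, societal_ranges=None):
    """Payer (ICER) and societal (SMV) tornado diagrams, CSV + PNG."""
    out_dir = _mkdir(out_dir)
    manifest = RunManifest("tornado", config_digest(mp, cp))
    results = {}
    for label, outcome, ranges in (
        ("payer", "icer", payer_ranges if payer_ranges is not None else PAYER_TORNADO_RANGES),
        ("societal", "smv", societal_ranges if societal_ranges is not None else SOCIETAL_TORNADO_RANGES),
    ):
        entries = tornado(mp, cp, ranges, outcome=outcome, wtp=wtp) if ranges else []
        df = tornado_frame(entries)
        df.to_csv(manifest.add(out_dir / f"tornado_{label}.csv"), index=False)
        results[label] = entries
        if entries:
            fig, ax = plt.subplots(figsize=(7, 0.5 * len(entries) + 1.5))
            base = entries[0].outcome_base
            names = [e.parameter for e in entries][::-1]
            lows = np.array([min(e.outcome_low, e.outcome_high) for e in entries])[::-1]
            highs = np.array([max(e.outcome_low, e.outcome_high) for e in entries])[::-1]
            ax.barh(names, highs - lows, left=lows, color="#4878b0")
            ax.axvline(base, color="k", lw=1)
            ax.set_xlabel({"icer": "ICER (JPY per QALY)", "smv": "SMV (JPY)"}[outcome])
            ax.set_title(f"One-way sensitivity ({label} perspective)")
            fig.tight_layout()
            fig.savefig(manifest.add(out_dir / f"tornado_{label}.png"), dpi=150)
            plt.close(fig)
    manifest.write(out_dir)
    return results


def fixtures_report(out_dir="results/fixtures", seed: int = 0) -> dict:
    """Write every synthetic fixture as CSV with the documented schema."""
    out_dir = _mkdir(out_dir)
    mp, cp = ModelParameters(), CostParameters()
    manifest = RunManifest("fixtures", config_digest(mp, cp), seed)
    lt = make_life_table(0, 60)
    pop = make_population()
    survey, means = simulate_vas_survey(seed=seed)
    lt.to_frame().to_csv(manifest.add(out_dir / "life_table.csv"), index=False)
    pop.to_frame().to_csv(manifest.add(out_dir / "population.csv"), index=False)
    survey.to_csv(manifest.add(out_dir / "vas_survey.csv"), index=False)
    targets_to_csv(default_targets(), manifest.add(out_dir / "calibration_targets.csv"))
    manifest.add(out_dir / "vas_survey_means.json").write_text(
        json.dumps(means, indent=2) + "\n"
    )
    manifest.write(out_dir)
    return {"life_table": lt, "population": pop, "vas_means": means}
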
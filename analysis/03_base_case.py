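#!/usr/bin/env python
"""Base-case cost-effectiveness and cost-benefit evaluation.

Runs both strategy arms of the calibrated Markov cohort (girls aged 12 with
dysmenorrhea, followed 23 yearly cycles to age 35, 3% discounting) and
reports the published-style comparison: expected payer cost and QALYs per arm,
the incremental row with the ICER against the 5 million JPY/QALY
willingness-to-pay threshold, the societal totals with the societal monetary
value (SMV), and the relative reduction in cumulative endometriosis onset.
"""

import argparse

from endocea.cohort import Strategy, prevalence_counts
from endocea.parameters import base_case_parameters, load_parameters
from endocea.report import base_case_report
from endocea.synthetic import make_population


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default=None,
                        help="parameter YAML (e.g. results/calibrated_parameters.yaml)")
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    if args.config:
        mp, cp = load_parameters(args.config)
    else:
        mp, cp, _ = base_case_parameters()
    out = base_case_report(mp, cp, args.out_dir)
    rep = out["report"]

    print(f"{'arm':14s} {'payer cost (JPY)':>18s} {'QALYs':>7s} {'societal (JPY)':>16s}")
    for key, label in (("intervention", "intervention"), ("self_care", "self-care")):
        r = rep[key]
        print(f"{label:14s} {r['expected_cost_payer_jpy']:>18,.0f} "
              f"{r['expected_effectiveness_qalys']:>7.1f} "
              f"{r['expected_cost_societal_jpy']:>16,.0f}")
    inc = rep["incremental"]
    print(f"{'incremental':14s} {inc['cost_payer_jpy']:>18,.0f} {inc['effect_qalys']:>7.1f}")
    print(f"ICER: {inc['icer_jpy_per_qaly']:,.0f} JPY/QALY "
          f"(~${inc['icer_usd_per_qaly']:,.0f}/QALY); "
          f"cost-effective at 5M JPY WTP: {rep['cost_effective']}")
    print(f"SMV: {rep['societal']['smv_jpy']:+,.0f} JPY (positive favours intervention)")
    print(f"cumulative endometriosis onset reduced by "
          f"{rep['endometriosis_reduction_pct']:.1f}% under intervention")

    pop = make_population()
    _, total = prevalence_counts(out["traces"][Strategy.SELF_CARE], pop)
    print(f"implied national endometriosis caseload (self-care): {total:,.0f} cases")


if __name__ == "__main__":
    main()
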
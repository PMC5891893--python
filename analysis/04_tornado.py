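#!/usr/bin/env python
"""One-way deterministic sensitivity analysis (tornado diagrams).

Re-runs the full pipeline at the low and high end of each published
sensitivity range: ten payer-perspective parameters on the ICER and seven
societal-perspective parameters on the SMV.  The robustness claim of the
base case holds if every ICER endpoint stays below the 5 million JPY/QALY
threshold and no SMV endpoint changes sign.
"""

import argparse

from endocea.parameters import base_case_parameters, load_parameters
from endocea.report import tornado_report


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--config", default=None)
    parser.add_argument("--out-dir", default="results")
    args = parser.parse_args()

    if args.config:
        mp, cp = load_parameters(args.config)
    else:
        mp, cp, _ = base_case_parameters()
    results = tornado_report(mp, cp, out_dir=args.out_dir)

    for label, entries in results.items():
        outcome = entries[0].outcome if entries else "?"
        print(f"\n{label} perspective ({outcome}), widest bar first:")
        for e in entries:
            print(f"  {e.parameter:28s} [{e.low:>9.3f}, {e.high:>9.3f}] -> "
                  f"[{e.outcome_low:>13,.0f}, {e.outcome_high:>13,.0f}]  spread {e.spread:,.0f}")

    icer_entries = results["payer"]
    robust = all(max(e.outcome_low, e.outcome_high) < 5_000_000 for e in icer_entries)
    print(f"\nall payer ICER endpoints below the 5M JPY/QALY threshold: {robust}")
    positive = all(min(e.outcome_low, e.outcome_high) > 0 for e in results["societal"])
    print(f"all societal SMV endpoints remain positive: {positive}")


if __name__ == "__main__":
    main()
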
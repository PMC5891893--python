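#!/usr/bin/env python
"""Generate the synthetic external inputs the analysis depends on.

The decision model needs three inputs that exist only as national statistics
or institutional surveys, none of them published as tables: a young-female
life table, a population denominator for prevalence scaling (~1.6 million
women with functional dysmenorrhea), and a VAS utility survey whose stage
means (0.637 mild, 0.549 severe) enter the model as utilities.  This script
writes all of them, plus the calibration target file, as CSV under
results/fixtures/ so every later stage runs offline and reproducibly.
"""

import argparse

from endocea.report import fixtures_report


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", default="results/fixtures")
    args = parser.parse_args()

    out = fixtures_report(args.out_dir, seed=args.seed)
    lt, pop = out["life_table"], out["population"]
    print(f"life table: annual mortality {min(lt.qx):.2e}..{max(lt.qx):.2e} "
          f"over ages {lt.ages[0]}-{lt.ages[-1]}")
    print(f"population: {pop.total:,.0f} women across ages {pop.ages[0]}-{pop.ages[-1]}")
    print("VAS survey stage means:",
          ", ".join(f"{k}={v:.3f}" for k, v in out["vas_means"].items()))
    print(f"fixtures written to {args.out_dir}/")


if __name__ == "__main__":
    main()
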
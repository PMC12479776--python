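"""One-off calibration of the synthetic-cohort link coefficients.

Simulates a large cohort under candidate LinkSpec internals and prints
the realized raw-scale associations next to their targets.  The frozen
defaults in ``effortmet.synthetic_cohort.LinkSpec`` were chosen with
this script; rerun it after any change to the generator to re-check.

Usage: python scripts/calibrate_cohort.py [--n 4000] [--seed 0]
       [--a-asp-kem X] [--a-glu2-kem X] [--a-asp-klm X]
"""

import argparse

from effortmet.synthetic_cohort import LinkSpec, emulation_check, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=4000)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--a-asp-kem", type=float, default=None)
    ap.add_argument("--a-glu2-kem", type=float, default=None)
    ap.add_argument("--a-asp-klm", type=float, default=None)
    args = ap.parse_args()

    links = LinkSpec()
    for attr in ("a_asp_kem", "a_glu2_kem", "a_asp_klm"):
        val = getattr(args, attr)
        if val is not None:
            setattr(links, attr, val)

    cohort = generate_cohort(args.n, links=links, seed=args.seed)
    report = emulation_check(cohort, links, tol=3.0)
    print(report.to_string(index=False, float_format=lambda v: f"{v: .4f}"))


if __name__ == "__main__":
    main()
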
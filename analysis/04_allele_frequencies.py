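#!/usr/bin/env python
"""Invert phenotypic fractions to dominant-model risk-allele frequencies.

From the fitted FH+ upper-mode fraction and the 8th-decile relative risk:
alpha_FH- = alpha_FH+ / RR_8, q = 1 - sqrt(1 - alpha) per group, and the
spouse-pool relation q_T2DM = 2 q_FH+ - q_FH- for the unobserved affected
relatives.  Includes the population-obesity sensitivity substitution and the
T2DM risk bounds.  Writes results/allele_estimates.json.
"""

import json
from pathlib import Path

from adiposeg.hwe import (
    allele_estimates,
    sensitivity_substitute_alpha,
    t2dm_risk_bounds,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

#: Obesity prevalence in the wider population (sensitivity substitution for
#: the in-sample FH- upper-mode fraction).
POPULATION_OBESITY = 0.28


def main() -> None:
    seg = json.loads((RESULTS / "segregation.json").read_text())
    alpha_plus = seg["bimodal_fit"]["alpha"]
    rr_8 = seg["decile_profile"]["rr"][7]

    est = allele_estimates(alpha_plus, rr_8)
    sens = sensitivity_substitute_alpha(POPULATION_OBESITY, est)
    risk_lo, risk_hi = t2dm_risk_bounds(est.alpha_fh_plus)

    out = {
        "inputs": {"alpha_fh_plus": alpha_plus, "rr_8": rr_8},
        "estimates": est.to_dict(),
        "sensitivity_population_obesity": sens.to_dict(),
        "t2dm_risk_bounds": {"independent": risk_lo, "pleiotropic": risk_hi},
    }
    (RESULTS / "allele_estimates.json").write_text(json.dumps(out, indent=2) + "\n")

    print(f"inputs: alpha_FH+ = {alpha_plus:.2f}, RR_8 = {rr_8:.2f}")
    for grp in ("FH-", "FH+", "T2DM"):
        a = est.to_dict()["alpha"][grp]
        q = est.to_dict()["q"][grp]
        print(f"  {grp:5s} alpha = {a:.2f}  q = {q:.2f}")
    print(f"sensitivity (alpha_FH- -> {POPULATION_OBESITY}): "
          f"alpha_T2DM {est.alpha_t2dm:.2f} -> {sens.alpha_t2dm:.2f}")
    print(f"T2DM risk in FH+: {risk_lo:.0%} (independent) to {risk_hi:.0%} (pleiotropic)")


if __name__ == "__main__":
    main()
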
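"""Reproduce the calibrated constants frozen in hetefx.synthetic_data.

The a1 preset's effect sizes are repository-derived: they are solved so that
the generator's *population* subgroup margins match a stated set of targets,
rather than transcribed from any external data-generating process.

Targets
-------
subgroup risk differences   : eGFR<73 -0.12 | eGFR>=73 +0.05 | aspirin=0 -0.21 | aspirin=1 +0.13
subgroup risk ratios        : 0.51 | 1.37 | 0.25 | 2.19   (fix the untreated-risk structure,
                              via r0 = RD / (RR - 1))
aspirin prevalence          : 0.5117
eGFR mean gap by aspirin use: 4.57 (the modifier correlation)
treated fraction            : 0.30 (solved per-draw by bisection, not frozen)

Run:  python scripts/calibrate_preset.py
"""

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

RD_TARGETS = {"egfr_low": -0.12, "egfr_high": 0.05, "aspirin0": -0.21, "aspirin1": 0.13}
RR_TARGETS = {"egfr_low": 0.51, "egfr_high": 1.37, "aspirin0": 0.25, "aspirin1": 2.19}
RD_OVERALL, RR_OVERALL = -0.03, 0.82
ASPIRIN_PREVALENCE = 0.5117
EGFR_GAP = 75.31 - 70.74  # between-cluster eGFR means


def main(n: int = 2_000_000, seed: int = 12345) -> dict:
    rng = np.random.default_rng(seed)
    z_e = rng.standard_normal(n)
    egfr = 73 + 10 * z_e
    u = rng.random(n)

    def gap(a1, a0=0.0):
        a = u < expit(a0 + a1 * z_e)
        return egfr[a].mean() - egfr[~a].mean()

    a1 = brentq(lambda v: gap(v) - EGFR_GAP, 0.1, 2.0, xtol=1e-4)
    a0 = brentq(lambda v: expit(v + a1 * z_e).mean() - ASPIRIN_PREVALENCE, -1, 1, xtol=1e-6)

    asp = (u < expit(a0 + a1 * z_e)).astype(float)
    high = (egfr >= 73).astype(float)
    p_a_h = [asp[high == h].mean() for h in (0, 1)]   # P(aspirin=1 | eGFR stratum)
    p_h_a = [high[asp == a].mean() for a in (0, 1)]   # P(eGFR>=73 | aspirin stratum)

    # untreated-risk structure r0 = b0 + ba*aspirin + bh*high: least squares on
    # the margins implied by the RD/RR target pairs
    m = {k: RD_TARGETS[k] / (RR_TARGETS[k] - 1) for k in RD_TARGETS}
    m["overall"] = RD_OVERALL / (RR_OVERALL - 1)
    A = np.array([
        [1, 0.0, p_h_a[0]],        # aspirin = 0
        [1, 1.0, p_h_a[1]],        # aspirin = 1
        [1, p_a_h[0], 0.0],        # eGFR < 73
        [1, p_a_h[1], 1.0],        # eGFR >= 73
        [1, asp.mean(), high.mean()],
    ])
    tgt = np.array([m["aspirin0"], m["aspirin1"], m["egfr_low"], m["egfr_high"], m["overall"]])
    b0, ba, bh = np.linalg.lstsq(A, tgt, rcond=None)[0]

    # additive cell effects d = c0 + ca*aspirin + ch*high: least squares on
    # the four RD margins
    M = np.array([
        [1, p_a_h[0], 0.0],
        [1, p_a_h[1], 1.0],
        [1, 0.0, p_h_a[0]],
        [1, 1.0, p_h_a[1]],
    ])
    rd = np.array([RD_TARGETS["egfr_low"], RD_TARGETS["egfr_high"],
                   RD_TARGETS["aspirin0"], RD_TARGETS["aspirin1"]])
    c0, ca, ch = np.linalg.lstsq(M, rd, rcond=None)[0]

    out = {
        "aspirin_intercept": round(a0, 5),
        "aspirin_egfr_slope": round(a1, 5),
        "baseline_risk": round(b0, 5),
        "risk_aspirin": round(ba, 5),
        "risk_egfr_high": round(bh, 5),
        "effect_base": round(c0, 5),
        "effect_aspirin": round(ca, 5),
        "effect_egfr_high": round(ch, 5),
    }

    # verification: realized clipped margins
    r0 = np.clip(b0 + ba * asp + bh * high, 0.001, 0.999)
    d = c0 + ca * asp + ch * high
    r1 = np.clip(r0 + d, 0.001, 0.999)
    rdv = r1 - r0
    check = {
        "rd_egfr_low": rdv[high == 0].mean(), "rd_egfr_high": rdv[high == 1].mean(),
        "rd_aspirin0": rdv[asp == 0].mean(), "rd_aspirin1": rdv[asp == 1].mean(),
        "rd_overall": rdv.mean(),
        "rr_overall": r1.mean() / r0.mean(),
    }
    return out, check


if __name__ == "__main__":
    constants, check = main()
    print("frozen constants:")
    for k, v in constants.items():
        print(f"  {k:>20s} = {v}")
    print("realized population margins:")
    for k, v in check.items():
        print(f"  {k:>20s} = {v:+.4f}")
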
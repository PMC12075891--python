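"""Synthetic observational cohorts with known heterogeneous treatment effects.

The generator emulates an observational blood-pressure-treatment cohort:
five baseline covariates (age, systolic blood pressure, sex, aspirin use,
and estimated glomerular filtration rate, eGFR), a binary treatment assigned
by a logistic model on the confounders (age, SBP, sex) with the intercept
calibrated by bisection to hit a target treated fraction, and a binary
outcome whose risk is additive in baseline covariates plus a treatment
effect that depends on two true effect modifiers: aspirin use and the eGFR
threshold 1{eGFR >= 73}.

Aspirin use depends mildly on eGFR (higher eGFR -> more likely user), so the
two modifiers are positively correlated, as in real cohorts where both track
vascular health.

Every row's true potential-outcome risks (and hence its true individual risk
difference) are emitted alongside the cohort, so downstream estimates can be
scored for bias and confidence-interval coverage exactly.

The default effect-size constants were calibrated once (see
scripts/calibrate_preset.py, which reproduces them): the cell effects and
baseline-risk structure solve for stated subgroup risk-difference and
risk-ratio margins, and the aspirin-eGFR dependence for a stated
between-cluster eGFR mean gap.  They are repository-derived constants, not
values transcribed from any external study.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .design import CohortTable

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "preset",
           "PRESETS", "simulation_roles"]


def simulation_roles() -> "VariableRoles":
    """Role declaration matching the generator: age, SBP and sex confound
    treatment assignment; every baseline covariate is a candidate modifier."""
    from .design import VariableRoles

    return VariableRoles(
        confounders=["age", "sbp", "sex"],
        candidate_modifiers=["age", "sbp", "sex", "aspirin", "egfr"],
    )


@dataclass
class SimulationConfig:
    n: int = 10_000
    seed: int = 0
    treated_fraction_target: float = 0.30

    # covariate distributions
    age_mean: float = 65.0
    age_sd: float = 8.0
    sbp_mean: float = 135.0
    sbp_sd: float = 15.0
    p_female: float = 0.5
    egfr_mean: float = 73.0
    egfr_sd: float = 10.0
    # aspirin ~ Bernoulli(expit(a0 + a1 * z_egfr)): the eGFR link induces the
    # modifier correlation
    aspirin_intercept: float = 0.04887
    aspirin_egfr_slope: float = 0.48169

    # treatment log-odds on standardized confounders (intercept bisected)
    treat_age: float = 0.40
    treat_sbp: float = 0.35
    treat_sex: float = 0.30

    # untreated risk: b0 + ba*aspirin + bh*1{eGFR>=cutoff} + confounder terms
    baseline_risk: float = 0.30684
    risk_aspirin: float = -0.15613
    risk_egfr_high: float = -0.08105
    risk_age: float = 0.04
    risk_sbp: float = 0.03
    risk_sex: float = 0.02

    # treatment effect on the risk scale per (aspirin, 1{eGFR>=cutoff}) cell:
    # d = c0 + ca*aspirin + ch*high
    effect_base: float = -0.25466
    effect_aspirin: float = 0.31956
    effect_egfr_high: float = 0.11122
    true_cutoff: float = 73.0

    homogeneous: bool = False  # null DGP: constant effect at the marginal mean
    risk_floor: float = 0.001

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError("n must be >= 100")
        if not 0 < self.treated_fraction_target < 1:
            raise ValueError("treated fraction target must lie in (0,1)")
        # central cell risks must be probabilities before clipping ever bites
        for a in (0, 1):
            for h in (0, 1):
                r0 = self.baseline_risk + self.risk_aspirin * a + self.risk_egfr_high * h
                d = self.effect_base + self.effect_aspirin * a + self.effect_egfr_high * h
                if not (0 <= r0 <= 1 and 0 <= r0 + d <= 1):
                    raise ValueError("configuration produces cell risks outside [0,1]")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class SimulatedCohort:
    table: CohortTable
    truth: pd.DataFrame  # per-row risk1, risk0, true_rd
    config: SimulationConfig

    def true_subgroup_rd(self, mask: np.ndarray | pd.Series) -> float:
        return float(self.truth.loc[np.asarray(mask, bool), "true_rd"].mean())


def _cell_effect(cfg: SimulationConfig, aspirin: np.ndarray, high: np.ndarray) -> np.ndarray:
    return cfg.effect_base + cfg.effect_aspirin * aspirin + cfg.effect_egfr_high * high


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort.  Deterministic given (config, seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    z_age = rng.standard_normal(n)
    z_sbp = rng.standard_normal(n)
    sex = (rng.random(n) < cfg.p_female).astype(float)
    z_egfr = rng.standard_normal(n)
    egfr = cfg.egfr_mean + cfg.egfr_sd * z_egfr
    aspirin = (rng.random(n) < expit(cfg.aspirin_intercept + cfg.aspirin_egfr_slope * z_egfr)).astype(float)
    high = (egfr >= cfg.true_cutoff).astype(float)

    lin = cfg.treat_age * z_age + cfg.treat_sbp * z_sbp + cfg.treat_sex * (sex - 0.5)
    t0 = brentq(lambda v: expit(v + lin).mean() - cfg.treated_fraction_target, -20, 20)
    x = (rng.random(n) < expit(t0 + lin)).astype(float)
    realized = x.mean()
    if abs(realized - cfg.treated_fraction_target) > 0.02:
        # the bisection calibrates the expected fraction exactly; at small n
        # the realized fraction can drift by sampling noise alone
        warnings.warn(
            f"realized treated fraction {realized:.3f} more than 0.02 from "
            f"target {cfg.treated_fraction_target:.2f} (sampling noise at n={n})"
        )

    r0 = (cfg.baseline_risk + cfg.risk_aspirin * aspirin + cfg.risk_egfr_high * high
          + cfg.risk_age * z_age + cfg.risk_sbp * z_sbp + cfg.risk_sex * (sex - 0.5))
    if cfg.homogeneous:
        # constant effect at the marginal mean of the heterogeneous cells
        p_a = expit(cfg.aspirin_intercept + cfg.aspirin_egfr_slope * z_egfr).mean()
        p_h = high.mean()
        d = np.full(n, cfg.effect_base + cfg.effect_aspirin * p_a + cfg.effect_egfr_high * p_h)
    else:
        d = _cell_effect(cfg, aspirin, high)
    r0 = np.clip(r0, cfg.risk_floor, 1 - cfg.risk_floor)
    r1 = np.clip(r0 + d, cfg.risk_floor, 1 - cfg.risk_floor)
    risk = np.where(x == 1, r1, r0)
    y = (rng.random(n) < risk).astype(float)

    df = pd.DataFrame(
        {
            "treatment": x,
            "y": y,
            "age": cfg.age_mean + cfg.age_sd * z_age,
            "sbp": cfg.sbp_mean + cfg.sbp_sd * z_sbp,
            "sex": sex,
            "aspirin": aspirin,
            "egfr": egfr,
        },
        index=pd.RangeIndex(n, name="id"),
    )
    truth = pd.DataFrame(
        {"risk1": r1, "risk0": r0, "true_rd": r1 - r0}, index=df.index
    )
    return SimulatedCohort(
        table=CohortTable(df, treatment="treatment", outcome="y"),
        truth=truth,
        config=cfg,
    )


# The three main presets share one data-generating process and differ only
# in n; "null" switches the homogeneous flag; "hrs_like" mimics a
# lower-incidence, majority-treated cohort structurally (report-format
# testing only — no claim of matching any real cohort's joint structure).
PRESETS = ("a1", "a2", "a3", "null", "hrs_like")


def preset(name: str, **overrides) -> SimulationConfig:
    if name == "a1":
        cfg = SimulationConfig(n=10_000)
    elif name == "a2":
        cfg = SimulationConfig(n=100_000)
    elif name == "a3":
        cfg = SimulationConfig(n=1_000)
    elif name == "null":
        cfg = SimulationConfig(n=10_000, homogeneous=True)
    elif name == "hrs_like":
        cfg = SimulationConfig(
            n=11_033,
            treated_fraction_target=0.59,
            baseline_risk=0.093,
            risk_aspirin=-0.02,
            risk_egfr_high=-0.01,
            effect_base=0.016,
            effect_aspirin=0.10,
            effect_egfr_high=0.02,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg
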
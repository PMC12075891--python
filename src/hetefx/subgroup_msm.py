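"""Subgroup treatment effects from a marginal structural model (MSM).

For each discovered modifier the cohort is split into two groups G (a
continuous modifier is binarized at its cluster-derived cut-off) and the
potential-outcome means in the four treatment x group cells are estimated
either by

* ``iptw``  — a saturated model {1, X, G, X.G} fitted with stabilized
  inverse-probability-of-treatment weights.  The standardized risks are the
  weighted cell means, so the risk difference (RD) and risk ratio (RR) come
  from one consistent set of risks; RD-scale inference uses the
  heteroskedasticity-robust (sandwich) covariance of the weighted linear
  model and RR-scale inference the same saturated model fitted as a weighted
  log-link Poisson (log-binomial attempted first) with robust covariance; or

* ``gcomp`` — an unweighted outcome model retaining confounder main effects,
  standardized within each group by recycled predictions, with bootstrap
  (percentile) confidence intervals.

The p-for-interaction is the Wald test of the X.G term: on the additive
scale it tests RD1 = RD0, on the relative scale log RR1 = log RR0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .design import CohortTable
from .penalized_outcome import WeightVector

__all__ = [
    "SubgroupEstimate",
    "binarize_modifier",
    "fit_msm",
    "subgroup_contrasts",
    "p_interaction",
    "bootstrap_inference",
]


@dataclass
class SubgroupEstimate:
    modifier: str
    label: str  # e.g. "egfr < 73.0" / "egfr >= 73.0" / "aspirin = 1"
    n: int
    proportion: float  # percent of the analysis sample
    rd: float
    rd_ci: tuple[float, float]
    rr: float
    rr_ci: tuple[float, float]
    p_interaction_rd: float | None
    p_interaction_rr: float | None
    estimator: str  # iptw | gcomp
    inference: str  # sandwich | bootstrap

    def __post_init__(self) -> None:
        for est, (lo, hi) in ((self.rd, self.rd_ci), (self.rr, self.rr_ci)):
            if np.isfinite(est) and np.isfinite(lo) and np.isfinite(hi):
                if not lo <= est <= hi:
                    raise ValueError("CI must bracket the point estimate")


def binarize_modifier(
    table: CohortTable, modifier: str, cutoff: float | None = None
) -> tuple[pd.Series, dict[int, str]]:
    """Group indicator for one modifier: 1{value >= cutoff} for a continuous
    modifier, identity for a binary one.  Returns (group, level labels)."""
    v = table.df[modifier]
    if table.is_binary(modifier):
        lo, hi = sorted(v.unique())
        group = (v == hi).astype(int)
        labels = {0: f"{modifier} = {lo:g}", 1: f"{modifier} = {hi:g}"}
    else:
        if cutoff is None:
            raise ValueError("cutoff required for a continuous modifier")
        if not v.min() <= cutoff <= v.max():
            raise ValueError("cutoff outside the observed range (empty subgroup)")
        group = (v >= cutoff).astype(int)
        labels = {0: f"{modifier} < {cutoff:.1f}", 1: f"{modifier} >= {cutoff:.1f}"}
    return group, labels


@dataclass
class MsmFit:
    """Fitted treatment x group MSM plus everything inference needs."""

    modifier: str
    labels: dict[int, str]
    estimator: str
    group: pd.Series
    table: CohortTable = field(repr=False)
    weights: np.ndarray | None = field(repr=False, default=None)
    rd_fit: object = field(repr=False, default=None)  # WLS results, params [1,X,G,XG]
    rr_fit: object = field(repr=False, default=None)  # log-link GLM results
    confounders: list[str] | None = None
    boot: dict | None = field(repr=False, default=None)  # bootstrap draws (gcomp)
    degenerate: bool = False


def _design_xg(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, g, x * g])


def _fit_rr_model(y, X, w):
    """Weighted log-link fit for the relative scale: log-binomial first,
    Poisson with robust SE as the standard fallback."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()),
                         var_weights=w).fit(cov_type="HC0", maxiter=200)
        if fit.converged and np.all(np.isfinite(fit.bse)):
            return fit
    except Exception:
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=sm.families.Poisson(),
                      var_weights=w).fit(cov_type="HC0")


def fit_msm(
    table: CohortTable,
    group: pd.Series,
    weights: WeightVector | None = None,
    estimator: str = "iptw",
    modifier: str = "",
    labels: dict[int, str] | None = None,
    confounders: list[str] | None = None,
) -> MsmFit:
    """Fit the saturated treatment x group model {1, X, G, X.G}."""
    if estimator not in ("iptw", "gcomp"):
        raise ValueError("estimator must be iptw or gcomp")
    x = table.df[table.treatment].to_numpy(float)
    g = group.to_numpy(float)
    y = table.df[table.outcome].to_numpy(float)
    labels = labels or {0: f"{modifier} = 0", 1: f"{modifier} = 1"}

    degenerate = len(np.unique(g)) < 2
    if degenerate:
        warnings.warn(f"group for {modifier!r} is constant; reporting the overall effect only")
        g = np.zeros_like(g)
    else:
        cells = {(int(a), int(b)) for a, b in zip(x, g)}
        if len(cells) < 4:
            raise ValueError(
                f"empty treatment x group cell for {modifier!r} (positivity violation); "
                "consider a coarser dichotomization"
            )

    if estimator == "iptw":
        if weights is None:
            raise ValueError("iptw estimator requires a WeightVector")
        w = weights.weights.loc[table.df.index].to_numpy()
    else:
        w = np.ones_like(y)

    X = _design_xg(x, g) if not degenerate else np.column_stack([np.ones_like(x), x])
    rd_fit = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    rr_fit = _fit_rr_model(y, X, w)
    return MsmFit(
        modifier=modifier, labels=labels, estimator=estimator,
        group=pd.Series(g, index=table.df.index),
        table=table, weights=w, rd_fit=rd_fit, rr_fit=rr_fit,
        confounders=confounders, degenerate=degenerate,
    )


def _rd_with_ci(fit, g: int, z: float = 1.959964) -> tuple[float, tuple[float, float]]:
    cvec = np.zeros(len(fit.params))
    cvec[1] = 1.0
    if g == 1 and len(cvec) == 4:
        cvec[3] = 1.0
    est = float(cvec @ fit.params)
    se = float(np.sqrt(cvec @ fit.cov_params() @ cvec))
    return est, (est - z * se, est + z * se)


def _rr_with_ci(fit, g: int, z: float = 1.959964) -> tuple[float, tuple[float, float]]:
    cvec = np.zeros(len(fit.params))
    cvec[1] = 1.0
    if g == 1 and len(cvec) == 4:
        cvec[3] = 1.0
    logrr = float(cvec @ fit.params)
    se = float(np.sqrt(cvec @ fit.cov_params() @ cvec))
    return float(np.exp(logrr)), (float(np.exp(logrr - z * se)), float(np.exp(logrr + z * se)))


def p_interaction(msm: MsmFit, scale: str = "RD") -> float:
    """Wald p-value for equality of the treatment effect across the two
    subgroups on the stated scale."""
    if msm.degenerate:
        raise ValueError("non-estimable: the group is constant")
    if msm.estimator == "gcomp":
        if msm.boot is None:
            raise ValueError("run bootstrap_inference before p_interaction under gcomp")
        key = "rd_diff" if scale.upper() == "RD" else "logrr_diff"
        draws = msm.boot[key]
        est, se = msm.boot[key + "_est"], draws.std(ddof=1)
        return float(2 * norm.sf(abs(est / se))) if se > 0 else 1.0
    fit = msm.rd_fit if scale.upper() == "RD" else msm.rr_fit
    return float(fit.pvalues[3])


def subgroup_contrasts(msm: MsmFit) -> list[SubgroupEstimate]:
    """One estimate per level of G.  Under iptw the risks are the weighted
    cell means of the saturated fit, so sign(RD) and sign(RR-1) agree."""
    if msm.estimator == "gcomp":
        return _gcomp_contrasts(msm)
    out = []
    n = len(msm.group)
    if msm.degenerate:
        rd, rd_ci = _rd_with_ci(msm.rd_fit, 0)
        rr, rr_ci = _rr_with_ci(msm.rr_fit, 0)
        return [SubgroupEstimate(msm.modifier, "overall (degenerate group)", n, 100.0,
                                 rd, rd_ci, rr, rr_ci, None, None, msm.estimator, "sandwich")]
    p_rd = p_interaction(msm, "RD")
    p_rr = p_interaction(msm, "RR")
    for g in (0, 1):
        n_g = int((msm.group == g).sum())
        rd, rd_ci = _rd_with_ci(msm.rd_fit, g)
        rr, rr_ci = _rr_with_ci(msm.rr_fit, g)
        out.append(SubgroupEstimate(
            modifier=msm.modifier, label=msm.labels[g], n=n_g,
            proportion=100.0 * n_g / n, rd=rd, rd_ci=rd_ci, rr=rr, rr_ci=rr_ci,
            p_interaction_rd=p_rd, p_interaction_rr=p_rr,
            estimator=msm.estimator, inference="sandwich",
        ))
    return out


# ---------------------------------------------------------------------------
# G-computation estimator with bootstrap inference
# ---------------------------------------------------------------------------

def _gcomp_risks(table: CohortTable, group: np.ndarray, confounders: list[str]):
    """Standardized risks by recycled predictions from a linear outcome model
    with confounder mains, within each group level."""
    x = table.df[table.treatment].to_numpy(float)
    y = table.df[table.outcome].to_numpy(float)
    C = table.df[confounders].to_numpy(float) if confounders else np.empty((len(y), 0))
    X = np.column_stack([np.ones_like(x), x, group, x * group, C])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    risks = {}
    for g in (0, 1):
        m = group == g
        if m.sum() == 0:
            raise ValueError("empty subgroup")
        for xv in (0, 1):
            Xc = X[m].copy()
            Xc[:, 1] = xv
            Xc[:, 3] = xv * g
            risks[(xv, g)] = float((Xc @ beta).mean())
    return risks


def bootstrap_inference(msm: MsmFit, B: int = 500, seed: int = 0) -> MsmFit:
    """Percentile bootstrap over rows for the gcomp estimator: resample,
    refit, collect subgroup risks.  Resamples with an empty treatment x group
    cell are skipped; more than 10% skipped is an error."""
    if msm.estimator != "gcomp":
        raise ValueError("bootstrap inference applies to the gcomp estimator")
    if B < 100:
        raise ValueError("B must be >= 100")
    table, confounders = msm.table, msm.confounders or []
    g_all = msm.group.to_numpy(int)
    point = _gcomp_risks(table, g_all, confounders)
    rng = np.random.default_rng(seed)
    n = table.n
    draws = {key: [] for key in ("rd0", "rd1", "rr0", "rr1", "rd_diff", "logrr_diff")}
    skipped = 0
    x = table.df[table.treatment].to_numpy(int)
    for _ in range(B):
        idx = rng.integers(0, n, n)
        gb, xb = g_all[idx], x[idx]
        if len({(a, b) for a, b in zip(xb, gb)}) < 4:
            skipped += 1
            continue
        sub = CohortTable(table.df.iloc[idx].reset_index(drop=True), table.treatment, table.outcome)
        r = _gcomp_risks(sub, gb, confounders)
        rd0, rd1 = r[(1, 0)] - r[(0, 0)], r[(1, 1)] - r[(0, 1)]
        draws["rd0"].append(rd0)
        draws["rd1"].append(rd1)
        draws["rd_diff"].append(rd1 - rd0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr0 = r[(1, 0)] / r[(0, 0)]
            rr1 = r[(1, 1)] / r[(0, 1)]
        draws["rr0"].append(rr0)
        draws["rr1"].append(rr1)
        draws["logrr_diff"].append(np.log(rr1) - np.log(rr0))
    if skipped > 0.1 * B:
        raise ValueError(f"{skipped}/{B} bootstrap resamples had empty cells")
    boot = {k: np.asarray(v) for k, v in draws.items()}
    boot["point"] = point
    boot["rd_diff_est"] = (point[(1, 1)] - point[(0, 1)]) - (point[(1, 0)] - point[(0, 0)])
    with np.errstate(divide="ignore", invalid="ignore"):
        boot["logrr_diff_est"] = float(
            np.log(point[(1, 1)] / point[(0, 1)]) - np.log(point[(1, 0)] / point[(0, 0)])
        )
    msm.boot = boot
    return msm


def _gcomp_contrasts(msm: MsmFit) -> list[SubgroupEstimate]:
    if msm.boot is None:
        raise ValueError("run bootstrap_inference first for the gcomp estimator")
    point, boot = msm.boot["point"], msm.boot
    n = len(msm.group)
    p_rd = p_interaction(msm, "RD")
    p_rr = p_interaction(msm, "RR")
    out = []
    for g in (0, 1):
        n_g = int((msm.group == g).sum())
        rd = point[(1, g)] - point[(0, g)]
        rd_ci = tuple(np.percentile(boot[f"rd{g}"], [2.5, 97.5]))
        denom = point[(0, g)]
        if denom <= 0:
            warnings.warn("zero or negative denominator risk: RR undefined")
            rr, rr_ci = np.nan, (np.nan, np.nan)
        else:
            rr = point[(1, g)] / denom
            rr_ci = tuple(np.percentile(boot[f"rr{g}"], [2.5, 97.5]))
        out.append(SubgroupEstimate(
            modifier=msm.modifier, label=msm.labels[g], n=n_g,
            proportion=100.0 * n_g / n, rd=rd, rd_ci=rd_ci, rr=rr, rr_ci=rr_ci,
            p_interaction_rd=p_rd, p_interaction_rr=p_rr,
            estimator="gcomp", inference="bootstrap",
        ))
    return out


def overall_effect(
    table: CohortTable,
    weights: WeightVector | None = None,
    estimator: str = "iptw",
) -> SubgroupEstimate:
    """The no-interaction MSM {1, X}: the marginal treatment effect row."""
    x = table.df[table.treatment].to_numpy(float)
    y = table.df[table.outcome].to_numpy(float)
    w = weights.weights.loc[table.df.index].to_numpy() if weights is not None else np.ones_like(y)
    X = np.column_stack([np.ones_like(x), x])
    rd_fit = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
    rr_fit = _fit_rr_model(y, X, w)
    rd, rd_ci = _rd_with_ci(rd_fit, 0)
    rr, rr_ci = _rr_with_ci(rr_fit, 0)
    return SubgroupEstimate(
        modifier="(overall)", label="overall", n=table.n, proportion=100.0,
        rd=rd, rd_ci=rd_ci, rr=rr, rr_ci=rr_ci,
        p_interaction_rd=None, p_interaction_rr=None,
        estimator=estimator, inference="sandwich",
    )
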
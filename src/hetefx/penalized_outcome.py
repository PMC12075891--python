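"""Regularized outcome model, post-double selection and stabilized IPTW.

The elastic-net loss minimized here, on the same scale the field usually
prints it, is

    L(b) = sum_i (y_i - b0 - sum_j b_j c_ij)^2
           + lambda * sum_j pf_j * [ alpha*|b_j| + (1-alpha)/2 * b_j^2 ]

for the gaussian family, with the residual sum of squares replaced by the
deviance (-2 log-likelihood) for the binomial family.  alpha=1 is the LASSO,
alpha -> 0 approaches ridge, lambda=0 is the ordinary unpenalized fit.

`pf_j` are per-term penalty factors: the intercept and the treatment main
effect are never penalized (pf=0) so the treatment effect cannot be selected
out of its own model.  No installed solver exposes per-term factors, so the
coordinate-descent solver lives here; sklearn and statsmodels serve as
cross-checks in the test-suite.

lambda="cv" selects lambda on a 100-point log grid from lambda_max (the
smallest value zeroing every penalized term) down to 1e-4*lambda_max by
K-fold cross-validation with deterministic folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import numba
import statsmodels.api as sm
from scipy.special import expit

from .design import CohortTable, DesignMatrix, VariableRoles

__all__ = [
    "PenaltySpec",
    "FittedOutcomeModel",
    "WeightVector",
    "penalty_loss",
    "fit_penalized",
    "post_double_select",
    "fit_iptw",
]

_EPS_MU = 1e-9


@dataclass
class PenaltySpec:
    family: str = "gaussian"  # gaussian | binomial
    alpha: float = 1.0  # 1 = LASSO, -> 0 = ridge
    lam: float | str = "cv"  # penalty strength or "cv"
    n_folds: int = 10
    fold_seed: int = 0
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-4
    one_se: bool = False  # CV rule: minimum mean loss unless enabled

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be gaussian or binomial")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0,1]")
        if isinstance(self.lam, str) and self.lam != "cv":
            raise ValueError('lam must be a number or "cv"')
        if not isinstance(self.lam, str) and self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class FittedOutcomeModel:
    intercept: float
    coef: pd.Series  # aligned to design columns
    lam: float
    alpha: float
    family: str
    center: pd.Series | None = None
    scale: pd.Series | None = None
    cv_lambdas: np.ndarray | None = None
    cv_loss: np.ndarray | None = None

    @property
    def active_set(self) -> list[str]:
        return [c for c, b in self.coef.items() if b != 0.0]

    def linear_predictor(self, design: DesignMatrix) -> np.ndarray:
        if list(design.columns) != list(self.coef.index):
            raise ValueError("design columns misaligned with model coefficients")
        return self.intercept + design.values() @ self.coef.to_numpy()

    def predict(self, design: DesignMatrix) -> np.ndarray:
        eta = self.linear_predictor(design)
        if self.family == "binomial":
            mu = expit(eta)
            return np.clip(mu, _EPS_MU, 1 - _EPS_MU)
        return eta

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "intercept": self.intercept,
            "coef": self.coef.to_dict(),
            "lambda": self.lam,
            "alpha": self.alpha,
            "center": None if self.center is None else self.center.to_dict(),
            "scale": None if self.scale is None else self.scale.to_dict(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedOutcomeModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coef=pd.Series(d["coef"]),
            lam=d["lambda"],
            alpha=d["alpha"],
            family=d["family"],
            center=None if d["center"] is None else pd.Series(d["center"]),
            scale=None if d["scale"] is None else pd.Series(d["scale"]),
        )


@dataclass
class WeightVector:
    weights: pd.Series  # stabilized IPT weights aligned to table rows
    truncation: tuple[float, float]  # percentile bounds used
    propensity: pd.Series = field(repr=False, default=None)
    balance: pd.DataFrame | None = None  # standardized mean differences

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")
        if not 0.9 <= w.mean() <= 1.1:
            warnings.warn(
                f"stabilized-weight mean {w.mean():.3f} outside [0.9, 1.1]: "
                "possible positivity problem"
            )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _penalty(beta: np.ndarray, lam: float, alpha: float, pf: np.ndarray | None = None) -> float:
    if pf is None:
        pf = np.ones_like(beta)
    return float(lam * np.sum(pf * (alpha * np.abs(beta) + 0.5 * (1 - alpha) * beta**2)))


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _EPS_MU, 1 - _EPS_MU)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def penalty_loss(
    y: np.ndarray,
    design: DesignMatrix | np.ndarray,
    beta: np.ndarray,
    lam: float,
    alpha: float,
    intercept: float = 0.0,
    family: str = "gaussian",
) -> float:
    """Objective value: RSS (gaussian) or deviance (binomial) + elastic-net
    penalty on `beta` (the intercept is never penalized).  lambda=0 reduces to
    the ordinary least-squares / log-likelihood loss.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0,1]")
    X = design.values() if isinstance(design, DesignMatrix) else np.asarray(design, float)
    beta = np.asarray(beta, float)
    if X.shape[1] != beta.size or X.shape[0] != len(y):
        raise ValueError("dimension mismatch")
    eta = intercept + X @ beta
    fit = _deviance(np.asarray(y, float), expit(eta)) if family == "binomial" \
        else float(np.sum((np.asarray(y, float) - eta) ** 2))
    return fit + _penalty(beta, lam, alpha)


# ---------------------------------------------------------------------------
# coordinate-descent solver
# ---------------------------------------------------------------------------

def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@numba.njit(fastmath=False)
def _cd_kernel(G, b, lam, alpha, pfa, ba, tol, max_iter):  # pragma: no cover - jitted
    p1 = ba.shape[0]
    grad = G @ ba
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p1):
            zj = b[j] - grad[j] + G[j, j] * ba[j]
            if pfa[j] > 0.0:
                t = lam * alpha * pfa[j]
                if zj > t:
                    num = zj - t
                elif zj < -t:
                    num = zj + t
                else:
                    num = 0.0
                new = num / (G[j, j] + lam * (1.0 - alpha) * pfa[j])
            else:
                new = zj / G[j, j]
            step = new - ba[j]
            if step != 0.0:
                for k in range(p1):
                    grad[k] += G[k, j] * step
                ba[j] = new
                if abs(step) > delta:
                    delta = abs(step)
        if delta < tol:
            break
    return ba


def _gram(X: np.ndarray, y: np.ndarray, sw: np.ndarray | None = None):
    """Sufficient statistics for the weighted quadratic loss sum sw*(y-eta)^2
    over the intercept-augmented design: G = 2*Xa'diag(sw)Xa, b = 2*Xa'(sw*y)."""
    n = len(y)
    Xa = np.column_stack([np.ones(n), X])
    Xw = Xa if sw is None else Xa * sw[:, None]
    return 2.0 * (Xw.T @ Xa), 2.0 * (Xw.T @ y)


def _cd_gram(
    G: np.ndarray,
    b: np.ndarray,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    beta: np.ndarray,
    intercept: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[float, np.ndarray]:
    """Cyclic coordinate descent on the Gram form of the elastic-net problem.

    Each update costs O(p); the data only enter through (G, b), so one Gram
    computation serves an entire warm-started lambda path.
    """
    p = len(pf)
    ba = np.empty(p + 1)
    ba[0] = intercept
    ba[1:] = beta
    pfa = np.empty(p + 1)
    pfa[0] = 0.0  # intercept never penalized
    pfa[1:] = pf
    ba = _cd_kernel(np.ascontiguousarray(G, float), np.ascontiguousarray(b, float),
                    float(lam), float(alpha), pfa, ba, float(tol), max_iter)
    return float(ba[0]), ba[1:]


def _cd_gaussian(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    beta: np.ndarray,
    intercept: float,
    sw: np.ndarray | None = None,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray]:
    """Elastic-net fit of sum sw*(y-eta)^2 + penalty (sw default 1)."""
    G, b = _gram(X, y, sw)
    return _cd_gram(G, b, lam, alpha, pf, beta.copy(), intercept, tol=tol)


def _fit_binomial(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    pf: np.ndarray,
    beta: np.ndarray,
    intercept: float,
    tol: float = 1e-8,
    max_outer: int = 50,
) -> tuple[float, np.ndarray]:
    """Penalized logistic fit: IRLS around the deviance with an inner
    weighted-least-squares coordinate descent.

    The local quadratic model of the deviance is sum w_i (z_i - eta_i)^2
    (up to a constant) with w = mu(1-mu) and working response
    z = eta + (y-mu)/w, so each outer step is a weighted elastic-net solve
    with the same penalty.
    """
    beta = beta.copy()
    for _ in range(max_outer):
        eta = intercept + X @ beta
        mu = np.clip(expit(eta), 1e-6, 1 - 1e-6)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        old = np.concatenate([[intercept], beta])
        G, b = _gram(X, z, w)
        intercept, beta = _cd_gram(G, b, lam, alpha, pf, beta, intercept, tol=tol / 10)
        if np.max(np.abs(np.concatenate([[intercept], beta]) - old)) < tol:
            break
    return intercept, beta


def _default_penalty_factors(design: DesignMatrix) -> np.ndarray:
    """Everything penalized except the treatment main effect."""
    return np.array(
        [0.0 if p.kind == "treatment-main" else 1.0 for p in design.provenance]
    )


def _lambda_max(
    X: np.ndarray, y: np.ndarray, alpha: float, pf: np.ndarray, family: str
) -> float:
    """Smallest lambda zeroing all penalized terms: fit the unpenalized block
    alone, then bound the score of each penalized coordinate."""
    free = pf == 0
    beta = np.zeros(X.shape[1])
    if family == "gaussian":
        if free.any():
            Xf = np.column_stack([np.ones(len(y)), X[:, free]])
            coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
            resid = y - Xf @ coef
        else:
            resid = y - y.mean()
        score = 2.0 * np.abs(X.T @ resid)
    else:
        b0, beta = _fit_binomial(X[:, free], y, 0.0, alpha, np.zeros(free.sum()),
                                 np.zeros(free.sum()), float(np.log(y.mean() / (1 - y.mean()))))
        mu = expit(b0 + X[:, free] @ beta)
        score = 2.0 * np.abs(X.T @ (y - mu))
    alpha_eff = max(alpha, 1e-3)  # ridge limit: finite grid anchor, glmnet convention
    lam = np.max(score[pf > 0] / (alpha_eff * pf[pf > 0]))
    return float(lam)


def _lambda_grid(lam_max: float, spec: PenaltySpec) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambdas)


def _fold_indices(n: int, n_folds: int, fold_seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(fold_seed)
    perm = rng.permutation(n)
    return [perm[i::n_folds] for i in range(n_folds)]


def _solve_path(X, y, grid, alpha, pf, family):
    """Warm-started fits along a decreasing lambda grid.  For the gaussian
    family one Gram computation serves the whole path."""
    p = X.shape[1]
    beta = np.zeros(p)
    if family == "binomial":
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        intercept = float(np.log(pbar / (1 - pbar)))
    else:
        intercept = float(y.mean())
    out = []
    if family == "gaussian":
        G, b = _gram(X, y)
        for lam in grid:
            intercept, beta = _cd_gram(G, b, lam, alpha, pf, beta, intercept)
            out.append((intercept, beta.copy()))
    else:
        for lam in grid:
            intercept, beta = _fit_binomial(X, y, lam, alpha, pf, beta, intercept)
            out.append((intercept, beta.copy()))
    return out


def _fit_arrays(
    X: np.ndarray, y: np.ndarray, spec: PenaltySpec, pf: np.ndarray
) -> tuple[float, np.ndarray, float, np.ndarray | None, np.ndarray | None]:
    """Elastic-net fit on raw arrays, with CV lambda selection when asked."""
    cv_lambdas = cv_loss = None
    if spec.lam == "cv":
        lam_max = _lambda_max(X, y, spec.alpha, pf, spec.family)
        grid = _lambda_grid(lam_max, spec)
        folds = _fold_indices(len(y), spec.n_folds, spec.fold_seed)
        losses = np.zeros((spec.n_folds, len(grid)))
        for fi, hold in enumerate(folds):
            mask = np.ones(len(y), bool)
            mask[hold] = False
            path = _solve_path(X[mask], y[mask], grid, spec.alpha, pf, spec.family)
            for li, (b0, b) in enumerate(path):
                eta = b0 + X[hold] @ b
                if spec.family == "binomial":
                    losses[fi, li] = _deviance(y[hold], expit(eta)) / len(hold)
                else:
                    losses[fi, li] = np.mean((y[hold] - eta) ** 2)
        mean_loss = losses.mean(axis=0)
        best = int(np.argmin(mean_loss))
        if spec.one_se:
            se = losses.std(axis=0, ddof=1) / np.sqrt(spec.n_folds)
            threshold = mean_loss[best] + se[best]
            best = int(np.nonzero(mean_loss <= threshold)[0][0])  # largest lambda within 1 SE
        lam = float(grid[best])
        cv_lambdas, cv_loss = grid, mean_loss
    else:
        lam = float(spec.lam)

    if spec.family == "gaussian":
        intercept, beta = _cd_gaussian(
            X, y, lam, spec.alpha, pf, np.zeros(X.shape[1]), float(y.mean())
        )
    else:
        pbar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        intercept, beta = _fit_binomial(
            X, y, lam, spec.alpha, pf, np.zeros(X.shape[1]), float(np.log(pbar / (1 - pbar)))
        )
    beta[np.abs(beta) < 1e-12] = 0.0
    return float(intercept), beta, lam, cv_lambdas, cv_loss


def fit_penalized(
    design: DesignMatrix,
    y: np.ndarray | pd.Series,
    spec: PenaltySpec,
    penalty_factors: np.ndarray | None = None,
) -> FittedOutcomeModel:
    """Fit the elastic-net outcome model on a (standardized) training design.

    With lam="cv" the penalty is chosen to minimize the mean cross-validated
    loss (MSE for gaussian, deviance for binomial) over the lambda grid; folds
    are deterministic given fold_seed.
    """
    y = np.asarray(y, float)
    X = design.values()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or outcome")
    if spec.family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial family requires a 0/1 outcome")
    pf = _default_penalty_factors(design) if penalty_factors is None else np.asarray(penalty_factors, float)
    intercept, beta, lam, cv_lambdas, cv_loss = _fit_arrays(X, y, spec, pf)
    return FittedOutcomeModel(
        intercept=intercept,
        coef=pd.Series(beta, index=design.columns),
        lam=lam,
        alpha=spec.alpha,
        family=spec.family,
        center=design.center,
        scale=design.scale,
        cv_lambdas=cv_lambdas,
        cv_loss=cv_loss,
    )


# ---------------------------------------------------------------------------
# post-double selection
# ---------------------------------------------------------------------------

def post_double_select(
    train: CohortTable,
    roles: VariableRoles,
    spec: PenaltySpec,
    design: DesignMatrix,
) -> list[str]:
    """Union of (a) design terms kept by the penalized outcome regression,
    (b) confounders kept by a penalized treatment (propensity) regression and
    (c) treatment x modifier interactions kept by the outcome regression.

    Run on the training split only; the final outcome model is refit on this
    union without penalty (see `refit_unpenalized`).
    """
    y = train.df[train.outcome].to_numpy(float)
    outcome_fit = fit_penalized(design, y, spec)
    selected = set(outcome_fit.active_set)

    # propensity LASSO: treatment on confounder mains (array-level fit, the
    # treatment is the response here, not a design column)
    conf_cols = [p.name for p in design.provenance
                 if p.kind == "covariate-main" and p.constituents[0] in roles.confounders]
    Xc = design.data[conf_cols].to_numpy(float)
    x = train.df[train.treatment].to_numpy(float)
    ps_spec = PenaltySpec(family="binomial", alpha=spec.alpha, lam="cv",
                          n_folds=spec.n_folds, fold_seed=spec.fold_seed,
                          one_se=spec.one_se)
    _, ps_beta, _, _, _ = _fit_arrays(Xc, x, ps_spec, np.ones(len(conf_cols)))
    selected |= {c for c, b in zip(conf_cols, ps_beta) if b != 0.0}

    # treatment x modifier interactions kept by the outcome fit
    for p in design.provenance:
        if p.kind == "treatment-x-term" and outcome_fit.coef[p.name] != 0.0:
            selected.add(p.name)

    if not selected - {design.treatment}:
        warnings.warn("post-double selection selected nothing; falling back to confounder mains")
        selected = set(conf_cols)
    selected.add(design.treatment)
    return [c for c in design.columns if c in selected]


def refit_unpenalized(
    design: DesignMatrix, y: np.ndarray, terms: list[str], family: str = "gaussian"
) -> FittedOutcomeModel:
    """OLS/GLM refit on the selected term union (coefficients of dropped
    terms pinned at zero so prediction code is unchanged)."""
    X = sm.add_constant(design.data[terms].to_numpy(float))
    if family == "gaussian":
        res = sm.OLS(np.asarray(y, float), X).fit()
    else:
        res = sm.GLM(np.asarray(y, float), X, family=sm.families.Binomial()).fit()
    coef = pd.Series(0.0, index=design.columns)
    coef[terms] = res.params[1:]
    return FittedOutcomeModel(
        intercept=float(res.params[0]),
        coef=coef,
        lam=0.0,
        alpha=1.0,
        family=family,
        center=design.center,
        scale=design.scale,
    )


# ---------------------------------------------------------------------------
# stabilized IPTW
# ---------------------------------------------------------------------------

def _smd(v: np.ndarray, x: np.ndarray, w: np.ndarray) -> float:
    """Weighted standardized mean difference (pooled unweighted SD)."""
    w1, w0 = w[x == 1], w[x == 0]
    m1 = np.average(v[x == 1], weights=w1)
    m0 = np.average(v[x == 0], weights=w0)
    sd = np.sqrt((v[x == 1].var(ddof=1) + v[x == 0].var(ddof=1)) / 2)
    return float((m1 - m0) / sd) if sd > 0 else 0.0


def fit_iptw(
    table: CohortTable,
    confounders: list[str],
    truncation: tuple[float, float] = (1.0, 99.0),
) -> WeightVector:
    """Stabilized inverse-probability-of-treatment weights from a logistic
    propensity model on confounder main effects, truncated at the given
    percentiles, with before/after balance diagnostics."""
    x = table.df[table.treatment].to_numpy(float)
    C = table.df[confounders].to_numpy(float)
    exog = sm.add_constant(C)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(x, exog, family=sm.families.Binomial()).fit()
        except Exception as err:  # statsmodels raises/warns on separation
            raise ValueError(f"perfect separation in the propensity model: {err}") from err
    ps = np.asarray(res.fittedvalues)
    if np.any(ps <= 1e-12) or np.any(ps >= 1 - 1e-12):
        raise ValueError("estimated propensity of 0 or 1: positivity violation")
    px = x.mean()
    w = np.where(x == 1, px / ps, (1 - px) / (1 - ps))
    lo, hi = np.percentile(w, truncation)
    w_trunc = np.clip(w, lo, hi)
    balance = pd.DataFrame(
        {
            "smd_unweighted": [_smd(table.df[c].to_numpy(float), x, np.ones_like(w)) for c in confounders],
            "smd_weighted": [_smd(table.df[c].to_numpy(float), x, w_trunc) for c in confounders],
        },
        index=confounders,
    )
    return WeightVector(
        weights=pd.Series(w_trunc, index=table.df.index),
        truncation=(float(lo), float(hi)),
        propensity=pd.Series(ps, index=table.df.index),
        balance=balance,
    )
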
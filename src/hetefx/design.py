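"""Variable roles, sample splitting and the saturated treatment-interaction design.

This module covers the first two steps of the pipeline: declaring which
columns of a cohort table act as confounders and which as candidate effect
modifiers, splitting the cohort into a training and a testing subsample, and
expanding the covariates into a design matrix that contains the treatment
indicator, covariate main effects, optional covariate products, and the
treatment interactions that carry all the effect heterogeneity the outcome
model can express.

Scaling parameters for continuous columns are always estimated on the
training split and re-applied (never re-estimated) to the testing split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "VariableRoles",
    "DesignSpec",
    "ColumnProvenance",
    "DesignMatrix",
    "validate_roles",
    "split_sample",
    "build_design",
    "standardize",
    "destandardize",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """One row per individual: binary treatment, outcome, covariates.

    Parameters
    ----------
    df : DataFrame with an `id` column (or unique index), the treatment
        column, the outcome column, and covariate columns.
    treatment, outcome : column names of the exposure indicator and outcome.
    """

    df: pd.DataFrame
    treatment: str = "treatment"
    outcome: str = "y"

    def __post_init__(self) -> None:
        if self.df.empty:
            raise ValueError("cohort table is empty")
        for col in (self.treatment, self.outcome):
            if col not in self.df.columns:
                raise KeyError(f"column {col!r} not in table")
        x = self.df[self.treatment]
        if not set(np.unique(x)) <= {0, 1}:
            raise ValueError("treatment column must be coded 0/1")
        if x.nunique() < 2:
            raise ValueError("both treatment arms must be non-empty")
        if self.df.isna().any().any():
            raise ValueError("missing values present; imputation is upstream of this tool")
        if not self.df.index.is_unique:
            raise ValueError("row ids (index) must be unique")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in (self.treatment, self.outcome)]

    def is_binary(self, col: str) -> bool:
        """A covariate with exactly two distinct values is treated as binary
        and never rescaled, so its coefficients and cluster means stay on the
        original scale."""
        return self.df[col].nunique() == 2

    def subset(self, index) -> "CohortTable":
        return CohortTable(self.df.loc[index], self.treatment, self.outcome)


@dataclass
class VariableRoles:
    """Investigator-declared roles: the backdoor set C and candidates W.

    Overlap is allowed and expected — modifiers that are also confounders
    belong to both lists.
    """

    confounders: list[str]
    candidate_modifiers: list[str]

    @property
    def all_covariates(self) -> list[str]:
        out = list(self.confounders)
        out.extend(c for c in self.candidate_modifiers if c not in out)
        return out


@dataclass
class DesignSpec:
    """How the saturated design is expanded.

    interaction_order is the maximum number of covariates multiplied together
    inside a treatment-interaction term (1 = plain treatment x covariate).
    """

    interaction_order: int = 1
    include_covariate_covariate_interactions: bool = False
    standardize: bool = True
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction_order < 1:
            raise ValueError("interaction_order must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0,1)")


@dataclass(frozen=True)
class ColumnProvenance:
    kind: str  # treatment-main | covariate-main | covariate-x-covariate | treatment-x-term
    constituents: tuple[str, ...]

    @property
    def name(self) -> str:
        return "*".join(self.constituents)


@dataclass
class DesignMatrix:
    """Expanded design with provenance and (training) scaling parameters."""

    data: pd.DataFrame
    provenance: list[ColumnProvenance]
    treatment: str
    center: pd.Series | None = None
    scale: pd.Series | None = None
    standardized: bool = False
    continuous_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_treat = sum(p.kind == "treatment-main" for p in self.provenance)
        if n_treat != 1:
            raise ValueError("design must contain exactly one treatment-main column")
        if len({p for p in self.provenance}) != len(self.provenance):
            raise ValueError("duplicate column provenance")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def validate_roles(table: CohortTable, roles: VariableRoles) -> VariableRoles:
    """Structural validation of declared roles (the causal judgment itself —
    backdoor sufficiency, collider exclusion — stays with the investigator).
    """
    if table.df.empty:
        raise ValueError("cohort table is empty")
    known = set(table.covariates)
    for name in roles.confounders + roles.candidate_modifiers:
        if name in (table.treatment, table.outcome):
            raise ValueError(f"{name!r} is the treatment or outcome, not a covariate")
        if name not in known:
            raise KeyError(f"unknown column {name!r}")
    if not roles.all_covariates:
        raise ValueError("confounder and modifier sets are both empty")
    extra = [m for m in roles.candidate_modifiers if m not in roles.confounders]
    if extra:
        warnings.warn(
            "candidate modifiers not in the confounder set (fine if they do not "
            f"confound treatment assignment): {extra}",
            stacklevel=2,
        )
    return roles


def split_sample(
    table: CohortTable, fraction: float = 0.7, seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Simple random train/test partition with |train| = round(fraction*n).

    Both splits must contain both treatment arms; a handful of re-draws are
    attempted before giving up (tiny samples).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0,1)")
    n = table.n
    n_train = round(fraction * n)
    if n_train in (0, n):
        raise ValueError("split leaves one part empty")
    rng = np.random.default_rng(seed)
    x = table.df[table.treatment].to_numpy()
    for attempt in range(20):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if len(np.unique(x[tr])) == 2 and len(np.unique(x[te])) == 2:
            if attempt > 0:
                warnings.warn(f"resampled split {attempt} time(s) to keep both arms in both splits")
            idx = table.df.index
            return table.subset(idx[tr]), table.subset(idx[te])
    raise ValueError("sample too small to keep both treatment arms in both splits")


def _term_columns(
    table: CohortTable, roles: VariableRoles, spec: DesignSpec
) -> list[ColumnProvenance]:
    covs = roles.all_covariates
    if len(covs) != len(set(covs)):
        raise ValueError("duplicate covariate names in roles")
    if spec.interaction_order > len(covs):
        raise ValueError("interaction_order exceeds the number of covariates")
    prov: list[ColumnProvenance] = [ColumnProvenance("treatment-main", (table.treatment,))]
    prov += [ColumnProvenance("covariate-main", (c,)) for c in covs]
    products: list[tuple[str, ...]] = []
    for order in range(2, spec.interaction_order + 1):
        products += sorted(itertools.combinations(sorted(covs), order))
    if spec.include_covariate_covariate_interactions:
        prov += [ColumnProvenance("covariate-x-covariate", p) for p in products]
    # treatment interactions mirror mains then products
    for c in covs:
        prov.append(ColumnProvenance("treatment-x-term", (table.treatment, c)))
    for p in products:
        prov.append(ColumnProvenance("treatment-x-term", (table.treatment, *p)))
    return prov


def build_design(
    table: CohortTable, roles: VariableRoles, spec: DesignSpec
) -> DesignMatrix:
    """Expand the cohort into {X} u {mains} u {products} u {X x term}.

    Column order is fixed: treatment, mains in declared order, covariate
    products in lexicographic order of constituents, then the treatment
    interactions mirroring that order — so coefficient vectors are comparable
    across runs.
    """
    prov = _term_columns(table, roles, spec)
    cols = {}
    for p in prov:
        v = np.ones(table.n)
        for c in p.constituents:
            v = v * table.df[c].to_numpy(dtype=float)
        cols[p.name] = v
    data = pd.DataFrame(cols, index=table.df.index)
    continuous = [
        p.name
        for p in prov
        if p.kind != "treatment-main" and data[p.name].nunique() != 2
    ]
    return DesignMatrix(
        data=data,
        provenance=prov,
        treatment=table.treatment,
        continuous_columns=continuous,
    )


def standardize(design: DesignMatrix, reference: DesignMatrix | None = None) -> DesignMatrix:
    """Center/scale continuous columns; binary and treatment columns pass through.

    With `reference`, the reference's (training) parameters are applied —
    never re-estimated — so test-set predictions line up with the training
    coefficients.
    """
    if design.standardized:
        raise ValueError("design is already standardized")
    if reference is not None:
        if [p for p in reference.provenance] != [p for p in design.provenance]:
            raise ValueError("reference design has different column provenance")
        center, scale = reference.center, reference.scale
        if center is None or scale is None:
            raise ValueError("reference design carries no scaling parameters")
        cont = reference.continuous_columns
    else:
        cont = design.continuous_columns
        center = pd.Series(0.0, index=design.columns)
        scale = pd.Series(1.0, index=design.columns)
        for c in cont:
            v = design.data[c]
            sd = v.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"zero-variance continuous column {c!r}")
            center[c], scale[c] = v.mean(), sd
    data = (design.data - center) / scale
    return replace(
        design,
        data=data,
        center=center.copy(),
        scale=scale.copy(),
        standardized=True,
        continuous_columns=list(cont),
    )


def destandardize(design: DesignMatrix) -> DesignMatrix:
    """Invert `standardize` using the parameters stored on the matrix."""
    if not design.standardized:
        raise ValueError("design is not standardized")
    data = design.data * design.scale + design.center
    return replace(design, data=data, standardized=False)
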
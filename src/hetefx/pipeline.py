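"""End-to-end orchestration of the seven-step effect-modifier pipeline.

    1. validate declared variable roles
    2. train/test split + saturated treatment-interaction design
    3. cross-validated penalized outcome model (optionally post-double
       selection) and stabilized IPT weights
    4. recycled predictions of both potential outcomes on the test split
    5. individual-level contrasts (CATEs) + distribution summary
    6. Ward clustering of the CATEs, Beale k-selection, z-score variable
       importance, continuous cut-offs
    7. subgroup MSM per selected modifier with sandwich (IPTW) or bootstrap
       (G-computation) inference, on additive and relative scales
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modifier_discovery as md
from . import subgroup_msm as msm
from .design import (
    CohortTable,
    DesignSpec,
    VariableRoles,
    build_design,
    split_sample,
    standardize,
    validate_roles,
)
from .gcomputation import compute_cate, predict_potential_outcomes, summarize_cate_distribution
from .penalized_outcome import (
    PenaltySpec,
    fit_iptw,
    fit_penalized,
    post_double_select,
    refit_unpenalized,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    roles: VariableRoles
    design: DesignSpec = field(default_factory=DesignSpec)
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    double_selection: bool = False
    weight_truncation: tuple[float, float] = (1.0, 99.0)
    jitter_relative_sd: float = 1e-3
    jitter_seed: int = 0
    k_max: int = 5
    beale_alpha: float = 0.10
    importance_threshold: float = 0.2
    estimator: str = "iptw"  # iptw | gcomp for step 7
    bootstrap_B: int = 500
    bootstrap_seed: int = 0
    msm_on_full_data: bool = True  # step 7 on the entire dataset (else test split)


@dataclass
class PipelineResult:
    train: CohortTable
    test: CohortTable
    model: object
    weights: object
    cate: object
    cate_summary: dict
    k: int
    clusters: md.ClusterSolution | None
    importance: pd.DataFrame | None
    selected_modifiers: list[str]
    cutoffs: dict[str, float]
    estimates: list[msm.SubgroupEstimate]
    report: pd.DataFrame

    def report_csv(self, path) -> None:
        self.report.to_csv(path, index=False)


def _report_frame(estimates: list[msm.SubgroupEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "variable_and_threshold": e.label,
            "n": e.n,
            "proportion_pct": round(e.proportion, 2),
            "rd": e.rd,
            "rd_ci_low": e.rd_ci[0],
            "rd_ci_high": e.rd_ci[1],
            "p_interaction_rd": e.p_interaction_rd,
            "rr": e.rr,
            "rr_ci_low": e.rr_ci[0],
            "rr_ci_high": e.rr_ci[1],
            "p_interaction_rr": e.p_interaction_rr,
            "estimator": e.estimator,
            "inference": e.inference,
        })
    return pd.DataFrame(rows)


def run_pipeline(table: CohortTable, config: PipelineConfig) -> PipelineResult:
    roles = validate_roles(table, config.roles)

    # step 2: split + design
    train, test = split_sample(table, config.design.split_fraction, config.design.seed)
    train_design = build_design(train, roles, config.design)
    if config.design.standardize:
        train_design = standardize(train_design)

    # step 3: penalized outcome model (+ optional post-double selection), IPTW
    y_train = train.df[train.outcome].to_numpy(float)
    if config.double_selection:
        terms = post_double_select(train, roles, config.penalty, train_design)
        model = refit_unpenalized(train_design, y_train, terms, config.penalty.family)
    else:
        model = fit_penalized(train_design, y_train, config.penalty)
    weights = fit_iptw(table, roles.confounders, config.weight_truncation)

    # steps 4-5: recycled predictions and contrasts on the test split
    y1, y0 = predict_potential_outcomes(model, test, roles, config.design)
    cate = compute_cate(
        y1, y0, ids=test.df.index,
        modifiers=test.df[roles.candidate_modifiers],
        family=config.penalty.family,
    )
    cate_summary = summarize_cate_distribution(cate)

    # step 6: clustering and variable importance
    jittered = md.jitter_cates(cate.contrast, config.jitter_relative_sd, config.jitter_seed)
    k, trace = md.select_k_beale(jittered, config.k_max, config.beale_alpha, return_trace=True)
    clusters = importance = None
    selected: list[str] = []
    cutoffs: dict[str, float] = {}
    if k >= 2:
        clusters = md.ward_cluster(jittered, k, cate=cate.contrast,
                                   modifiers=cate.modifiers, k_trace=trace)
        binary = {m for m in roles.candidate_modifiers if table.is_binary(m)}
        importance = md.importance_table(clusters, cate.modifiers,
                                         config.importance_threshold, binary_cols=binary)
        selected = list(importance.index[importance["selected"]])
        cutoffs = {m: float(importance.loc[m, "cutoff"])
                   for m in selected if np.isfinite(importance.loc[m, "cutoff"])}

    # step 7: subgroup MSM per selected modifier
    analysis = table if config.msm_on_full_data else test
    estimates = [msm.overall_effect(
        analysis,
        weights if config.estimator == "iptw" else None,
        config.estimator,
    )]
    for m in selected:
        group, labels = msm.binarize_modifier(analysis, m, cutoffs.get(m))
        fit = msm.fit_msm(analysis, group, weights=weights if config.estimator == "iptw" else None,
                          estimator=config.estimator, modifier=m, labels=labels,
                          confounders=roles.confounders)
        if config.estimator == "gcomp":
            fit = msm.bootstrap_inference(fit, config.bootstrap_B, config.bootstrap_seed)
        estimates.extend(msm.subgroup_contrasts(fit))

    return PipelineResult(
        train=train, test=test, model=model, weights=weights,
        cate=cate, cate_summary=cate_summary, k=k, clusters=clusters,
        importance=importance, selected_modifiers=selected, cutoffs=cutoffs,
        estimates=estimates, report=_report_frame(estimates),
    )
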
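"""Cluster the CATE distribution and rank candidate effect modifiers.

A Ward hierarchical clustering of the 1-D individualized-effect estimates
finds groups of individuals with similar effects; a tiny seeded jitter makes
near-degenerate CATE vectors clusterable and is used *only* for building the
tree and choosing k — every reported quantity (cluster means, z-scores,
cut-offs) is computed on the un-jittered values.

The number of clusters is chosen with Beale's pseudo-F ratio comparing the
k- and (k+1)-cluster Ward solutions,

    F = [(W_k - W_{k+1}) / W_{k+1}] /
        [ ((n-k)/(n-k-1)) * ((k+1)/k)^(2/p) - 1 ],        p = 1,

declaring the extra cluster justified when F exceeds the F(p, (n-k-1)p)
critical value.  The default significance level is 0.10, the convention of
the NbClust implementation of this index; it is a config knob.

A candidate modifier's importance is the absolute difference of its cluster
z-scores (cluster mean minus overall mean, over the overall SD); candidates
whose importance reaches the threshold (default 0.2) are selected, and a
selected continuous modifier is binarized at the midpoint of its two extreme
cluster means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f as f_dist

__all__ = [
    "ClusterSolution",
    "jitter_cates",
    "select_k_beale",
    "ward_cluster",
    "importance_table",
    "continuous_cutoff",
]


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1..k, canonicalized by ascending mean CATE
    cluster_cate_means: np.ndarray  # on the un-jittered CATEs
    cluster_sizes: np.ndarray
    modifier_means: pd.DataFrame | None = None  # clusters x modifiers
    k_trace: pd.DataFrame | None = None  # Beale statistic trace

    def __post_init__(self) -> None:
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if self.cluster_sizes.sum() != len(self.labels) or (self.cluster_sizes < 1).any():
            raise ValueError("cluster sizes must be >= 1 and sum to n")
        if not np.all(np.diff(self.cluster_cate_means) >= 0):
            raise ValueError("clusters must be labelled by ascending mean CATE")


def jitter_cates(cate: np.ndarray, relative_sd: float = 1e-3, seed: int = 0) -> np.ndarray:
    """cate + Normal(0, (relative_sd * SD(cate))^2) noise, seeded.

    For a constant vector the scale would collapse to zero, which would
    defeat the point of the trick, so an absolute floor of 1e-8 is used (with
    a warning).
    """
    if relative_sd <= 0:
        raise ValueError("relative_sd must be > 0")
    cate = np.asarray(cate, float)
    sd = cate.std()
    # a vector constant to machine precision jitters below float resolution,
    # defeating the point of the trick: fall back to an absolute scale
    if sd < 1e-12 * max(1.0, float(np.abs(cate).max())):
        warnings.warn("constant CATE vector: jitter falls back to absolute scale 1e-8")
        scale = 1e-8
    else:
        scale = relative_sd * sd
    rng = np.random.default_rng(seed)
    return cate + rng.normal(0.0, scale, size=cate.shape)


def _ward_linkage(values: np.ndarray) -> np.ndarray:
    return linkage(np.asarray(values, float).reshape(-1, 1), method="ward")


def _within_ss(values: np.ndarray, labels: np.ndarray) -> float:
    return float(sum(((values[labels == g] - values[labels == g].mean()) ** 2).sum()
                     for g in np.unique(labels)))


def select_k_beale(
    jittered: np.ndarray,
    k_max: int = 5,
    alpha: float = 0.10,
    return_trace: bool = False,
):
    """Number of Ward clusters by Beale's pseudo-F rule.

    The statistic F(k) compares the k- and (k+1)-cluster solutions; a
    significant F justifies the (k+1)-th cluster.  F is evaluated for every
    k up to k_max and the returned k is the largest cluster count whose
    creation was significant (1 when no split ever is).  Scanning all k
    rather than stopping at the first non-significant improvement matters
    for structures such as three equal spikes, where the 1-vs-2 improvement
    ratio is modest (the best 2-split still leaves one heterogeneous
    cluster) but the 2-vs-3 improvement is decisive.
    """
    jittered = np.asarray(jittered, float)
    n = len(jittered)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of points")
    if len(np.unique(jittered)) < k_max + 1:
        raise ValueError("need more distinct values than clusters (jitter the input)")
    Z = _ward_linkage(jittered)
    W = {}
    for k in range(1, k_max + 2):
        W[k] = _within_ss(jittered, fcluster(Z, k, criterion="maxclust"))
    rows = []
    chosen = 1
    for k in range(1, k_max + 1):
        if W[k + 1] <= 0:
            F, crit, significant = np.inf, np.nan, W[k] > 0
        else:
            num = (W[k] - W[k + 1]) / W[k + 1]
            denom = ((n - k) / (n - k - 1)) * ((k + 1) / k) ** 2 - 1
            F = num / denom
            crit = f_dist.ppf(1 - alpha, 1, n - k - 1)
            significant = F > crit
        rows.append({"k": k, "W_k": W[k], "W_k1": W[k + 1], "F": F,
                     "crit": crit, "significant": significant})
        if significant and k + 1 <= k_max:
            chosen = k + 1
    trace = pd.DataFrame(rows)
    return (chosen, trace) if return_trace else chosen


def ward_cluster(
    jittered: np.ndarray,
    k: int,
    cate: np.ndarray | None = None,
    modifiers: pd.DataFrame | None = None,
    k_trace: pd.DataFrame | None = None,
) -> ClusterSolution:
    """Cut the Ward tree of the jittered values at k clusters.

    Labels are canonicalized by ascending cluster mean of the *un-jittered*
    CATEs (`cate`; defaults to the jittered values when not given), and all
    reported means are computed on those un-jittered values and on the raw
    modifier columns.
    """
    jittered = np.asarray(jittered, float)
    n = len(jittered)
    if k < 1 or k > n:
        raise ValueError("k must lie in 1..n")
    values = jittered if cate is None else np.asarray(cate, float)
    if k == 1:
        raw = np.ones(n, dtype=int)
    else:
        if len(np.unique(jittered)) < k:
            raise ValueError("fewer distinct values than clusters")
        raw = fcluster(_ward_linkage(jittered), k, criterion="maxclust")
    means = np.array([values[raw == g].mean() for g in range(1, raw.max() + 1)])
    order = np.argsort(means, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(1, len(order) + 1)
    labels = relabel[raw - 1]
    sizes = np.bincount(labels, minlength=len(order) + 1)[1:]
    mod_means = None
    if modifiers is not None:
        mod_means = pd.DataFrame(
            {m: [modifiers[m].to_numpy()[labels == g].mean() for g in range(1, len(order) + 1)]
             for m in modifiers.columns},
            index=pd.RangeIndex(1, len(order) + 1, name="cluster"),
        )
    return ClusterSolution(
        k=len(order),
        labels=labels,
        cluster_cate_means=np.sort(means),
        cluster_sizes=sizes,
        modifier_means=mod_means,
        k_trace=k_trace,
    )


def continuous_cutoff(cluster_mean_1: float, cluster_mean_2: float) -> float:
    """Binarization cut-off for a selected continuous modifier: the average
    of its means across the two (extreme) clusters."""
    if not (np.isfinite(cluster_mean_1) and np.isfinite(cluster_mean_2)):
        raise ValueError("cluster means must be finite")
    return (cluster_mean_1 + cluster_mean_2) / 2.0


def importance_table(
    solution: ClusterSolution,
    modifiers: pd.DataFrame,
    threshold: float = 0.2,
    binary_cols: set[str] | None = None,
) -> pd.DataFrame:
    """Per-candidate z-scores in each cluster, importance, selection flag and
    (for selected continuous modifiers) the binarization cut-off.

    z-score of modifier m in cluster g = (mean of m in g - overall mean of m)
    / overall SD of m.  Importance is the absolute z difference between the
    two clusters (max pairwise difference when k > 2).  With one cluster
    there is nothing to contrast and every importance is 0.
    """
    if binary_cols is None:
        binary_cols = {c for c in modifiers.columns if modifiers[c].nunique() == 2}
    labels = solution.labels
    rows = []
    for m in modifiers.columns:
        v = modifiers[m].to_numpy(float)
        mu, sd = v.mean(), v.std()
        if sd == 0:
            warnings.warn(f"modifier {m!r} has zero variance; importance set to 0")
            zs = np.zeros(solution.k)
        else:
            zs = np.array([(v[labels == g].mean() - mu) / sd for g in range(1, solution.k + 1)])
        imp = float(zs.max() - zs.min()) if solution.k >= 2 else 0.0
        selected = imp >= threshold
        cutoff = np.nan
        if selected and m not in binary_cols and solution.k >= 2:
            # midpoint of the two extreme clusters' means (the only case the
            # method demonstrates is k=2, where these are the two clusters)
            lo, hi = int(np.argmin(zs)) + 1, int(np.argmax(zs)) + 1
            cutoff = continuous_cutoff(v[labels == lo].mean(), v[labels == hi].mean())
        row = {"modifier": m, "importance": imp, "selected": selected,
               "cutoff": cutoff, "threshold": threshold}
        for g in range(1, solution.k + 1):
            row[f"z{g}"] = zs[g - 1] if solution.k >= 1 else np.nan
        rows.append(row)
    cols = ["modifier"] + [f"z{g}" for g in range(1, solution.k + 1)] + \
        ["importance", "selected", "cutoff", "threshold"]
    return pd.DataFrame(rows)[cols].set_index("modifier")
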
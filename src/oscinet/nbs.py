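"""Network-based statistic (NBS): edge-wise inference with FWER control.

Testing every edge of an N-node connectivity matrix multiplies comparisons
by N(N-1)/2.  The NBS controls the family-wise error rate by borrowing the
cluster-statistic idea from voxelwise imaging: edge statistics are
thresholded at an (uncorrected) primary threshold, connected components of
the surviving edges are identified, and each observed component's size (in
edges) is referred to the permutation null distribution of the *maximal*
component size.  Inference is at the component level: individual edges are
never declared significant on their own.

Two designs are supported: two-group contrasts (pooled-variance independent
t per edge, labels permuted across subjects) and simple regression of edge
strength on a per-subject covariate (standardized beta = Pearson r, with
t = r * sqrt((n-2)/(1-r^2)); the covariate is permuted).  Subject-level
permutation preserves the within-subject edge covariance that the null must
respect.

A conjunction (global-null, logical-AND) operation intersects the edges of
significant components across several NBS results, isolating effects
present in every contrast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse, stats

from .connectivity import ConnectivityMatrix

__all__ = [
    "DesignSpec",
    "EdgeStatMatrix",
    "NbsResult",
    "edge_stats",
    "suprathreshold_components",
    "nbs",
    "conjunction",
    "default_primary_threshold",
]

T_CAP = 1e6  # cap for |t| at perfect correlation (r = +/-1)


@dataclass
class DesignSpec:
    """Specification of one NBS analysis.

    ``kind='two_group'`` requires ``group_labels`` (per-subject, exactly two
    distinct values; the *first-occurring* label is group A, and positive
    statistics mean A > B).  ``kind='regression'`` requires ``covariate``
    (per-subject scalar, e.g. left-hemifield omission counts).
    """

    kind: str  # two_group | regression
    group_labels: list | None = None
    covariate: np.ndarray | None = None
    tail: str = "two_sided"  # two_sided | positive | negative
    primary_threshold: float | None = None  # None -> p=0.01 t quantile at design df
    nperm: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("two_group", "regression"):
            raise ValueError(f"kind must be two_group|regression, got {self.kind!r}")
        if self.tail not in ("two_sided", "positive", "negative"):
            raise ValueError(f"bad tail {self.tail!r}")
        if self.nperm < 100:
            raise ValueError(f"nperm must be >= 100, got {self.nperm}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.kind == "two_group":
            if self.group_labels is None:
                raise ValueError("two_group design needs group_labels")
            if len(set(self.group_labels)) != 2:
                raise ValueError("group_labels must contain exactly two distinct values")
        else:
            if self.covariate is None:
                raise ValueError("regression design needs a covariate")
            self.covariate = np.asarray(self.covariate, dtype=float)
            if not np.all(np.isfinite(self.covariate)):
                raise ValueError("covariate contains NaN/Inf")
            if self.covariate.std() == 0:
                raise ValueError("covariate has zero variance")

    @property
    def n_subjects(self) -> int:
        if self.kind == "two_group":
            return len(self.group_labels)
        return len(self.covariate)

    @property
    def df(self) -> int:
        return self.n_subjects - 2


@dataclass
class EdgeStatMatrix:
    """Symmetric per-edge test-statistic matrix for one design."""

    stat_kind: str  # t_two_sample | t_regression
    values: np.ndarray
    node_labels: list[str]
    design: DesignSpec
    beta: np.ndarray | None = None  # standardized beta (Pearson r), regression only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge statistics contain NaN/Inf")


@dataclass
class NbsResult:
    """Observed suprathreshold components with permutation p-values."""

    components: list[list[tuple[int, int]]]
    component_sizes: list[int]
    component_pvalues: list[float]
    null_max_sizes: np.ndarray
    observed_stats: EdgeStatMatrix
    threshold: float
    node_labels: list[str]
    alpha: float

    def significant_components(self, alpha: float | None = None) -> list[list[tuple[int, int]]]:
        a = self.alpha if alpha is None else alpha
        return [c for c, p in zip(self.components, self.component_pvalues) if p <= a]

    def significant_edges(self, alpha: float | None = None) -> set[tuple[int, int]]:
        return {e for comp in self.significant_components(alpha) for e in comp}

    def to_dict(self) -> dict:
        labels = self.node_labels
        return {
            "node_labels": labels,
            "threshold": self.threshold,
            "alpha": self.alpha,
            "stat_kind": self.observed_stats.stat_kind,
            "components": [
                {
                    "edges": [[labels[i], labels[j]] for i, j in comp],
                    "size": size,
                    "p_value": p,
                }
                for comp, size, p in zip(
                    self.components, self.component_sizes, self.component_pvalues
                )
            ],
            "null_max_size_histogram": {
                str(k): int(v)
                for k, v in zip(*np.unique(self.null_max_sizes, return_counts=True))
            },
            "nperm": int(len(self.null_max_sizes)),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def default_primary_threshold(design: DesignSpec, p_uncorrected: float = 0.01) -> float:
    """t quantile for the primary threshold at the design's degrees of freedom.

    Two-sided designs use the |t| quantile at p/2; one-tailed designs the
    quantile at p.  No primary threshold is canonical; sensitivity to this
    choice should always be reported alongside results.
    """
    df = design.df
    if df < 1:
        raise ValueError("not enough subjects for the design")
    if design.tail == "two_sided":
        return float(stats.t.ppf(1 - p_uncorrected / 2, df))
    return float(stats.t.ppf(1 - p_uncorrected, df))


def _subject_matrix(conn_stack, n_expected: int | None = None):
    """(n_subjects, n_edges) upper-triangular edge values plus metadata."""
    if isinstance(conn_stack, np.ndarray) and conn_stack.ndim == 3:
        arr = np.asarray(conn_stack, dtype=float)
        labels = [f"node{i:02d}" for i in range(arr.shape[1])]
    else:
        mats: list[ConnectivityMatrix] = list(conn_stack)
        labels = list(mats[0].node_labels)
        for m in mats:
            if list(m.node_labels) != labels:
                raise ValueError("node labels differ across subjects")
        arr = np.stack([m.values for m in mats])
    n_nodes = arr.shape[1]
    iu = np.triu_indices(n_nodes, k=1)
    vals = arr[:, iu[0], iu[1]]
    if n_expected is not None and vals.shape[0] != n_expected:
        raise ValueError(
            f"design describes {n_expected} subjects but stack has {vals.shape[0]}"
        )
    return vals, iu, n_nodes, labels


def _two_group_t(vals: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance t for rows selected by mask_a vs the rest."""
    a, b = vals[mask_a], vals[~mask_a]
    n1, n2 = a.shape[0], b.shape[0]
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def _regression_r(vals: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Pearson r of each edge column with the covariate."""
    vc = vals - vals.mean(axis=0)
    cc = cov - cov.mean()
    denom = np.sqrt((vc**2).sum(axis=0)) * np.sqrt((cc**2).sum())
    num = cc @ vc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def _r_to_t(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 0, None))
    capped = ~np.isfinite(t)
    if capped.any():
        warnings.warn("perfect correlation at some edges; |t| capped")
        t = np.where(capped, np.sign(r) * T_CAP, t)
    return t


def edge_stats(conn_stack, design: DesignSpec) -> EdgeStatMatrix:
    """Per-edge test statistic under the given design.

    Two-group: pooled-variance independent t per edge.  Regression: simple
    linear regression of edge value on the covariate; the standardized beta
    equals the Pearson correlation and is stored alongside its t value.
    Zero-variance edges yield statistic 0 with a warning.
    """
    vals, iu, n_nodes, labels = _subject_matrix(conn_stack, design.n_subjects)
    if vals.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    beta = None
    if design.kind == "two_group":
        labels_arr = np.asarray(design.group_labels)
        mask_a = labels_arr == labels_arr[0]
        if vals[mask_a].std(axis=0).min() == 0 or vals[~mask_a].std(axis=0).min() == 0:
            warnings.warn("zero-variance edges present; their t is 0")
        t = _two_group_t(vals, mask_a)
        kind = "t_two_sample"
    else:
        r = _regression_r(vals, design.covariate)
        if vals.std(axis=0).min() == 0:
            warnings.warn("zero-variance edges present; their statistic is 0")
        t = _r_to_t(r, vals.shape[0])
        beta_m = np.zeros((n_nodes, n_nodes))
        beta_m[iu] = r
        beta = beta_m + beta_m.T
        kind = "t_regression"
    values = np.zeros((n_nodes, n_nodes))
    values[iu] = t
    values = values + values.T
    return EdgeStatMatrix(stat_kind=kind, values=values, node_labels=labels,
                          design=design, beta=beta)


def _threshold_mask(stat_vals: np.ndarray, threshold: float, tail: str) -> np.ndarray:
    if tail == "two_sided":
        return np.abs(stat_vals) > threshold
    if tail == "positive":
        return stat_vals > threshold
    return stat_vals < -threshold


def suprathreshold_components(
    stats_matrix: EdgeStatMatrix | np.ndarray,
    threshold: float,
    tail: str = "two_sided",
    node_count: int | None = None,
) -> list[list[tuple[int, int]]]:
    """Connected components of the graph of edges passing the threshold.

    Components are returned as lists of (i, j) edge tuples (i < j), sorted
    by decreasing edge count.  Component size is its number of edges.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = stats_matrix.values if isinstance(stats_matrix, EdgeStatMatrix) else stats_matrix
    n = values.shape[0] if node_count is None else node_count
    iu = np.triu_indices(n, k=1)
    mask = _threshold_mask(values[iu], threshold, tail)
    g = nx.Graph()
    g.add_edges_from(zip(iu[0][mask], iu[1][mask]))
    comps = []
    for nodes in nx.connected_components(g):
        edges = sorted(
            (min(int(u), int(v)), max(int(u), int(v)))
            for u, v in g.subgraph(nodes).edges()
        )
        comps.append(edges)
    comps.sort(key=len, reverse=True)
    return comps


def _max_component_size(mask: np.ndarray, iu, n_nodes: int) -> int:
    """Edge count of the largest connected component among masked edges."""
    m = int(mask.sum())
    if m <= 1:
        return m
    rows, cols = iu[0][mask], iu[1][mask]
    adj = sparse.coo_matrix(
        (np.ones(m), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    _, comp_labels = sparse.csgraph.connected_components(adj, directed=False)
    # every kept edge belongs to the component of its first endpoint
    edge_comp = comp_labels[rows]
    return int(np.bincount(edge_comp).max())


def nbs(conn_stack, design: DesignSpec) -> NbsResult:
    """Run the full network-based statistic for one design.

    Observed suprathreshold components are sized in edges; the null
    distribution of maximal component size comes from ``design.nperm``
    subject-level permutations (group labels or covariate reshuffled).
    Each component's p-value is ``(1 + #{null >= size}) / (nperm + 1)``,
    never zero.  Per-edge statistics are reported alongside for description
    only; inference is at component level.
    """
    obs = edge_stats(conn_stack, design)
    vals, iu, n_nodes, labels = _subject_matrix(conn_stack, design.n_subjects)
    threshold = (
        design.primary_threshold
        if design.primary_threshold is not None
        else default_primary_threshold(design)
    )
    components = suprathreshold_components(obs, threshold, design.tail)
    sizes = [len(c) for c in components]

    rng = np.random.default_rng(design.seed)
    n_sub = vals.shape[0]
    null_max = np.zeros(design.nperm, dtype=int)
    if design.kind == "two_group":
        labels_arr = np.asarray(design.group_labels)
        base_mask = labels_arr == labels_arr[0]
        for p in range(design.nperm):
            perm_mask = rng.permutation(base_mask)
            t = _two_group_t(vals, perm_mask)
            mask = _threshold_mask(t, threshold, design.tail)
            null_max[p] = _max_component_size(mask, iu, n_nodes)
    else:
        cov = design.covariate
        for p in range(design.nperm):
            perm_cov = rng.permutation(cov)
            t = _r_to_t(_regression_r(vals, perm_cov), n_sub)
            mask = _threshold_mask(t, threshold, design.tail)
            null_max[p] = _max_component_size(mask, iu, n_nodes)

    pvals = [
        float((1 + np.sum(null_max >= s)) / (design.nperm + 1)) for s in sizes
    ]
    return NbsResult(
        components=components,
        component_sizes=sizes,
        component_pvalues=pvals,
        null_max_sizes=null_max,
        observed_stats=obs,
        threshold=float(threshold),
        node_labels=labels,
        alpha=design.alpha,
    )


def conjunction(results: list[NbsResult], alpha: float = 0.05) -> set[tuple[int, int]]:
    """Logical-AND conjunction across NBS results.

    Returns the edges that belong to some significant (p <= alpha)
    component in *every* input result; valid under the global null only
    because each contributing test is individually significant.  An empty
    set is a legitimate outcome.
    """
    if len(results) < 2:
        raise ValueError("conjunction needs at least 2 results")
    labels = results[0].node_labels
    for r in results[1:]:
        if r.node_labels != labels:
            raise ValueError("node labels differ between results")
    edge_sets = [r.significant_edges(alpha) for r in results]
    out = edge_sets[0]
    for s in edge_sets[1:]:
        out = out & s
    return out
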
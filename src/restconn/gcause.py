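"""Effective connectivity by Granger causality on multi-segment series.

A directed influence x -> y exists in the Granger sense when past values of
x improve the prediction of y beyond y's own past.  The test compares two
nested least-squares models of the target series under a vector
autoregression of order p,

    y(t) = sum_{j=1..p} A_j z(t - j) + e(t),

where z includes all modelled nodes (both nodes for the default pairwise,
bivariate analysis): the full model keeps the candidate source's lags, the
restricted model omits them, and the statistic

    F = ((RSS_r - RSS_f) / p) / (RSS_f / (n_obs - k_full))

is referred to F(p, n_obs - k_full).  Subjects contribute separate segments:
design rows never take lags across a segment boundary, so concatenation
across subjects pools the normal equations without seam artefacts.  The
model order is chosen by the Bayesian Information Criterion on the full
multivariate system, and edge families are thresholded with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, RankError, ValidationError
from .netstat import fdr_threshold


@dataclass
class SegmentedSeries:
    """Aligned multivariate series from multiple subject-sessions.

    ``segments`` holds one (n_nodes, T_r) array per subject-session; lagged
    regressions are always built within segments.
    """

    node_names: tuple[str, ...]
    segments: list[np.ndarray]
    condition: str = ""

    def __post_init__(self) -> None:
        self.node_names = tuple(self.node_names)
        if len(self.node_names) != len(set(self.node_names)):
            raise ValidationError("node names must be unique")
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        if not self.segments:
            raise ValidationError("at least one segment is required")
        k = len(self.node_names)
        for i, s in enumerate(self.segments):
            if s.ndim != 2 or s.shape[0] != k:
                raise ValidationError(
                    f"segment {i} has shape {s.shape}, expected ({k}, T)"
                )
            if not np.all(np.isfinite(s)):
                raise ValidationError(f"segment {i} contains non-finite values")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def min_length(self) -> int:
        return min(s.shape[1] for s in self.segments)

    def usable_rows(self, order: int) -> int:
        return sum(max(s.shape[1] - order, 0) for s in self.segments)

    def subset(self, names: list[str]) -> "SegmentedSeries":
        idx = [self.node_names.index(n) for n in names]
        return SegmentedSeries(
            tuple(names), [s[idx] for s in self.segments], self.condition
        )


@dataclass
class VarModel:
    """A fitted VAR(p): coeffs[lag][target][source], residuals and RSS."""

    order: int
    coeffs: np.ndarray  # (p, k, k)
    residuals: np.ndarray  # (n_obs, k)
    rss: np.ndarray  # (k,)
    n_obs: int
    node_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class CausalEdge:
    """A directed Granger edge with its F statistic."""

    source: str
    target: str
    f_score: float
    p_value: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError("self-edges are undefined")
        if self.f_score < 0:
            raise ValidationError(f"F must be >= 0, got {self.f_score}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p must lie in [0, 1], got {self.p_value}")


@dataclass
class CausalGraph:
    """FDR-thresholded directed graph over one condition's node set."""

    nodes: tuple[str, ...]
    edges: list[CausalEdge]
    q: float
    condition: str = ""

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValidationError(f"edge {e.source}->{e.target} uses unknown nodes")

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}


@dataclass
class DegreeTable:
    """Out-degree, in-degree and their difference per node."""

    nodes: tuple[str, ...]
    out_degree: np.ndarray
    in_degree: np.ndarray

    @property
    def out_in(self) -> np.ndarray:
        return self.out_degree - self.in_degree

    def as_dict(self) -> dict[str, tuple[int, int, int]]:
        return {
            n: (int(o), int(i), int(o - i))
            for n, o, i in zip(self.nodes, self.out_degree, self.in_degree)
        }


# ---------------------------------------------------------------------------
# construction and design matrices


def concatenate_segments(
    per_subject_series: list[np.ndarray],
    node_names: list[str] | tuple[str, ...],
    order_reserve: int = 1,
    condition: str = "",
) -> SegmentedSeries:
    """Pool subject series as separate segments of one SegmentedSeries.

    ``order_reserve`` is the largest model order later fits may use; every
    segment must keep at least ``5 * order_reserve`` samples.
    """
    series = SegmentedSeries(tuple(node_names), list(per_subject_series), condition)
    if series.min_length() < 5 * order_reserve:
        raise ValidationError(
            f"segments of length {series.min_length()} are too short for order "
            f"{order_reserve} (need >= {5 * order_reserve})"
        )
    return series


def _lagged_design(series: SegmentedSeries, order: int, start: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (X, Y) for a VAR(order); rows never span a segment boundary.

    ``start`` (default ``order``) is the first usable index within each
    segment; passing a common ``start = max_order`` makes fits of different
    orders comparable on identical rows.
    """
    if start is None:
        start = order
    if start < order:
        raise ValidationError("start offset must be >= order")
    k = series.n_nodes
    xs, ys = [], []
    for seg in series.segments:
        t_r = seg.shape[1]
        if t_r <= start:
            continue
        rows = t_r - start
        x = np.empty((rows, order * k))
        for lag in range(1, order + 1):
            x[:, (lag - 1) * k : lag * k] = seg[:, start - lag : t_r - lag].T
        xs.append(x)
        ys.append(seg[:, start:].T)
    if not xs:
        raise ValidationError("no usable regression rows; segments too short")
    return np.concatenate(xs), np.concatenate(ys)


def _check_rank(x: np.ndarray, order: int, names: tuple[str, ...]) -> None:
    k = len(names)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[-1] <= max(x.shape) * np.finfo(float).eps * s[0]:
        culprit = int(np.argmax(np.abs(vt[-1])))
        lag, node = divmod(culprit, k)
        raise RankError(
            f"collinear regressors: lag {lag + 1} of node {names[node]!r} is "
            "linearly dependent on the remaining columns"
        )


def fit_var(series: SegmentedSeries, order: int, start: int | None = None) -> VarModel:
    """Per-equation OLS fit of a VAR(order) on pooled within-segment rows.

    No intercept is included: inputs are expected zero-mean per segment.
    """
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    x, y = _lagged_design(series, order, start)
    _check_rank(x, order, series.node_names)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)  # (order*k, k)
    resid = y - x @ beta
    rss = (resid**2).sum(axis=0)
    k = series.n_nodes
    coeffs = np.empty((order, k, k))
    for lag in range(order):
        # beta rows (lag*k + source, target) -> coeffs[lag][target][source]
        coeffs[lag] = beta[lag * k : (lag + 1) * k, :].T
    return VarModel(order, coeffs, resid, rss, n_obs=y.shape[0], node_names=series.node_names)


def select_order_bic(series: SegmentedSeries, max_order: int) -> int:
    """BIC-minimising VAR order over p in 1..max_order.

    All candidates are evaluated on the rows available at ``max_order`` so
    their likelihoods are comparable; BIC = n ln det(Sigma_res) + p k^2 ln n.
    """
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    if max_order > series.min_length() / 5:
        raise ValidationError(
            f"max_order {max_order} exceeds shortest segment length / 5 "
            f"({series.min_length()} / 5)"
        )
    k = series.n_nodes
    best_p, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        x, y = _lagged_design(series, p, start=max_order)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        n = y.shape[0]
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise DegenerateInputError("residual covariance is singular; series degenerate")
        bic = n * logdet + p * k * k * np.log(n)
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


# ---------------------------------------------------------------------------
# Granger tests


def granger_f(series: SegmentedSeries, source: str, target: str, order: int) -> CausalEdge:
    """Nested-model F-test of source -> target at the given order.

    All nodes present in ``series`` condition the regression; pass a two-node
    series for the pairwise bivariate form.
    """
    if source == target:
        raise ValidationError("source and target must differ")
    for name in (source, target):
        if name not in series.node_names:
            raise ValidationError(f"unknown node {name!r}")
    k = series.n_nodes
    x, y = _lagged_design(series, order)
    tgt = series.node_names.index(target)
    src = series.node_names.index(source)
    yt = y[:, tgt]
    keep = np.array(
        [lag * k + node for lag in range(order) for node in range(k) if node != src]
    )
    beta_f, *_ = np.linalg.lstsq(x, yt, rcond=None)
    rss_f = float(np.sum((yt - x @ beta_f) ** 2))
    xr = x[:, keep]
    beta_r, *_ = np.linalg.lstsq(xr, yt, rcond=None)
    rss_r = float(np.sum((yt - xr @ beta_r) ** 2))
    n_obs = yt.size
    k_full = order * k
    dof = n_obs - k_full
    if dof <= 0:
        raise ValidationError("not enough observations for the full model")
    scale = max(rss_f, rss_r, 1.0)
    if rss_f <= 1e-12 * scale:
        if rss_r <= 1e-12 * scale:
            raise DegenerateInputError(
                f"F undefined for {source}->{target}: both models fit exactly"
            )
        warnings.warn(
            f"{source}->{target}: deterministic dependence, F diverges",
            RuntimeWarning,
            stacklevel=2,
        )
        return CausalEdge(source, target, np.inf, 0.0)
    f = ((rss_r - rss_f) / order) / (rss_f / dof)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, order, dof))
    return CausalEdge(source, target, float(f), p)


def pairwise_granger(series: SegmentedSeries, order: int) -> list[CausalEdge]:
    """Bivariate Granger F-test for every ordered node pair (source-major)."""
    if series.n_nodes < 2:
        raise ValidationError("need at least 2 nodes")
    edges: list[CausalEdge] = []
    for src in series.node_names:
        for tgt in series.node_names:
            if src == tgt:
                continue
            pair = series.subset([src, tgt])
            try:
                edges.append(granger_f(pair, src, tgt, order))
            except ValidationError as err:
                raise type(err)(f"pair {src}->{tgt}: {err}") from err
    return edges


def conditional_granger(series: SegmentedSeries, order: int) -> list[CausalEdge]:
    """Conditional (full-multivariate) Granger test for every ordered pair."""
    if series.n_nodes < 2:
        raise ValidationError("need at least 2 nodes")
    return [
        granger_f(series, src, tgt, order)
        for src in series.node_names
        for tgt in series.node_names
        if src != tgt
    ]


def build_causal_graph(
    edges: list[CausalEdge],
    q: float,
    nodes: tuple[str, ...] | None = None,
    condition: str = "",
) -> CausalGraph:
    """Benjamini-Hochberg FDR across all evaluated directed edges."""
    if not edges:
        raise ValidationError("empty edge list")
    if nodes is None:
        seen: list[str] = []
        for e in edges:
            for n in (e.source, e.target):
                if n not in seen:
                    seen.append(n)
        nodes = tuple(seen)
    p = np.array([e.p_value for e in edges])
    reject, _ = fdr_threshold(p, q)
    significant = [e for e, r in zip(edges, reject) if r]
    return CausalGraph(nodes=nodes, edges=significant, q=q, condition=condition)


def graph_from_edge_list(
    edge_list: list[tuple[str, str, float]],
    nodes: tuple[str, ...],
    q: float = 0.001,
    condition: str = "",
) -> CausalGraph:
    """Build a graph directly from already-thresholded (source, target, F) rows."""
    edges = [CausalEdge(s, t, float(f), 0.0) for s, t, f in edge_list]
    return CausalGraph(nodes=nodes, edges=edges, q=q, condition=condition)


def out_in_degree(graph: CausalGraph) -> DegreeTable:
    """Count causal out-flow and in-flow connections per node.

    A node with a high positive out-in degree acts as a causal source, a
    strongly negative one as a causal target.  The out-in values always sum
    to zero over the graph.
    """
    idx = {n: i for i, n in enumerate(graph.nodes)}
    out = np.zeros(len(graph.nodes), dtype=int)
    inn = np.zeros(len(graph.nodes), dtype=int)
    for e in graph.edges:
        out[idx[e.source]] += 1
        inn[idx[e.target]] += 1
    return DegreeTable(graph.nodes, out, inn)


# ---------------------------------------------------------------------------
# high-level route shared by the network- and ROI-level analyses


def effective_connectivity(
    per_subject_series: list[np.ndarray],
    node_names: list[str] | tuple[str, ...],
    q: float,
    order: int | str = "bic",
    max_order: int = 10,
    mode: str = "pairwise",
    condition: str = "",
) -> tuple[CausalGraph, list[CausalEdge], int]:
    """Concatenate subject segments, choose the order, test all pairs, FDR.

    Returns the thresholded graph, the full evaluated edge list, and the
    order used.  ``order='bic'`` selects one common order on the full
    multivariate system.
    """
    series = concatenate_segments(per_subject_series, node_names,
                                  order_reserve=max_order, condition=condition)
    if order == "bic":
        p = select_order_bic(series, max_order)
    else:
        p = int(order)
    tester = pairwise_granger if mode == "pairwise" else conditional_granger
    edges = tester(series, p)
    graph = build_causal_graph(edges, q, nodes=series.node_names, condition=condition)
    return graph, edges, p
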
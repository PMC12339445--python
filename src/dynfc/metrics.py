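"""Static and dynamic functional-connectivity metrics.

Four metrics summarise a (simulated or empirical) BOLD run:

* **sFC** — static functional connectivity: Fisher-z Pearson correlation
  between each pair of regional time courses over the whole scan.
* **FCV** — FC variance: per-pair sample variance of the sliding-window FC
  across windows, capturing temporal variability of each connection.
* **TC** — temporal correlation: per-node consistency of its binarized-graph
  neighbourhood between consecutive windows (1 = static neighbourhood,
  0 = fully reshuffled).
* **NC** — node cohesion: per-pair count of windows at which the two regions
  switch communities together.

Windowed FC uses a tapered sliding window (rectangle convolved with a
Gaussian), the dynamic graph keeps the top fraction of connectivities per
window, and communities come from seeded per-window Louvain modularity with
greedy Jaccard label matching across windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.stats import norm

from .connectomes import BoldSeries

__all__ = [
    "SlidingWindowSpec",
    "FCMetricSet",
    "DynamicGraph",
    "CommunitySequence",
    "static_fc",
    "sliding_window_fc",
    "fc_variance",
    "binarize_dynamic",
    "temporal_correlation",
    "detect_communities",
    "node_cohesion",
    "global_efficiency",
    "node_graph_metrics",
    "compute_metrics",
    "average_metric_sets",
]

#: Fisher z of a correlation of exactly +-1 is clipped at arctanh(1 - 1e-7).
_FISHER_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Sliding-window geometry: ~60 s tapered windows sliding by 2 s."""

    window_length: float = 60.0
    step: float = 2.0
    taper_sigma: float = 6.0
    tr: float = 0.72

    def __post_init__(self) -> None:
        if not (self.window_length > self.step > 0):
            raise ValueError("need window_length > step > 0")
        if self.taper_sigma <= 0:
            raise ValueError("taper_sigma must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    def n_windows(self, n_samples: int) -> int:
        total = n_samples * self.tr
        if total < self.window_length:
            raise ValueError("series shorter than one window")
        return int(np.floor((total - self.window_length) / self.step)) + 1


@dataclass(frozen=True)
class FCMetricSet:
    """One subject's (or simulation's) sFC, FCV, TC, and NC.

    Any subset may be absent (``None``) when only part of the battery was
    requested, e.g. when fitting on sFC and TC alone.
    """

    sfc: np.ndarray | None = None
    fcv: np.ndarray | None = None
    tc: np.ndarray | None = None
    nc: np.ndarray | None = None


@dataclass(frozen=True)
class DynamicGraph:
    """Binary windowed graph: (W, N, N) boolean adjacency at fixed density."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, bool)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("adjacency must be (W, N, N)")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_windows(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[1]


@dataclass(frozen=True)
class CommunitySequence:
    """Integer community labels per window and node: (W, N)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        l = np.asarray(self.labels, dtype=np.int64)
        if l.ndim != 2:
            raise ValueError("labels must be (W, N)")
        object.__setattr__(self, "labels", l)


def _as_data(series) -> np.ndarray:
    if isinstance(series, BoldSeries):
        return series.data
    return np.asarray(series, float)


def static_fc(series, fisher: bool = True) -> np.ndarray:
    """Pairwise Pearson correlation over the whole scan, diagonal zeroed.

    With ``fisher`` the off-diagonal entries are arctanh-transformed
    (variance-stabilised), clipping |r| at 1 - 1e-7 first.
    """
    data = _as_data(series)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance regions: {dead.tolist()}")
    r = np.corrcoef(data, rowvar=False)
    if fisher:
        r = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
    np.fill_diagonal(r, 0.0)
    return r


def window_weights(spec: SlidingWindowSpec) -> np.ndarray:
    """Tapered window profile: rectangle convolved with a Gaussian.

    Returned in samples (length = round(window_length / tr)), normalised to
    sum one.  A very large ``taper_sigma`` approaches uniform weights.
    """
    L = int(round(spec.window_length / spec.tr))
    sig = spec.taper_sigma / spec.tr  # in samples
    # (rect * gauss)(t) = Phi((t - 0) / sig) - Phi((t - L) / sig), evaluated
    # at the window's own sample positions (the central L points).
    t = np.arange(L) + 0.5
    w = norm.cdf(t / sig) - norm.cdf((t - L) / sig)
    return w / w.sum()


def _weighted_corr(data: np.ndarray, w: np.ndarray) -> np.ndarray:
    mu = w @ data
    xc = data - mu
    cov = (xc * w[:, None]).T @ xc
    sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    return cov / np.outer(sd, sd)


def sliding_window_fc(series, spec: SlidingWindowSpec | None = None) -> np.ndarray:
    """Windowed FC: (W, N, N) tapered weighted Pearson correlations.

    W = floor((T*tr - window_length) / step) + 1 windows; window w starts at
    sample floor(w*step / tr).
    """
    spec = spec or SlidingWindowSpec()
    data = _as_data(series)
    if isinstance(series, BoldSeries) and abs(series.tr - spec.tr) > 1e-12:
        raise ValueError("spec.tr does not match the series tr")
    T, N = data.shape
    W = spec.n_windows(T)
    L = int(round(spec.window_length / spec.tr))
    w = window_weights(spec)
    out = np.empty((W, N, N))
    for k in range(W):
        start = int(np.floor(k * spec.step / spec.tr))
        stop = min(start + L, T)
        seg = data[start:stop]
        out[k] = _weighted_corr(seg, w[: stop - start] / w[: stop - start].sum())
        np.fill_diagonal(out[k], 1.0)
    return out


def fc_variance(window_fc: np.ndarray) -> np.ndarray:
    """Per-pair sample variance (ddof=1) of windowed FC across windows."""
    window_fc = np.asarray(window_fc, float)
    if window_fc.shape[0] < 2:
        raise ValueError("need at least 2 windows for a variance")
    out = np.var(window_fc, axis=0, ddof=1)
    np.fill_diagonal(out, 0.0)
    return out


def binarize_dynamic(window_fc: np.ndarray, density: float = 0.10) -> DynamicGraph:
    """Binarize windowed FC keeping the top ``density`` fraction per window.

    Exactly floor(density * N(N-1)/2) upper-triangle pairs become edges in
    every window; ties are broken by value, then (i, j) lexicographic order,
    so the result is deterministic.
    """
    if not (0 < density < 1):
        raise ValueError("density must lie in (0, 1)")
    window_fc = np.asarray(window_fc, float)
    W, N, _ = window_fc.shape
    iu, ju = np.triu_indices(N, k=1)
    k = int(np.floor(density * iu.size))
    adj = np.zeros((W, N, N), dtype=bool)
    for t in range(W):
        vals = window_fc[t, iu, ju]
        order = np.lexsort((ju, iu, -vals))[:k]
        adj[t, iu[order], ju[order]] = True
        adj[t, ju[order], iu[order]] = True
    return DynamicGraph(adjacency=adj, density=density)


def temporal_correlation(g: DynamicGraph) -> np.ndarray:
    """Per-node neighbourhood persistence between consecutive windows.

    C_i = mean over t of |N_i(t) & N_i(t+1)| / sqrt(deg_i(t) * deg_i(t+1)),
    with a term counted as 0 whenever node i is isolated at t or t+1.
    Bounded in [0, 1]; 1 means a time-constant neighbourhood.
    """
    A = g.adjacency.astype(float)
    if A.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    overlap = np.einsum("tij,tij->ti", A[:-1], A[1:])
    deg = A.sum(axis=2)
    denom = np.sqrt(deg[:-1] * deg[1:])
    terms = np.divide(overlap, denom, out=np.zeros_like(overlap), where=denom > 0)
    return terms.mean(axis=0)


def _match_labels(prev: np.ndarray, groups: list[set], next_label: int) -> tuple[np.ndarray, int]:
    # Greedy maximal-Jaccard matching of this window's communities onto the
    # previous window's labels; ties resolved toward the smaller label.
    prev_groups: dict[int, set] = {}
    for node, lab in enumerate(prev):
        prev_groups.setdefault(int(lab), set()).add(node)
    candidates = []
    for gi, nodes in enumerate(groups):
        for lab, pnodes in prev_groups.items():
            inter = len(nodes & pnodes)
            if inter:
                jac = inter / len(nodes | pnodes)
                candidates.append((-jac, lab, gi))
    candidates.sort()
    out = np.full(len(prev), -1, dtype=np.int64)
    used_labels: set[int] = set()
    assigned: set[int] = set()
    for neg_jac, lab, gi in candidates:
        if gi in assigned or lab in used_labels:
            continue
        assigned.add(gi)
        used_labels.add(lab)
        for node in groups[gi]:
            out[node] = lab
    for gi, nodes in enumerate(groups):
        if gi not in assigned:
            for node in nodes:
                out[node] = next_label
            next_label += 1
    return out, next_label


def detect_communities(g: DynamicGraph, seed: int = 0) -> CommunitySequence:
    """Per-window modularity communities with cross-window label matching.

    Each window is partitioned independently by greedy (CNM) modularity
    maximisation — chosen over Louvain because it terminates on every
    graph and is fully deterministic, making ``seed`` irrelevant to the
    result (the argument is kept so callers can treat the operation as
    seeded). Isolated nodes become singletons.  Labels are propagated
    across consecutive windows by greedy maximal-Jaccard matching so a
    persisting community keeps its label and genuinely new communities get
    fresh ones.
    """
    W, N = g.n_windows, g.n_nodes
    labels = np.zeros((W, N), dtype=np.int64)
    next_label = 0
    prev = None
    for t in range(W):
        G = nx.from_numpy_array(g.adjacency[t].astype(int))
        if G.number_of_edges() == 0:
            comms = [{n} for n in range(N)]
        else:
            comms = nx.community.greedy_modularity_communities(G)
        groups = [set(c) for c in sorted(comms, key=lambda c: min(c))]
        if prev is None:
            for gi, nodes in enumerate(groups):
                for node in nodes:
                    labels[0, node] = gi
            next_label = len(groups)
        else:
            labels[t], next_label = _match_labels(prev, groups, next_label)
        prev = labels[t]
    return CommunitySequence(labels=labels)


def node_cohesion(cs: CommunitySequence) -> np.ndarray:
    """Count of co-switches: windows at which a pair moves together.

    nc[i, j] counts consecutive window pairs where i and j share a community
    before and after the transition and that community label changes.
    """
    lab = cs.labels
    if lab.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    W, N = lab.shape
    nc = np.zeros((N, N), dtype=np.int64)
    for t in range(W - 1):
        a, b = lab[t], lab[t + 1]
        together_before = a[:, None] == a[None, :]
        together_after = b[:, None] == b[None, :]
        switched = (a != b)[:, None] & (a != b)[None, :]
        co = together_before & together_after & switched
        nc += co
    np.fill_diagonal(nc, 0)
    return nc


def global_efficiency(fc: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered region pairs.

    Positive entries act as edges with distance 1/weight; disconnected pairs
    contribute 0 (1/inf).
    """
    fc = np.asarray(fc, float)
    n = fc.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions")
    with np.errstate(divide="ignore"):
        dist = np.where(fc > 0, 1.0 / np.where(fc > 0, fc, 1.0), np.inf)
    np.fill_diagonal(dist, 0.0)
    sp = shortest_path(dist, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(sp[off]), 0.0, 1.0 / sp[off])
    return float(inv.mean())


def node_graph_metrics(matrix: np.ndarray, kind: str = "weights"):
    """Per-node degree (strength), betweenness, and closeness centrality.

    ``kind='fc'`` drops negative entries first (correlation matrices);
    betweenness and closeness use distance = 1/weight, betweenness is
    normalised.  Returns a dict of N-vectors.
    """
    m = np.asarray(matrix, float).copy()
    if kind == "fc":
        m[m < 0] = 0.0
    elif np.any(m < 0):
        raise ValueError("negative entries in a structural matrix")
    np.fill_diagonal(m, 0.0)
    n = m.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(m, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(int(i), int(j), weight=m[i, j], distance=1.0 / m[i, j])
    degree = m.sum(axis=1)
    bc = nx.betweenness_centrality(G, weight="distance", normalized=True)
    cc = nx.closeness_centrality(G, distance="distance")
    return {
        "degree": degree,
        "betweenness": np.array([bc[i] for i in range(n)]),
        "closeness": np.array([cc[i] for i in range(n)]),
    }


_ALL_METRICS = ("sfc", "fcv", "tc", "nc")


def compute_metrics(
    series,
    spec: SlidingWindowSpec | None = None,
    density: float = 0.10,
    seed: int = 0,
    include: Sequence[str] = _ALL_METRICS,
) -> FCMetricSet:
    """Compute the requested metric battery for one BOLD run."""
    unknown = set(include) - set(_ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    spec = spec or SlidingWindowSpec()
    out: dict[str, np.ndarray | None] = {m: None for m in _ALL_METRICS}
    if "sfc" in include:
        out["sfc"] = static_fc(series, fisher=True)
    if {"fcv", "tc", "nc"} & set(include):
        wfc = sliding_window_fc(series, spec)
        if "fcv" in include:
            out["fcv"] = fc_variance(wfc)
        if {"tc", "nc"} & set(include):
            g = binarize_dynamic(wfc, density=density)
            if "tc" in include:
                out["tc"] = temporal_correlation(g)
            if "nc" in include:
                out["nc"] = node_cohesion(detect_communities(g, seed=seed)).astype(float)
    return FCMetricSet(**out)


def _mean_or_none(arrays: list) -> np.ndarray | None:
    if any(a is None for a in arrays):
        if not all(a is None for a in arrays):
            raise ValueError("inconsistent metric availability across sets")
        return None
    return np.mean(arrays, axis=0)


def average_metric_sets(sets: Iterable[FCMetricSet]) -> FCMetricSet:
    """Element-wise mean of metric sets (e.g. the two scan sessions)."""
    sets = list(sets)
    if not sets:
        raise ValueError("no metric sets to average")
    return FCMetricSet(
        sfc=_mean_or_none([s.sfc for s in sets]),
        fcv=_mean_or_none([s.fcv for s in sets]),
        tc=_mean_or_none([s.tc for s in sets]),
        nc=_mean_or_none([s.nc for s in sets]),
    )
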
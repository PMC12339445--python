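"""Univariate association of model outcomes with FC features across subjects.

Each subject contributes four fitted parameters (G, J_N, J_i, w_p) and four
fit correlations from the combined-criterion winner; features are either
the sFC of every region pair (N(N-1)/2 edges, row-major strict upper
triangle) or the TC of every region.  Significance comes from permutation
nulls (the outcome vector is permuted over subjects, features stay fixed),
p-values are Benjamini-Hochberg FDR-adjusted within each outcome-by-family
block, and results are summarised over the seven canonical resting-state
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectomes import CANONICAL_NETWORKS, Parcellation

__all__ = [
    "FeatureTable",
    "edge_feature_table",
    "node_feature_table",
    "correlate_features",
    "permutation_pvalues",
    "fdr_adjust",
    "summarize_by_rsn",
    "group_compare",
    "association_table",
]

OUTCOME_COLUMNS = ("G", "J_N", "J_i", "w_p", "r_sfc", "r_fcv", "r_tc", "r_nc")


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x features matrix with a feature kind and labels.

    ``kind='edge_sfc'`` columns follow the row-major strict upper triangle
    of the N x N sFC matrix (so the 2415-edge indexing at N=70 is
    reproducible); ``kind='node_tc'`` columns are regions in order.
    """

    values: np.ndarray
    kind: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("values must be subjects x features")
        if len(self.labels) != v.shape[1]:
            raise ValueError("label count does not match feature count")
        if self.kind not in ("edge_sfc", "node_tc"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def edge_feature_table(sfc_matrices: Sequence[np.ndarray]) -> FeatureTable:
    """Stack per-subject sFC matrices into an edge feature table."""
    mats = [np.asarray(m, float) for m in sfc_matrices]
    n = mats[0].shape[0]
    iu, ju = np.triu_indices(n, k=1)
    values = np.stack([m[iu, ju] for m in mats])
    labels = tuple(f"edge_{i}_{j}" for i, j in zip(iu, ju))
    return FeatureTable(values=values, kind="edge_sfc", labels=labels)


def node_feature_table(tc_vectors: Sequence[np.ndarray]) -> FeatureTable:
    """Stack per-subject TC vectors into a node feature table."""
    values = np.stack([np.asarray(v, float) for v in tc_vectors])
    labels = tuple(f"node_{i}" for i in range(values.shape[1]))
    return FeatureTable(values=values, kind="node_tc", labels=labels)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    return (x - mu), sd


def correlate_features(outcome: np.ndarray, features: FeatureTable) -> np.ndarray:
    """Pearson r of the outcome with every feature column.

    Constant columns yield NaN (undefined correlation) rather than failing:
    downstream FDR treats them as missing.
    """
    y = np.asarray(outcome, float)
    X = features.values
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome and features disagree on subject count")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    yc, ysd = _standardize(y[:, None])
    Xc, xsd = _standardize(X)
    n = y.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc).sum(axis=0) / (n * xsd * ysd[0])
    r[xsd == 0] = np.nan
    return r


def permutation_pvalues(
    outcome: np.ndarray,
    features: FeatureTable,
    n_perm: int = 100_000,
    seed: int = 0,
    block: int = 2000,
) -> np.ndarray:
    """Two-sided permutation p-values for every outcome-feature correlation.

    The outcome is permuted over subjects ``n_perm`` times (one shared
    permutation stream across all features), the correlation recomputed, and
    p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1) — the add-one estimator,
    never exactly zero.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    y = np.asarray(outcome, float)
    X = features.values
    r_obs = correlate_features(y, features)
    rng = np.random.default_rng(seed)
    n = y.shape[0]
    Xc, xsd = _standardize(X)
    ok = xsd > 0
    Z = np.zeros_like(Xc)
    Z[:, ok] = Xc[:, ok] / (xsd[ok] * n)
    yz = (y - y.mean()) / y.std()
    exceed = np.zeros(X.shape[1], dtype=np.int64)
    thresh = np.abs(r_obs)
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perms = np.empty((n, m))
        for k in range(m):
            perms[:, k] = yz[rng.permutation(n)]
        r_null = Z.T @ perms  # features x m
        exceed += (np.abs(r_null) >= thresh[:, None] - 1e-12).sum(axis=1)
        done += m
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[~ok] = np.nan
    return p


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1).

    NaN entries (undefined correlations) pass through as NaN and do not
    count toward the number of tests.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values outside [0, 1]")
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def _network_index(parc: Parcellation) -> np.ndarray:
    order = {net: k for k, net in enumerate(CANONICAL_NETWORKS)}
    return np.array([order[n] for n in parc.rsn_assignment])


def summarize_by_rsn(
    values: np.ndarray,
    q: np.ndarray,
    parc: Parcellation,
    kind: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Average significant values within networks (nodes) or network pairs.

    Values with q >= alpha (or NaN) are set to 0 first, then averaged per
    network (``kind='node_tc'``: a 1 x 7 frame) or per unordered network
    pair (``kind='edge_sfc'``: a symmetric 7 x 7 frame).
    """
    values = np.asarray(values, float)
    q = np.asarray(q, float)
    if values.shape != q.shape:
        raise ValueError("values and q-values must align")
    masked = np.where(np.isnan(q) | (q >= alpha), 0.0, values)
    net_idx = _network_index(parc)
    n_net = len(CANONICAL_NETWORKS)
    if kind == "node_tc":
        if values.size != parc.n_regions:
            raise ValueError("node values do not match the parcellation")
        sums = np.zeros(n_net)
        counts = np.zeros(n_net)
        np.add.at(sums, net_idx, masked)
        np.add.at(counts, net_idx, 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), 0.0)
        return pd.DataFrame([means], columns=list(CANONICAL_NETWORKS))
    if kind == "edge_sfc":
        n = parc.n_regions
        iu, ju = np.triu_indices(n, k=1)
        if values.size != iu.size:
            raise ValueError("edge values do not match the parcellation")
        sums = np.zeros((n_net, n_net))
        counts = np.zeros((n_net, n_net))
        a = np.minimum(net_idx[iu], net_idx[ju])
        b = np.maximum(net_idx[iu], net_idx[ju])
        np.add.at(sums, (a, b), masked)
        np.add.at(counts, (a, b), 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), 0.0)
        means = means + np.triu(means, k=1).T
        return pd.DataFrame(
            means, index=list(CANONICAL_NETWORKS), columns=list(CANONICAL_NETWORKS)
        )
    raise ValueError(f"unknown kind {kind!r}")


def group_compare(
    outcomes: pd.DataFrame, grouping: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Welch t-tests of every outcome between every pair of groups.

    ``outcomes`` is a subjects x outcomes frame (index = subject ids);
    ``grouping`` maps subject id to a category.  Every group needs at least
    two members.  Returns a long frame (outcome, group_a, group_b, t, p).
    """
    groups = pd.Series(grouping).reindex(outcomes.index)
    if groups.isna().any():
        raise ValueError("grouping missing for some subjects")
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 members: {list(small.index)}")
    rows = []
    for col in outcomes.columns:
        for a, b in combinations(sorted(counts.index), 2):
            xa = outcomes.loc[groups == a, col].to_numpy(float)
            xb = outcomes.loc[groups == b, col].to_numpy(float)
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"outcome": col, "group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def association_table(
    outcomes: pd.DataFrame,
    features: FeatureTable,
    n_perm: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format association results for every outcome column.

    For each outcome: per-feature Pearson r, permutation p, and BH-FDR q
    adjusted within that outcome-by-family block.  Seeds per outcome derive
    from ``seed`` in column order.
    """
    rows = []
    for k, col in enumerate(outcomes.columns):
        y = outcomes[col].to_numpy(float)
        if y.std() == 0:
            # a grid can pin an outcome to one value; no correlation defined
            for label in features.labels:
                rows.append(
                    {"outcome": col, "feature": label, "kind": features.kind,
                     "r": np.nan, "p": np.nan, "q": np.nan}
                )
            continue
        r = correlate_features(y, features)
        p = permutation_pvalues(y, features, n_perm=n_perm, seed=seed + k)
        q = fdr_adjust(p)
        for label, ri, pi, qi in zip(features.labels, r, p, q):
            rows.append(
                {"outcome": col, "feature": label, "kind": features.kind,
                 "r": ri, "p": pi, "q": qi}
            )
    return pd.DataFrame(rows)
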
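"""Brain-region cFos coactivation network analysis.

Downstream analysis of per-animal region x cFos-count tables (ClearMap
style exports): volcano statistics (Welch t per region, q-values by
Benjamini-Hochberg, pass rule fold change > 0 and -log10 p > 1.3),
within-group inter-regional correlation matrices, hierarchical modules
(average linkage on 1 - r), Louvain communities on the positive-weight
correlation graph, and a permutation test for between-group community
reorganization.

The reorganization statistic - one minus the normalized mutual
information between the two groups' community partitions, with a null
built by permuting animal group labels - is this package's formalization
of "significant community reorganization"; it is a design choice, not a
published formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats
from sklearn.metrics import normalized_mutual_info_score

from .stats import adjust_pvalues

__all__ = [
    "RegionCountMatrix",
    "CoactivationNetwork",
    "ReorganizationResult",
    "VOLCANO_NEGLOG10_P",
    "region_volcano",
    "region_correlation_matrix",
    "module_clustering",
    "louvain_communities",
    "community_reorganization",
]

#: -log10 p must exceed this for the volcano pass flag (p < 0.05).
VOLCANO_NEGLOG10_P = -np.log10(0.05)  # = 1.30...


@dataclass
class RegionCountMatrix:
    """Animals x regions cFos+ cell counts with group labels."""

    counts: pd.DataFrame  # index: animal ids, columns: region names
    groups: pd.Series  # animal id -> group label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("cFos counts must be non-negative")
        if self.counts.isna().to_numpy().any():
            raise ValueError("missing cells in count matrix")
        self.groups = self.groups.reindex(self.counts.index)
        if self.groups.isna().any():
            raise ValueError("every animal needs a group label")

    @property
    def regions(self) -> list[str]:
        return list(self.counts.columns)

    def group_counts(self, group: str) -> pd.DataFrame:
        sub = self.counts.loc[self.groups == group]
        if len(sub) == 0:
            raise KeyError(f"no animals in group {group!r}")
        return sub

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "RegionCountMatrix":
        """Build from a long table with columns animal, group, region, count."""
        counts = df.pivot(index="animal", columns="region", values="count")
        groups = df.drop_duplicates("animal").set_index("animal")["group"]
        return cls(counts=counts, groups=groups)


@dataclass
class CoactivationNetwork:
    """Correlation structure of one treatment group's region counts."""

    r: pd.DataFrame  # regions x regions correlation matrix
    group: str = ""
    dropped_regions: list[str] = field(default_factory=list)  # constant regions
    linkage: np.ndarray | None = None
    modules: pd.Series | None = None  # region -> module id (hierarchical)
    leaf_order: list[str] | None = None
    communities: pd.Series | None = None  # region -> Louvain community id
    modularity: float | None = None


def region_volcano(
    rcm: RegionCountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-region volcano statistics comparing two groups.

    Per region: Welch's unequal-variance t test of group_b vs group_a,
    Benjamini-Hochberg q-value across regions, and
    log2 fold change = log2((mean_b + 1) / (mean_a + 1)) (pseudo-count 1
    guards zero-count regions). The pass flag is exactly
    (fold change > 0) and (-log10 p > 1.3), i.e. an increase at p < 0.05.
    Regions with zero variance in both groups get an undefined p and
    never pass.
    """
    a = rcm.group_counts(group_a)
    b = rcm.group_counts(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 animals per group")
    rows = []
    for region in rcm.regions:
        xa, xb = a[region].to_numpy(float), b[region].to_numpy(float)
        fc = np.log2((xb.mean() + pseudocount) / (xa.mean() + pseudocount))
        if xa.std() == 0 and xb.std() == 0:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(xb, xa, equal_var=False)
        rows.append({"region": region, "log2_fc": fc, "t": t, "p": p})
    out = pd.DataFrame(rows)
    defined = out["p"].notna()
    q = np.full(len(out), np.nan)
    if defined.any():
        q[defined.to_numpy()] = adjust_pvalues(out.loc[defined, "p"].tolist(), method="bh")
    out["q"] = q
    with np.errstate(divide="ignore"):
        neglog = -np.log10(out["p"].to_numpy(float))
    out["neglog10_p"] = neglog
    out["passed"] = (out["log2_fc"] > 0) & (out["neglog10_p"] > VOLCANO_NEGLOG10_P)
    out["undefined"] = ~defined
    return out


def region_correlation_matrix(
    rcm: RegionCountMatrix, group: str, method: str = "pearson"
) -> CoactivationNetwork:
    """Pairwise inter-regional correlation across animals of one group.

    Constant regions have undefined correlations; they are dropped from
    the matrix and reported in ``dropped_regions``.
    """
    sub = rcm.group_counts(group)
    if len(sub) < 3:
        raise ValueError("need at least 3 animals for a correlation matrix")
    constant = [c for c in sub.columns if sub[c].nunique() == 1]
    sub = sub.drop(columns=constant)
    r = sub.corr(method=method)
    np.fill_diagonal(r.values, 1.0)
    return CoactivationNetwork(r=r, group=group, dropped_regions=constant)


def module_clustering(
    net: CoactivationNetwork, k: int = 4, linkage_method: str = "average"
) -> CoactivationNetwork:
    """Hierarchical modules from the correlation matrix.

    Agglomerative clustering on the distance 1 - r, tree cut at ``k``
    clusters; the matrix row/column order is the dendrogram leaf order
    (a pure permutation of the regions). Results are stored on the
    network and also returned.
    """
    regions = list(net.r.columns)
    if k > len(regions):
        raise ValueError(f"k={k} exceeds the {len(regions)} regions available")
    if net.r.isna().to_numpy().any():
        raise ValueError("correlation matrix has missing entries")
    dist = 1.0 - net.r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = ssd.squareform(dist, checks=False)
    Z = sch.linkage(condensed, method=linkage_method)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    order = sch.leaves_list(Z)
    net.linkage = Z
    net.modules = pd.Series(labels, index=regions, name="module")
    net.leaf_order = [regions[i] for i in order]
    return net


_IG_RNG = None


def _seed_igraph(seed: int) -> None:
    """Route igraph's internal randomness through a dedicated, seeded
    generator (it otherwise consumes the global ``random`` state)."""
    global _IG_RNG
    import random

    import igraph as ig

    if _IG_RNG is None:
        _IG_RNG = random.Random()
        ig.set_random_number_generator(_IG_RNG)
    _IG_RNG.seed(seed)


def _modularity_np(w: np.ndarray, member: np.ndarray) -> float:
    """Weighted Newman modularity of a membership vector on a dense
    symmetric weight matrix with zero diagonal."""
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    k = w.sum(axis=1)
    same = member[:, None] == member[None, :]
    return float((w[same].sum() - np.outer(k, k)[same].sum() / two_m) / two_m)


def _refine_membership(w: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Greedy single-node move refinement: move nodes between
    communities (or to a fresh one) while any move improves weighted
    modularity. Guarantees the returned partition is a single-move local
    optimum of Q."""
    member = member.copy()
    two_m = w.sum()
    if two_m == 0:
        return member
    k = w.sum(axis=1)
    for _ in range(200):  # safety bound; converges in a few sweeps
        labels, member = np.unique(member, return_inverse=True)
        n_comm = len(labels)
        onehot = np.zeros((len(member), n_comm + 1))
        onehot[np.arange(len(member)), member] = 1.0
        s = w @ onehot  # s[i, c] = weight from i into community c
        K = k @ onehot  # community strengths (empty slot appended)
        cur = member
        s_cur = s[np.arange(len(member)), cur]
        K_wo = K[cur] - k  # community strength without the node itself
        # gain of moving i into community c (vectorized over both)
        gain = (s - s_cur[:, None]) / (two_m / 2.0) - k[:, None] * (
            K[None, :] - K_wo[:, None]
        ) / (2.0 * (two_m / 2.0) ** 2)
        gain[np.arange(len(member)), cur] = 0.0
        i, c = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[i, c] <= 1e-12:
            break
        member[i] = c
    _, member = np.unique(member, return_inverse=True)
    return member


def _louvain_membership(
    w: np.ndarray, seed: int = 0, restarts: int = 10
) -> tuple[np.ndarray, float]:
    """Louvain partition of a dense non-negative weight matrix.

    Restarts permute the vertex order with a seeded generator and the
    partition with the best modularity Q is kept; igraph's own RNG is
    seeded per run, so the result is deterministic for fixed seed and
    node order."""
    import igraph as ig

    n = w.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    keep = w[ii, jj] > 0
    edges = list(zip(ii[keep].tolist(), jj[keep].tolist()))
    weights = w[ii, jj][keep].tolist()
    if not edges:
        return np.arange(n), 0.0
    rng = np.random.default_rng(seed)
    best_q, best_m = -np.inf, None
    for k in range(max(1, restarts)):
        order = np.arange(n) if k == 0 else rng.permutation(n)
        inv = np.empty(n, dtype=int)
        inv[order] = np.arange(n)
        g = ig.Graph(n=n, edges=[(inv[a], inv[b]) for a, b in edges])
        g.es["weight"] = weights
        _seed_igraph(seed * 7919 + k)
        member = np.asarray(g.community_multilevel(weights="weight").membership)[inv]
        member = _refine_membership(w, member)
        q = _modularity_np(w, member)
        if q > best_q:
            best_q = q
            best_m = member
    # canonical labels: communities numbered by first appearance
    _, canon = np.unique(best_m, return_inverse=True)
    first = {c: np.min(np.nonzero(canon == c)[0]) for c in np.unique(canon)}
    order_c = sorted(first, key=first.get)
    remap = {c: i for i, c in enumerate(order_c)}
    return np.array([remap[c] for c in canon]), float(best_q)


def _edge_weights(r: np.ndarray, edge_rule: str) -> np.ndarray:
    if edge_rule == "positive":
        w = np.clip(r, 0.0, None)
    elif edge_rule == "absolute":
        w = np.abs(r)
    else:
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 0.0)
    return w


def louvain_communities(
    net: CoactivationNetwork,
    edge_rule: str = "positive",
    seed: int = 0,
    restarts: int = 10,
) -> CoactivationNetwork:
    """Louvain community detection on the correlation graph.

    Each region is a node and each correlation an edge weight; by default
    negative correlations are clipped to zero (standard weighted
    modularity is defined for non-negative weights; ``edge_rule=
    "absolute"`` is available). Louvain is run ``restarts`` times with
    seeds derived from ``seed`` and the partition with the best
    modularity Q is kept, with nodes in sorted order for reproducible
    tie-breaking. Deterministic for fixed seed and node order.
    """
    if len(net.r.columns) == 0:
        raise ValueError("empty graph")
    w = _edge_weights(net.r.to_numpy(float), edge_rule)
    member, q = _louvain_membership(w, seed=seed, restarts=restarts)
    net.communities = pd.Series(member, index=net.r.columns, name="community")
    net.modularity = q
    return net


@dataclass
class ReorganizationResult:
    """Between-group community reorganization test."""

    score: float  # consensus co-membership distance between groups
    p_value: float
    nmi_score: float  # 1 - NMI between the two groups' hard partitions
    changed_regions: pd.Series  # region -> bool, membership changed
    null_scores: np.ndarray
    network_a: CoactivationNetwork
    network_b: CoactivationNetwork


def _partition_labels(
    counts: pd.DataFrame, method: str, edge_rule: str, seed: int, restarts: int
) -> pd.Series:
    constant = [c for c in counts.columns if counts[c].nunique() == 1]
    r = counts.drop(columns=constant).corr(method=method)
    net = CoactivationNetwork(r=r)
    louvain_communities(net, edge_rule=edge_rule, seed=seed, restarts=restarts)
    return net.communities.reindex(counts.columns)  # NaN for dropped regions


def _match_partitions(lab_a: pd.Series, lab_b: pd.Series) -> pd.Series:
    """Align partition b's labels to a by maximum overlap, then flag
    regions whose aligned community membership changed."""
    from scipy.optimize import linear_sum_assignment

    common = lab_a.dropna().index.intersection(lab_b.dropna().index)
    a = lab_a[common].astype(int)
    b = lab_b[common].astype(int)
    ca, cb = sorted(a.unique()), sorted(b.unique())
    overlap = np.zeros((len(ca), len(cb)))
    for i, x in enumerate(ca):
        for j, y in enumerate(cb):
            overlap[i, j] = ((a == x) & (b == y)).sum()
    ri, cj = linear_sum_assignment(-overlap)
    mapping = {cb[j]: ca[i] for i, j in zip(ri, cj)}
    b_aligned = b.map(lambda y: mapping.get(y, -1))
    changed = (a != b_aligned).reindex(lab_a.index, fill_value=True)
    return changed


def _corr_np(x: np.ndarray) -> np.ndarray:
    """Pearson correlation across rows (animals) of an animals x regions
    array; constant regions yield zero rows/columns."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    r = (xc / sd_safe).T @ (xc / sd_safe) / len(x)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    return r


def _consensus_comembership(
    x: np.ndarray,
    seed: int,
    n_subsamples: int,
    subsample_fraction: float,
    edge_rule: str,
) -> np.ndarray:
    """Co-membership frequency matrix over Louvain partitions of animal
    subsamples: entry (i, j) is the fraction of subsamples in which
    regions i and j fall in the same community.

    The subsample index sequence is a pure function of ``seed`` and the
    group size, so two identical groups scored with the same seed yield
    identical matrices (paired subsampling)."""
    rng = np.random.default_rng(seed)
    n_animals, n_regions = x.shape
    k = max(3, int(round(subsample_fraction * n_animals)))
    co = np.zeros((n_regions, n_regions))
    for _ in range(n_subsamples):
        sub = x[rng.choice(n_animals, size=k, replace=False)]
        w = _edge_weights(_corr_np(sub), edge_rule)
        member, _ = _louvain_membership(w, restarts=1)
        co += member[:, None] == member[None, :]
    return co / n_subsamples


def community_reorganization(
    rcm: RegionCountMatrix,
    group_a: str,
    group_b: str,
    n_permutations: int = 1000,
    method: str = "pearson",
    edge_rule: str = "positive",
    seed: int = 0,
    restarts: int = 10,
    n_subsamples: int = 32,
    subsample_fraction: float = 0.7,
) -> ReorganizationResult:
    """Permutation test for community reorganization between groups.

    For each group a consensus co-membership matrix is built: Louvain
    partitions over seeded animal subsamples, averaged into the
    frequency with which every region pair shares a community. The
    reorganization score is the mean absolute difference between the
    two groups' co-membership matrices over region pairs (0 = identical
    community structure, 1 = fully reorganized). A consensus over
    subsamples is used rather than the two hard partitions because a
    hard-partition distance saturates: when the pooled data supports two
    near-tied merges, label-permuted halves occasionally adopt opposite
    merges and produce maximal null scores regardless of sample size.
    The co-membership frequencies degrade continuously instead.

    The null distribution is built by permuting animal group labels
    (preserving group sizes) and recomputing both consensus matrices;
    p = (1 + #{null >= observed}) / (n_permutations + 1).

    Also reported: ``nmi_score`` (1 - NMI between the two groups' hard
    Louvain partitions) and per-region change flags from the hard
    partitions aligned by maximal overlap.
    """
    import warnings

    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives a coarse p-value", stacklevel=2)
    if method != "pearson":
        raise NotImplementedError("the permutation engine supports pearson only")
    a = rcm.group_counts(group_a).to_numpy(float)
    b = rcm.group_counts(group_b).to_numpy(float)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(a.shape[1], k=1)

    def score_of(xa: np.ndarray, xb: np.ndarray) -> float:
        # paired subsampling: same index sequence on both sides
        s = int(rng.integers(2**31))
        ca = _consensus_comembership(xa, s, n_subsamples, subsample_fraction, edge_rule)
        cb = _consensus_comembership(xb, s, n_subsamples, subsample_fraction, edge_rule)
        return float(np.mean(np.abs(ca - cb)[iu]))

    obs = score_of(a, b)
    pooled = np.vstack([a, b])
    n_a = len(a)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(pooled))
        null[i] = score_of(pooled[perm[:n_a]], pooled[perm[n_a:]])
    p = (1.0 + np.sum(null >= obs - 1e-12)) / (n_permutations + 1.0)

    lab_a = _partition_labels(rcm.group_counts(group_a), method, edge_rule, seed, restarts)
    lab_b = _partition_labels(rcm.group_counts(group_b), method, edge_rule, seed + 1, restarts)
    common = lab_a.dropna().index.intersection(lab_b.dropna().index)
    nmi = normalized_mutual_info_score(lab_a[common].astype(int), lab_b[common].astype(int))
    changed = _match_partitions(lab_a, lab_b)
    net_a = region_correlation_matrix(rcm, group_a, method)
    louvain_communities(net_a, edge_rule=edge_rule, seed=seed, restarts=restarts)
    net_b = region_correlation_matrix(rcm, group_b, method)
    louvain_communities(net_b, edge_rule=edge_rule, seed=seed + 1, restarts=restarts)
    return ReorganizationResult(
        score=obs,
        p_value=float(p),
        nmi_score=float(1.0 - nmi),
        changed_regions=changed,
        null_scores=null,
        network_a=net_a,
        network_b=net_b,
    )
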
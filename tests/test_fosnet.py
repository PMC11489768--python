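"""Volcano stats, correlation networks, modules, communities, reorganization."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nicocircuit import synth
from nicocircuit.fosnet import (
    VOLCANO_NEGLOG10_P,
    CoactivationNetwork,
    RegionCountMatrix,
    community_reorganization,
    louvain_communities,
    module_clustering,
    region_correlation_matrix,
    region_volcano,
)

REGIONS = [f"R{i:02d}" for i in range(10)]
MODULES = [REGIONS[:5], REGIONS[5:]]


def rcm_from_arrays(a, b, regions=None):
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    regions = regions or [f"R{i}" for i in range(a.shape[1])]
    counts = pd.DataFrame(
        np.vstack([a, b]),
        index=[f"A{i}" for i in range(len(a))] + [f"B{i}" for i in range(len(b))],
        columns=regions,
    )
    groups = pd.Series(["SAC"] * len(a) + ["NIC"] * len(b), index=counts.index)
    return RegionCountMatrix(counts=counts, groups=groups)


class TestVolcano:
    def test_pass_rule_exact(self):
        """Pass iff fold change > 0 and -log10 p > 1.3 (p < 0.05)."""
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(6, 3)).astype(float)
        up = base.copy()
        up[:, 0] *= 3.0  # strong increase: passes
        up[:, 1] *= 0.3  # decrease: fc <= 0, never passes
        rcm = rcm_from_arrays(base, up)
        out = region_volcano(rcm, "SAC", "NIC").set_index("region")
        assert bool(out.loc["R0", "passed"])
        assert not bool(out.loc["R1", "passed"])
        # the flag is exactly the stated conjunction, bit-reproducible
        expected = (out["log2_fc"] > 0) & (out["neglog10_p"] > VOLCANO_NEGLOG10_P)
        assert (out["passed"] == expected).all()

    def test_identical_groups_never_pass(self):
        x = np.tile([[100.0, 200.0, 300.0]], (5, 1)) + np.arange(5)[:, None]
        out = region_volcano(rcm_from_arrays(x, x), "SAC", "NIC")
        assert np.allclose(out["log2_fc"], 0.0)
        assert (out["p"] > 0.9).all()
        assert not out["passed"].any()

    def test_zero_variance_region_flagged_undefined(self):
        a = np.column_stack([np.full(5, 10.0), np.arange(5.0)])
        b = np.column_stack([np.full(5, 10.0), np.arange(5.0) + 3])
        out = region_volcano(rcm_from_arrays(a, b), "SAC", "NIC").set_index("region")
        assert bool(out.loc["R0", "undefined"])
        assert not bool(out.loc["R0", "passed"])

    def test_welch_t_matches_scipy_and_q_is_bh(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a, b = rng.poisson(80, (6, 8)).astype(float), rng.poisson(95, (7, 8)).astype(float)
        out = region_volcano(rcm_from_arrays(a, b), "SAC", "NIC")
        for j, row in out.iterrows():
            t, p = sps.ttest_ind(b[:, j], a[:, j], equal_var=False)
            assert row["p"] == pytest.approx(p)
        # BH step-up by hand
        p = out["p"].to_numpy()
        order = np.argsort(p)
        q_hand = np.empty_like(p)
        m = len(p)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q_hand[i] = running
        np.testing.assert_allclose(out["q"].to_numpy(), q_hand)


class TestCorrelationMatrix:
    def test_duplicated_region_correlates_perfectly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(100, 10, size=10)
        counts = np.column_stack([x, x, rng.normal(100, 10, size=10)])
        net = region_correlation_matrix(rcm_from_arrays(counts, counts + 1), "SAC")
        assert net.r.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_region_correlates_minus_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(100, 10, size=10)
        counts = np.column_stack([x, 200 - x])
        net = region_correlation_matrix(rcm_from_arrays(counts, counts), "SAC")
        assert net.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        rcm, _ = synth.gen_region_counts(20, REGIONS, MODULES, 0.5, seed=4)
        net = region_correlation_matrix(rcm, "NIC")
        r = net.r.to_numpy()
        np.testing.assert_allclose(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.all((r >= -1 - 1e-12) & (r <= 1 + 1e-12))

    def test_constant_region_dropped_and_flagged(self):
        rng = np.random.default_rng(5)
        counts = np.column_stack([np.full(8, 50.0), rng.normal(100, 10, (8, 2))])
        net = region_correlation_matrix(rcm_from_arrays(counts, counts), "SAC")
        assert net.dropped_regions == ["R0"]
        assert "R0" not in net.r.columns

    def test_planted_blocks_have_higher_within_correlation(self):
        rcm, _ = synth.gen_region_counts(100, REGIONS, MODULES, 0.8, seed=6)
        net = region_correlation_matrix(rcm, "SAC")
        within, between = [], []
        for a, b in itertools.combinations(REGIONS, 2):
            same = (a in MODULES[0]) == (b in MODULES[0])
            (within if same else between).append(net.r.loc[a, b])
        assert np.mean(within) > np.mean(between)


class TestModuleClustering:
    def test_two_perfect_blocks_recovered_exactly(self):
        rng = np.random.default_rng(7)
        f1, f2 = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        counts = np.column_stack([100 + 10 * f1] * 3 + [100 + 10 * f2] * 3)
        net = region_correlation_matrix(rcm_from_arrays(counts, counts), "SAC")
        module_clustering(net, k=2)
        labels = net.modules
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_k_equals_n_singletons_and_k_one_single_module(self):
        rcm, _ = synth.gen_region_counts(10, REGIONS, MODULES, 0.3, seed=8)
        net = region_correlation_matrix(rcm, "SAC")
        module_clustering(net, k=len(REGIONS))
        assert net.modules.nunique() == len(REGIONS)
        module_clustering(net, k=1)
        assert net.modules.nunique() == 1

    def test_k_above_n_rejected(self):
        rcm, _ = synth.gen_region_counts(5, REGIONS, MODULES, 0.3, seed=9)
        net = region_correlation_matrix(rcm, "SAC")
        with pytest.raises(ValueError):
            module_clustering(net, k=len(REGIONS) + 1)

    def test_leaf_order_is_permutation(self):
        rcm, _ = synth.gen_region_counts(10, REGIONS, MODULES, 0.5, seed=10)
        net = region_correlation_matrix(rcm, "SAC")
        module_clustering(net, k=4)
        assert sorted(net.leaf_order) == sorted(REGIONS)
        reordered = net.r.loc[net.leaf_order, net.leaf_order]
        assert np.allclose(np.sort(reordered.to_numpy().ravel()), np.sort(net.r.to_numpy().ravel()))


def modularity_bruteforce_best(g):
    """Exhaustive search of the max-modularity partition (<= 8 nodes)."""
    nodes = sorted(g.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] + [first]] + part[k + 1 :]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(p) for p in part], weight="weight")
        best = max(best, q)
    return best


class TestLouvain:
    def net_from_graph(self, g):
        nodes = sorted(g.nodes)
        r = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for u, v, d in g.edges(data=True):
            r.loc[u, v] = r.loc[v, u] = d.get("weight", 1.0)
        np.fill_diagonal(r.values, 1.0)
        return CoactivationNetwork(r=r)

    def test_two_cliques_joined_by_one_edge(self):
        g = nx.Graph()
        for base in (0, 4):
            for u, v in itertools.combinations(range(base, base + 4), 2):
                g.add_edge(f"n{u}", f"n{v}", weight=1.0)
        g.add_edge("n0", "n4", weight=1.0)
        net = louvain_communities(self.net_from_graph(g), seed=0)
        comm = net.communities
        assert comm[[f"n{u}" for u in range(4)]].nunique() == 1
        assert comm[[f"n{u}" for u in range(4, 8)]].nunique() == 1
        assert comm["n0"] != comm["n4"]
        assert net.modularity == pytest.approx(modularity_bruteforce_best(g), abs=1e-9)

    def test_q_never_below_singleton_partition(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = 7
            r = rng.uniform(-0.5, 1.0, size=(n, n))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            names = [f"n{i}" for i in range(n)]
            net = louvain_communities(
                CoactivationNetwork(r=pd.DataFrame(r, index=names, columns=names)), seed=1
            )
            g = nx.Graph()
            g.add_nodes_from(names)
            for i, j in itertools.combinations(range(n), 2):
                if r[i, j] > 0:
                    g.add_edge(names[i], names[j], weight=r[i, j])
            q_singleton = nx.community.modularity(
                g, [{x} for x in names], weight="weight"
            )
            assert net.modularity >= q_singleton - 1e-12

    def test_deterministic_under_fixed_seed(self):
        rcm, _ = synth.gen_region_counts(15, REGIONS, MODULES, 0.6, seed=12)
        n1 = louvain_communities(region_correlation_matrix(rcm, "SAC"), seed=5)
        n2 = louvain_communities(region_correlation_matrix(rcm, "SAC"), seed=5)
        assert n1.communities.equals(n2.communities)
        assert n1.modularity == n2.modularity

    def test_planted_modules_recovered_with_high_nmi(self):
        from sklearn.metrics import normalized_mutual_info_score

        rcm, gt = synth.gen_region_counts(100, REGIONS, MODULES, 0.8, seed=13)
        net = louvain_communities(region_correlation_matrix(rcm, "SAC"), seed=0)
        truth = [gt.params["module_of"][r] for r in net.r.columns]
        nmi = normalized_mutual_info_score(truth, net.communities[net.r.columns])
        assert nmi >= 0.9


class TestReorganization:
    def test_identical_tables_score_zero(self):
        rng = np.random.default_rng(14)
        counts = rng.poisson(100, size=(10, 6)).astype(float)
        rcm = rcm_from_arrays(counts, counts)
        res = community_reorganization(rcm, "SAC", "NIC", n_permutations=100, seed=0)
        assert res.score == pytest.approx(0.0)
        assert not res.changed_regions.any()

    def test_planted_module_swap_detected(self):
        """Group B moves 4 regions between the two planted modules: the
        permutation test flags the reorganization and the moved regions."""
        moved = {"R00", "R05", "R06", "R07"}
        swapped = [REGIONS[1:5] + REGIONS[5:8], [REGIONS[0]] + REGIONS[8:]]
        rcm_a, _ = synth.gen_region_counts(100, REGIONS, MODULES, 0.8, seed=115)
        rcm_b, _ = synth.gen_region_counts(100, REGIONS, swapped, 0.8, seed=116)
        counts = pd.concat(
            [rcm_a.group_counts("SAC"), rcm_b.group_counts("SAC").set_axis(
                [f"X{i}" for i in range(100)]
            )]
        )
        groups = pd.Series(["SAC"] * 100 + ["NIC"] * 100, index=counts.index)
        rcm = RegionCountMatrix(counts=counts, groups=groups)
        res = community_reorganization(rcm, "SAC", "NIC", n_permutations=199, seed=1)
        assert res.score > 0.2
        assert res.p_value < 0.05
        flagged = set(res.changed_regions[res.changed_regions].index)
        assert flagged == moved

    def test_low_permutation_count_warned(self):
        rng = np.random.default_rng(17)
        counts = rng.poisson(100, size=(12, 5)).astype(float)
        rcm = rcm_from_arrays(counts[:6], counts[6:])
        with pytest.warns(UserWarning):
            community_reorganization(rcm, "SAC", "NIC", n_permutations=50, seed=2)
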
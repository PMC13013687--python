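import itertools
import math

import networkx as nx
import numpy as np
import pytest

from nbsconn import (
    EdgeSet,
    build_design,
    component_effect_sizes,
    continuous_nbs,
    fdr_adjust,
    group_contrast,
    nbs_test,
    ordered_pattern_test,
    supra_threshold_components,
)
from nbsconn.glm import DesignMatrix


def random_instance(rng, n_nodes=12, n_edges=30):
    pairs = list(itertools.combinations(range(n_nodes), 2))
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    backbone = EdgeSet.from_pairs([pairs[k] for k in idx], n_nodes)
    stats = rng.normal(size=len(backbone)) * 2
    return backbone, stats


def nx_components(backbone, mask):
    """Oracle: connected components of the kept-edge graph via networkx."""
    g = nx.Graph()
    for (i, j), keep in zip(backbone.edges, mask):
        if keep:
            g.add_edge(int(i), int(j))
    comps = []
    for nodes in nx.connected_components(g):
        comps.append(frozenset(
            (int(i), int(j)) for (i, j), keep in zip(backbone.edges, mask)
            if keep and int(i) in nodes and int(j) in nodes))
    return set(comps)


class TestComponents:
    def test_all_subthreshold_gives_empty(self):
        bb = EdgeSet.from_pairs([(0, 1), (1, 2)], 3)
        assert supra_threshold_components(np.array([1.0, 2.0]), 4.0,
                                          "two_sided_F", bb) == []

    def test_path_graph_single_component(self):
        bb = EdgeSet.from_pairs([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)], 6)
        comps = supra_threshold_components(np.full(5, 9.0), 4.0, "two_sided_F", bb)
        assert len(comps) == 1 and len(comps[0]) == 5

    def test_matches_networkx_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            bb, stats = random_instance(rng)
            comps = supra_threshold_components(stats, 1.0, "greater", bb)
            mine = {frozenset(map(tuple, c.edges.tolist())) for c in comps}
            assert mine == nx_components(bb, stats > 1.0)
            # extents sorted descending
            extents = [len(c) for c in comps]
            assert extents == sorted(extents, reverse=True)

    def test_directions(self):
        bb = EdgeSet.from_pairs([(0, 1), (1, 2), (2, 3)], 4)
        t = np.array([2.5, -2.5, 0.5])
        up = supra_threshold_components(t, 2.0, "greater", bb)
        down = supra_threshold_components(t, 2.0, "less", bb)
        assert [tuple(e) for e in up[0].edges] == [(0, 1)]
        assert [tuple(e) for e in down[0].edges] == [(1, 2)]


def tiny_problem(n=6, n_edges=8, seed=0, effect=0.0):
    """n-subject two-group problem on a small graph for exhaustive tests."""
    rng = np.random.default_rng(seed)
    bb, _ = random_instance(rng, n_nodes=6, n_edges=n_edges)
    group = np.array([0, 1] * (n // 2))
    X = np.column_stack([np.ones(n), group.astype(float)])
    design = DesignMatrix(X, ("intercept", "group"), np.array([1]))
    Y = rng.normal(size=(n, len(bb)))
    Y[:, :3] += effect * group[:, None]
    return bb, design, Y


def oracle_exhaustive_p(Y, X_base, bb, threshold):
    """Independent oracle: per-edge OLS F over all label permutations, with
    components found by networkx, reporting the exact max-extent p."""
    n = Y.shape[0]

    def f_stats(group):
        X = np.column_stack([np.ones(n), group])
        F = np.empty(Y.shape[1])
        for e in range(Y.shape[1]):
            y = Y[:, e]
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            rss1 = np.sum((y - X @ b) ** 2)
            rss0 = np.sum((y - y.mean()) ** 2)
            F[e] = ((rss0 - rss1) / 1) / (rss1 / (n - 2))
        return F

    def max_extent(F):
        comps = nx_components(bb, F > threshold)
        return max((len(c) for c in comps), default=0)

    group0 = X_base[:, 1]
    obs = max_extent(f_stats(group0))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        count += max_extent(f_stats(group0[list(perm)])) >= obs
    return obs, count / total


class TestNBSTest:
    def test_exhaustive_permutation_equals_enumeration_oracle(self):
        """All-n! Monte Carlo equals independent exhaustive enumeration."""
        bb, design, Y = tiny_problem(n=6, seed=5, effect=1.5)
        res = nbs_test(Y, design, bb, threshold=2.0, direction="two_sided_F",
                       scheme="label", exhaustive=True)
        obs, p_oracle = oracle_exhaustive_p(Y, design.X, bb, threshold=2.0)
        assert res.observed_max_extent == obs
        assert res.n_perm == math.factorial(6)
        assert res.p_fwe[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_minimum_attainable_p(self):
        bb, design, Y = tiny_problem(n=8, seed=2, effect=8.0)
        K = 199
        res = nbs_test(Y, design, bb, threshold=2.0, n_perm=K, seed=0,
                       scheme="label")
        assert min(res.p_fwe) >= 1.0 / (K + 1)

    def test_p_invariant_to_edge_relabeling(self):
        bb, design, Y = tiny_problem(n=10, seed=3, effect=2.0)
        res = nbs_test(Y, design, bb, threshold=2.0, n_perm=150, seed=4)
        # consistently permute the backbone edge order and the Y columns
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(bb))
        inv_order = np.lexsort((bb.edges[perm][:, 1], bb.edges[perm][:, 0]))
        # EdgeSet enforces lexicographic order, so relabeled edges resort to
        # the same backbone; shuffle Y accordingly and expect identical p
        res2 = nbs_test(Y[:, perm][:, inv_order], design, bb, threshold=2.0,
                        n_perm=150, seed=4)
        assert np.array_equal(res.p_fwe, res2.p_fwe)

    def test_empty_backbone_rejected(self):
        _, design, Y = tiny_problem()
        empty = EdgeSet(np.empty((0, 2), dtype=int), 6)
        with pytest.raises(Exception, match="backbone"):
            nbs_test(Y[:, :0], design, empty, 2.0)

    def test_huge_threshold_gives_no_components(self):
        bb, design, Y = tiny_problem(n=10, seed=6)
        res = nbs_test(Y, design, bb, threshold=1e6, n_perm=100, seed=0)
        assert res.components == [] and len(res.p_fwe) == 0

    def test_low_n_perm_warns(self):
        bb, design, Y = tiny_problem(n=10, seed=7)
        with pytest.warns(UserWarning, match="n_perm"):
            nbs_test(Y, design, bb, threshold=2.0, n_perm=50, seed=0)


class TestOrderedPattern:
    def test_recovers_planted_conjunction(self, planted_dataset):
        d = planted_dataset
        res = ordered_pattern_test(
            d["Y"], d["design"], d["backbone"],
            group_contrast(d["design"], "MDD", "HC"),
            group_contrast(d["design"], "MDD_ANX", "HC"),
            threshold=1.962, n_perm=200, seed=1)
        assert res.components, "no pattern component found"
        found = set(map(tuple, res.components[0].edges.tolist()))
        planted = set(map(tuple, d["truth"].planted.edges.tolist()))
        jaccard = len(found & planted) / len(found | planted)
        assert jaccard >= 0.5
        assert res.p_fwe[0] <= 0.01

    def test_hypo_only_shift_yields_no_conjunction(self):
        from conftest import scaled_config
        from nbsconn import build_backbone, generate_dataset, stack_edges

        cfg = scaled_config(delta_hyper=0.0, delta_hypo=-0.8, seed=21)
        _, cohort, conns, truth = generate_dataset(cfg)
        bb = build_backbone(conns, 0.05)
        Y = stack_edges(conns, bb)
        design = build_design(cohort)
        res = ordered_pattern_test(
            Y, design, bb,
            group_contrast(design, "MDD", "HC"),
            group_contrast(design, "MDD_ANX", "HC"),
            threshold=1.962, n_perm=150, seed=2)
        assert res.observed_max_extent <= 3  # chance-level conjunctions only

    def test_retains_both_t_fields(self, planted_dataset):
        d = planted_dataset
        res = ordered_pattern_test(
            d["Y"], d["design"], d["backbone"],
            group_contrast(d["design"], "MDD", "HC"),
            group_contrast(d["design"], "MDD_ANX", "HC"),
            threshold=1.962, n_perm=100, seed=3)
        t_low, t_high = res.edge_stats
        assert t_low.values.shape == t_high.values.shape == (len(d["backbone"]),)


class TestFDR:
    def test_hand_computed_benjamini_hochberg(self):
        adj = fdr_adjust([0.01, 0.02, 0.9])
        assert adj == pytest.approx([0.03, 0.03, 0.9])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_stay_equal(self):
        adj = fdr_adjust([0.04, 0.04, 0.04])
        assert np.allclose(adj, 0.04)

    def test_empty_input(self):
        assert len(fdr_adjust([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 0.0])


class TestEffectSizes:
    def test_exact_one_sd_shift_gives_d_one(self):
        # two groups, component score separated by exactly 1 pooled SD
        n = 40
        groups = np.array(["HC"] * n + ["MDD"] * n)
        base = np.linspace(-1, 1, n)
        score = np.tile(base / base.std(ddof=1), 2)
        score[n:] += 1.0
        Y = score[:, None]
        bb = EdgeSet.from_pairs([(0, 1)], 2)
        X = np.column_stack([np.ones(2 * n), (groups == "MDD").astype(float)])
        design = DesignMatrix(X, ("intercept", "group_MDD"), np.array([1]))
        es = component_effect_sizes(Y, bb, bb, design, groups, pair=("MDD", "HC"))
        assert es["cohens_d"] == pytest.approx(1.0, abs=1e-10)

    def test_identical_groups_give_zero_effects(self):
        n = 30
        groups = np.array(["HC"] * n + ["MDD"] * n)
        score = np.tile(np.linspace(0, 1, n), 2)
        bb = EdgeSet.from_pairs([(0, 1)], 2)
        X = np.column_stack([np.ones(2 * n), (groups == "MDD").astype(float)])
        design = DesignMatrix(X, ("intercept", "group_MDD"), np.array([1]))
        es = component_effect_sizes(score[:, None], bb, bb, design, groups,
                                    pair=("MDD", "HC"))
        assert es["cohens_d"] == pytest.approx(0.0, abs=1e-10)
        assert es["partial_eta2"] == pytest.approx(0.0, abs=1e-10)

    def test_tiny_group_rejected(self):
        groups = np.array(["HC", "HC", "MDD"])
        bb = EdgeSet.from_pairs([(0, 1)], 2)
        X = np.column_stack([np.ones(3), (groups == "MDD").astype(float)])
        design = DesignMatrix(X, ("intercept", "group_MDD"), np.array([1]))
        with pytest.raises(ValueError, match="fewer than 2"):
            component_effect_sizes(np.zeros((3, 1)), bb, bb, design, groups,
                                   pair=("MDD", "HC"))

    def test_recovers_planted_component_d(self, planted_dataset):
        d = planted_dataset
        truth = d["truth"]
        es = component_effect_sizes(
            d["Y"], d["backbone"], truth.planted, d["design"],
            d["cohort"]["group"].to_numpy(), pair=("MDD_ANX", "HC"))
        expected = truth.expected_component_d("MDD_ANX")
        assert es["cohens_d"] == pytest.approx(expected, abs=0.35)


class TestContinuous:
    def test_score_coupled_edges_recovered(self, planted_dataset):
        d = planted_dataset
        design = build_design(d["cohort"], effect="continuous:stai_state")
        stage1, directed = continuous_nbs(
            d["Y"], design, d["backbone"], f_threshold=4.0, t_threshold=1.962,
            n_perm=150, seed=5, run_directed="always")
        assert "positive" in directed
        pos = directed["positive"]
        assert pos.components, "no positive-direction component"
        found = set(map(tuple, pos.components[0].edges.tolist()))
        coupled = set(map(tuple, d["truth"].anxiety_edges.edges.tolist()))
        assert len(found & coupled) / len(coupled) >= 0.5

    def test_perfectly_correlated_scores_identical_components(self, planted_dataset):
        d = planted_dataset
        cohort = d["cohort"].copy()
        cohort["double"] = 2.0 * cohort["stai_state"]
        res = []
        for score in ("stai_state", "double"):
            design = build_design(cohort, effect=f"continuous:{score}")
            stage1, _ = continuous_nbs(
                d["Y"], design, d["backbone"], 4.0, 1.962,
                n_perm=120, seed=6, run_directed="auto")
            res.append(stage1)
        a, b = res
        assert [c.edges.tolist() for c in a.components] == \
            [c.edges.tolist() for c in b.components]
        assert np.array_equal(a.p_fwe, b.p_fwe)

    def test_constant_score_rejected(self, planted_dataset):
        from nbsconn.glm import DesignError

        cohort = planted_dataset["cohort"].copy()
        cohort["flat"] = 1.0
        with pytest.raises(DesignError, match="constant"):
            build_design(cohort, effect="continuous:flat")
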
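import numpy as np
import pandas as pd
import pytest

from shredmod.compare import (homogeneity_index, hv_distance,
                              mean_homogeneity_by_height, pair_scores,
                              partition_score, robust_pairs)
from shredmod.fixtures import FixtureSpec, make_random
from shredmod.graph import build_graph
from shredmod.modularity import ModularityMatrix, build_modularity_matrix
from shredmod.partition import (GAParams, ModuleNode, PartitionTree,
                                hierarchical_partition, LINK_COMPONENT,
                                LINK_PARTITION)
from shredmod.shred import all_pairs_shred


def chain_tree(splits) -> PartitionTree:
    """Build a tree by nested binary partition splits [(left, right), ...].

    Each split applies to the first (left-most) module of the previous level.
    """
    counter = iter(range(100))
    root_members = tuple(sorted(set().union(*map(set, splits[0]))))
    root = ModuleNode(id=next(counter), members=root_members)
    node = root
    for left, right in splits:
        kids = [ModuleNode(id=next(counter), members=tuple(sorted(left)),
                           link_type=LINK_PARTITION, depth=node.depth + 1),
                ModuleNode(id=next(counter), members=tuple(sorted(right)),
                           link_type=LINK_PARTITION, depth=node.depth + 1)]
        node.children = kids
        node = kids[0]
    from shredmod.partition import _assign_heights
    _assign_heights(root)
    return PartitionTree(root=root)


class TestHomogeneity:
    def test_pure_module(self):
        m = ModuleNode(id=0, members=("a", "b", "c", "d"))
        assert homogeneity_index(m, {r: "TCA" for r in m.members}) == 1.0

    def test_modal_fraction(self):
        m = ModuleNode(id=0, members=tuple("abcde"))
        groups = {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g3"}
        assert homogeneity_index(m, groups) == pytest.approx(0.6)

    def test_tie_uses_modal_count(self):
        m = ModuleNode(id=0, members=tuple("abcd"))
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        assert homogeneity_index(m, groups) == pytest.approx(0.5)

    def test_missing_labels_default_unassigned(self):
        m = ModuleNode(id=0, members=("a", "b"))
        assert homogeneity_index(m, {}) == 1.0


class TestMeanHomogeneityByHeight:
    def test_matches_hand_computation(self):
        tree = chain_tree([ (("a", "b"), ("c", "d")), (("a",), ("b",)) ])
        groups = {"a": "x", "b": "y", "c": "x", "d": "x"}
        means = mean_homogeneity_by_height(tree, groups)
        # height 0: leaves {a}, {b} (1.0 each) and {c,d} (1.0) -> 1.0
        # height 1: {a,b} -> 0.5 ; height 2: root {a,b,c,d} -> 3/4
        assert means[0] == pytest.approx(1.0)
        assert means[1] == pytest.approx(0.5)
        assert means[2] == pytest.approx(0.75)

    def test_singleton_leaves_height_zero_pure(self):
        tree = chain_tree([ (("a",), ("b",)) ])
        groups = {"a": "x", "b": "y"}
        assert mean_homogeneity_by_height(tree, groups)[0] == 1.0


class TestPartitionScore:
    def test_immediate_separation_zero(self):
        tree = chain_tree([ (("a", "b"), ("c", "d")) ])
        assert partition_score(tree, "a", "c") == 0.0

    def test_together_in_terminal_module_gives_one(self):
        # a and b end in the same leaf at depth 1: Shared = 2, m = 1 -> H = 1
        tree = chain_tree([ (("a", "b"), ("c",)) ])
        assert partition_score(tree, "a", "b") == pytest.approx(1.0)

    def test_separated_at_final_split(self):
        # share root and the depth-1 module, separate at depth 2:
        # Shared = 2, m_i = m_j = 2 -> H = 0.5
        tree = chain_tree([ (("a", "b"), ("c",)), (("a",), ("b",)) ])
        assert partition_score(tree, "a", "b") == pytest.approx(0.5)

    def test_intermediate_value(self):
        # deepest shared module at depth 1, both terminal depth 2 -> H = 0.5
        tree = chain_tree([ (("a", "b", "c", "d"), ("e",)),
                            (("a", "b"), ("c", "d")) ])
        for kid in tree.root.children[0].children:
            left, right = kid.members
            kid.children = [
                ModuleNode(id=60 + ord(left), members=(left,),
                           link_type=LINK_PARTITION, depth=3),
                ModuleNode(id=70 + ord(right), members=(right,),
                           link_type=LINK_PARTITION, depth=3)]
        # terminal depths are now 3; deepest shared depth still 1
        assert partition_score(tree, "a", "c") == pytest.approx(
            1 * 0.5 * (1 / 3 + 1 / 3))

    def test_terminal_depth_zero_gives_zero(self):
        # b peels off as a disconnected component before any partition
        root = ModuleNode(id=0, members=("a", "b", "c"))
        comp1 = ModuleNode(id=1, members=("a", "c"), link_type=LINK_COMPONENT,
                           depth=0)
        comp2 = ModuleNode(id=2, members=("b",), link_type=LINK_COMPONENT,
                           depth=0)
        comp1.children = [
            ModuleNode(id=3, members=("a",), link_type=LINK_PARTITION, depth=1),
            ModuleNode(id=4, members=("c",), link_type=LINK_PARTITION, depth=1)]
        root.children = [comp1, comp2]
        tree = PartitionTree(root=root)
        assert partition_score(tree, "a", "b") == 0.0

    def test_component_links_do_not_inflate_score(self):
        # a red split between root and the black partitions must not push H
        # above 1 for pairs that stay together to full depth
        root = ModuleNode(id=0, members=("a", "b", "x"))
        comp = ModuleNode(id=1, members=("a", "b"), link_type=LINK_COMPONENT,
                          depth=0)
        iso = ModuleNode(id=2, members=("x",), link_type=LINK_COMPONENT, depth=0)
        comp.children = [
            ModuleNode(id=3, members=("a",), link_type=LINK_PARTITION, depth=1),
            ModuleNode(id=4, members=("b",), link_type=LINK_PARTITION, depth=1)]
        root.children = [comp, iso]
        tree = PartitionTree(root=root)
        assert partition_score(tree, "a", "b") == pytest.approx(0.0)

    def test_unknown_reaction_rejected(self):
        tree = chain_tree([ (("a",), ("b",)) ])
        with pytest.raises(KeyError):
            partition_score(tree, "a", "zzz")

    def test_h_in_unit_interval_on_random_trees(self):
        for seed in range(8):
            model, state, _ = make_random(
                FixtureSpec(seed=seed, n_reactions=15, cycle_count=3,
                            bridge_ratio=0.04))
            g = build_graph(model, "flux", state)
            tree = hierarchical_partition(g, GAParams(seed=seed))
            nodes = list(g.nodes)
            for a in range(len(nodes)):
                for b in range(a + 1, len(nodes)):
                    h = partition_score(tree, nodes[a], nodes[b])
                    assert 0.0 <= h <= 1.0


class TestPairScores:
    @pytest.fixture
    def partitioned_state(self):
        model, state, _ = make_random(
            FixtureSpec(seed=4, n_reactions=12, cycle_count=2))
        g = build_graph(model, "flux", state)
        root_v = build_modularity_matrix(all_pairs_shred(g))
        tree = hierarchical_partition(g, GAParams(seed=4))
        return g, tree, root_v

    def test_one_row_per_defined_pair(self, partitioned_state):
        g, tree, root_v = partitioned_state
        df = pair_scores(tree, root_v)
        assert len(df) == len(root_v.entries)
        n = len(g.nodes)
        assert len(df) <= n * (n - 1) // 2
        assert ((df["H"] >= 0) & (df["H"] <= 1)).all()

    def test_undefined_rootv_pairs_omitted(self):
        model, state, _ = make_random(
            FixtureSpec(seed=0, n_reactions=12, cycle_count=2))
        g = build_graph(model, "flux", state)
        root_v = build_modularity_matrix(all_pairs_shred(g))
        # drop one entry to emulate an unreachable pair
        dropped = next(iter(root_v.entries))
        del root_v.entries[dropped]
        tree = hierarchical_partition(g, GAParams(seed=0))
        df = pair_scores(tree, root_v)
        assert dropped not in set(zip(df["i"], df["j"]))


class TestRobustPairs:
    def make_scores(self, rows, label):
        df = pd.DataFrame(rows, columns=["i", "j", "H", "V"])
        df["state"] = label
        return df

    def test_single_state_counts(self):
        s = self.make_scores([("a", "b", 0.9, 5.0), ("a", "c", 0.2, 5.0)], "s1")
        rep = robust_pairs({"s1": s})
        assert rep.loc[("a", "b"), "count"] == 1
        assert ("a", "c") not in rep.index

    def test_threshold_is_strict(self):
        s = self.make_scores([("a", "b", 0.7, 5.0), ("a", "c", 0.71, 3.0)], "s1")
        rep = robust_pairs({"s1": s})
        assert len(rep) == 0  # H = 0.7 and V = 3.0 both fail strictly

    def test_require_all_states(self):
        s1 = self.make_scores([("a", "b", 0.9, 5.0), ("a", "c", 0.9, 5.0)], "s1")
        s2 = self.make_scores([("a", "b", 0.8, 4.0), ("a", "c", 0.1, 5.0)], "s2")
        rep = robust_pairs({"s1": s1, "s2": s2})
        assert bool(rep.loc[("a", "b"), "robust"])
        assert not bool(rep.loc[("a", "c"), "robust"])
        assert rep.loc[("a", "c"), "count"] == 1

    def test_thresholds_at_minus_inf_return_everything(self):
        s = self.make_scores([("a", "b", 0.0, -9.0), ("a", "c", 0.1, 0.0)], "s1")
        rep = robust_pairs({"s1": s}, h_min=-np.inf, v_min=-np.inf)
        assert len(rep) == 2 and rep["robust"].all()


class TestHvDistance:
    def make_scores(self, rows, label="s"):
        df = pd.DataFrame(rows, columns=["i", "j", "H", "V"])
        df["state"] = label
        return df

    def test_identical_states_zero(self):
        s = self.make_scores([("a", "b", 0.5, 2.0), ("a", "c", 0.8, 1.0)])
        dist, missing = hv_distance(s, s.copy())
        assert np.allclose(dist.values, 0.0)
        assert len(missing) == 0

    def test_single_axis_displacement(self):
        a = self.make_scores([("a", "b", 0.4, 2.0), ("a", "c", 0.6, 2.0)])
        b = self.make_scores([("a", "b", 0.4, 2.0), ("a", "c", 0.6, 2.0)])
        # scale state B's H by mean-preserving swap: distances reflect the
        # normalized coordinates, computed by hand below
        b.loc[0, "H"] = 0.6
        b.loc[1, "H"] = 0.4
        dist, _ = hv_distance(a, b)
        # both means are 0.5 -> normalized H displacement is 0.4 for each pair
        assert dist[("a", "b")] == pytest.approx(0.4)
        assert dist[("a", "c")] == pytest.approx(0.4)

    def test_symmetric_in_states(self):
        rng = np.random.default_rng(3)
        a = self.make_scores([("a", str(k), rng.uniform(0.1, 1), rng.normal())
                              for k in range(5)])
        b = self.make_scores([("a", str(k), rng.uniform(0.1, 1), rng.normal())
                              for k in range(5)])
        d1, _ = hv_distance(a, b)
        d2, _ = hv_distance(b, a)
        assert np.allclose(d1.values, d2.values)

    def test_pairs_missing_in_one_state_reported(self):
        a = self.make_scores([("a", "b", 0.5, 1.0), ("a", "c", 0.5, 1.0)])
        b = self.make_scores([("a", "b", 0.5, 1.0)])
        dist, missing = hv_distance(a, b)
        assert len(dist) == 1 and len(missing) == 1
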
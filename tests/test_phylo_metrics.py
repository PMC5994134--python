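"""Diversity statistics against brute-force oracles and planted structure."""

import numpy as np
import pandas as pd
import pytest

from ecoscope import phylo_metrics as pm
from ecoscope import synthetic_data as sd
from ecoscope.tables_io import FormatError, read_newick, write_newick


def _root_path_edges(tree, label):
    node = {l.taxon.label: l for l in tree.leaf_node_iter()}[label]
    edges = []
    while node.parent_node is not None:
        edges.append(node)
        node = node.parent_node
    return edges


def brute_force_pd(tree, present):
    """Union of root-path edge sets, summed — the definitional oracle."""
    edges = set()
    for label in present:
        edges.update(_root_path_edges(tree, label))
    return sum(n.edge.length or 0.0 for n in edges)


class TestFaithPd:
    def test_all_tips_total_length(self, yule50):
        tips = [l.taxon.label for l in yule50.leaf_node_iter()]
        total = sum(
            e.length for e in yule50.preorder_edge_iter() if e.length is not None
        )
        assert pm.faith_pd(yule50, tips) == pytest.approx(total)

    def test_single_tip_root_path(self, yule50):
        tip = next(yule50.leaf_node_iter())
        assert pm.faith_pd(yule50, [tip.taxon.label]) == pytest.approx(
            tip.distance_from_root()
        )

    def test_empty_set(self, yule50):
        assert pm.faith_pd(yule50, []) == 0.0

    def test_random_subsets_match_edge_union_oracle(self, yule50, rng):
        tips = [l.taxon.label for l in yule50.leaf_node_iter()]
        for _ in range(20):
            sub = rng.choice(tips, size=10, replace=False)
            assert pm.faith_pd(yule50, sub) == pytest.approx(
                brute_force_pd(yule50, sub), abs=1e-10
            )

    def test_unknown_tip(self, yule50):
        with pytest.raises(FormatError):
            pm.faith_pd(yule50, ["not-a-tip"])


class TestMeanPdSubsampled:
    def test_full_pool_zero_sd(self, yule50):
        tips = [l.taxon.label for l in yule50.leaf_node_iter()][:8]
        out = pm.mean_pd_subsampled(yule50, {"b": tips}, subsample_size=8, iterations=5)
        mean, sdv = out["b"]
        assert sdv == 0.0
        assert mean == pytest.approx(pm.faith_pd(yule50, tips))

    def test_matches_exhaustive_average(self):
        from itertools import combinations

        tree = sd.simulate_tree(10, seed=8)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        exact = np.array([pm.faith_pd(tree, c) for c in combinations(tips, 4)])
        out = pm.mean_pd_subsampled(
            tree, {"b": tips}, subsample_size=4, iterations=800, seed=1
        )
        mean, sdv = out["b"]
        se = exact.std() / np.sqrt(800)
        assert abs(mean - exact.mean()) < 2.5 * se

    def test_subsample_larger_than_pool(self, yule50):
        with pytest.raises(ValueError, match="exceeds"):
            pm.mean_pd_subsampled(yule50, {"b": ["t1", "t2"]}, subsample_size=3)


def brute_force_psv(tree, present):
    """PSV from an MRCA-depth covariance matrix built independently."""
    present = sorted(present)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(present)
    V = np.zeros((n, n))
    for i, a in enumerate(present):
        for j, b in enumerate(present):
            if i == j:
                node = [l for l in tree.leaf_node_iter() if l.taxon.label == a][0]
                V[i, j] = node.distance_from_root()
            else:
                mrca = pdm.mrca(taxa[a], taxa[b])
                V[i, j] = mrca.distance_from_root()
    C = V / np.sqrt(np.outer(np.diag(V), np.diag(V)))
    return (n * np.trace(C) - C.sum()) / (n * (n - 1))


class TestPsv:
    def test_star_tree_is_one(self):
        star = read_newick("(A:1,B:2,C:1.5,D:0.7);")
        assert pm.psv(star, ["A", "B", "C", "D"]) == pytest.approx(1.0)

    def test_fully_shared_path_is_zero(self):
        tree = read_newick("((A:0,B:0):1,C:1);")
        assert pm.psv(tree, ["A", "B"]) == pytest.approx(0.0)

    def test_matches_covariance_oracle(self):
        tree = sd.simulate_tree(8, seed=21)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        assert pm.psv(tree, tips) == pytest.approx(brute_force_psv(tree, tips), abs=1e-10)
        assert pm.psv(tree, tips[:5]) == pytest.approx(
            brute_force_psv(tree, tips[:5]), abs=1e-10
        )

    def test_invariant_to_branch_scaling(self):
        tree = sd.simulate_tree(12, seed=22)
        tips = [l.taxon.label for l in tree.leaf_node_iter()][:6]
        before = pm.psv(tree, tips)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.3
        assert pm.psv(tree, tips) == pytest.approx(before, abs=1e-12)


class TestPsvNull:
    def test_degenerate_all_ones_matrix(self, yule50):
        tips = [l.taxon.label for l in yule50.leaf_node_iter()][:10]
        occ = pd.DataFrame(1, index=["s1", "s2", "s3"], columns=tips)
        res = pm.psv_null(yule50, occ, model=1, iterations=50, seed=0)
        assert res.p_values[1] == pytest.approx(1.0)
        assert np.ptp(res.null_means[1]) < 1e-12

    def test_null_model_constraints(self, rng):
        occ = (rng.random((6, 15)) < 0.4).astype(int)
        m1 = pm.null_community_matrix(occ, 1, rng)
        assert np.array_equal(m1.sum(axis=0), occ.sum(axis=0))
        m2 = pm.null_community_matrix(occ, 2, rng)
        assert np.array_equal(m2.sum(axis=1), occ.sum(axis=1))

    @staticmethod
    def _clades(tree, lo=8, hi=20):
        out = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if lo <= len(node.leaf_nodes()) <= hi:
                out.append([l.taxon.label for l in node.leaf_iter()])
        return out

    def test_model2_detects_clade_restricted_composition(self):
        """Sites sampling one clade sit below the taxon-pool (model 2) null."""
        hits = 0
        for seed in range(20):
            tree = sd.simulate_tree(40, seed=300 + seed)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            clade = self._clades(tree)[0]
            r = np.random.default_rng(seed)
            occ = pd.DataFrame(0, index=[f"s{i}" for i in range(5)], columns=tips)
            for s in occ.index:
                occ.loc[s, r.choice(clade, size=6, replace=False)] = 1
            res = pm.psv_null(tree, occ, model=2, iterations=200, seed=seed)
            hits += res.observed_mean < res.null_quantiles[2][0]
        assert hits >= 18  # >= 90% of seeded runs

    def test_model1_detects_per_site_clustering(self):
        """Each site concentrated in its own clade beats the occurrence-preserving null."""
        hits = 0
        for seed in range(20):
            tree = sd.simulate_tree(40, seed=300 + seed)
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            clades = self._clades(tree)
            r = np.random.default_rng(seed)
            occ = pd.DataFrame(0, index=[f"s{i}" for i in range(6)], columns=tips)
            for i, s in enumerate(occ.index):
                cl = clades[i % len(clades)]
                occ.loc[s, r.choice(cl, size=min(6, len(cl)), replace=False)] = 1
            res = pm.psv_null(tree, occ, model=1, iterations=200, seed=seed)
            hits += res.observed_mean < res.null_quantiles[1][0]
        assert hits >= 18


def brute_force_unifrac(tree, a, b):
    a, b = set(a), set(b)
    unique = shared = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        in_a, in_b = bool(below & a), bool(below & b)
        if in_a and in_b:
            shared += node.edge.length or 0.0
        elif in_a or in_b:
            unique += node.edge.length or 0.0
    return unique / (unique + shared)


class TestUnifrac:
    def test_identical_communities(self, balanced4):
        assert pm.unweighted_unifrac(balanced4, ["A", "B"], ["A", "B"]) == 0.0

    def test_mutually_exclusive_clades(self, balanced4):
        assert pm.unweighted_unifrac(balanced4, ["A", "B"], ["C", "D"]) == 1.0

    def test_matches_edge_classification_oracle(self, rng):
        tree = sd.simulate_tree(20, seed=31)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        for _ in range(15):
            a = rng.choice(tips, size=rng.integers(2, 10), replace=False)
            b = rng.choice(tips, size=rng.integers(2, 10), replace=False)
            assert pm.unweighted_unifrac(tree, a, b) == pytest.approx(
                brute_force_unifrac(tree, a, b), abs=1e-10
            )

    def test_metric_properties_on_random_triples(self, rng):
        tree = sd.simulate_tree(15, seed=32)
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        for _ in range(10):
            comms = [
                set(rng.choice(tips, size=rng.integers(2, 8), replace=False))
                for _ in range(3)
            ]
            d = lambda x, y: pm.unweighted_unifrac(tree, x, y)
            dab, dba = d(comms[0], comms[1]), d(comms[1], comms[0])
            assert dab == pytest.approx(dba, abs=1e-12)
            assert d(comms[0], comms[0]) == 0.0
            assert d(comms[0], comms[2]) <= dab + d(comms[1], comms[2]) + 1e-12

    def test_empty_community_rejected(self, balanced4):
        with pytest.raises(ValueError):
            pm.unweighted_unifrac(balanced4, [], ["A"])


def _join_tree_from_groups(groups, seed, shuffle_backbone=True):
    """Random tree in which each group is a clade (planted shared clades)."""
    r = np.random.default_rng(seed)

    def random_subtree(labels):
        parts = [f"{l}:{r.uniform(0.5, 1.5):.4f}" for l in labels]
        while len(parts) > 1:
            i, j = sorted(r.choice(len(parts), size=2, replace=False), reverse=True)
            merged = f"({parts[i]},{parts[j]}):{r.uniform(0.5, 1.5):.4f}"
            del parts[i]
            del parts[j]
            parts.append(merged)
        return parts[0]

    clades = [random_subtree(g) for g in groups]
    backbone = random_subtree([f"__g{i}__" for i in range(len(groups))])
    # placeholder tips become the group clades (keeping the stem lengths)
    for i, c in enumerate(clades):
        backbone = backbone.replace(f"__g{i}__", f"({c})", 1)
    return read_newick(backbone + ";")


class TestProposeSubgroups:
    def test_identical_trees_outermost_partition(self):
        nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        tree_a, tree_b = read_newick(nwk), read_newick(nwk)
        out = pm.propose_subgroups(tree_a, tree_b, min_size=3)
        members = sorted(tuple(sorted(s.members)) for s in out)
        assert members == [
            ("A", "B", "C", "D"),
            ("E", "F", "G", "H"),
        ]

    def test_regraft_breaks_clade(self):
        nwk_a = "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,(F:1,(G:1,H:1):1):1):1);"
        # E moved inside the ABCD clade in tree B: the 4-tip clade differs
        nwk_b = "(((A:1,B:1):1,(C:1,E:1):1):1,(D:1,(F:1,(G:1,H:1):1):1):1);"
        out = pm.propose_subgroups(read_newick(nwk_a), read_newick(nwk_b), min_size=3)
        assert all(s.members != frozenset("ABCD") for s in out)

    def test_planted_shared_clades_recovered(self):
        r = np.random.default_rng(77)
        labels = [f"x{i}" for i in range(120)]
        sizes = [11, 12, 14, 15, 16, 20, 32]
        groups, pos = [], 0
        for s in sizes:
            groups.append(labels[pos : pos + s])
            pos += s
        tree_a = _join_tree_from_groups(groups, seed=1)
        tree_b = _join_tree_from_groups(groups, seed=2)
        out = pm.propose_subgroups(tree_a, tree_b, min_size=10)
        recovered = {frozenset(s.members) for s in out}
        assert recovered == {frozenset(g) for g in groups}

    def test_tip_set_mismatch(self):
        with pytest.raises(FormatError):
            pm.propose_subgroups(
                read_newick("(A:1,B:1);"), read_newick("(A:1,C:1);"), min_size=0
            )

    def test_min_identity_annotation(self):
        nwk = "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"
        ids = ["A", "B", "C", "D", "E"]
        mat = pd.DataFrame(100.0, index=ids, columns=ids)
        mat.loc["A", "B"] = mat.loc["B", "A"] = 88.0
        mat.loc["A", "C"] = mat.loc["C", "A"] = 91.0
        mat.loc["B", "C"] = mat.loc["C", "B"] = 93.5
        out = pm.propose_subgroups(
            read_newick(nwk), read_newick(nwk), min_size=2, identity=mat
        )
        abc = [s for s in out if s.members == frozenset("ABC")][0]
        assert abc.min_identity == pytest.approx(88.0)


class TestSubgroupCoverage:
    @pytest.mark.parametrize(
        "total,ungrouped,expected",
        [(3584, 592, 83.5), (100, 0, 100.0), (200, 50, 75.0)],
    )
    def test_coverage(self, total, ungrouped, expected):
        assert pm.subgroup_coverage(total, ungrouped) == expected

    def test_zero_total(self):
        with pytest.raises(ValueError):
            pm.subgroup_coverage(0, 0)
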
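"""Distance matrices, NJ/UPGMA construction, Robinson–Foulds, deletion test.

dendropy serves as the independent oracle for tree distances and for an
alternative NJ implementation.
"""

import itertools

import dendropy
import numpy as np
import pytest

from foldcompare.errors import TreeError
from foldcompare.structree import (
    DistanceMatrix,
    PhyloTree,
    build_tree,
    class_monophyly,
    deletion_experiment,
    robinson_foulds,
    structure_distance_matrix,
)
from foldcompare.synthetic import make_fold_template, perturb


def random_additive(n, seed):
    """Random binary tree on n taxa; returns (newick, additive matrix)."""
    rng = np.random.default_rng(seed)
    nodes = [f"t{i}" for i in range(n)]
    subtrees = {lab: lab for lab in nodes}
    dist = {}
    for a, b in itertools.combinations(nodes, 2):
        dist[(a, b)] = 0.0
    # agglomerate randomly, accumulating branch lengths to members
    members = {lab: [lab] for lab in nodes}
    depth = {lab: 0.0 for lab in nodes}
    active = list(nodes)
    pair_d = {(a, b): None for a, b in itertools.combinations(sorted(nodes), 2)}
    leaf_dist = {lab: {lab: 0.0} for lab in nodes}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.1, 1.0, 2)
        for x in members[a]:
            leaf_dist[a][x] += la
        for y in members[b]:
            leaf_dist[b][y] += lb
        for x in members[a]:
            for y in members[b]:
                key = tuple(sorted((x, y)))
                pair_d[key] = leaf_dist[a][x] + leaf_dist[b][y]
        newick_ab = f"({subtrees[a]}:{la:.6f},{subtrees[b]}:{lb:.6f})"
        merged = f"merge{len(active)}"
        subtrees[merged] = newick_ab
        members[merged] = members[a] + members[b]
        leaf_dist[merged] = {**leaf_dist[a], **leaf_dist[b]}
        active = [x for x in active if x not in (a, b)] + [merged]
    newick = subtrees[active[0]] + ";"
    labels = sorted(nodes)
    D = np.zeros((n, n))
    for x, y in itertools.combinations(labels, 2):
        d = pair_d[(x, y)]
        ix, iy = labels.index(x), labels.index(y)
        D[ix, iy] = D[iy, ix] = d
    return newick, DistanceMatrix(labels, D)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(TreeError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(TreeError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0.0]]))
        with pytest.raises(TreeError):
            DistanceMatrix(["a", "b"], np.array([[0, np.nan], [np.nan, 0]]))

    def test_duplicate_traces_have_zero_distance(self, template150):
        a = perturb(template150, 0.0, new_id="a")
        b = perturb(template150, 0.0, new_id="b")
        c = perturb(template150, 1.0, seed=1, new_id="c")
        dm = structure_distance_matrix([a, b, c])
        i, j = dm.labels.index("a_A"), dm.labels.index("b_A")
        assert dm.values[i, j] == pytest.approx(0.0, abs=1e-9)

    def test_distance_grows_with_noise(self, template150):
        traces = [
            perturb(template150, s, seed=9, new_id=f"s{k}")
            for k, s in enumerate((0.2, 0.8, 2.0))
        ]
        dm = structure_distance_matrix([template150] + traces)
        d0 = dm.values[0, 1:]
        assert d0[0] < d0[1] < d0[2]


class TestBuildTree:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        )
        tree = build_tree(dm, "nj")
        lengths = {n.label: n.length for n in tree.root.children}
        assert lengths == {
            "a": pytest.approx(1.0),  # (3+4-5)/2
            "b": pytest.approx(2.0),  # (3+5-4)/2
            "c": pytest.approx(3.0),  # (4+5-3)/2
        }

    def test_additive_five_taxon_recovery_with_lengths(self):
        nwk = "((A:1,B:2):1,(C:3,D:1):2,E:4);"
        truth = PhyloTree.from_newick(nwk)
        labels = ["A", "B", "C", "D", "E"]
        # path-length matrix of the generating tree
        D = np.array(
            [
                [0, 3, 7, 5, 6],
                [3, 0, 8, 6, 7],
                [7, 8, 0, 4, 9],
                [5, 6, 4, 0, 7],
                [6, 7, 9, 7, 0],
            ],
            float,
        )
        nj = build_tree(DistanceMatrix(labels, D), "nj")
        assert robinson_foulds(nj, truth) == 0
        assert nj.to_newick() == truth.to_newick()

    @pytest.mark.parametrize("seed", range(15))
    def test_nj_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        nwk, dm = random_additive(n, seed + 1000)
        tree = build_tree(dm, "nj")
        assert robinson_foulds(tree, PhyloTree.from_newick(nwk)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_nj_agrees_with_dendropy_on_generic_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        pts = rng.normal(size=(n, 4))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        labels = [f"t{i}" for i in range(n)]
        mine = build_tree(DistanceMatrix(labels, D), "nj")
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(x) for x in D[i]) for i in range(n)
        )
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        dtree = pdm.nj_tree()
        theirs = PhyloTree.from_newick(
            dtree.as_string(schema="newick", suppress_rooting=True)
        )
        assert robinson_foulds(mine, theirs) == 0

    def test_upgma_is_ultrametric(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(9, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        tree = build_tree(DistanceMatrix([f"t{i}" for i in range(9)], D), "upgma")
        depths = []

        def walk(node, d):
            d += node.length
            if node.is_leaf:
                depths.append(d)
            for c in node.children:
                walk(c, d)

        walk(tree.root, 0.0)
        assert np.ptp(depths) < 1e-9

    def test_small_or_bad_matrices_refused(self):
        with pytest.raises(TreeError):
            build_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))), "nj")
        with pytest.raises(TreeError):
            build_tree(
                DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))), "median-joining"
            )

    def test_negative_branch_clamped_with_warning(self):
        # triangle-inequality violation forces a negative three-point length
        D = np.array([[0, 2, 10], [2, 0, 3], [10, 3, 0.0]])
        dm = DistanceMatrix(["a", "b", "c"], D)
        with pytest.warns(UserWarning, match="clamped"):
            tree = build_tree(dm, "nj")
        assert all(n.length >= 0 for n in tree.postorder())


class TestRobinsonFoulds:
    def test_identity_and_four_taxon_distance(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = PhyloTree.from_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert robinson_foulds(t1, t1) == 0
        assert robinson_foulds(t1, t2) == 2
        assert robinson_foulds(t2, t1) == 2

    def test_leaf_set_mismatch_refused(self):
        t1 = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        t2 = PhyloTree.from_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(TreeError):
            robinson_foulds(t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dendropy_bipartition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        trees = []
        for k in range(2):
            pts = rng.normal(size=(n, 3))
            D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            trees.append(build_tree(DistanceMatrix([f"t{i}" for i in range(n)], D), "nj"))
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(
            data=trees[0].to_newick(), schema="newick",
            taxon_namespace=tns, preserve_underscores=True,
        )
        d2 = dendropy.Tree.get(
            data=trees[1].to_newick(), schema="newick",
            taxon_namespace=tns, preserve_underscores=True,
        )
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(trees[0], trees[1]) == expected

    def test_newick_round_trip_preserves_lengths(self):
        nwk, dm = random_additive(7, 5)
        tree = build_tree(dm, "nj")
        back = PhyloTree.from_newick(tree.to_newick())
        assert robinson_foulds(tree, back) == 0
        l1 = sorted(n.length for n in tree.postorder())
        l2 = sorted(n.length for n in back.postorder())
        np.testing.assert_allclose(l1, l2, atol=1e-6)


@pytest.fixture(scope="module")
def small_family():
    template = make_fold_template(90, seed=21)
    return [perturb(template, 0.15, seed=k, new_id=f"m{k+1}") for k in range(6)]


class TestDeletionExperiment:
    def test_empty_regions_reproduce_the_tree(self, small_family):
        result = deletion_experiment(small_family, {})
        assert result.rf == 0
        assert result.tree_full.to_newick() == result.tree_deleted.to_newick()

    def test_common_loop_deletion_keeps_classification(self, small_family):
        regions = {t.label: (40, 44) for t in small_family}
        classes = {t.label: ("X" if i < 3 else "Y") for i, t in enumerate(small_family)}
        result = deletion_experiment(small_family, regions, classes=classes)
        assert result.rf == 0
        assert result.class_diff == {}

    def test_overlong_deletion_refused(self, small_family):
        regions = {small_family[0].label: (1, 60)}
        with pytest.raises(TreeError, match="half"):
            deletion_experiment(small_family, regions)

    def test_class_monophyly_detects_split_classes(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        good = class_monophyly(tree, {"a": "X", "b": "X", "c": "Y", "d": "Y"})
        assert good == {"X": True, "Y": True}
        bad = class_monophyly(tree, {"a": "X", "c": "X", "b": "Y", "d": "Y"})
        assert bad == {"X": False, "Y": False}
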
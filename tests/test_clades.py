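"""p-distances, neighbor joining, clade cutting, and clade-HMM validation.

Oracles: NJ must reproduce additive trees exactly (patristic distances
equal the input matrix), match an exhaustive least-squares topology
search for five taxa, and agree topologically with an independent NJ
implementation (scikit-bio).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ice_scout.clades import (
    CladeAssignment,
    DistanceMatrix,
    TreeNode,
    build_and_validate_clade_hmms,
    build_clade_hmms,
    clade_family,
    cut_clades,
    nj_tree,
    p_distance_matrix,
    tree_leaf_distance,
    tree_splits,
    validate_clades,
)
from ice_scout.phmm import Msa
from ice_scout.synthetic import mutate_protein, random_protein


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(Msa(["a", "b"], ["ACDEF", "ACDEF"]))
        assert dm.d[0, 1] == 0.0

    def test_quarter_difference(self):
        dm = p_distance_matrix(Msa(["a", "b"], ["AAAA", "AAAT"]))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        # comparable columns are 0 and 2 (both non-gap), both identical
        dm = p_distance_matrix(Msa(["a", "b"], ["A-CD", "AEC-"]))
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError, match="no comparable columns"):
            p_distance_matrix(Msa(["a", "b"], ["A-", "-A"]))

    def test_metric_on_gapfree_alignments(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            rows = ["".join(rng.choice(list("ACDE"), size=30)) for _ in range(4)]
            dm = p_distance_matrix(Msa(list("wxyz"), rows))
            d = dm.d
            assert np.all(d >= 0) and np.all(d <= 1)
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def additive_matrix_from_tree(tree: TreeNode, labels):
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree_leaf_distance(tree, a, labels[j])
    return DistanceMatrix(list(labels), d)


def random_additive_tree(labels, rng) -> TreeNode:
    """A random binary topology with random positive branch lengths."""
    nodes = [TreeNode(l, length=float(rng.uniform(0.5, 3.0))) for l in labels]
    count = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        count += 1
        parent = TreeNode(f"i{count}", length=float(rng.uniform(0.5, 3.0)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode("root")
    root.children = nodes
    return root


def ls_fit_rss(topology: TreeNode, dm: DistanceMatrix) -> float:
    """Least-squares branch-length fit of a fixed topology; returns RSS."""
    labels = dm.labels
    edges = list(topology.edges())
    rows = []
    y = []
    leafsets = [frozenset(child.leaf_names()) for _p, child in edges]
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            row = [1.0 if (a in s) != (labels[j] in s) else 0.0 for s in leafsets]
            rows.append(row)
            y.append(dm.d[i, j])
    X = np.array(rows)
    y = np.array(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((X @ beta - y) ** 2))


def enumerate_topologies(labels):
    """All unrooted binary topologies (15 for five taxa), built by
    sequential leaf insertion into every edge."""
    base = TreeNode("root")
    base.children = [TreeNode(labels[0]), TreeNode(labels[1]), TreeNode(labels[2])]

    def clone(node):
        c = TreeNode(node.name, node.length)
        c.children = [clone(ch) for ch in node.children]
        return c

    trees = [base]
    counter = itertools.count()
    for leaf in labels[3:]:
        new_trees = []
        for t in trees:
            edges = list(t.edges())
            for idx in range(len(edges)):
                t2 = clone(t)
                e2 = list(t2.edges())
                parent, child = e2[idx]
                mid = TreeNode(f"m{next(counter)}")
                parent.children[parent.children.index(child)] = mid
                mid.children = [child, TreeNode(leaf)]
                new_trees.append(t2)
        trees = new_trees
    return trees


class TestNeighborJoining:
    def test_recovers_known_four_taxon_tree(self):
        """Distances computed from ((A:1,B:2):1,(C:3,D:4)) are recovered
        exactly: same split and identical patristic distances."""
        ab = TreeNode("ab", 1.0)
        ab.children = [TreeNode("A", 1.0), TreeNode("B", 2.0)]
        root = TreeNode("root")
        cd = TreeNode("cd", 0.0)
        cd.children = [TreeNode("C", 3.0), TreeNode("D", 4.0)]
        root.children = [ab, cd]
        dm = additive_matrix_from_tree(root, ["A", "B", "C", "D"])
        assert dm.d[0, 1] == 3.0 and dm.d[0, 2] == 5.0 and dm.d[2, 3] == 7.0
        tree = nj_tree(dm)
        assert tree_splits(tree) == {frozenset({"A", "B"})}
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, 4):
                assert tree_leaf_distance(tree, a, dm.labels[j]) == pytest.approx(
                    dm.d[i, j], abs=1e-9
                )

    def test_additive_battery_exact(self):
        """NJ is consistent on additive data up to 8 taxa: patristic
        distances equal the input matrix."""
        rng = np.random.default_rng(99)
        for n in (4, 5, 6, 7, 8):
            for _ in range(5):
                labels = [f"t{i}" for i in range(n)]
                truth = random_additive_tree(labels, rng)
                dm = additive_matrix_from_tree(truth, labels)
                tree = nj_tree(dm)
                for i, a in enumerate(labels):
                    for j in range(i + 1, n):
                        assert tree_leaf_distance(tree, a, labels[j]) == pytest.approx(
                            dm.d[i, j], abs=1e-8
                        )
                assert tree_splits(tree) == tree_splits(truth)

    def test_five_taxon_least_squares_oracle(self):
        """NJ topology equals the best of all 15 unrooted five-taxon
        topologies under least squares, on additive matrices."""
        rng = np.random.default_rng(123)
        labels = ["a", "b", "c", "d", "e"]
        for _ in range(8):
            truth = random_additive_tree(labels, rng)
            dm = additive_matrix_from_tree(truth, labels)
            got = tree_splits(nj_tree(dm))
            best = min(enumerate_topologies(labels), key=lambda t: ls_fit_rss(t, dm))
            assert got == tree_splits(best)

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check on non-additive (noisy) matrices."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(6)]
        truth = random_additive_tree(labels, rng)
        dm = additive_matrix_from_tree(truth, labels)
        noisy = dm.d + rng.uniform(0, 0.05, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = tree_splits(nj_tree(DistanceMatrix(labels, noisy)))
        sk = skbio_nj(SkbioDM(noisy, labels))
        sk_splits = set()
        all_leaves = frozenset(labels)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                sk_splits.add(min(side, all_leaves - side, key=lambda s: (len(s), sorted(s))))
        assert ours == sk_splits

    def test_tie_case_deterministic(self):
        labels = list("abcd")
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(labels, d)).newick()
        t2 = nj_tree(DistanceMatrix(labels, d)).newick()
        assert t1 == t2

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# clade cutting
# ---------------------------------------------------------------------------

def two_group_tree(sep_length=1.0, twig=0.05) -> TreeNode:
    left = TreeNode("L", sep_length)
    left.children = [TreeNode("A", twig), TreeNode("B", twig)]
    mid = TreeNode("M", twig)
    mid.children = [TreeNode("C", twig), TreeNode("D", twig)]
    root = TreeNode("root")
    root.children = [left, mid, TreeNode("E", twig)]
    return root


class TestCutClades:
    def test_long_branch_separates_two_clades(self):
        asn = cut_clades(two_group_tree(sep_length=0.5, twig=0.05))
        assert asn.k == 2
        assert asn.labels["A"] == asn.labels["B"]
        assert asn.labels["C"] == asn.labels["D"] == asn.labels["E"]
        assert asn.labels["A"] != asn.labels["C"]

    def test_isolated_leaf_between_cuts_is_outlier(self):
        left = TreeNode("L", 0.5)
        left.children = [TreeNode("A", 0.05), TreeNode("B", 0.05)]
        right = TreeNode("R", 0.5)
        right.children = [TreeNode("C", 0.05), TreeNode("D", 0.05)]
        root = TreeNode("root")
        root.children = [left, right, TreeNode("E", 0.05)]
        asn = cut_clades(root)
        assert asn.k == 2
        assert asn.labels["E"] == "outlier"

    def test_uniform_lengths_single_clade(self):
        asn = cut_clades(two_group_tree(sep_length=0.05, twig=0.05))
        assert asn.k == 1
        assert set(asn.labels.values()) == {"clade_1"}

    def test_max_clades_cuts_longest_branches(self):
        asn = cut_clades(two_group_tree(sep_length=0.5), max_clades=1)
        assert asn.k == 1

    def test_three_planted_groups_recovered(self):
        """Synthetic family with three groups at 0.1 within / 0.5 between
        divergence clades into exactly the generating groups."""
        rng = np.random.default_rng(31)
        root = random_protein(250, rng)
        groups = {g: mutate_protein(root, 0.25, rng) for g in "XYZ"}
        members = {}
        for g, template in groups.items():
            for i in range(5):
                members[f"{g}{i}"] = mutate_protein(template, 0.10, rng)
        aln = Msa(sorted(members), [members[k] for k in sorted(members)])
        tree = nj_tree(p_distance_matrix(aln))
        asn = cut_clades(tree)
        assert asn.k == 3
        for g in "XYZ":
            labels = {asn.labels[f"{g}{i}"] for i in range(5)}
            assert len(labels) == 1


# ---------------------------------------------------------------------------
# clade HMM validation
# ---------------------------------------------------------------------------

def planted_two_clade_family(rng, between=0.6, within=0.08, n=5, length=220):
    root = random_protein(length, rng)
    t1 = mutate_protein(root, between / 2, rng)
    t2 = mutate_protein(root, between / 2, rng)
    members = {}
    for i in range(n):
        members[f"p{i}"] = mutate_protein(t1, within, rng)
        members[f"q{i}"] = mutate_protein(t2, within, rng)
    truth = {m: ("one" if m.startswith("p") else "two") for m in members}
    return members, truth


class TestCladeValidation:
    def test_separated_clades_confirmed(self):
        rng = np.random.default_rng(77)
        members, truth = planted_two_clade_family(rng)
        asn = CladeAssignment(
            "fam",
            {m: ("clade_1" if truth[m] == "one" else "clade_2") for m in members},
            k=2,
        )
        hmms = build_clade_hmms(members, asn)
        val = validate_clades(members, asn, hmms, margin_bits=10.0)
        assert val.all_confirmed
        for clade, stats in val.per_clade.items():
            assert stats["min_within_bits"] >= stats["max_cross_bits"] + 10.0

    def test_random_split_of_homogeneous_group_unconfirmed(self):
        """Splitting one homogeneous group into two fake clades must fail
        the margin check (permutation control)."""
        rng = np.random.default_rng(78)
        root = random_protein(220, rng)
        members = {f"m{i}": mutate_protein(root, 0.08, rng) for i in range(10)}
        fake = CladeAssignment(
            "fam",
            {m: ("clade_1" if i % 2 == 0 else "clade_2") for i, m in enumerate(sorted(members))},
            k=2,
        )
        hmms = build_clade_hmms(members, fake)
        val = validate_clades(members, fake, hmms, margin_bits=10.0)
        assert not val.all_confirmed

    def test_single_clade_trivially_confirmed(self):
        rng = np.random.default_rng(79)
        root = random_protein(200, rng)
        members = {f"m{i}": mutate_protein(root, 0.05, rng) for i in range(4)}
        asn = CladeAssignment("fam", {m: "clade_1" for m in members}, k=1)
        hmms = build_clade_hmms(members, asn)
        val = validate_clades(members, asn, hmms)
        assert val.all_confirmed
        assert val.per_clade["clade_1"]["max_cross_bits"] == -np.inf

    def test_margin_monotone_in_divergence(self):
        """Increasing between-group divergence never shrinks the
        validation margin (divergence ladder, fixed seed)."""
        margins = []
        for between in (0.3, 0.5, 0.7):
            rng = np.random.default_rng(55)
            members, truth = planted_two_clade_family(rng, between=between)
            asn = CladeAssignment(
                "fam",
                {m: ("clade_1" if truth[m] == "one" else "clade_2") for m in members},
                k=2,
            )
            hmms = build_clade_hmms(members, asn)
            val = validate_clades(members, asn, hmms)
            margins.append(
                min(
                    s["min_within_bits"] - s["max_cross_bits"]
                    for s in val.per_clade.values()
                )
            )
        assert margins == sorted(margins)

    def test_failed_validation_triggers_recut(self):
        rng = np.random.default_rng(80)
        root = random_protein(220, rng)
        members = {f"m{i}": mutate_protein(root, 0.08, rng) for i in range(8)}
        aln = Msa(sorted(members), [members[k] for k in sorted(members)])
        tree = nj_tree(p_distance_matrix(aln))
        fake = CladeAssignment(
            "fam",
            {m: ("clade_1" if i % 2 == 0 else "clade_2") for i, m in enumerate(sorted(members))},
            k=2,
        )
        hmms, val, final = build_and_validate_clade_hmms(members, fake, tree=tree)
        assert final.k == 1
        assert val.all_confirmed

    def test_truncated_members_labelled_posthoc(self):
        rng = np.random.default_rng(81)
        members, truth = planted_two_clade_family(rng)
        frag = members["p0"][: len(members["p0"]) // 2]
        members["frag"] = frag
        asn, val, tree, hmms = clade_family(
            members, family_id="fam", truncated={"frag"}
        )
        assert asn.labels["frag"] == asn.labels["p0"]
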
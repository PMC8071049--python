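"""Tree machinery: distances, NJ exactness, bootstrap, rooting, RF,
monophyly and branch-length outliers."""

import numpy as np
import pytest

from nifloss.phylo import (
    Alignment,
    DistanceMatrix,
    PhyloError,
    PhyloTree,
    branch_length_outliers,
    bootstrap_support,
    concatenate,
    deconcatenate,
    first_diverging_clade,
    is_monophyletic,
    neighbor_joining,
    protein_distance,
    robinson_foulds,
    robinson_foulds_restricted,
    root_at_outgroup,
)

from conftest import (
    bipartitions_of,
    clades_of,
    random_topology,
    random_tree_with_distances,
    struct_to_newick,
)


# ---------------------------------------------------------------------------
# alignments and distances


def test_concatenate_lengths_and_partitions():
    m1 = Alignment(["A", "B"], ["MKVLAWYNQE", "MKVLAWYNQE"])
    m2 = Alignment(["A", "B"], ["CCCCCDDDDDEEEEE", "CCCCCDDDDDEEEEE"])
    concat = concatenate({"m1": m1, "m2": m2})
    assert concat.length == 25
    assert concat.partitions == [("m1", 1, 10), ("m2", 11, 25)]


def test_concatenate_single_marker_is_identity():
    m1 = Alignment(["A", "B"], ["MKVLA", "MKVLG"])
    concat = concatenate({"m1": m1})
    assert concat.rows == m1.rows
    assert concat.partitions == [("m1", 1, 5)]


def test_deconcatenate_round_trips(rng):
    markers = {}
    taxa = [f"T{i}" for i in range(5)]
    for m in range(4):
        L = int(rng.integers(3, 20))
        rows = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
            for _ in taxa
        ]
        markers[f"m{m}"] = Alignment(list(taxa), rows)
    concat = concatenate(markers)
    back = deconcatenate(concat)
    assert set(back) == set(markers)
    for name in markers:
        assert back[name].rows == markers[name].rows


def test_concatenate_missing_taxon_errors_by_default():
    m1 = Alignment(["A", "B"], ["MKVLA", "MKVLG"])
    m2 = Alignment(["A"], ["CCCCC"])
    with pytest.raises(PhyloError, match="missing"):
        concatenate({"m1": m1, "m2": m2})
    filled = concatenate({"m1": m1, "m2": m2}, fill_missing=True)
    assert filled.rows[1].endswith("-----")


def test_p_distance_counts_and_gap_handling():
    aln = Alignment(["A", "B"], ["MKVLAWYNQE", "MKVLAWYNQE"])
    assert protein_distance(aln).values[0, 1] == 0.0
    aln = Alignment(["A", "B"], ["AAAAACCCCC", "AAAAADDDDD"])
    assert protein_distance(aln).values[0, 1] == pytest.approx(0.5)
    # gapped columns are excluded pairwise
    aln = Alignment(["A", "B"], ["AA--AC", "AAC-AD"])
    # comparable columns: 0,1,4,5 -> 1 mismatch of 4
    assert protein_distance(aln).values[0, 1] == pytest.approx(0.25)


def test_poisson_correction_closed_form():
    aln = Alignment(["A", "B"], ["AAAAACCCCC", "AAAAADDDDD"])
    d = protein_distance(aln, model="poisson").values[0, 1]
    assert d == pytest.approx(-np.log(0.5), abs=1e-9)  # 0.6931


def test_poisson_saturation_flagged():
    aln = Alignment(["A", "B"], ["AAAA", "CCCC"])
    dm = protein_distance(aln, model="poisson")
    assert dm.values[0, 1] == 10.0
    assert ("A", "B") in dm.saturated


def test_zero_comparable_columns_errors():
    aln = Alignment(["A", "B"], ["AA--", "--CC"])
    with pytest.raises(PhyloError, match="A.*B"):
        protein_distance(aln)


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_quartet_recovers_split_and_lengths():
    D = DistanceMatrix(
        ["A", "B", "C", "D"],
        np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        ),
    )
    tree = neighbor_joining(D)
    assert tree.bipartitions() == frozenset({frozenset({"C", "D"})})
    # all five edges exactly recovered
    for pair, want in (("AB", 2), ("CD", 2), ("AC", 3), ("AD", 3), ("BC", 3)):
        assert tree.patristic_distance(pair[0], pair[1]) == pytest.approx(want)


def test_nj_three_taxa_closed_form():
    D = DistanceMatrix(
        ["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    )
    tree = neighbor_joining(D)
    # three-point formulas: a = (3+4-5)/2 = 1, b = 2, c = 3
    assert tree.patristic_distance("A", "B") == pytest.approx(3)
    assert tree.patristic_distance("A", "C") == pytest.approx(4)
    assert tree.patristic_distance("B", "C") == pytest.approx(5)


def test_nj_exact_on_random_additive_matrices(rng):
    for _ in range(30):
        n = int(rng.integers(4, 13))
        newick, labels, dist = random_tree_with_distances(rng, n)
        D = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dist[tuple(sorted((a, labels[j])))]
        tree = neighbor_joining(DistanceMatrix(labels, D))
        truth = PhyloTree.from_newick(newick, rooted=False)
        assert robinson_foulds(tree, truth) == 0


def test_nj_matches_independent_implementation(rng):
    """Cross-check against scikit-bio's neighbor joining on a noisy matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj

    n = 8
    labels = [f"L{i}" for i in range(n)]
    newick, labels, dist = random_tree_with_distances(rng, n)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            base = dist[tuple(sorted((a, labels[j])))]
            D[i, j] = D[j, i] = base * (1 + 0.01 * ((i * 7 + j) % 5))
    ours = neighbor_joining(DistanceMatrix(labels, D))
    theirs = skbio_nj(skbio.DistanceMatrix(D, labels))
    theirs_tree = PhyloTree.from_newick(str(theirs).strip(), rooted=False)
    assert robinson_foulds(ours, theirs_tree) == 0


def test_nj_rejects_small_or_asymmetric_input():
    with pytest.raises(PhyloError):
        neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
    with pytest.raises(PhyloError, match="symmetric"):
        DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float))


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_unanimous_signal_gives_full_support():
    aln = Alignment(
        ["A", "B", "C", "D"],
        ["AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "CCCCCCCCCC"],
    )
    tree = bootstrap_support(aln, n_reps=100, seed=1)
    labels = [
        n.label
        for n in tree.tree.preorder_node_iter()
        if not n.is_leaf() and n.label is not None
    ]
    assert labels == ["100"]


def test_bootstrap_deterministic_and_bounded():
    rng = np.random.default_rng(2)
    taxa = ["A", "B", "C", "D", "E"]
    rows = ["".join(rng.choice(list("ACDE"), size=30)) for _ in taxa]
    aln = Alignment(taxa, rows)
    t1 = bootstrap_support(aln, n_reps=50, seed=9)
    t2 = bootstrap_support(aln, n_reps=50, seed=9)
    assert t1.to_newick() == t2.to_newick()
    for node in t1.tree.preorder_node_iter():
        if node.label is not None:
            assert 0 <= int(node.label) <= 100


def test_bootstrap_invariant_under_taxon_reordering():
    rng = np.random.default_rng(3)
    taxa = ["A", "B", "C", "D", "E"]
    rows = ["".join(rng.choice(list("ACDE"), size=40)) for _ in taxa]
    aln1 = Alignment(taxa, rows)
    order = [3, 1, 4, 0, 2]
    aln2 = Alignment([taxa[i] for i in order], [rows[i] for i in order])
    s1 = bootstrap_support(aln1, n_reps=30, seed=4)
    s2 = bootstrap_support(aln2, n_reps=30, seed=4)

    def supports(t):
        out = {}
        leaves = t.leaf_labels
        ref = min(leaves)
        for node, ls in t.node_leafsets().items():
            if node.label is not None and not node.is_leaf():
                side = leaves - ls if ref in ls else ls
                out[frozenset(side)] = node.label
        return out

    assert supports(s1) == supports(s2)


def test_bootstrap_split_signal_near_fifty():
    """50/50 conflicting columns on 4 taxa: support follows the binomial
    resampling model (assertion bounds computed from that model)."""
    n1, n2 = 50, 51  # odd total: replicates can never tie
    rows = {
        "A": "A" * n1 + "A" * n2,
        "B": "A" * n1 + "C" * n2,
        "C": "C" * n1 + "A" * n2,
        "D": "C" * n1 + "C" * n2,
    }
    aln = Alignment(list(rows), list(rows.values()))
    n_reps = 1000
    tree = bootstrap_support(aln, n_reps=n_reps, model="p", seed=5)
    (support,) = [
        int(n.label)
        for n in tree.tree.preorder_node_iter()
        if not n.is_leaf() and n.label is not None
    ]
    # replicate majority is Binomial(101, 51/101); p = P(type-2 majority)
    from scipy.stats import binom

    p_majority = 1.0 - binom.cdf(50, n1 + n2, n2 / (n1 + n2))
    se = 100 * np.sqrt(p_majority * (1 - p_majority) / n_reps)
    assert abs(support - 100 * p_majority) <= 3 * se + 1


def test_bootstrap_zero_reps_errors():
    aln = Alignment(["A", "B", "C", "D"], ["AA", "AA", "CC", "CC"])
    with pytest.raises(PhyloError):
        bootstrap_support(aln, n_reps=0)


# ---------------------------------------------------------------------------
# rooting


def test_root_at_single_leaf_outgroup():
    tree = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:3);", rooted=False)
    rooted = root_at_outgroup(tree, {"D"})
    assert rooted.rooted
    kids = sorted(
        tuple(sorted(ls))
        for ch in rooted.tree.seed_node.child_nodes()
        for ls in [rooted.node_leafsets()[ch]]
    )
    assert kids == [("A", "B", "C"), ("D",)]


def test_root_on_internal_edge_splits_length():
    tree = PhyloTree.from_newick("((A:1,B:1):2,C:1,D:1);", rooted=False)
    rooted = root_at_outgroup(tree, {"C", "D"})
    for ch in rooted.tree.seed_node.child_nodes():
        assert ch.edge.length == pytest.approx(1.0)


def test_root_unroot_round_trip_preserves_bipartitions(rng):
    for _ in range(30):
        n = int(rng.integers(4, 10))
        newick, labels, _ = random_tree_with_distances(rng, n)
        tree = PhyloTree.from_newick(newick, rooted=False)
        og = labels[int(rng.integers(n))]
        rooted = root_at_outgroup(tree, {og})
        assert rooted.bipartitions() == tree.bipartitions()


def test_paraphyletic_outgroup_errors():
    tree = PhyloTree.from_newick("((A:1,C:1):1,B:1,D:1);", rooted=False)
    with pytest.raises(PhyloError, match="paraphyletic"):
        root_at_outgroup(tree, {"A", "B"})


# ---------------------------------------------------------------------------
# Robinson-Foulds


def test_rf_identity_and_four_taxon_case():
    t1 = PhyloTree.from_newick("((A,B),(C,D));")
    t2 = PhyloTree.from_newick("((A,C),(B,D));")
    assert robinson_foulds(t1, t1) == 0
    assert robinson_foulds(t1, t2) == 2
    assert robinson_foulds(t2, t1) == 2


def test_rf_leaf_set_mismatch_errors():
    t1 = PhyloTree.from_newick("((A,B),(C,D));")
    t2 = PhyloTree.from_newick("((A,B),(C,E));")
    with pytest.raises(PhyloError, match="E"):
        robinson_foulds(t1, t2)


def test_rf_matches_dendropy_oracle(rng):
    import dendropy
    from dendropy.calculate import treecompare

    for _ in range(60):
        n = int(rng.integers(4, 9))
        labels = [f"L{i}" for i in range(n)]
        s1 = random_topology(rng, labels)
        s2 = random_topology(rng, list(labels))
        n1, n2 = struct_to_newick(s1), struct_to_newick(s2)
        ours = robinson_foulds(
            PhyloTree.from_newick(n1, rooted=False),
            PhyloTree.from_newick(n2, rooted=False),
        )
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        assert ours == treecompare.symmetric_difference(d1, d2)
        # and against the from-first-principles bipartition oracle
        leaves = frozenset(labels)
        assert ours == len(
            bipartitions_of(s1, leaves) ^ bipartitions_of(s2, leaves)
        )


def test_restricted_rf_equals_pruned_rf(rng):
    for _ in range(20):
        n = int(rng.integers(6, 10))
        labels = [f"L{i}" for i in range(n)]
        t1 = PhyloTree.from_newick(
            struct_to_newick(random_topology(rng, labels)), rooted=False
        )
        t2 = PhyloTree.from_newick(
            struct_to_newick(random_topology(rng, list(labels))), rooted=False
        )
        subset = set(rng.choice(labels, size=n - 2, replace=False))
        pruned = robinson_foulds(t1.prune_to(subset), t2.prune_to(subset))
        assert robinson_foulds_restricted(t1, t2, subset) == pruned


# ---------------------------------------------------------------------------
# monophyly


def test_monophyly_simple_cases():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    assert is_monophyletic(tree, {"A", "B"}).monophyletic
    res = is_monophyletic(tree, {"A", "C"})
    assert not res.monophyletic
    assert res.intruders == frozenset({"B", "D"})


def test_monophyly_requires_rooted_tree():
    tree = PhyloTree.from_newick("((A,B),C,D);", rooted=False)
    with pytest.raises(PhyloError, match="rooted"):
        is_monophyletic(tree, {"A", "B"})


def test_monophyly_matches_exhaustive_clade_oracle(rng):
    for _ in range(60):
        n = int(rng.integers(4, 11))
        labels = [f"L{i}" for i in range(n)]
        struct = random_topology(rng, labels)
        tree = PhyloTree.from_newick(struct_to_newick(struct), rooted=True)
        k = int(rng.integers(2, n))
        group = frozenset(rng.choice(labels, size=k, replace=False))
        res = is_monophyletic(tree, group)
        # oracle: smallest clade (from the construction structure) >= group
        containing = [c for c in clades_of(struct) if group <= c]
        smallest = min(containing, key=len)
        assert res.clade_taxa == smallest
        assert res.monophyletic == (smallest == group)
        assert res.intruders == smallest - group


# ---------------------------------------------------------------------------
# branch-length outliers


def test_outliers_all_equal_lengths_no_flags():
    tree = PhyloTree.from_newick(
        "((A:1,B:1):1,(C:1,D:1):1,(E:1,F:1):1);", rooted=False
    )
    with pytest.warns(UserWarning, match="equal"):
        report = branch_length_outliers(tree, scope="external")
    assert report.flagged == []


def test_outliers_flag_single_long_external_branch():
    taxa = [f"T{i}" for i in range(9)]
    parts = ",".join(f"{t}:1" for t in taxa)
    tree = PhyloTree.from_newick(f"({parts},X:10);", rooted=False)
    report = branch_length_outliers(tree, k=3, scope="external")
    assert [fe.edge_id for fe in report.flagged] == ["X"]
    # by hand: median 1; MAD 0 (nine equal lengths), so the scale falls back
    # to 1.2533 * meanAD = 1.2533 * 0.9 -> z = 9 / 1.128 = 7.98
    assert report.median == 1.0
    assert report.flagged[0].z == pytest.approx(9.0 / (1.2533 * 0.9), rel=1e-6)


def test_outlier_flag_covering_handles_sister_pairs():
    # long internal branch subtending a 2-leaf clade
    tree = PhyloTree.from_newick(
        "(((A:1,B:1):9,C:1):1,(D:1,E:1):1,(F:1,G:1):1);", rooted=False
    )
    report = branch_length_outliers(tree, k=3, scope="both")
    fe = report.flag_covering("A")
    assert fe is not None and not fe.external
    assert report.flag_covering("D") is None


def test_first_diverging_clade():
    tree = PhyloTree.from_newick("(A,((B,C),(D,(E,F))));", rooted=True)
    assert first_diverging_clade(tree) == frozenset({"A"})
    assert first_diverging_clade(tree, {"B", "C", "D", "E"}) == frozenset(
        {"B", "C"}
    )
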
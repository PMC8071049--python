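"""Dollo loss reconstruction and horizontal-transfer classification."""

import numpy as np
import pytest

from nifloss.hgt_loss import (
    GeneHistoryCall,
    HistoryConfig,
    PresenceProfile,
    classify_gene_history,
    count_gains_without_losses,
    dollo_reconstruct,
    summarize_history,
)
from nifloss.phylo import PhyloError, PhyloTree, branch_length_outliers

from conftest import (
    clades_of,
    oracle_min_losses,
    random_topology,
    struct_to_newick,
)


# ---------------------------------------------------------------------------
# Dollo


def test_full_presence_needs_no_losses():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    hist = dollo_reconstruct(tree, PresenceProfile("g", frozenset("ABCD")))
    assert hist.n_losses == 0
    assert hist.gain_clade == frozenset("ABCD")


def test_alternating_presence_needs_two_losses():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    hist = dollo_reconstruct(tree, PresenceProfile("g", frozenset("AC")))
    assert hist.n_losses == 2
    assert sorted(sorted(c) for c in hist.loss_clades) == [["B"], ["D"]]


def test_gain_node_is_mrca_of_present():
    tree = PhyloTree.from_newick("((A,B),((C,D),E));", rooted=True)
    hist = dollo_reconstruct(tree, PresenceProfile("g", frozenset("CD")))
    assert hist.gain_clade == frozenset("CD")
    assert hist.n_losses == 0


def test_pinned_gain_contradiction_errors():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    with pytest.raises(PhyloError, match="contradicts pinned gain"):
        dollo_reconstruct(
            tree,
            PresenceProfile("g", frozenset("AC")),
            pinned_gain=frozenset("AB"),
        )


def test_pinned_gain_at_root_counts_outside_losses():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    hist = dollo_reconstruct(
        tree, PresenceProfile("g", frozenset("AB")), pinned_gain=frozenset("ABCD")
    )
    assert hist.n_losses == 1
    assert hist.loss_clades == [frozenset("CD")]


def test_dollo_matches_brute_force_on_random_instances(rng):
    for _ in range(60):
        n = int(rng.integers(4, 11))
        labels = [f"L{i}" for i in range(n)]
        struct = random_topology(rng, labels)
        tree = PhyloTree.from_newick(struct_to_newick(struct), rooted=True)
        k = int(rng.integers(1, n + 1))
        present = frozenset(rng.choice(labels, size=k, replace=False))
        hist = dollo_reconstruct(tree, PresenceProfile("g", present))
        clades = clades_of(struct)
        gain = min((c for c in clades if present <= c), key=len)
        assert hist.gain_clade == gain
        assert hist.n_losses == oracle_min_losses(clades, gain, present)


def test_adding_a_present_taxon_only_splits_its_own_loss_clade(rng):
    """Monotone repair under a fixed (root-pinned) gain: presence at one more
    leaf removes exactly the loss clade containing it and replaces it with
    sub-clades of that clade; all other loss events are untouched.  Without
    pinning, the gain clade can only grow."""
    for _ in range(40):
        n = int(rng.integers(5, 11))
        labels = [f"L{i}" for i in range(n)]
        struct = random_topology(rng, labels)
        tree = PhyloTree.from_newick(struct_to_newick(struct), rooted=True)
        root = frozenset(labels)
        k = int(rng.integers(1, n))
        present = frozenset(rng.choice(labels, size=k, replace=False))
        extra = min(set(labels) - present)
        h0 = dollo_reconstruct(tree, PresenceProfile("g", present), pinned_gain=root)
        h1 = dollo_reconstruct(
            tree, PresenceProfile("g", present | {extra}), pinned_gain=root
        )
        (split,) = [c for c in h0.loss_clades if extra in c]
        kept = [c for c in h0.loss_clades if c is not split]
        new = [c for c in h1.loss_clades if c not in kept]
        assert all(c < split for c in new)
        assert sorted(map(sorted, kept + new)) == sorted(
            map(sorted, h1.loss_clades)
        )
        # MRCA gain only grows
        g0 = dollo_reconstruct(tree, PresenceProfile("g", present))
        g1 = dollo_reconstruct(tree, PresenceProfile("g", present | {extra}))
        assert g0.gain_clade <= g1.gain_clade


def test_gain_count_without_losses():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    profile = PresenceProfile("g", frozenset("AC"))
    assert count_gains_without_losses(tree, profile) == 2
    assert count_gains_without_losses(
        tree, PresenceProfile("g", frozenset("ABCD"))
    ) == 1


# ---------------------------------------------------------------------------
# classification


def _vertical_setting():
    species = PhyloTree.from_newick(
        "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);", rooted=True
    )
    gene = PhyloTree.from_newick(
        "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);", rooted=True
    )
    return species, gene


def test_vertical_family_all_vertical():
    species, gene = _vertical_setting()
    report = branch_length_outliers(gene, scope="both")
    for taxon in sorted(gene.leaf_labels):
        call = classify_gene_history(taxon, "nifB", gene, species, report)
        assert call.verdict == "vertical"


def test_long_root_proximal_branch_is_extra_phylum():
    species = PhyloTree.from_newick(
        "((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);", rooted=True
    )
    # X joins near the root on a very long branch
    gene = PhyloTree.from_newick(
        "(((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1):0.2,X:15);", rooted=True
    )
    report = branch_length_outliers(gene, scope="both")
    call = classify_gene_history("X", "nifS", gene, species, report)
    assert call.verdict == "extra_phylum_hgt"
    assert call.root_proximal


def test_wrong_clade_normal_branch_is_intra_phylum():
    species = PhyloTree.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);",
        rooted=True,
    )
    # F placed inside the A/B clade with an ordinary branch length
    gene = PhyloTree.from_newick(
        "(((A:1,(B:1,F:1):1):1,(C:1,D:1):1):1,((E:1,G:1):1,(H:1,X0:1):1):1);",
        rooted=True,
    ).prune_to({"A", "B", "C", "D", "E", "F", "G", "H"})
    gene.rooted = True
    report = branch_length_outliers(gene, scope="both")
    call = classify_gene_history("F", "nifV", gene, species, report)
    assert call.verdict == "intra_phylum_hgt"
    assert call.rf_improvement >= 2


def test_verdict_invariants_enforced():
    with pytest.raises(ValueError):
        GeneHistoryCall("A", "nifB", "extra_phylum_hgt")
    with pytest.raises(ValueError):
        GeneHistoryCall("A", "nifB", "intra_phylum_hgt", long_branch_z=5.0)


def test_classification_stable_under_taxon_relabeling():
    species, gene = _vertical_setting()
    report = branch_length_outliers(gene, scope="both")
    base = {
        t: classify_gene_history(t, "nifB", gene, species, report).verdict
        for t in sorted(gene.leaf_labels)
    }
    # relabel by a fixed permutation on both trees
    perm = dict(zip("ABCDEF", "FEDCBA"))
    sp2 = PhyloTree.from_newick(
        "".join(perm.get(ch, ch) for ch in species.to_newick()), rooted=True
    )
    g2 = PhyloTree.from_newick(
        "".join(perm.get(ch, ch) for ch in gene.to_newick()), rooted=True
    )
    report2 = branch_length_outliers(g2, scope="both")
    for t, verdict in base.items():
        assert (
            classify_gene_history(perm[t], "nifB", g2, sp2, report2).verdict
            == verdict
        )


def test_taxon_absent_from_gene_tree_errors():
    species, gene = _vertical_setting()
    report = branch_length_outliers(gene, scope="both")
    with pytest.raises(PhyloError, match="absent"):
        classify_gene_history("Z", "nifB", gene, species, report)


def test_within_phylum_grafts_recovered_as_intra_phylum():
    """A gene copy grafted from a distant clade (ordinary branch length) is
    classified intra-phylum in >= 90% of 100 simulated replicates."""
    import numpy as np

    from nifloss.phylo import (
        Alignment,
        first_diverging_clade,
        neighbor_joining,
        protein_distance,
        root_at_outgroup,
    )
    from nifloss.simulate import simulate_sequences, simulate_species_tree

    AA = "ACDEFGHIKLMNPQRSTVWY"
    rng = np.random.default_rng(41)
    ok = 0
    for _ in range(100):
        ts, qs = (int(x) for x in rng.integers(2**31, size=2))
        tree = simulate_species_tree(12, 1.0, seed=ts)
        aln = simulate_sequences(tree, 300, 0.1, seed=qs)
        seqs = dict(zip(aln.taxa, aln.rows))
        taxa = sorted(seqs)
        recip = taxa[int(rng.integers(len(taxa)))]
        donor = max(
            (t for t in taxa if t != recip),
            key=lambda t: tree.patristic_distance(recip, t),
        )
        graft = list(seqs[donor])
        mr = np.random.default_rng(qs + 1)
        for i in mr.choice(len(graft), size=4, replace=False):
            graft[i] = AA[int(mr.integers(20))]
        seqs[recip] = "".join(graft)
        gene = neighbor_joining(
            protein_distance(
                Alignment(taxa, [seqs[t] for t in taxa]), model="jc20"
            )
        )
        og = first_diverging_clade(tree)
        try:
            rooted = root_at_outgroup(gene, og & gene.leaf_labels)
        except PhyloError:
            rooted = root_at_outgroup(gene, {min(og)})
        report = branch_length_outliers(rooted, scope="both")
        call = classify_gene_history(recip, "nifB", rooted, tree, report)
        ok += call.verdict == "intra_phylum_hgt"
    assert ok >= 90


# ---------------------------------------------------------------------------
# summary


def test_summary_reports_gains_losses_and_headline():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    hist = dollo_reconstruct(tree, PresenceProfile("nifHDK", frozenset("ABC")))
    calls = [GeneHistoryCall("A", "nifH", "vertical")]
    report = summarize_history(
        calls, {"nifHDK": hist}, tree, {"A": True, "B": True, "C": True, "D": False}
    )
    assert report.per_template["nifHDK"]["n_losses"] == 1
    assert report.per_template["nifHDK"]["loss_clades"] == [["D"]]
    assert "zero extra-phylum transfers" in report.headline
    text = report.to_text()
    assert "diazotrophs: 3/4" in text


def test_summary_headline_with_transfer():
    tree = PhyloTree.from_newick("((A,B),(C,D));", rooted=True)
    hist = dollo_reconstruct(tree, PresenceProfile("nifHDK", frozenset("ABCD")))
    calls = [
        GeneHistoryCall(
            "C", "nifS", "extra_phylum_hgt", long_branch_z=8.0, root_proximal=True
        )
    ]
    report = summarize_history(
        calls, {"nifHDK": hist}, tree, {t: True for t in "ABCD"}
    )
    assert "1 extra-phylum transfer" in report.headline
    payload = report.to_json()
    assert '"verdict": "extra_phylum_hgt"' in payload
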
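"""Choosing among multiple copies of a nif gene, and nif1/nif2 set identity.

When an operon carries two copies of the same gene (a duplication, or the
second copy of a dual operon set), one representative must be chosen for the
family phylogeny.  The criterion is congruence with the species tree: each
candidate is placed in a gene tree together with the single-copy sequences
from the other genomes, and the candidate whose tree is topologically closest
(pruned Robinson–Foulds) to the species tree wins.  Ties go to the shorter
external branch, then to the lexicographically smaller locus tag, so the
choice is deterministic.

Dual operon sets are labelled nif1/nif2 by affinity to a reference genome
whose sets are already known (the A. variabilis convention): per gene tree,
the set whose tip is patristically closer to the reference nif1 tip votes
nif1, and the per-genome label is the majority over genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .phylo import (
    Alignment,
    PhyloTree,
    neighbor_joining,
    protein_distance,
    robinson_foulds,
)

__all__ = [
    "CopyCandidate",
    "CongruenceScore",
    "score_candidate",
    "select_copy",
    "assign_set_identity",
    "SetIdentity",
    "tip_label",
    "write_score_table",
]


def tip_label(genome_id: str, set_label: str | None = None) -> str:
    """Gene-tree tip naming convention for (possibly dual-set) genomes."""
    return genome_id if set_label in (None, "set1") else f"{genome_id}@{set_label}"


@dataclass(frozen=True)
class CopyCandidate:
    gene_name: str
    genome_id: str
    locus_tag: str
    sequence: str
    operon_call: object | None = None  # OperonCall back-reference, if any


@dataclass
class CongruenceScore:
    candidate: CopyCandidate
    rf: int
    external_branch: float
    tie_break_rank: int = 0


def _gene_tree_with(
    candidate: CopyCandidate, cohort: Mapping[str, str]
) -> PhyloTree:
    taxa = [candidate.genome_id] + sorted(cohort)
    rows = [candidate.sequence] + [cohort[g] for g in sorted(cohort)]
    aln = Alignment(taxa, rows)
    return neighbor_joining(protein_distance(aln, model="jc20"))


def score_candidate(
    candidate: CopyCandidate,
    cohort: Mapping[str, str],
    species_tree: PhyloTree,
) -> CongruenceScore:
    """Congruence of the candidate-bearing gene tree with the species tree.

    ``cohort`` maps genome_id -> aligned single-copy sequence from the other
    genomes.  The species tree is pruned to the shared genome set and the
    Robinson–Foulds distance to the gene tree is the score (lower = more
    species-tree-like placement).
    """
    if candidate.genome_id in cohort:
        raise ValueError("cohort must not contain the candidate's genome")
    if len(cohort) < 3:
        raise ValueError("insufficient cohort: need >= 3 other genomes")
    gene_tree = _gene_tree_with(candidate, cohort)
    pruned = species_tree.prune_to(gene_tree.leaf_labels)
    rf = robinson_foulds(gene_tree, pruned)
    return CongruenceScore(
        candidate=candidate,
        rf=rf,
        external_branch=gene_tree.external_branch_length(candidate.genome_id),
    )


def select_copy(
    candidates: Sequence[CopyCandidate],
    cohort: Mapping[str, str],
    species_tree: PhyloTree,
) -> tuple[CopyCandidate, list[CongruenceScore]]:
    """Pick the copy whose placement best matches the species tree.

    Minimal RF wins; ties broken by (1) shorter external branch in the gene
    tree, (2) lexicographic locus_tag.  A single candidate is returned
    unscored.  Deterministic under permutation of the input order.
    """
    if not candidates:
        raise ValueError("no candidates")
    if len(candidates) == 1:
        return candidates[0], []
    scores = [score_candidate(c, cohort, species_tree) for c in candidates]
    ranked = sorted(
        scores,
        key=lambda s: (s.rf, s.external_branch, s.candidate.locus_tag),
    )
    for rank, s in enumerate(ranked):
        s.tie_break_rank = rank
    return ranked[0].candidate, ranked


def write_score_table(scores: Sequence[CongruenceScore], path: str | Path) -> None:
    rows = [
        {
            "genome_id": s.candidate.genome_id,
            "gene": s.candidate.gene_name,
            "locus_tag": s.candidate.locus_tag,
            "rf": s.rf,
            "external_branch": s.external_branch,
            "rank": s.tie_break_rank,
            "selected": "1" if s.tie_break_rank == 0 else "",
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SetIdentity:
    """nif1/nif2 labels for one dual-set genome, with the voting margin."""

    genome_id: str
    labels: dict[str, str]  # set1/set2 -> nif1/nif2
    votes_nif1_set1: int
    votes_total: int

    @property
    def margin(self) -> float:
        if self.votes_total == 0:
            return 0.0
        return abs(2 * self.votes_nif1_set1 - self.votes_total) / self.votes_total


def assign_set_identity(
    dual_genomes: Sequence[str],
    reference_genome: str,
    reference_labels: Mapping[str, str],
    gene_trees: Mapping[str, PhyloTree],
) -> dict[str, SetIdentity]:
    """Label each dual genome's operon sets nif1/nif2 by reference affinity.

    ``reference_labels`` maps the reference genome's set1/set2 to nif1/nif2
    (external knowledge, as for A. variabilis).  For every gene tree that
    contains the reference nif1 tip and both of a genome's set tips, the set
    patristically closer to the reference nif1 tip votes nif1; the per-genome
    label is the majority across genes.  A genome with a single set is nif1
    by default (vertical presumption).  Symmetric under swapping the
    arbitrary set1/set2 bookkeeping labels.
    """
    ref_set_for_nif1 = next(
        (s for s, lab in reference_labels.items() if lab == "nif1"), None
    )
    if ref_set_for_nif1 is None:
        raise ValueError("reference_labels must assign nif1 to one set")
    ref_tip = tip_label(reference_genome, ref_set_for_nif1)

    out: dict[str, SetIdentity] = {}
    for genome in dual_genomes:
        votes_set1 = 0
        total = 0
        for gene, tree in gene_trees.items():
            tips = tree.leaf_labels
            t1, t2 = tip_label(genome, "set1"), tip_label(genome, "set2")
            if ref_tip not in tips or t1 not in tips or t2 not in tips:
                continue  # this gene abstains
            d1 = tree.patristic_distance(t1, ref_tip)
            d2 = tree.patristic_distance(t2, ref_tip)
            if d1 == d2:
                continue
            total += 1
            if d1 < d2:
                votes_set1 += 1
        if total == 0:
            raise ValueError(
                f"{genome}: every gene tree abstains; cannot assign nif1/nif2"
            )
        if votes_set1 * 2 >= total:
            labels = {"set1": "nif1", "set2": "nif2"}
            n1 = votes_set1
        else:
            labels = {"set1": "nif2", "set2": "nif1"}
            n1 = votes_set1
        out[genome] = SetIdentity(
            genome_id=genome, labels=labels, votes_nif1_set1=n1, votes_total=total
        )
    return out


def write_set_identity_report(
    identities: Mapping[str, SetIdentity], path: str | Path
) -> None:
    rows = [
        {
            "genome_id": si.genome_id,
            "set1": si.labels["set1"],
            "set2": si.labels["set2"],
            "votes_nif1_set1": si.votes_nif1_set1,
            "votes_total": si.votes_total,
            "margin": si.margin,
        }
        for si in identities.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
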
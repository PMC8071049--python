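"""Ground-truth simulator: species trees, protein evolution, operon-bearing
gene orders, lineage losses, dual operon sets and injected transfers.

A :class:`SyntheticScenario` describes the generating conditions; calling
:func:`generate_scenario` produces a :class:`GroundTruth` whose every event is
recorded, and :func:`emit_dataset` serializes it into exactly the file
formats the analysis readers consume (gene-table TSVs, protein FASTAs, an
orthogroup table, marker alignments, a species-tree Newick and a truth JSON).

The generating model, in outline:

* species tree — Yule (pure birth) with exponential waiting times; one
  distant outgroup leaf ("OUT") is attached below the ingroup root so that
  inferred trees can be rooted the way the real workflow roots them;
* sequences — root sequence uniform over the 20 amino acids; along each
  edge every site is replaced with probability 1 - exp(-rate * length), the
  replacement drawn uniformly from the other 19 letters (no indels, so
  family members are mutually aligned by construction);
* nif history — the full repertoire is gained at the (ingroup) root; each
  edge loses the whole repertoire with ``loss_prob_per_edge`` (inherited by
  descendants); a lost lineage keeps a residual nifS or nifV with
  ``residual_retention_prob``; with ``dual_set_prob`` one diazotroph clade
  receives a second, donor-derived operon set (the nif2 analogue); explicit
  extra-phylum transfer events replace a carrier's gene with a copy evolved
  from the root on a branch ``multiplier`` times the mean root-to-tip depth;
* gene order — operon blocks embedded in unlabeled filler genes, with
  optional internal filler insertions, block translocations, fused nifEN
  records and a distantly placed second operon set for dual genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .annotation_io import GeneRecord, GenomeAnnotation, NifCatalog, write_gene_table
from .orthogroups import OrthogroupTable, write_orthogroup_table
from .phylo import AA_ALPHABET, Alignment, PhyloTree

__all__ = [
    "SyntheticScenario",
    "ExtraHgtEvent",
    "GroundTruth",
    "simulate_species_tree",
    "simulate_sequences",
    "simulate_histories",
    "generate_scenario",
    "emit_dataset",
    "expected_p_distance",
    "OUTGROUP_LABEL",
]

OUTGROUP_LABEL = "OUT"

#: mean lengths (aa) of the short accessory proteins seen in real genomes;
#: the remaining nif proteins are set to a generic 300 aa
DEFAULT_NIF_LENGTHS: dict[str, int] = {
    "nifB": 300, "nifS": 300, "nifU": 300,
    "nifH": 300, "nifD": 300, "nifK": 300,
    "nifE": 300, "nifN": 300, "nifX": 137, "nifW": 106,
    "nifV": 300, "nifZ": 94, "nifT": 67,
}

OPERON_BLOCKS: dict[str, tuple[str, ...]] = {
    "nifBSU": ("nifB", "nifS", "nifU"),
    "nifHDK": ("nifH", "nifD", "nifK"),
    "nifENXW": ("nifE", "nifN", "nifX", "nifW"),
    "nifVZT": ("nifV", "nifZ", "nifT"),
}

RESIDUAL_GENES = ("nifS", "nifV")


@dataclass(frozen=True)
class ExtraHgtEvent:
    """One extra-phylum transfer: replace ``target``'s copy of ``gene`` with a
    root-attached copy on a branch ``multiplier`` x the mean tree depth.
    ``target``/``gene`` left as None are drawn at generation time among
    carriers (gene drawn from the residual-prone pair nifS/nifV)."""

    target: str | None = None
    gene: str | None = None
    multiplier: float = 5.0


@dataclass
class SyntheticScenario:
    """Generating conditions for one synthetic dataset.

    Defaults are the package's standing study conditions: 20 ingroup taxa on
    a Yule tree, 31 markers, per-edge repertoire-loss probability 0.05,
    occasional residual nifS/nifV retention, occasional fused nifEN, and a
    moderate chance of one dual operon set transferred within the phylum.
    """

    seed: int = 0
    n_taxa: int = 20
    birth_rate: float = 1.0
    n_markers: int = 31
    marker_length: int = 100
    nif_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_NIF_LENGTHS)
    )
    substitution: float = 0.1
    loss_prob_per_edge: float = 0.05
    residual_retention_prob: float = 0.1
    insertion_prob: float = 0.2
    fusion_prob: float = 0.1
    dual_set_prob: float = 0.3
    extra_hgt: tuple[ExtraHgtEvent, ...] = ()
    include_outgroup: bool = True
    background_genes: int = 40

    def __post_init__(self) -> None:
        for name, p in [
            ("loss_prob_per_edge", self.loss_prob_per_edge),
            ("residual_retention_prob", self.residual_retention_prob),
            ("insertion_prob", self.insertion_prob),
            ("fusion_prob", self.fusion_prob),
            ("dual_set_prob", self.dual_set_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if any(l <= 0 for l in self.nif_lengths.values()):
            raise ValueError("nif lengths must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "SyntheticScenario":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        hgt = tuple(
            ExtraHgtEvent(
                target=e.get("target"),
                gene=e.get("gene"),
                multiplier=e.get("multiplier", 5.0),
            )
            for e in data.pop("extra_hgt", [])
        )
        return cls(extra_hgt=hgt, **data)


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> PhyloTree:
    """Rooted Yule tree with ``n_taxa`` leaves labelled T001..Tnnn.

    Starting from two lineages, each phase waits Exp(k * birth_rate) and
    splits a uniformly chosen lineage; a final waiting time gives the
    terminal branches positive length.  The root split is therefore uniform
    on 1..n-1, the classic Yule property.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    while len(active) < n_taxa:
        k = len(active)
        t = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            node.edge.length += t
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    t = rng.exponential(1.0 / (birth_rate * n_taxa))
    for node in active:
        node.edge.length += t

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    width = max(3, len(str(n_taxa)))
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        leaf.taxon = tns.new_taxon(f"T{str(i).zfill(width)}")
    tree.is_rooted = True
    return PhyloTree(tree, rooted=True)


def _attach_outgroup(ingroup: PhyloTree) -> PhyloTree:
    """New root with the ingroup on a short stem and OUT on a long branch."""
    depths = ingroup.depths()
    mean_depth = float(
        np.mean([depths[lf] for lf in ingroup.tree.leaf_node_iter()])
    )
    old_root = ingroup.tree.seed_node
    new_root = dendropy.Node()
    new_root.add_child(old_root)
    old_root.edge.length = 0.3 * mean_depth
    out_leaf = dendropy.Node()
    out_leaf.taxon = ingroup.tree.taxon_namespace.new_taxon(OUTGROUP_LABEL)
    out_leaf.edge.length = 1.3 * mean_depth
    new_root.add_child(out_leaf)
    tree = dendropy.Tree(
        taxon_namespace=ingroup.tree.taxon_namespace, seed_node=new_root
    )
    tree.is_rooted = True
    return PhyloTree(tree, rooted=True)


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve(
    tree: PhyloTree, length: int, rate: float, rng: np.random.Generator
) -> dict[dendropy.Node, np.ndarray]:
    """Sequences (as int codes 0..19) at every node, evolved preorder."""
    seqs: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = rng.integers(0, 20, size=length)
            continue
        parent_seq = seqs[node.parent_node]
        ell = node.edge.length or 0.0
        p_replace = 1.0 - np.exp(-rate * ell)
        mask = rng.random(length) < p_replace
        seq = parent_seq.copy()
        if mask.any():
            # uniform over the 19 letters other than the current one
            shift = rng.integers(1, 20, size=int(mask.sum()))
            seq[mask] = (seq[mask] + shift) % 20
        seqs[node] = seq
    return seqs


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


def _evolve_along_path(
    start: np.ndarray, lengths: Iterable[float], rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    seq = start.copy()
    for ell in lengths:
        p_replace = 1.0 - np.exp(-rate * ell)
        mask = rng.random(seq.size) < p_replace
        if mask.any():
            shift = rng.integers(1, 20, size=int(mask.sum()))
            seq[mask] = (seq[mask] + shift) % 20
    return seq


def simulate_sequences(
    tree: PhyloTree, length: int, rate: float, seed: int = 0
) -> Alignment:
    """Gap-free alignment of one protein family evolved along the tree."""
    if length <= 0 or rate < 0:
        raise ValueError("length must be positive and rate nonnegative")
    rng = np.random.default_rng(seed)
    seqs = _evolve(tree, length, rate, rng)
    leaves = sorted(tree.tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    return Alignment(
        [lf.taxon.label for lf in leaves],
        [_codes_to_str(seqs[lf]) for lf in leaves],
    )


def expected_p_distance(edge_lengths: Iterable[float], rate: float) -> float:
    """Exact expected p-distance between two tips under the edge-replacement
    model, for the path between them decomposed into ``edge_lengths``.

    Per edge, the probability of matching the start state contracts by
    1 - (20/19) * q with q = 1 - exp(-rate * l); stationarity is uniform.
    """
    prod = 1.0
    for ell in edge_lengths:
        q = 1.0 - np.exp(-rate * ell)
        prod *= 1.0 - (20.0 / 19.0) * q
    return (19.0 / 20.0) * (1.0 - prod)


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class TruthGene:
    genome_id: str
    locus_tag: str
    gene_name: str | None  # None for filler genes
    set_label: str | None = None
    fused: bool = False


@dataclass
class DualSetEvent:
    recipient_clade: frozenset[str]
    donor: str


@dataclass
class GroundTruth:
    """Full record of one simulated dataset; every emitted gene traces back
    to a :class:`TruthGene` and every event is listed."""

    scenario: SyntheticScenario
    tree: PhyloTree  # includes OUT when configured
    ingroup_taxa: tuple[str, ...]
    diazotroph: dict[str, bool]
    loss_clades: list[frozenset[str]]
    residuals: dict[str, str]  # lost taxon -> retained gene
    dual_event: DualSetEvent | None
    hgt_events: list[tuple[str, str, float]]  # (taxon, gene, multiplier)
    fused_genomes: frozenset[str]
    layouts: dict[str, list[TruthGene]]
    nif_sequences: dict[str, dict[str, str]]  # gene -> tip label -> sequence
    marker_alignments: dict[str, Alignment]

    @property
    def ingroup_tree(self) -> PhyloTree:
        if OUTGROUP_LABEL in self.tree.leaf_labels:
            sub = self.tree.prune_to(set(self.ingroup_taxa))
            sub.rooted = True
            return sub
        return self.tree

    def carriers(self, gene: str) -> frozenset[str]:
        """Ingroup taxa carrying ``gene`` (vertically, residually or by HGT)."""
        out = {t for t in self.ingroup_taxa if self.diazotroph[t]}
        out |= {t for t, g in self.residuals.items() if g == gene}
        return frozenset(out)

    def dual_genomes(self) -> frozenset[str]:
        if self.dual_event is None:
            return frozenset()
        return frozenset(
            t for t in self.dual_event.recipient_clade if self.diazotroph[t]
        )

    def dollo_truth(self, name: str = "repertoire") -> tuple[frozenset[str], int]:
        """Identifiable gain clade and minimal loss count on the true tree."""
        from .hgt_loss import PresenceProfile, dollo_reconstruct

        present = frozenset(t for t in self.ingroup_taxa if self.diazotroph[t])
        hist = dollo_reconstruct(
            self.ingroup_tree, PresenceProfile(name, present)
        )
        return frozenset(hist.gain_clade), hist.n_losses


# ---------------------------------------------------------------------------
# history + sequence generation


def sample_repertoire_losses(
    tree: PhyloTree,
    loss_prob_per_edge: float,
    rng: np.random.Generator,
    ingroup_taxa: Iterable[str] | None = None,
) -> list[frozenset[str]]:
    """Preorder Bernoulli loss sampling below the ingroup root.

    An edge that loses the repertoire passes the loss to all descendants, so
    sampling stops there; the recorded clades are therefore the maximal lost
    clades, mutually disjoint by construction.
    """
    leafsets = tree.node_leafsets()
    if ingroup_taxa is None:
        ingroup_taxa = tuple(sorted(tree.leaf_labels - {OUTGROUP_LABEL}))
    ingroup_root = next(
        n for n, ls in leafsets.items() if ls == frozenset(ingroup_taxa)
    )
    loss_clades: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if rng.random() < loss_prob_per_edge:
                loss_clades.append(leafsets[child])
            else:
                walk(child)

    walk(ingroup_root)
    return loss_clades


def simulate_histories(
    tree: PhyloTree, scenario: SyntheticScenario, seed: int | None = None
) -> GroundTruth:
    """Sample losses, residuals, dual sets and transfers, then evolve every
    marker and nif family (with transfer-modified paths) along the tree.

    ``tree`` must be the rooted species tree over the ingroup taxa plus the
    outgroup leaf when ``scenario.include_outgroup`` is set.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    ingroup_taxa = tuple(
        sorted(tree.leaf_labels - {OUTGROUP_LABEL})
    )
    leafsets = tree.node_leafsets()

    # --- losses: preorder below the ingroup root, inherited ----------------
    loss_clades = sample_repertoire_losses(
        tree, scenario.loss_prob_per_edge, rng, ingroup_taxa=ingroup_taxa
    )
    lost = set().union(*loss_clades) if loss_clades else set()
    diazotroph = {t: t not in lost for t in ingroup_taxa}
    if OUTGROUP_LABEL in tree.leaf_labels:
        diazotroph[OUTGROUP_LABEL] = False

    residuals: dict[str, str] = {}
    for t in sorted(lost):
        if rng.random() < scenario.residual_retention_prob:
            residuals[t] = RESIDUAL_GENES[int(rng.integers(len(RESIDUAL_GENES)))]

    # --- dual operon set ----------------------------------------------------
    dual_event: DualSetEvent | None = None
    if rng.random() < scenario.dual_set_prob:
        candidates = [
            (n, ls)
            for n, ls in leafsets.items()
            if 2 <= len(ls) <= 4
            and ls <= frozenset(ingroup_taxa)
            and all(diazotroph[t] for t in ls)
        ]
        donors_pool = [
            t for t in ingroup_taxa if diazotroph[t]
        ]
        if candidates:
            candidates.sort(key=lambda item: sorted(item[1]))
            node, clade = candidates[int(rng.integers(len(candidates)))]
            donors = [t for t in donors_pool if t not in clade]
            if donors:
                donor = donors[int(rng.integers(len(donors)))]
                dual_event = DualSetEvent(recipient_clade=clade, donor=donor)

    # --- extra-phylum transfers --------------------------------------------
    hgt_events: list[tuple[str, str, float]] = []
    for ev in scenario.extra_hgt:
        gene = ev.gene or RESIDUAL_GENES[int(rng.integers(len(RESIDUAL_GENES)))]
        carriers = sorted(
            [t for t in ingroup_taxa if diazotroph[t]]
            + [t for t, g in residuals.items() if g == gene]
        )
        if ev.target is None:
            if not carriers:
                continue  # nobody carries the gene; the event cannot land
            target = carriers[int(rng.integers(len(carriers)))]
        else:
            target = ev.target
            if target not in carriers:
                raise ValueError(
                    f"contradictory config: extra_hgt targets {target} which "
                    f"does not carry {gene} (lost lineage without residual)"
                )
        hgt_events.append((target, gene, ev.multiplier))

    # --- fusion -------------------------------------------------------------
    fused = frozenset(
        t for t in ingroup_taxa
        if diazotroph[t] and rng.random() < scenario.fusion_prob
    )

    # --- sequences ----------------------------------------------------------
    depths = tree.depths()
    mean_depth = float(
        np.mean([depths[lf] for lf in tree.tree.leaf_node_iter()])
    )
    node_by_label = {
        lf.taxon.label: lf for lf in tree.tree.leaf_node_iter()
    }
    marker_alignments: dict[str, Alignment] = {}
    for m in range(scenario.n_markers):
        name = f"marker{str(m + 1).zfill(2)}"
        seqs = _evolve(tree, scenario.marker_length, scenario.substitution, rng)
        leaves = sorted(tree.tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
        marker_alignments[name] = Alignment(
            [lf.taxon.label for lf in leaves],
            [_codes_to_str(seqs[lf]) for lf in leaves],
        )

    nif_sequences: dict[str, dict[str, str]] = {}
    dual_genomes = (
        sorted(t for t in dual_event.recipient_clade if diazotroph[t])
        if dual_event
        else []
    )
    for gene in sorted(scenario.nif_lengths):
        length = scenario.nif_lengths[gene]
        seqs = _evolve(tree, length, scenario.substitution, rng)
        tips: dict[str, str] = {}
        root_seq = seqs[tree.tree.seed_node]
        for t in ingroup_taxa:
            if diazotroph[t] or residuals.get(t) == gene:
                tips[t] = _codes_to_str(seqs[node_by_label[t]])
        # dual set: donor-lineage copy re-evolved down the recipient subtree
        if dual_event is not None:
            donor_parent = node_by_label[dual_event.donor].parent_node
            start = seqs[donor_parent]
            sub_leaves: dict[str, np.ndarray] = {}
            rec_node = next(
                n for n, ls in leafsets.items() if ls == dual_event.recipient_clade
            )

            def evolve_down(node: dendropy.Node, seq: np.ndarray) -> None:
                for child in node.child_nodes():
                    child_seq = _evolve_along_path(
                        seq, [child.edge.length or 0.0],
                        scenario.substitution, rng,
                    )
                    if child.is_leaf():
                        sub_leaves[child.taxon.label] = child_seq
                    else:
                        evolve_down(child, child_seq)

            stem_seq = _evolve_along_path(
                start, [rec_node.edge.length or 0.0], scenario.substitution, rng
            )
            evolve_down(rec_node, stem_seq)
            for t in dual_genomes:
                tips[f"{t}@set2"] = _codes_to_str(sub_leaves[t])
        # extra-phylum transfers: replace the copy with a root-attached one
        for target, hgt_gene, multiplier in hgt_events:
            if hgt_gene != gene:
                continue
            foreign = _evolve_along_path(
                root_seq, [multiplier * mean_depth], scenario.substitution, rng
            )
            tips[target] = _codes_to_str(foreign)
        nif_sequences[gene] = tips

    # --- gene order layouts -------------------------------------------------
    layouts = _build_layouts(
        scenario, rng, ingroup_taxa, diazotroph, residuals,
        dual_genomes, fused,
    )

    return GroundTruth(
        scenario=scenario,
        tree=tree,
        ingroup_taxa=ingroup_taxa,
        diazotroph=diazotroph,
        loss_clades=sorted(loss_clades, key=lambda ls: (len(ls), sorted(ls))),
        residuals=residuals,
        dual_event=dual_event,
        hgt_events=hgt_events,
        fused_genomes=fused,
        layouts=layouts,
        nif_sequences=nif_sequences,
        marker_alignments=marker_alignments,
    )


def _build_layouts(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    ingroup_taxa: tuple[str, ...],
    diazotroph: Mapping[str, bool],
    residuals: Mapping[str, str],
    dual_genomes: list[str],
    fused: frozenset[str],
) -> dict[str, list[TruthGene]]:
    layouts: dict[str, list[TruthGene]] = {}
    for genome in ingroup_taxa:

        def block(set_label: str | None, is_fused: bool) -> list[list[tuple]]:
            names = list(OPERON_BLOCKS)
            order = rng.permutation(len(names))  # operon-block translocation
            blocks = []
            for bi in order:
                bname = names[bi]
                members: list[tuple] = []
                for g in OPERON_BLOCKS[bname]:
                    if is_fused and g == "nifE":
                        members.append(("nifEN", set_label, True))
                        continue
                    if is_fused and g == "nifN":
                        continue
                    members.append((g, set_label, False))
                # internal filler insertions (gap stays below the merge limit)
                with_ins: list[tuple] = []
                for i, mem in enumerate(members):
                    with_ins.append(mem)
                    if i < len(members) - 1 and rng.random() < scenario.insertion_prob:
                        with_ins.append((None, None, False))
                blocks.append(with_ins)
            return blocks

        stream: list[tuple] = []

        def fillers(k: int) -> None:
            stream.extend([(None, None, False)] * k)

        if diazotroph[genome]:
            is_fused = genome in fused
            fillers(5)
            for blk in block("set1", is_fused):
                stream.extend(blk)
                fillers(6)
            fillers(scenario.background_genes)
            if genome in dual_genomes:
                fillers(60)  # "distant positions": beyond any merge range
                for blk in block("set2", is_fused):
                    stream.extend(blk)
                    fillers(6)
            fillers(5)
        else:
            fillers(scenario.background_genes // 2)
            if genome in residuals:
                stream.append((residuals[genome], None, False))
            fillers(scenario.background_genes // 2)

        layout: list[TruthGene] = []
        for idx, (gene, set_label, is_fused_rec) in enumerate(stream):
            layout.append(
                TruthGene(
                    genome_id=genome,
                    locus_tag=f"{genome}_{str(idx).zfill(4)}",
                    gene_name=gene,
                    set_label=set_label,
                    fused=is_fused_rec,
                )
            )
        layouts[genome] = layout
    return layouts


def generate_scenario(scenario: SyntheticScenario) -> GroundTruth:
    """Simulate tree + histories + sequences for one scenario (deterministic
    under ``scenario.seed``)."""
    ss = np.random.SeedSequence(scenario.seed)
    tree_seed, hist_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    tree = simulate_species_tree(scenario.n_taxa, scenario.birth_rate, tree_seed)
    if scenario.include_outgroup:
        tree = _attach_outgroup(tree)
    return simulate_histories(tree, scenario, seed=hist_seed)


# ---------------------------------------------------------------------------
# emission


def truth_catalog() -> NifCatalog:
    """Catalog whose orthogroup map matches the emitted orthogroup table."""
    mapping = {f"OG_{g}": g for g in DEFAULT_NIF_LENGTHS}
    mapping["OG_nifEN"] = "nifEN"
    return NifCatalog().with_orthogroup_map(mapping)


def _random_protein(rng: np.random.Generator, length: int = 250) -> str:
    return _codes_to_str(rng.integers(0, 20, size=length))


def truth_annotations(truth: GroundTruth) -> dict[str, GenomeAnnotation]:
    """In-memory gene tables corresponding to the truth layouts."""
    out: dict[str, GenomeAnnotation] = {}
    for genome, layout in truth.layouts.items():
        records = []
        for i, tg in enumerate(layout):
            start = 1 + i * 1000
            records.append(
                GeneRecord(
                    genome_id=genome,
                    contig_id="c1",
                    ordinal=i,
                    start=start,
                    end=start + 899,
                    strand="+",
                    locus_tag=tg.locus_tag,
                    gene_label=tg.gene_name,
                    orthogroup_id=f"OG_{tg.gene_name}" if tg.gene_name else None,
                )
            )
        out[genome] = GenomeAnnotation.from_records(genome, records)
    return out


def truth_orthogroups(truth: GroundTruth) -> OrthogroupTable:
    groups: dict[str, set[tuple[str, str]]] = {}
    for genome, layout in truth.layouts.items():
        for tg in layout:
            if tg.gene_name is None:
                continue
            groups.setdefault(f"OG_{tg.gene_name}", set()).add(
                (genome, tg.locus_tag)
            )
    return OrthogroupTable(groups)


def truth_proteomes(truth: GroundTruth) -> dict[str, dict[str, str]]:
    """Per-genome protein sequences keyed by locus_tag.

    nif proteins carry their simulated family sequences (a fused nifEN gene
    carries the nifE and nifN sequences concatenated); fillers are fresh
    random sequences, unalignable by construction.
    """
    rng = np.random.default_rng(
        int(np.random.SeedSequence([truth.scenario.seed, 7]).generate_state(1)[0])
        % (2**31)
    )
    out: dict[str, dict[str, str]] = {}
    for genome, layout in truth.layouts.items():
        prot: dict[str, str] = {}
        for tg in layout:
            if tg.gene_name is None:
                prot[tg.locus_tag] = _random_protein(rng)
                continue
            tip = genome if tg.set_label in (None, "set1") else f"{genome}@set2"
            if tg.gene_name == "nifEN":
                seq = (
                    truth.nif_sequences["nifE"][tip]
                    + truth.nif_sequences["nifN"][tip]
                )
            else:
                seq = truth.nif_sequences[tg.gene_name][tip]
            prot[tg.locus_tag] = seq
        out[genome] = prot
    return out


def emit_dataset(truth: GroundTruth, outdir: str | Path) -> Path:
    """Write the dataset files; every file parses cleanly by the package's
    own readers and every byte is determined by the scenario seed."""
    outdir = Path(outdir)
    for sub in ("genomes", "proteomes", "markers"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    annotations = truth_annotations(truth)
    for genome, ann in sorted(annotations.items()):
        write_gene_table(ann, outdir / "genomes" / f"{genome}.tsv")

    proteomes = truth_proteomes(truth)
    for genome, prot in sorted(proteomes.items()):
        with open(outdir / "proteomes" / f"{genome}.faa", "w") as fh:
            for tag, seq in prot.items():
                fh.write(f">{tag}\n{seq}\n")

    write_orthogroup_table(truth_orthogroups(truth), outdir / "orthogroups.tsv")

    for name, aln in sorted(truth.marker_alignments.items()):
        aln.write_fasta(outdir / "markers" / f"{name}.afa")

    truth.tree.write_newick(outdir / "species_tree.nwk")

    payload = {
        "seed": truth.scenario.seed,
        "ingroup_taxa": list(truth.ingroup_taxa),
        "diazotroph": truth.diazotroph,
        "loss_clades": [sorted(ls) for ls in truth.loss_clades],
        "residuals": truth.residuals,
        "dual": (
            {
                "recipient_clade": sorted(truth.dual_event.recipient_clade),
                "donor": truth.dual_event.donor,
            }
            if truth.dual_event
            else None
        ),
        "hgt_events": [
            {"taxon": t, "gene": g, "multiplier": m}
            for t, g, m in truth.hgt_events
        ],
        "fused_genomes": sorted(truth.fused_genomes),
    }
    (outdir / "truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    return outdir
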
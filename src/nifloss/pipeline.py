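"""End-to-end orchestration: dataset directory in, scenario report out.

The driver reproduces the full inference chain on a dataset laid out the way
:func:`nifloss.simulate.emit_dataset` writes it (and the way a user would
arrange real exports):

    genomes/<genome>.tsv      ordered gene tables
    proteomes/<genome>.faa    protein sequences keyed by locus_tag
    orthogroups.tsv           orthogroup table
    markers/<marker>.afa      aligned marker FASTAs (species phylogeny)

Steps: species tree from concatenated markers (NJ, outgroup-rooted);
orthogroup-based nif tagging; operon detection with dual-set calls; one
representative copy per (genome, operon set, gene) via species-tree
congruence; per-gene trees with branch-length-outlier screening and
vertical / intra- / extra-phylum verdicts; Dollo loss histories per operon
template; a machine-readable scenario report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation_io, operons
from .annotation_io import GenomeAnnotation, NifCatalog
from .hgt_loss import (
    GeneHistoryCall,
    HistoryConfig,
    LossHistory,
    PresenceProfile,
    ScenarioReport,
    classify_gene_history,
    dollo_reconstruct,
    summarize_history,
    write_history_calls,
)
from .operons import Config, OperonCall, call_operons
from .orthogroups import read_orthogroup_table, read_protein_fasta
from .paralog_selection import CopyCandidate, select_copy, tip_label
from .phylo import (
    Alignment,
    PhyloError,
    PhyloTree,
    branch_length_outliers,
    concatenate,
    first_diverging_clade,
    neighbor_joining,
    protein_distance,
    root_at_outgroup,
)
from .simulate import OUTGROUP_LABEL

__all__ = ["PipelineResult", "run_pipeline", "build_species_tree", "build_gene_tree"]

NIF_GENES = tuple(sorted(annotation_io.NIF_GENE_NAMES))


@dataclass
class PipelineResult:
    species_tree: PhyloTree  # rooted, ingroup only
    full_species_tree: PhyloTree  # rooted, incl. outgroup when present
    annotations: dict[str, GenomeAnnotation]
    operon_calls: dict[str, list[OperonCall]]
    diazotroph: dict[str, bool]
    gene_trees: dict[str, PhyloTree]
    outlier_reports: dict[str, object]
    history_calls: list[GeneHistoryCall]
    loss_histories: dict[str, LossHistory]
    report: ScenarioReport
    copy_sequences: dict[str, dict[str, str]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_calls = [c for calls in self.operon_calls.values() for c in calls]
        operons.write_operon_calls(
            sorted(all_calls, key=lambda c: (c.genome_id, c.contig_id, c.span)),
            outdir / "operon_calls.tsv",
        )
        self.species_tree.write_newick(outdir / "species_tree.nwk")
        for gene, tree in sorted(self.gene_trees.items()):
            (outdir / "gene_trees").mkdir(exist_ok=True)
            tree.write_newick(outdir / "gene_trees" / f"{gene}.nwk")
        write_history_calls(self.history_calls, outdir / "history_calls.tsv")
        (outdir / "scenario_report.json").write_text(self.report.to_json() + "\n")
        (outdir / "scenario_report.txt").write_text(self.report.to_text())
        maps = []
        for genome in sorted(self.annotations):
            maps.append(
                operons.render_operon_map(
                    self.annotations[genome], self.operon_calls[genome]
                )
            )
        (outdir / "operon_maps.txt").write_text("".join(maps))
        return outdir


def build_species_tree(
    markers: dict[str, Alignment], outgroup: str | None = OUTGROUP_LABEL
) -> tuple[PhyloTree, PhyloTree]:
    """(rooted ingroup tree, rooted full tree) from marker alignments."""
    concat = concatenate(markers)
    nj = neighbor_joining(protein_distance(concat, model="jc20"))
    if outgroup is not None and outgroup in nj.leaf_labels:
        full = root_at_outgroup(nj, {outgroup})
        ingroup = full.prune_to(full.leaf_labels - {outgroup})
        ingroup.rooted = True
        return ingroup, full
    # no outgroup available: root at the lexicographically first taxon
    anchor = min(nj.leaf_labels)
    full = root_at_outgroup(nj, {anchor})
    return full, full


def _family_length(seqs: dict[str, tuple[str, bool]]) -> int:
    plain = [len(s) for s, fused in seqs.values() if not fused]
    if plain:
        return Counter(plain).most_common(1)[0][0]
    return min(len(s) for s, _ in seqs.values())


def build_gene_tree(
    gene: str,
    tip_seqs: dict[str, tuple[str, bool]],
    species_tree_rooted: PhyloTree,
) -> tuple[PhyloTree, frozenset[str]] | None:
    """NJ gene tree from per-tip (sequence, is_fused) pairs, outgroup-rooted.

    Fused nifEN proteins contribute their nifE prefix / nifN suffix at the
    family's modal length.  The gene-tree outgroup is the earliest-diverging
    clade of the species tree among the (plain) tips present; if that clade
    is not recoverable in the gene tree its first member alone is used.
    Returns None when fewer than 4 tips exist.
    """
    if len(tip_seqs) < 4:
        return None
    L = _family_length(tip_seqs)
    rows = {}
    for tip, (seq, fused) in tip_seqs.items():
        if fused and len(seq) > L:
            rows[tip] = seq[:L] if gene == "nifE" else seq[-L:]
        else:
            rows[tip] = seq[:L]
    taxa = sorted(rows)
    aln = Alignment(taxa, [rows[t] for t in taxa])
    nj = neighbor_joining(protein_distance(aln, model="jc20"))

    plain = {t for t in taxa if "@" not in t} & species_tree_rooted.leaf_labels
    og = first_diverging_clade(species_tree_rooted, plain) if len(plain) >= 2 else None
    rooted = None
    if og:
        try:
            rooted = root_at_outgroup(nj, frozenset(og) & nj.leaf_labels)
        except PhyloError:
            rooted = None
        if rooted is None:
            try:
                rooted = root_at_outgroup(nj, {min(og)})
            except PhyloError:
                rooted = None
    if rooted is None:
        rooted = root_at_outgroup(nj, {min(nj.leaf_labels)})
        og = frozenset({min(nj.leaf_labels)})
    return rooted, frozenset(og)


def run_pipeline(
    dataset_dir: str | Path,
    config: Config | None = None,
    history_config: HistoryConfig | None = None,
    catalog: NifCatalog | None = None,
) -> PipelineResult:
    """Run the full inference chain on a dataset directory."""
    dataset_dir = Path(dataset_dir)
    config = config or Config()
    history_config = history_config or HistoryConfig()

    # --- inputs -------------------------------------------------------------
    markers = {
        p.stem: Alignment.read_fasta(p)
        for p in sorted((dataset_dir / "markers").glob("*.afa"))
    }
    orthogroups = read_orthogroup_table(dataset_dir / "orthogroups.tsv")
    annotations: dict[str, GenomeAnnotation] = {}
    for p in sorted((dataset_dir / "genomes").glob("*.tsv")):
        ann = annotation_io.parse_gene_table(p)
        annotations[ann.genome_id] = ann
    proteomes = {
        p.stem: read_protein_fasta(p)
        for p in sorted((dataset_dir / "proteomes").glob("*.faa"))
    }

    # --- species tree -------------------------------------------------------
    species_tree, full_tree = build_species_tree(markers)

    # --- tagging + operon calls --------------------------------------------
    if catalog is None:
        base = NifCatalog()
        mapping = annotation_io.infer_orthogroup_map(
            annotations.values(), orthogroups, base
        )
        catalog = base.with_orthogroup_map(mapping)
    operon_calls: dict[str, list[OperonCall]] = {}
    tagged: dict[str, GenomeAnnotation] = {}
    for genome, ann in annotations.items():
        t = annotation_io.tag_nif_candidates(ann, orthogroups, catalog)
        tagged[genome] = t
        operon_calls[genome] = call_operons(t, config)
    diazotroph = {
        genome: operons.is_diazotroph(calls)
        for genome, calls in operon_calls.items()
    }

    # --- copy selection per (genome, set, gene) -----------------------------
    # candidates[gene][tip_label] -> list of CopyCandidate (with fused flag)
    candidates: dict[str, dict[str, list[tuple[CopyCandidate, bool]]]] = {
        g: {} for g in NIF_GENES
    }
    for genome, calls in operon_calls.items():
        prot = proteomes.get(genome, {})
        seen: set[tuple[str, str]] = set()  # (locus_tag, gene) dedupe
        for call in calls:
            for rec in call.member_records:
                for gene in sorted(rec.nif_labels()):
                    if (rec.locus_tag, gene) in seen:
                        continue
                    seen.add((rec.locus_tag, gene))
                    seq = prot.get(rec.locus_tag)
                    if seq is None:
                        continue
                    tip = tip_label(genome, call.set_label)
                    candidates[gene].setdefault(tip, []).append(
                        (
                            CopyCandidate(gene, genome, rec.locus_tag, seq, call),
                            bool(rec.fused_components),
                        )
                    )

    copy_sequences: dict[str, dict[str, tuple[str, bool]]] = {}
    for gene in NIF_GENES:
        per_tip = candidates[gene]
        if not per_tip:
            continue
        # cohort of unambiguous single-copy plain genomes, for tie resolution
        cohort = {
            tip: cands[0][0].sequence
            for tip, cands in per_tip.items()
            if len(cands) == 1 and "@" not in tip
        }
        chosen: dict[str, tuple[str, bool]] = {}
        for tip, cands in sorted(per_tip.items()):
            if len(cands) == 1:
                chosen[tip] = (cands[0][0].sequence, cands[0][1])
                continue
            genome = cands[0][0].genome_id
            cohort_minus = {
                g: s for g, s in cohort.items() if g != genome and "@" not in g
            }
            lens = {len(c.sequence) for c, fused in cands if not fused}
            if len(cohort_minus) >= 3 and len(lens) <= 1:
                winner, _ = select_copy(
                    [c for c, _ in cands], cohort_minus, species_tree
                )
            else:  # fall back to the deterministic lexicographic rule
                winner = sorted(cands, key=lambda cf: cf[0].locus_tag)[0][0]
            fused = next(f for c, f in cands if c.locus_tag == winner.locus_tag)
            chosen[tip] = (winner.sequence, fused)
        copy_sequences[gene] = chosen

    # --- gene trees, outliers, history calls --------------------------------
    gene_trees: dict[str, PhyloTree] = {}
    outlier_reports: dict[str, object] = {}
    history_calls: list[GeneHistoryCall] = []
    species_bips = species_tree.bipartitions()
    for gene in NIF_GENES:
        tip_seqs = copy_sequences.get(gene)
        if not tip_seqs:
            continue
        built = build_gene_tree(gene, tip_seqs, species_tree)
        if built is None:
            continue
        gtree, og = built
        gene_trees[gene] = gtree
        try:
            report = branch_length_outliers(
                gtree, k=history_config.outlier_k, scope="both"
            )
        except PhyloError:
            continue
        outlier_reports[gene] = report
        gene_bips = gtree.bipartitions()
        for tip in sorted(gtree.leaf_labels):
            if "@" in tip:
                continue  # set2 copies are adjudicated via set identity
            history_calls.append(
                classify_gene_history(
                    tip, gene, gtree, species_tree, report, history_config,
                    _bipartitions=(gene_bips, species_bips),
                )
            )

    # --- Dollo per template -------------------------------------------------
    loss_histories: dict[str, LossHistory] = {}
    for template in operons.CANONICAL_TEMPLATES:
        present = frozenset(
            genome
            for genome, calls in operon_calls.items()
            if any(c.template == template.name for c in calls)
        ) & species_tree.leaf_labels
        if not present:
            continue
        loss_histories[template.name] = dollo_reconstruct(
            species_tree, PresenceProfile(template.name, present)
        )

    report = summarize_history(
        history_calls, loss_histories, species_tree, diazotroph
    )
    return PipelineResult(
        species_tree=species_tree,
        full_species_tree=full_tree,
        annotations=tagged,
        operon_calls=operon_calls,
        diazotroph=diazotroph,
        gene_trees=gene_trees,
        outlier_reports=outlier_reports,
        history_calls=history_calls,
        loss_histories=loss_histories,
        report=report,
        copy_sequences={
            g: {t: s for t, (s, _) in tips.items()}
            for g, tips in copy_sequences.items()
        },
    )
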
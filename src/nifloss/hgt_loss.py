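"""Vertical-vs-horizontal adjudication and Dollo gene-loss reconstruction.

Two complementary analyses decide why a gene family is distributed the way it
is across the species tree:

* :func:`dollo_reconstruct` assumes a single ancestral gain (Dollo parsimony)
  and finds the minimum set of loss events — one per maximal absent clade
  below the gain node — explaining a presence/absence profile.
* :func:`classify_gene_history` inspects a gene tree for the two signatures
  of horizontal transfer: an anomalously long branch attaching near the root
  (transfer from outside the phylum: the donor is not in the tree, so the
  foreign copy joins basally on a long branch) versus an ordinary-length
  branch placed in the wrong clade (transfer within the phylum).

:func:`summarize_history` rolls the per-family verdicts and loss histories
into a scenario report, including the headline judgement: single ancestral
gain plus independent losses, with or without extra-phylum transfers among
the operon genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .phylo import (
    OutlierReport,
    PhyloError,
    PhyloTree,
    robinson_foulds,
    robinson_foulds_restricted,
)

__all__ = [
    "PresenceProfile",
    "GeneHistoryCall",
    "LossHistory",
    "HistoryConfig",
    "dollo_reconstruct",
    "count_gains_without_losses",
    "classify_gene_history",
    "summarize_history",
    "ScenarioReport",
]


@dataclass
class PresenceProfile:
    name: str  # gene or operon-template name
    present_taxa: frozenset[str]
    source: str = "operon_call"  # or "ortholog_hit"


@dataclass
class GeneHistoryCall:
    taxon: str
    gene_name: str
    verdict: str  # vertical | intra_phylum_hgt | extra_phylum_hgt | unresolved
    long_branch_z: float | None = None
    root_proximal: bool | None = None
    extreme_length: bool | None = None
    rf_improvement: int | None = None

    def __post_init__(self) -> None:
        if self.verdict == "extra_phylum_hgt" and self.long_branch_z is None:
            raise ValueError("extra_phylum_hgt requires the long-branch flag")
        if self.verdict == "intra_phylum_hgt" and self.long_branch_z is not None:
            raise ValueError("intra_phylum_hgt excludes the long-branch flag")


@dataclass
class LossHistory:
    """Single-gain/minimum-loss history of one family on the species tree."""

    name: str
    gain_clade: frozenset[str]  # leaves under the gain node
    loss_clades: list[frozenset[str]]  # leaves under each loss edge

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)


@dataclass
class HistoryConfig:
    outlier_k: float = 3.0
    incongruence_margin: int = 2  # RF improvement on leaf removal
    max_flag_clade: int = 2  # internal flags count for clades this small
    #: a flagged branch at least this multiple of the gene tree's median
    #: root-to-tip depth is "extreme": more change on one edge than a typical
    #: lineage accumulated since the root, implausible for an in-group origin
    extreme_depth_ratio: float = 1.0


# ---------------------------------------------------------------------------
# Dollo reconstruction


def dollo_reconstruct(
    species_tree: PhyloTree,
    profile: PresenceProfile,
    pinned_gain: Iterable[str] | None = None,
) -> LossHistory:
    """Minimum-loss history under a single gain.

    The gain node is the MRCA of the present taxa (or a user-pinned clade,
    e.g. the root when the gain is known to predate the sampled lineages).
    Below it, each maximal clade containing no present leaf receives exactly
    one loss; this is the unique minimal loss set, because splitting a loss
    adds events and raising one above a present leaf contradicts presence.
    """
    if not species_tree.rooted:
        raise PhyloError("Dollo reconstruction requires a rooted species tree")
    present = frozenset(profile.present_taxa)
    if not present:
        raise PhyloError("empty presence profile")
    leaves = species_tree.leaf_labels
    stray = present - leaves
    if stray:
        raise PhyloError(f"present taxa not in tree: {sorted(stray)}")

    leafsets = species_tree.node_leafsets()
    if pinned_gain is not None:
        pinned = frozenset(pinned_gain)
        if not present <= pinned:
            raise PhyloError(
                "profile contradicts pinned gain: present taxa "
                f"{sorted(present - pinned)} outside the pinned clade"
            )
        gain_node = next(
            (n for n, ls in leafsets.items() if ls == pinned), None
        )
        if gain_node is None:
            raise PhyloError("pinned gain clade is not a clade of the tree")
    else:
        gain_node = min(
            (n for n, ls in leafsets.items() if present <= ls),
            key=lambda n: len(leafsets[n]),
        )

    losses: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            ls = leafsets[child]
            if ls & present:
                walk(child)
            else:
                losses.append(ls)  # maximal absent clade: one loss

    walk(gain_node)
    losses.sort(key=lambda ls: (len(ls), sorted(ls)))
    return LossHistory(
        name=profile.name, gain_clade=leafsets[gain_node], loss_clades=losses
    )


def count_gains_without_losses(
    species_tree: PhyloTree, profile: PresenceProfile
) -> int:
    """Gains needed if losses are forbidden: one per maximal present clade.

    Reported alongside the Dollo history as the competing explanation
    (independent acquisitions instead of ancestral gain + losses).
    """
    present = frozenset(profile.present_taxa)
    leafsets = species_tree.node_leafsets()
    gains = 0

    def walk(node: dendropy.Node) -> None:
        nonlocal gains
        ls = leafsets[node]
        if ls <= present:
            gains += 1
            return
        for child in node.child_nodes():
            if leafsets[child] & present:
                walk(child)

    walk(species_tree.tree.seed_node)
    return gains


# ---------------------------------------------------------------------------
# HGT classification


def classify_gene_history(
    taxon: str,
    gene_name: str,
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    outlier_report: OutlierReport,
    config: HistoryConfig | None = None,
    *,
    _bipartitions: tuple[frozenset, frozenset] | None = None,
) -> GeneHistoryCall:
    """Adjudicate one taxon's copy of a gene family.

    * extra_phylum_hgt — the taxon's external branch (or the internal branch
      subtending it and at most one sister) is a flagged length outlier AND
      extreme: at least ``extreme_depth_ratio`` times the gene tree's median
      root-to-tip depth, i.e. more divergence on that one edge than a
      typical in-group lineage accumulated since the root — implausible for
      a within-phylum origin regardless of where the (often unreliable)
      placement of such a saturated sequence lands.  Whether the edge also
      attaches root-proximally is recorded as corroborating evidence.
    * intra_phylum_hgt — no long-branch flag, but removing the taxon improves
      the pruned RF distance to the species tree by at least the configured
      margin: an ordinary branch sitting in the wrong clade.
    * unresolved — a long-branch flag that falls short of the extreme-length
      bar (a conflicting, weaker signal).
    * vertical — neither signal.
    """
    config = config or HistoryConfig()
    if taxon not in gene_tree.leaf_labels:
        raise PhyloError(f"taxon {taxon} absent from gene tree")

    flag = outlier_report.flag_covering(taxon, max_clade=config.max_flag_clade)
    if flag is not None:
        depths = gene_tree.depths()
        tip_depths = [
            depths[lf] for lf in gene_tree.tree.leaf_node_iter()
        ]
        import numpy as np

        extreme = bool(
            flag.length
            >= config.extreme_depth_ratio * float(np.median(tip_depths))
        )
        if extreme:
            return GeneHistoryCall(
                taxon, gene_name, "extra_phylum_hgt",
                long_branch_z=flag.z, root_proximal=flag.root_proximal,
                extreme_length=extreme,
            )
        return GeneHistoryCall(
            taxon, gene_name, "unresolved",
            long_branch_z=flag.z, root_proximal=flag.root_proximal,
            extreme_length=False,
        )

    shared = gene_tree.leaf_labels & species_tree.leaf_labels
    improvement = None
    if taxon in shared and len(shared) >= 5:
        if _bipartitions is None:
            _bipartitions = (gene_tree.bipartitions(), species_tree.bipartitions())
        gb, sb = _bipartitions
        base = robinson_foulds_restricted(gb, sb, shared)
        reduced = robinson_foulds_restricted(gb, sb, shared - {taxon})
        improvement = base - reduced
        if improvement >= config.incongruence_margin:
            return GeneHistoryCall(
                taxon, gene_name, "intra_phylum_hgt", rf_improvement=improvement
            )
    return GeneHistoryCall(taxon, gene_name, "vertical", rf_improvement=improvement)


# ---------------------------------------------------------------------------
# scenario summary


@dataclass
class ScenarioReport:
    per_template: dict[str, dict]
    diazotrophs: dict[str, bool]
    hgt_calls: list[GeneHistoryCall]
    headline: str

    def to_json(self) -> str:
        payload = {
            "per_template": self.per_template,
            "diazotrophs": self.diazotrophs,
            "hgt_calls": [
                {
                    "taxon": c.taxon,
                    "gene": c.gene_name,
                    "verdict": c.verdict,
                    "long_branch_z": c.long_branch_z,
                    "root_proximal": c.root_proximal,
                    "extreme_length": c.extreme_length,
                    "rf_improvement": c.rf_improvement,
                }
                for c in self.hgt_calls
            ],
            "headline": self.headline,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["scenario summary", "================"]
        for name, info in sorted(self.per_template.items()):
            lines.append(
                f"{name}: gain clade of {info['gain_size']} taxa, "
                f"{info['n_losses']} loss event(s), "
                f"{info['n_gains_alternative']} gain(s) if losses forbidden"
            )
        n_dia = sum(self.diazotrophs.values())
        lines.append(f"diazotrophs: {n_dia}/{len(self.diazotrophs)} genomes")
        for c in self.hgt_calls:
            if c.verdict != "vertical":
                lines.append(f"  {c.gene_name}/{c.taxon}: {c.verdict}")
        lines.append(f"verdict: {self.headline}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def summarize_history(
    calls: Sequence[GeneHistoryCall],
    loss_histories: Mapping[str, LossHistory],
    species_tree: PhyloTree,
    diazotrophs: Mapping[str, bool],
) -> ScenarioReport:
    """Roll per-gene verdicts and per-template loss histories into a report.

    The headline states whether the data fit "single ancestral gain + N
    independent losses, zero extra-phylum transfers among operon genes", or
    which alternative was observed.
    """
    per_template: dict[str, dict] = {}
    for name, hist in loss_histories.items():
        profile = PresenceProfile(
            name,
            frozenset(hist.gain_clade)
            - frozenset().union(*hist.loss_clades) if hist.loss_clades
            else frozenset(hist.gain_clade),
        )
        per_template[name] = {
            "gain_clade": sorted(hist.gain_clade),
            "gain_size": len(hist.gain_clade),
            "n_losses": hist.n_losses,
            "loss_clades": [sorted(ls) for ls in hist.loss_clades],
            "n_gains_alternative": count_gains_without_losses(
                species_tree, profile
            ),
        }
    n_extra = sum(1 for c in calls if c.verdict == "extra_phylum_hgt")
    n_intra = sum(1 for c in calls if c.verdict == "intra_phylum_hgt")
    total_losses = sum(h.n_losses for h in loss_histories.values())
    if n_extra == 0:
        headline = (
            f"single ancestral gain + {total_losses} independent losses, "
            f"zero extra-phylum transfers among operon genes"
            + (f" ({n_intra} intra-phylum transfer signals)" if n_intra else "")
        )
    else:
        headline = (
            f"{n_extra} extra-phylum transfer(s) detected alongside "
            f"{total_losses} losses"
        )
    return ScenarioReport(
        per_template=per_template,
        diazotrophs=dict(sorted(diazotrophs.items())),
        hgt_calls=sorted(calls, key=lambda c: (c.gene_name, c.taxon)),
        headline=headline,
    )


def write_history_calls(calls: Iterable[GeneHistoryCall], path: str | Path) -> None:
    rows = [
        {
            "taxon": c.taxon,
            "gene": c.gene_name,
            "verdict": c.verdict,
            "long_branch_z": c.long_branch_z if c.long_branch_z is not None else "",
            "root_proximal": c.root_proximal if c.root_proximal is not None else "",
            "extreme_length": c.extreme_length if c.extreme_length is not None else "",
            "rf_improvement": c.rf_improvement if c.rf_improvement is not None else "",
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
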
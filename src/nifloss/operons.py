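"""Rule-based detection of nif operons from gene order.

The algorithm mirrors how conserved nitrogenase clusters are read off a
bacterial genome annotation:

1. *Gap rule* — two nif genes on the same contig belong to the same cluster
   when strictly fewer than ``max_gap`` (default 4) annotated genes lie
   between them.
2. *Bridging rule* — an isolated nif gene whose nearest nif clusters both
   upstream and downstream are multi-gene clusters is absorbed into them
   (it is assumed to sit inside a disrupted operon); bridged members are
   flagged for review.
3. *Template splitting* — a cluster is matched against the four canonical
   operon templates (nifBSU, nifHDK, nifENXW, nifVZT); a super-operon such as
   nifBSUHDKENXW yields one call per represented template.
4. *Dual sets* — genomes carrying two copies of the same template at distant
   genomic positions (different contigs, or >= ``dual_set_min_separation``
   genes apart) are flagged as carrying two operon sets (set1/set2), the
   pattern shown by heterocystous cyanobacteria with nif1/nif2 complements.

A fused nifEN gene satisfies both the nifE and nifN slots of nifENXW.  A nifK
sitting next to the nifENXW block while nifH/nifD lie elsewhere is reported
with that call (cross-referenced) rather than fabricated into a nifHDK call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import json

import pandas as pd

from .annotation_io import GeneRecord, GenomeAnnotation

__all__ = [
    "OperonTemplate",
    "NifCluster",
    "OperonCall",
    "Config",
    "CANONICAL_TEMPLATES",
    "cluster_nif_loci",
    "bridge_orphans",
    "split_and_match",
    "detect_dual_operon_sets",
    "call_operons",
    "write_operon_calls",
    "render_operon_map",
]


@dataclass(frozen=True)
class OperonTemplate:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"template {self.name}: duplicate members")


CANONICAL_TEMPLATES: tuple[OperonTemplate, ...] = (
    OperonTemplate("nifBSU", ("nifB", "nifS", "nifU")),
    OperonTemplate("nifHDK", ("nifH", "nifD", "nifK")),
    OperonTemplate("nifENXW", ("nifE", "nifN", "nifX", "nifW")),
    OperonTemplate("nifVZT", ("nifV", "nifZ", "nifT")),
)

_MEMBER_TO_TEMPLATE = {
    m: t.name for t in CANONICAL_TEMPLATES for m in t.members
}


@dataclass
class Config:
    """Tunable thresholds of the detector.

    max_gap: merge two neighbouring nif genes when strictly fewer than this
        many annotated genes lie between them (default 4, i.e. "<4 genes").
    bridging_enabled: apply the flanking-operon bridging rule.
    dual_set_min_separation: gene count treated as "distant positions" when
        deciding whether two same-template calls form dual operon sets.
    respect_strand: when on, a strand change also splits clusters (off by
        default: the gap rule counts genes only).
    """

    max_gap: int = 4
    bridging_enabled: bool = True
    dual_set_min_separation: int = 50
    respect_strand: bool = False

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


@dataclass
class NifCluster:
    genome_id: str
    contig_id: str
    member_records: list[GeneRecord]
    bridged_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.member_records = sorted(self.member_records, key=lambda r: r.ordinal)

    @property
    def span(self) -> tuple[int, int]:
        return (self.member_records[0].ordinal, self.member_records[-1].ordinal)

    @property
    def intervening_counts(self) -> list[int]:
        ords = [r.ordinal for r in self.member_records]
        return [b - a - 1 for a, b in zip(ords, ords[1:])]

    def labels(self) -> list[frozenset[str]]:
        return [r.nif_labels() for r in self.member_records]


@dataclass
class OperonCall:
    template: str
    genome_id: str
    contig_id: str
    member_records: list[GeneRecord]
    status: str  # complete | partial | split
    extras: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    insertions: int = 0
    set_label: str | None = None
    supernumerary: bool = False
    cross_ref: list[str] = field(default_factory=list)  # e.g. nifK carried by nifENXW

    @property
    def span(self) -> tuple[int, int]:
        ords = [r.ordinal for r in self.member_records]
        return (min(ords), max(ords))

    @property
    def present(self) -> set[str]:
        out: set[str] = set()
        for rec in self.member_records:
            out |= rec.nif_labels()
        return out


# ---------------------------------------------------------------------------
# clustering


def _nif_records(annotation: GenomeAnnotation, contig_id: str) -> list[GeneRecord]:
    return [r for r in annotation.contigs[contig_id] if r.is_nif]


def cluster_nif_loci(
    annotation: GenomeAnnotation, config: Config | None = None
) -> list[NifCluster]:
    """Gap-rule clustering of nif-tagged genes, per contig.

    Consecutive nif genes are merged whenever the number of non-nif genes
    strictly between them (ordinal difference minus one) is < ``max_gap``.
    Every nif gene lands in exactly one cluster, possibly a singleton;
    clusters never span contigs.
    """
    config = config or Config()
    clusters: list[NifCluster] = []
    for contig_id in annotation.contigs:
        nifs = _nif_records(annotation, contig_id)
        if not nifs:
            continue
        current = [nifs[0]]
        for prev, rec in zip(nifs, nifs[1:]):
            gap = rec.ordinal - prev.ordinal - 1
            same = gap < config.max_gap
            if same and config.respect_strand and rec.strand != prev.strand:
                same = False
            if same:
                current.append(rec)
            else:
                clusters.append(NifCluster(annotation.genome_id, contig_id, current))
                current = [rec]
        clusters.append(NifCluster(annotation.genome_id, contig_id, current))
    return clusters


def bridge_orphans(
    clusters: list[NifCluster],
    annotation: GenomeAnnotation,
    config: Config | None = None,
) -> list[NifCluster]:
    """Absorb isolated nif genes flanked by multi-gene clusters on both sides.

    Applied iteratively until a fixed point; bridged members keep a flag so
    downstream reports can show which memberships rest on the weaker rule.
    """
    config = config or Config()
    if not config.bridging_enabled:
        return clusters

    def one_pass(cls: list[NifCluster]) -> tuple[list[NifCluster], bool]:
        by_contig: dict[str, list[NifCluster]] = {}
        for c in cls:
            by_contig.setdefault(c.contig_id, []).append(c)
        out: list[NifCluster] = []
        changed = False
        for contig_id, group in by_contig.items():
            group.sort(key=lambda c: c.span[0])
            i = 0
            merged: list[NifCluster] = []
            while i < len(group):
                c = group[i]
                is_orphan = len(c.member_records) == 1
                up = merged[-1] if merged else None
                down = group[i + 1] if i + 1 < len(group) else None
                if (
                    is_orphan
                    and up is not None
                    and down is not None
                    and len(up.member_records) > 1
                    and len(down.member_records) > 1
                ):
                    merged[-1] = NifCluster(
                        c.genome_id,
                        contig_id,
                        up.member_records + c.member_records + down.member_records,
                        bridged_tags=up.bridged_tags
                        | down.bridged_tags
                        | c.bridged_tags
                        | {c.member_records[0].locus_tag},
                    )
                    i += 2  # consumed the downstream cluster as well
                    changed = True
                else:
                    merged.append(c)
                    i += 1
            out.extend(merged)
        return out, changed

    changed = True
    while changed:
        clusters, changed = one_pass(clusters)
    return clusters


# ---------------------------------------------------------------------------
# template matching


def split_and_match(
    cluster: NifCluster,
    templates: Sequence[OperonTemplate] = CANONICAL_TEMPLATES,
) -> list[OperonCall]:
    """Assign cluster members to operon templates; split super-operons.

    Members are routed to templates by their nif labels (a fused nifEN record
    satisfies both nifE and nifN).  One call is produced per template with at
    least one member present.  Duplicate copies of a member gene become
    ``extras``.  A nifK travelling with the nifENXW block while nifH and nifD
    are absent from the cluster is attached to the nifENXW call as a
    cross-reference instead of seeding a spurious nifHDK call.
    """
    member_to_template = {m: t.name for t in templates for m in t.members}
    by_template: dict[str, list[GeneRecord]] = {}
    unmatched: list[GeneRecord] = []
    for rec in cluster.member_records:
        routed = {member_to_template[m] for m in rec.nif_labels() if m in member_to_template}
        if not routed:
            unmatched.append(rec)
            continue
        for tname in sorted(routed):
            by_template.setdefault(tname, []).append(rec)

    # nifK-with-nifENXW convention
    cross_refs: dict[str, list[str]] = {}
    hdk = by_template.get("nifHDK", [])
    if (
        "nifENXW" in by_template
        and hdk
        and all(r.nif_labels() == frozenset({"nifK"}) for r in hdk)
    ):
        enxw_ords = [r.ordinal for r in by_template["nifENXW"]]
        if all(
            min(abs(r.ordinal - o) for o in enxw_ords) <= Config().max_gap
            for r in hdk
        ):
            by_template["nifENXW"].extend(hdk)
            cross_refs["nifENXW"] = [r.locus_tag for r in hdk]
            del by_template["nifHDK"]

    if not by_template:
        import warnings

        warnings.warn(
            f"cluster at {cluster.contig_id}:{cluster.span} has no template members"
        )
        return []

    calls: list[OperonCall] = []
    for t in templates:
        recs = by_template.get(t.name)
        if not recs:
            continue
        recs = sorted(set((r.locus_tag, r) for r in recs), key=lambda kv: kv[1].ordinal)
        recs = [r for _, r in recs]
        covered: set[str] = set()
        extras: list[str] = []
        for rec in recs:
            labels = rec.nif_labels() & set(t.members)
            if labels <= covered and labels:
                extras.extend(sorted(labels))
            covered |= labels
        missing = [m for m in t.members if m not in covered]
        ords = [r.ordinal for r in recs]
        insertions = (max(ords) - min(ords) + 1) - len(recs)
        calls.append(
            OperonCall(
                template=t.name,
                genome_id=cluster.genome_id,
                contig_id=cluster.contig_id,
                member_records=recs,
                status="complete" if not missing else "partial",
                extras=extras,
                missing=missing,
                insertions=insertions,
                cross_ref=cross_refs.get(t.name, []),
            )
        )
    # non-template nif labels (none exist among the canonical 13, but custom
    # template sets may leave some out): report as extras of the nearest call
    for rec in unmatched:
        if not calls:
            continue
        nearest = min(
            calls, key=lambda c: min(abs(rec.ordinal - o) for o in (c.span))
        )
        nearest.extras.extend(sorted(rec.nif_labels()))
    return calls


# ---------------------------------------------------------------------------
# dual operon sets


def detect_dual_operon_sets(
    calls: list[OperonCall], config: Config | None = None
) -> list[OperonCall]:
    """Partition one genome's calls into co-located sets; flag dual-set genomes.

    Calls within ``dual_set_min_separation`` genes of each other on the same
    contig share a set.  If any template occurs in two different sets the
    genome carries dual operon sets: the set containing the smallest genomic
    position becomes set1, the other set2.  Three or more copies of one
    template are flagged supernumerary.
    """
    config = config or Config()
    if not calls:
        return calls
    genomes = {c.genome_id for c in calls}
    if len(genomes) != 1:
        raise ValueError(f"calls span several genomes: {sorted(genomes)}")

    # union-find over calls by genomic proximity
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if a.contig_id != b.contig_id:
                continue
            dist = max(a.span[0], b.span[0]) - min(a.span[1], b.span[1])
            if dist < config.dual_set_min_separation:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(i)
    # deterministic ordering: by (contig, min ordinal)
    ordered = sorted(
        groups.values(),
        key=lambda idx: (calls[idx[0]].contig_id, min(calls[i].span[0] for i in idx)),
    )

    # does any template occur in two distinct groups?
    template_groups: dict[str, set[int]] = {}
    for gi, idxs in enumerate(ordered):
        for i in idxs:
            template_groups.setdefault(calls[i].template, set()).add(gi)
    dual = any(len(gs) > 1 for gs in template_groups.values())

    supernumerary = {
        t
        for t in template_groups
        if sum(1 for c in calls if c.template == t) > 2
    }

    for c in calls:
        c.set_label = None
        c.supernumerary = c.template in supernumerary
    if dual:
        # the two largest groups (ties broken by genomic position) get labels
        ranked = sorted(
            range(len(ordered)), key=lambda gi: (-len(ordered[gi]), gi)
        )[:2]
        ranked.sort()  # genomic order: earlier group is set1
        labels = {ranked[0]: "set1"}
        if len(ranked) > 1:
            labels[ranked[1]] = "set2"
        for gi, idxs in enumerate(ordered):
            for i in idxs:
                calls[i].set_label = labels.get(gi)
    else:
        for c in calls:
            c.set_label = "set1"
    return calls


# ---------------------------------------------------------------------------
# genome-level driver and reports


def call_operons(
    annotation: GenomeAnnotation,
    config: Config | None = None,
    templates: Sequence[OperonTemplate] = CANONICAL_TEMPLATES,
) -> list[OperonCall]:
    """Full per-genome detection: gap rule, bridging, splitting, dual sets.

    Same-template partial calls that end up co-located (within the dual-set
    separation) are re-marked ``split``: the template is present but broken
    across nearby clusters, as seen for nifB sitting apart from nifSU.
    """
    config = config or Config()
    clusters = cluster_nif_loci(annotation, config)
    clusters = bridge_orphans(clusters, annotation, config)
    calls: list[OperonCall] = []
    for cluster in clusters:
        calls.extend(split_and_match(cluster, templates))
    calls.sort(key=lambda c: (c.contig_id, c.span[0]))
    calls = detect_dual_operon_sets(calls, config)
    # co-located same-template partials -> status "split"
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            if (
                a.template == b.template
                and a.set_label == b.set_label
                and a.status != "complete"
                and b.status != "complete"
            ):
                a.status = b.status = "split"
    return calls


def is_diazotroph(calls: Iterable[OperonCall]) -> bool:
    """All four canonical templates represented (complete, partial or split)."""
    present = {c.template for c in calls}
    return all(t.name in present for t in CANONICAL_TEMPLATES)


def write_operon_calls(calls: Iterable[OperonCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "template": c.template,
                "status": c.status,
                "set_label": c.set_label or "",
                "members": ";".join(
                    f"{r.locus_tag}@{r.ordinal}" for r in c.member_records
                ),
                "missing": ";".join(c.missing),
                "extras": ";".join(c.extras),
                "insertions": c.insertions,
                "supernumerary": "1" if c.supernumerary else "",
                "cross_ref": ";".join(c.cross_ref),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "genome_id", "contig_id", "template", "status", "set_label",
            "members", "missing", "extras", "insertions", "supernumerary",
            "cross_ref",
        ],
    ).to_csv(path, sep="\t", index=False)


def genome_summary(genome_id: str, calls: list[OperonCall]) -> dict:
    return {
        "genome_id": genome_id,
        "diazotroph": is_diazotroph(calls),
        "dual_set": any(c.set_label == "set2" for c in calls),
        "templates": {
            t.name: [
                {
                    "status": c.status,
                    "set": c.set_label,
                    "contig": c.contig_id,
                    "span": list(c.span),
                    "missing": c.missing,
                }
                for c in calls
                if c.template == t.name
            ]
            for t in CANONICAL_TEMPLATES
        },
    }


def write_genome_summary(genome_id: str, calls: list[OperonCall], path: str | Path) -> None:
    Path(path).write_text(json.dumps(genome_summary(genome_id, calls), indent=2) + "\n")


def render_operon_map(annotation: GenomeAnnotation, calls: list[OperonCall]) -> str:
    """Plain-text map of detected operons in genomic order (one line each)."""
    lines = [f"# {annotation.genome_id}"]
    for c in sorted(calls, key=lambda c: (c.contig_id, c.span[0])):
        arrows = " ".join(
            ("<" if r.strand == "-" else ">") + (r.gene_label or r.locus_tag)
            for r in c.member_records
        )
        tag = f"[{c.template} {c.status}"
        if c.set_label:
            tag += f" {c.set_label}"
        tag += "]"
        lines.append(f"{c.contig_id}:{c.span[0]}-{c.span[1]} {tag} {arrows}")
    return "\n".join(lines) + "\n"
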
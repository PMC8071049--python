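"""Genome annotations as ordered gene tables, and nif-candidate tagging.

Operon detection works on gene *order*, not on nucleotide coordinates, so the
central object here is the :class:`GenomeAnnotation`: per contig, an ordered
list of :class:`GeneRecord` whose ``ordinal`` is the 0-based rank of the gene
along the contig (sorted by start coordinate).  Records are read either from
GenBank flat files or from a plain TSV gene table, and nif candidates are
tagged by orthogroup membership: a gene whose protein belongs to the
orthogroup containing known nifD sequences is a nifD candidate, and so on.

Coordinates follow the GenBank convention (1-based, inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from .orthogroups import OrthogroupTable

__all__ = [
    "GeneRecord",
    "GenomeAnnotation",
    "NifCatalog",
    "AnnotationError",
    "parse_genbank",
    "parse_gene_table",
    "write_gene_table",
    "tag_nif_candidates",
    "write_tagging_report",
    "infer_orthogroup_map",
]

#: canonical Mo-nitrogenase gene complement
NIF_GENE_NAMES = frozenset(
    {
        "nifB", "nifS", "nifU",
        "nifH", "nifD", "nifK",
        "nifE", "nifN", "nifX", "nifW",
        "nifV", "nifZ", "nifT",
    }
)

GENE_TABLE_COLUMNS = [
    "genome_id", "contig_id", "start", "end", "strand",
    "locus_tag", "gene_label", "orthogroup_id",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation inputs."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene/CDS feature in a genome's ordered gene table.

    ``fused_components`` is non-empty for fused genes (a fused nifEN record
    carries ``("nifE", "nifN")`` and satisfies both components in operon
    template matching).  ``unconfirmed`` marks genes annotated with a nif-like
    label but lacking orthogroup support; they are excluded from operon
    detection by default.
    """

    genome_id: str
    contig_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    locus_tag: str
    gene_label: str | None = None
    product: str | None = None
    orthogroup_id: str | None = None
    pseudo: bool = False
    unconfirmed: bool = False
    fused_components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.locus_tag}: bad strand {self.strand!r}")

    def nif_labels(self) -> frozenset[str]:
        """Canonical nif names this (confirmed, non-pseudo) record satisfies."""
        if self.unconfirmed or self.pseudo:
            return frozenset()
        if self.fused_components:
            return frozenset(self.fused_components)
        if self.gene_label in NIF_GENE_NAMES:
            return frozenset({self.gene_label})
        return frozenset()

    @property
    def is_nif(self) -> bool:
        return bool(self.nif_labels())


@dataclass
class GenomeAnnotation:
    """Ordered, stranded gene features of one genome, grouped by contig."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)
    taxon_name: str = ""

    @classmethod
    def from_records(
        cls, genome_id: str, records: Iterable[GeneRecord], taxon_name: str = ""
    ) -> "GenomeAnnotation":
        """Build an annotation, sorting per contig and (re)assigning ordinals."""
        by_contig: dict[str, list[GeneRecord]] = {}
        for rec in records:
            if rec.genome_id != genome_id:
                raise AnnotationError(
                    f"record {rec.locus_tag} belongs to {rec.genome_id}, "
                    f"not {genome_id}"
                )
            by_contig.setdefault(rec.contig_id, []).append(rec)
        contigs: dict[str, list[GeneRecord]] = {}
        seen_tags: set[str] = set()
        for contig_id, recs in by_contig.items():
            recs.sort(key=lambda r: (r.start, r.end, r.locus_tag))
            out = []
            for i, rec in enumerate(recs):
                if rec.locus_tag in seen_tags:
                    raise AnnotationError(f"duplicate locus_tag {rec.locus_tag!r}")
                seen_tags.add(rec.locus_tag)
                out.append(replace(rec, ordinal=i))
            contigs[contig_id] = out
        return cls(genome_id=genome_id, contigs=contigs,
                   taxon_name=taxon_name or genome_id)

    def records(self) -> Iterator[GeneRecord]:
        for recs in self.contigs.values():
            yield from recs

    def __len__(self) -> int:
        return sum(len(v) for v in self.contigs.values())

    def get(self, locus_tag: str) -> GeneRecord:
        for rec in self.records():
            if rec.locus_tag == locus_tag:
                return rec
        raise KeyError(locus_tag)


@dataclass
class NifCatalog:
    """Canonical nif gene names, fusion products, and orthogroup mapping."""

    gene_names: frozenset[str] = NIF_GENE_NAMES
    fused_names: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {"nifEN": ("nifE", "nifN")}
    )
    orthogroup_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fused, parts in self.fused_names.items():
            for p in parts:
                if p not in self.gene_names:
                    raise AnnotationError(f"fused component {p} not a nif gene")
        valid = set(self.gene_names) | set(self.fused_names)
        for og, name in self.orthogroup_map.items():
            if name not in valid:
                raise AnnotationError(f"orthogroup {og} maps to unknown name {name}")

    def with_orthogroup_map(self, mapping: Mapping[str, str]) -> "NifCatalog":
        return NifCatalog(self.gene_names, dict(self.fused_names), dict(mapping))

    def components(self, name: str) -> tuple[str, ...]:
        """Component gene names of ``name`` (itself, unless fused)."""
        if name in self.fused_names:
            return self.fused_names[name]
        return (name,)


# ---------------------------------------------------------------------------
# parsing


def parse_genbank(path: str | Path) -> GenomeAnnotation:
    """Read a GenBank flat file into an ordered gene table.

    One record per CDS/gene feature; when a CDS and a gene feature share a
    locus_tag the CDS wins.  Compound (join) locations are collapsed to their
    minimal start / maximal end.  Features without a locus_tag get a stable
    generated tag ``<contig>_<index>``.
    """
    path = Path(path)
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise AnnotationError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not seqrecords:
        raise AnnotationError(f"{path}: no GenBank records found")

    genome_id = path.stem
    taxon_name = ""
    records: list[GeneRecord] = []
    for seqrec in seqrecords:
        contig_id = seqrec.id or seqrec.name
        taxon_name = taxon_name or seqrec.annotations.get("organism", "")
        per_tag: dict[str, GeneRecord] = {}
        auto_idx = 0
        for feat in seqrec.features:
            if feat.type not in ("CDS", "gene"):
                continue
            start = int(feat.location.start) + 1  # to 1-based inclusive
            end = int(feat.location.end)
            quals = feat.qualifiers
            tag = quals.get("locus_tag", [None])[0]
            if tag is None:
                tag = f"{contig_id}_{auto_idx}"
            auto_idx += 1
            rec = GeneRecord(
                genome_id=genome_id,
                contig_id=contig_id,
                ordinal=-1,
                start=start,
                end=end,
                strand="-" if feat.location.strand == -1 else "+",
                locus_tag=tag,
                gene_label=quals.get("gene", [None])[0],
                product=quals.get("product", [None])[0],
                pseudo="pseudo" in quals or "pseudogene" in quals,
            )
            prev = per_tag.get(tag)
            # CDS preferred over plain gene feature for the same locus_tag
            if prev is None or feat.type == "CDS":
                per_tag[tag] = rec
        records.extend(per_tag.values())
    if not records:
        raise AnnotationError(f"{path}: empty annotation (no gene/CDS features)")
    return GenomeAnnotation.from_records(genome_id, records, taxon_name)


def parse_gene_table(path: str | Path) -> GenomeAnnotation:
    """Read the plain TSV gene-table format.

    Required columns: genome_id, contig_id, start, end, strand, locus_tag;
    optional: gene_label, orthogroup_id, product.  Ordinals are always
    recomputed from coordinates, never trusted from the file.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["genome_id", "contig_id", "start", "end", "strand", "locus_tag"]
    for col in required:
        if col not in df.columns:
            raise AnnotationError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise AnnotationError(f"{path}: empty annotation")
    dup = df["locus_tag"][df["locus_tag"].duplicated()]
    if not dup.empty:
        raise AnnotationError(f"{path}: duplicate locus_tag {dup.iloc[0]!r}")
    genome_ids = df["genome_id"].unique()
    if len(genome_ids) != 1:
        raise AnnotationError(f"{path}: expected one genome_id, got {list(genome_ids)}")

    def opt(row: pd.Series, col: str) -> str | None:
        val = row.get(col, "")
        return val if val else None

    records = []
    for _, row in df.iterrows():
        fused = opt(row, "fused_components")
        records.append(
            GeneRecord(
                genome_id=row["genome_id"],
                contig_id=row["contig_id"],
                ordinal=-1,
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                locus_tag=row["locus_tag"],
                gene_label=opt(row, "gene_label"),
                product=opt(row, "product"),
                orthogroup_id=opt(row, "orthogroup_id"),
                pseudo=row.get("pseudo", "") in ("1", "True", "true"),
                fused_components=tuple(fused.split(",")) if fused else (),
            )
        )
    return GenomeAnnotation.from_records(str(genome_ids[0]), records)


def write_gene_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the normalized TSV gene table (inverse of :func:`parse_gene_table`)."""
    rows = []
    for rec in annotation.records():
        rows.append(
            {
                "genome_id": rec.genome_id,
                "contig_id": rec.contig_id,
                "start": rec.start,
                "end": rec.end,
                "strand": rec.strand,
                "locus_tag": rec.locus_tag,
                "gene_label": rec.gene_label or "",
                "orthogroup_id": rec.orthogroup_id or "",
                "product": rec.product or "",
                "pseudo": "1" if rec.pseudo else "",
                "fused_components": ",".join(rec.fused_components),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# nif tagging


def tag_nif_candidates(
    annotation: GenomeAnnotation,
    orthogroups: OrthogroupTable,
    catalog: NifCatalog,
    *,
    include_unconfirmed: bool = False,
    manual_additions: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Tag nif candidate genes by orthogroup membership.

    A record whose protein (keyed by locus_tag) belongs to an orthogroup that
    the catalog maps to a canonical nif name gets that name as its
    ``gene_label``; a record mapping to a fused name (nifEN) carries both
    component labels.  Records already labelled ``nif*`` but without
    orthogroup support are flagged ``unconfirmed`` and excluded from operon
    detection unless ``include_unconfirmed``.  ``manual_additions`` maps
    locus_tag -> nif name for genes the orthogroup pipeline missed (the
    field's equivalent of manually rescuing an unannotated coding sequence).

    Never changes coordinates, ordinals or record count.
    """
    manual_additions = dict(manual_additions or {})
    known_ogs = {og for og in catalog.orthogroup_map}
    seen_ogs: set[str] = set()
    new_contigs: dict[str, list[GeneRecord]] = {}
    for contig_id, recs in annotation.contigs.items():
        out = []
        for rec in recs:
            og = orthogroups.protein_index.get(
                (annotation.genome_id, rec.locus_tag), rec.orthogroup_id
            )
            nif_name = catalog.orthogroup_map.get(og) if og else None
            if og:
                seen_ogs.add(og)
            if rec.locus_tag in manual_additions:
                nif_name = manual_additions[rec.locus_tag]
            if nif_name is not None and not rec.pseudo:
                fused = catalog.fused_names.get(nif_name, ())
                rec = replace(
                    rec,
                    gene_label=nif_name,
                    orthogroup_id=og,
                    fused_components=tuple(fused),
                    unconfirmed=False,
                )
            elif (
                rec.gene_label
                and rec.gene_label.startswith("nif")
                and not include_unconfirmed
            ):
                rec = replace(rec, unconfirmed=True, orthogroup_id=og)
            elif og:
                rec = replace(rec, orthogroup_id=og)
            out.append(rec)
        new_contigs[contig_id] = out
    missing = known_ogs - seen_ogs - set()
    absent = {og for og in missing if og not in orthogroups.groups}
    if absent:
        warnings.warn(
            f"{annotation.genome_id}: catalog orthogroups absent from table: "
            f"{sorted(absent)}"
        )
    return GenomeAnnotation(
        genome_id=annotation.genome_id,
        contigs=new_contigs,
        taxon_name=annotation.taxon_name,
    )


def write_tagging_report(
    annotations: Iterable[GenomeAnnotation], path: str | Path
) -> None:
    """TSV report of tagged nif candidates (one row per candidate gene)."""
    rows = []
    for ann in annotations:
        for rec in ann.records():
            labels = rec.nif_labels()
            if not labels and not rec.unconfirmed:
                continue
            rows.append(
                {
                    "genome_id": ann.genome_id,
                    "locus_tag": rec.locus_tag,
                    "nif_name": rec.gene_label or "",
                    "evidence": (
                        "unconfirmed_label"
                        if rec.unconfirmed
                        else f"orthogroup:{rec.orthogroup_id or 'manual'}"
                    ),
                }
            )
    pd.DataFrame(rows, columns=["genome_id", "locus_tag", "nif_name", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def infer_orthogroup_map(
    annotations: Iterable[GenomeAnnotation],
    orthogroups: OrthogroupTable,
    catalog: NifCatalog | None = None,
) -> dict[str, str]:
    """Infer orthogroup -> nif name from existing gene labels by majority vote.

    Mirrors the discovery step of a real analysis: orthogroups containing
    proteins annotated with a canonical nif name inherit that name (ties and
    conflicts are dropped with a warning).
    """
    catalog = catalog or NifCatalog()
    valid = set(catalog.gene_names) | set(catalog.fused_names)
    votes: dict[str, dict[str, int]] = {}
    for ann in annotations:
        for rec in ann.records():
            if rec.gene_label not in valid:
                continue
            og = orthogroups.protein_index.get((ann.genome_id, rec.locus_tag))
            if og is None:
                continue
            votes.setdefault(og, {}).setdefault(rec.gene_label, 0)
            votes[og][rec.gene_label] += 1
    mapping: dict[str, str] = {}
    for og, counts in votes.items():
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(best) > 1 and best[0][1] == best[1][1]:
            warnings.warn(f"orthogroup {og}: ambiguous nif identity {counts}")
            continue
        mapping[og] = best[0][0]
    return mapping
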
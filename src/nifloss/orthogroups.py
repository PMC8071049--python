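"""Orthogroup tables: reading the standard TSV dialect, or building a
lightweight reciprocal-best-hit stand-in from protein sequences.

The fidelity path is :func:`read_orthogroup_table`, which consumes the tab
separated Orthogroups table dialect (first column an orthogroup id, one column
per genome, comma-separated protein ids per cell).  For self-contained runs a
deliberately simple clusterer is provided: cosine similarity of amino-acid
k-mer count profiles, reciprocal best hits between genomes, single-linkage
connected components.  It is not a substitute for a real orthology pipeline
on diverged proteomes, but it resolves well-separated families cleanly.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import math

import networkx as nx
import pandas as pd

__all__ = [
    "OrthogroupTable",
    "OrthogroupError",
    "read_orthogroup_table",
    "write_orthogroup_table",
    "kmer_profile_similarity",
    "build_orthogroups_rbh",
    "read_protein_fasta",
]

Protein = tuple[str, str]  # (genome_id, protein_id)


class OrthogroupError(ValueError):
    pass


@dataclass
class OrthogroupTable:
    """A partition of proteins into orthogroups.

    ``protein_index`` is the reverse mapping; building it enforces that no
    protein belongs to two groups.
    """

    groups: dict[str, set[Protein]]
    protein_index: dict[Protein, str] = field(init=False)

    def __post_init__(self) -> None:
        self.protein_index = {}
        for og_id, members in self.groups.items():
            if not members:
                raise OrthogroupError(f"orthogroup {og_id} is empty")
            for prot in members:
                if prot in self.protein_index:
                    raise OrthogroupError(
                        f"protein {prot[1]} ({prot[0]}) in two orthogroups: "
                        f"{self.protein_index[prot]} and {og_id}"
                    )
                self.protein_index[prot] = og_id

    def genomes(self) -> list[str]:
        return sorted({g for members in self.groups.values() for g, _ in members})


def read_orthogroup_table(path: str | Path) -> OrthogroupTable:
    """Read the tab-separated orthogroups dialect.

    Header: ``Orthogroup<TAB>genomeA<TAB>genomeB...``; cells hold
    comma-separated protein ids, empty cells mean no members in that genome.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise OrthogroupError(f"{path}: need an id column plus genome columns")
    genome_cols = list(df.columns[1:])
    groups: dict[str, set[Protein]] = {}
    for _, row in df.iterrows():
        og_id = row.iloc[0]
        members: set[Protein] = set()
        for genome in genome_cols:
            cell = row[genome].strip()
            if not cell:
                continue
            for pid in cell.split(","):
                pid = pid.strip()
                if pid:
                    members.add((genome, pid))
        if members:
            groups[og_id] = members
    return OrthogroupTable(groups)


def write_orthogroup_table(table: OrthogroupTable, path: str | Path) -> None:
    genomes = table.genomes()
    rows = []
    for og_id in sorted(table.groups):
        row = {"Orthogroup": og_id}
        for genome in genomes:
            pids = sorted(p for g, p in table.groups[og_id] if g == genome)
            row[genome] = ", ".join(pids)
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *genomes]).to_csv(
        path, sep="\t", index=False
    )


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA -> {id: sequence} (order-stable, ids must be unique)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise OrthogroupError(f"{path}: duplicate protein id {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


# ---------------------------------------------------------------------------
# k-mer RBH clustering


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_profile_similarity(a: str, b: str, k: int = 4) -> float:
    """Cosine similarity of amino-acid k-mer count vectors, in [0, 1].

    Symmetric; 1.0 for identical sequences; 0.0 for disjoint k-mer sets.
    Sequences shorter than k have no profile and score 0 (with a warning).
    """
    if k < 1:
        raise OrthogroupError(f"k must be >= 1, got {k}")
    if len(a) < k or len(b) < k:
        warnings.warn(f"sequence shorter than k={k}; similarity set to 0")
        return 0.0
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    if ca == cb:
        return 1.0
    dot = sum(ca[m] * cb[m] for m in ca.keys() & cb.keys())
    if dot == 0:
        return 0.0
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return min(1.0, dot / (na * nb))  # guard rounding above exact 1.0


def build_orthogroups_rbh(
    proteomes: Mapping[str, Mapping[str, str]],
    k: int = 4,
    min_sim: float = 0.5,
) -> OrthogroupTable:
    """Cluster proteins into orthogroups by reciprocal best hits.

    For every ordered genome pair, each protein's best hit (cosine k-mer
    similarity, ties broken by lexicographic protein id) above ``min_sim`` is
    found; reciprocal best-hit pairs become edges and connected components
    become orthogroups.  Singletons are excluded.  Group ids are assigned
    deterministically (by size, then smallest member).
    """
    genomes = sorted(proteomes)
    if len(genomes) < 2:
        raise OrthogroupError("need at least 2 genomes")
    for g in genomes:
        if not proteomes[g]:
            raise OrthogroupError(f"empty proteome for genome {g!r}")

    profiles: dict[Protein, Counter] = {}
    for g in genomes:
        for pid, seq in proteomes[g].items():
            profiles[(g, pid)] = _kmer_counts(seq, k) if len(seq) >= k else Counter()
    norms = {p: math.sqrt(sum(v * v for v in c.values())) for p, c in profiles.items()}

    def sim(p: Protein, q: Protein) -> float:
        ca, cb = profiles[p], profiles[q]
        if not ca or not cb:
            return 0.0
        dot = sum(ca[m] * cb[m] for m in ca.keys() & cb.keys())
        return dot / (norms[p] * norms[q]) if dot else 0.0

    def best_hit(p: Protein, target: str) -> Protein | None:
        best: tuple[float, str] | None = None
        for pid in proteomes[target]:
            s = sim(p, (target, pid))
            if s < min_sim:
                continue
            # higher similarity wins; ties by lexicographic protein id
            if best is None or s > best[0] or (s == best[0] and pid < best[1]):
                best = (s, pid)
        return (target, best[1]) if best else None

    graph = nx.Graph()
    graph.add_nodes_from(profiles)
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            for pid in proteomes[ga]:
                p = (ga, pid)
                q = best_hit(p, gb)
                if q is not None and best_hit(q, ga) == p:
                    graph.add_edge(p, q)

    components = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    components.sort(key=lambda c: (-len(c), c[0]))
    width = max(7, len(str(len(components))))
    groups = {f"OG{str(i).zfill(width)}": set(c) for i, c in enumerate(components)}
    return OrthogroupTable(groups)
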
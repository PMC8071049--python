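"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written from first principles (exhaustive
pairwise merging, nested-tuple tree structures with distances tracked during
construction, exact-cover enumeration) so that they share no code path with
the package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nifloss.annotation_io import GeneRecord, GenomeAnnotation, NIF_GENE_NAMES

NIF_NAMES = sorted(NIF_GENE_NAMES)


# ---------------------------------------------------------------------------
# random gene tables


def random_gene_table(
    rng: np.random.Generator, genome_id: str = "G", max_genes: int = 30
) -> GenomeAnnotation:
    """Random annotation: <= max_genes genes on 1-2 contigs, ~1/3 nif."""
    n = int(rng.integers(2, max_genes + 1))
    n_contigs = int(rng.integers(1, 3))
    records = []
    for i in range(n):
        contig = f"c{int(rng.integers(n_contigs)) + 1}"
        label = None
        if rng.random() < 0.35:
            label = NIF_NAMES[int(rng.integers(len(NIF_NAMES)))]
        start = 1 + i * 100
        records.append(
            GeneRecord(
                genome_id=genome_id,
                contig_id=contig,
                ordinal=-1,
                start=start,
                end=start + 90,
                strand="+" if rng.random() < 0.5 else "-",
                locus_tag=f"{genome_id}_{i:03d}",
                gene_label=label,
                orthogroup_id=f"OG_{label}" if label else None,
            )
        )
    return GenomeAnnotation.from_records(genome_id, records)


# ---------------------------------------------------------------------------
# brute-force operon clustering oracle


def oracle_clusters(annotation: GenomeAnnotation, max_gap: int = 4,
                    bridging: bool = True) -> list[tuple[str, ...]]:
    """Exhaustive pairwise merging + iterated bridging, as locus-tag tuples."""
    out: list[tuple[str, ...]] = []
    for contig_id, recs in annotation.contigs.items():
        nifs = [r for r in recs if r.is_nif]
        if not nifs:
            continue
        # union-find over all pairs of nif genes that are nif-order neighbors
        parent = list(range(len(nifs)))

        def find(i: int) -> int:
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(nifs)), 2):
            between_nif = any(
                nifs[i].ordinal < nifs[k].ordinal < nifs[j].ordinal
                for k in range(len(nifs))
            )
            if between_nif:
                continue
            gap = nifs[j].ordinal - nifs[i].ordinal - 1
            if gap < max_gap:
                parent[find(i)] = find(j)

        def groups() -> list[list[int]]:
            acc: dict[int, list[int]] = {}
            for i in range(len(nifs)):
                acc.setdefault(find(i), []).append(i)
            return sorted(acc.values(), key=lambda g: nifs[g[0]].ordinal)

        # iterated bridging: singleton flanked by multi-gene clusters
        changed = bridging
        while changed:
            changed = False
            gs = groups()
            for gi in range(1, len(gs) - 1):
                if (
                    len(gs[gi]) == 1
                    and len(gs[gi - 1]) > 1
                    and len(gs[gi + 1]) > 1
                ):
                    parent[find(gs[gi][0])] = find(gs[gi - 1][0])
                    parent[find(gs[gi + 1][0])] = find(gs[gi - 1][0])
                    changed = True
                    break
        for g in groups():
            out.append(tuple(nifs[i].locus_tag for i in sorted(g, key=lambda i: nifs[i].ordinal)))
    return sorted(out)


# ---------------------------------------------------------------------------
# random trees as nested tuples (independent of the package tree type)


def random_topology(rng: np.random.Generator, labels: list[str]):
    """Random rooted binary topology by sequential random joins."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def random_tree_with_distances(
    rng: np.random.Generator, n_leaves: int, min_len: float = 0.1,
    max_len: float = 1.0,
):
    """(newick, exact leaf-to-leaf distances) with lengths drawn at build time.

    Distances are accumulated during construction (leaf depth bookkeeping at
    each join), giving an additive matrix independent of any tree code.
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    struct = random_topology(rng, labels)
    dist: dict[tuple[str, str], float] = {}

    def build(node) -> tuple[str, dict[str, float]]:
        if isinstance(node, str):
            return node, {node: 0.0}
        (sa, da), (sb, db) = build(node[0]), build(node[1])
        la = float(rng.uniform(min_len, max_len))
        lb = float(rng.uniform(min_len, max_len))
        for x in da:
            da[x] += la
        for y in db:
            db[y] += lb
        for x, dx in da.items():
            for y, dy in db.items():
                dist[tuple(sorted((x, y)))] = dx + dy
        return f"({sa}:{la:.6f},{sb}:{lb:.6f})", {**da, **db}

    newick, _ = build(struct)
    return newick + ";", labels, dist


def clades_of(struct) -> list[frozenset[str]]:
    """All clade leafsets of a nested-tuple rooted topology."""
    out: list[frozenset[str]] = []

    def walk(node) -> frozenset[str]:
        if isinstance(node, str):
            ls = frozenset({node})
        else:
            ls = walk(node[0]) | walk(node[1])
        out.append(ls)
        return ls

    walk(struct)
    return out


def struct_to_newick(struct, with_lengths: bool = False,
                     rng: np.random.Generator | None = None) -> str:
    def fmt(node) -> str:
        if isinstance(node, str):
            s = node
        else:
            s = f"({fmt(node[0])},{fmt(node[1])})"
        if with_lengths:
            s += f":{float(rng.uniform(0.1, 1.0)):.4f}"
        return s

    return fmt(struct) + ";"


def bipartitions_of(struct, leaves: frozenset[str]) -> frozenset[frozenset[str]]:
    """Non-trivial unrooted bipartitions of a nested-tuple topology,
    normalized to the side without the smallest leaf."""
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for clade in clades_of(struct):
        side = leaves - clade if ref in clade else clade
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Dollo brute force


def oracle_min_losses(
    clades: list[frozenset[str]], gain: frozenset[str], present: frozenset[str]
) -> int:
    """Exact-cover enumeration: the minimum number of loss clades (chosen
    among clades strictly below the gain clade that contain no present leaf)
    that exactly cover the absent leaves."""
    absent = gain - present
    if not absent:
        return 0
    candidates = [
        c for c in clades if c < gain and not (c & present)
    ]
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            total = frozenset().union(*combo)
            if total == absent and sum(len(c) for c in combo) == len(absent):
                return size
    raise AssertionError("no loss-edge cover found")


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
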
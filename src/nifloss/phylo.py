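"""Distance-based phylogenetics: alignments, NJ trees, bootstrap, rooting,
topology comparison, monophyly and branch-length outlier diagnostics.

Trees are stored as a thin wrapper (:class:`PhyloTree`) around a
:class:`dendropy.Tree`, which provides Newick I/O and traversal; the
operations layered on top are the ones the operon/loss analysis needs:

* neighbor joining on protein distance matrices (p or Poisson-corrected),
  exact on additive distances, with deterministic tie-breaking;
* nonparametric bootstrap (column resampling) for edge support;
* outgroup rooting;
* Robinson–Foulds distance on normalized non-trivial bipartition sets;
* monophyly tests against named taxon groups;
* robust (median/MAD) branch-length outlier detection with a
  root-proximal-attachment annotation, the operational reading of
  "long branches diverging from near the root" as horizontal-transfer
  evidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "ConcatenatedAlignment",
    "DistanceMatrix",
    "PhyloTree",
    "MonophylyResult",
    "FlaggedEdge",
    "OutlierReport",
    "PhyloError",
    "concatenate",
    "deconcatenate",
    "protein_distance",
    "neighbor_joining",
    "bootstrap_support",
    "root_at_outgroup",
    "robinson_foulds",
    "is_monophyletic",
    "branch_length_outliers",
    "first_diverging_clade",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = ord("-")


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """A protein multiple alignment: equal-length rows over AA + '-'."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise PhyloError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise PhyloError("duplicate taxon ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.rows), self.length)

    @classmethod
    def from_array(cls, taxa: Sequence[str], arr: np.ndarray) -> "Alignment":
        return cls(list(taxa), [bytes(row).decode("ascii") for row in arr])

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        return Alignment(list(taxa), [self.rows[index[t]] for t in taxa])

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq))
        if not taxa:
            raise PhyloError(f"{path}: empty FASTA")
        return cls(taxa, rows)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")


@dataclass
class ConcatenatedAlignment(Alignment):
    """Alignment plus 1-based, inclusive per-marker column partitions."""

    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        pos = 1
        for name, start, end in self.partitions:
            if start != pos or end < start:
                raise PhyloError(f"partitions do not tile columns at {name}")
            pos = end + 1
        if self.partitions and pos != self.length + 1:
            raise PhyloError("partitions do not cover the alignment")


def concatenate(
    alignments: Mapping[str, Alignment],
    taxa: Sequence[str] | None = None,
    *,
    fill_missing: bool = False,
) -> ConcatenatedAlignment:
    """Concatenate per-marker alignments into one partitioned alignment.

    By default every marker must cover every taxon (complete marker sets);
    with ``fill_missing`` a taxon absent from a marker is padded with gaps.
    """
    if len(set(alignments)) != len(alignments):
        raise PhyloError("duplicate marker names")
    names = list(alignments)
    if taxa is None:
        taxa = list(alignments[names[0]].taxa)
    parts: list[tuple[str, int, int]] = []
    rows = {t: [] for t in taxa}
    pos = 1
    for name in names:
        aln = alignments[name]
        index = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            if t in index:
                rows[t].append(index[t])
            elif fill_missing:
                rows[t].append("-" * aln.length)
            else:
                raise PhyloError(f"taxon {t} missing from marker {name}")
        parts.append((name, pos, pos + aln.length - 1))
        pos += aln.length
    return ConcatenatedAlignment(
        list(taxa), ["".join(rows[t]) for t in taxa], partitions=parts
    )


def deconcatenate(concat: ConcatenatedAlignment) -> dict[str, Alignment]:
    """Inverse of :func:`concatenate` (exact round-trip)."""
    return {
        name: Alignment(
            list(concat.taxa), [r[start - 1 : end] for r in concat.rows]
        )
        for name, start, end in concat.partitions
    }


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise PhyloError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise PhyloError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise PhyloError("distance matrix diagonal not zero")
        if np.any(self.values < 0):
            raise PhyloError("negative distances")

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t"
        )


def protein_distance(
    alignment: Alignment,
    model: str = "p",
    saturation_ceiling: float = 10.0,
) -> DistanceMatrix:
    """Pairwise protein distances, ignoring gapped columns.

    For each pair, columns where either row carries a gap are excluded and
    ``p`` is mismatches / compared columns.  Models: ``p`` (raw proportion),
    ``poisson`` (-ln(1 - p)), and ``jc20``, the 20-state Jukes-Cantor-type
    correction -(19/20) ln(1 - (20/19) p), which is additive in expectation
    under a uniform-replacement substitution process and is the model used
    for tree building throughout the pipeline.  Saturated pairs (corrected
    distance undefined) are set to ``saturation_ceiling`` and flagged.
    """
    if model not in ("p", "poisson", "jc20"):
        raise PhyloError(f"unknown model {model!r}")
    if len(alignment.taxa) < 2:
        raise PhyloError("need >= 2 taxa")
    arr = alignment.to_array()
    n = arr.shape[0]
    gap = arr == GAP
    D = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise PhyloError(
                    f"no comparable columns for pair "
                    f"({alignment.taxa[i]}, {alignment.taxa[j]})"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / m
            if model == "p":
                d = p
            elif model == "poisson":
                if p >= 1.0:
                    d = saturation_ceiling
                    saturated.add((alignment.taxa[i], alignment.taxa[j]))
                else:
                    d = -np.log(1.0 - p)
            else:  # jc20
                if p >= 19.0 / 20.0:
                    d = saturation_ceiling
                    saturated.add((alignment.taxa[i], alignment.taxa[j]))
                else:
                    d = -(19.0 / 20.0) * np.log(1.0 - (20.0 / 19.0) * p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(alignment.taxa), D, saturated)


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloTree:
    """A tree with branch lengths; thin wrapper over a dendropy Tree.

    An unrooted tree is stored rooted at an arbitrary (usually trifurcating)
    node with ``rooted=False``.
    """

    tree: dendropy.Tree
    rooted: bool = False

    # -- construction / IO ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        if rooted is None:
            rooted = newick.lstrip().startswith("[&R]") or (
                len(tree.seed_node.child_nodes()) == 2
            )
        tree.is_rooted = rooted
        return cls(tree, rooted)

    @classmethod
    def read_newick(cls, path: str | Path, rooted: bool | None = None) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text(), rooted=rooted)

    def to_newick(self, *, support_as_labels: bool = True) -> str:
        s = self.tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        ).strip()
        return s

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def clone(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1), self.rooted)

    # -- basic queries -------------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def node_leafsets(self) -> dict[dendropy.Node, frozenset[str]]:
        """Leaf labels subtended by each node (postorder accumulation)."""
        out: dict[dendropy.Node, frozenset[str]] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                out[node] = frozenset({node.taxon.label})
            else:
                acc: set[str] = set()
                for ch in node.child_nodes():
                    acc |= out[ch]
                out[node] = frozenset(acc)
        return out

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions of the unrooted topology.

        Each bipartition is normalized to the side NOT containing the
        lexicographically smallest leaf, so rooted storage introduces no
        duplicates and comparison across trees is direct.
        """
        leaves = self.leaf_labels
        ref = min(leaves)
        n = len(leaves)
        out: set[frozenset[str]] = set()
        leafsets = self.node_leafsets()
        for node, ls in leafsets.items():
            if node.parent_node is None:
                continue
            side = leaves - ls if ref in ls else ls
            if 2 <= len(side) <= n - 2:
                out.add(frozenset(side))
        return frozenset(out)

    def depths(self) -> dict[dendropy.Node, float]:
        """Branch-length distance from the (storage) root to each node."""
        out: dict[dendropy.Node, float] = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                out[node] = 0.0
            else:
                out[node] = out[node.parent_node] + (node.edge.length or 0.0)
        return out

    def patristic_distance(self, a: str, b: str) -> float:
        depths = self.depths()
        leafsets = self.node_leafsets()
        nodes = {next(iter(ls)): n for n, ls in leafsets.items() if len(ls) == 1}
        na, nb = nodes[a], nodes[b]
        # walk up from the deeper node until the ancestor covers both
        mrca = na
        while not {a, b} <= leafsets[mrca]:
            mrca = mrca.parent_node
        return depths[na] + depths[nb] - 2 * depths[mrca]

    def prune_to(self, taxa: Iterable[str]) -> "PhyloTree":
        """Restriction of the tree to ``taxa`` (unifurcations suppressed)."""
        keep = set(taxa)
        missing = keep - self.leaf_labels
        if missing:
            raise PhyloError(f"taxa not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(
            keep, suppress_unifurcations=True
        )
        sub.is_rooted = self.rooted
        return PhyloTree(sub, self.rooted)

    def external_branch_length(self, taxon: str) -> float:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == taxon:
                return lf.edge.length or 0.0
        raise PhyloError(f"taxon {taxon} not in tree")


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; exact on additive matrices.

    Determinism guarantees: ties in the Q criterion are broken by the
    lexicographic pair of cluster representatives (a cluster is represented
    by its smallest leaf label), and negative branch-length estimates are
    clamped to zero with the deficit logged.  Returns an unrooted tree
    (trifurcating storage root).
    """
    n = len(D.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    d = D.values.astype(float).copy()

    taxon_ns = dendropy.TaxonNamespace(D.taxa)
    nodes: list[dendropy.Node] = []
    for label in D.taxa:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)
    reps = list(D.taxa)  # cluster representatives for tie-breaking
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best: tuple[float, tuple[str, str], int, int] | None = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or q < best[0] or (q == best[0] and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = clamp(li), clamp(lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # new row reuses slot i
        for k in active:
            if k in (i, j):
                continue
            nd = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = max(nd, 0.0)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    center = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = ln
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 100,
    model: str = "p",
    seed: int = 0,
) -> PhyloTree:
    """NJ tree with bootstrap support percentages on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each internal
    edge of the full-data tree gets the percentage of replicate trees
    containing its bipartition (stored as the internal node label).
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    main = neighbor_joining(protein_distance(alignment, model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in main.bipartitions()}
    arr = alignment.to_array()
    # taxon-order invariance: resampling depends only on columns
    order = sorted(range(len(alignment.taxa)), key=lambda i: alignment.taxa[i])
    taxa_sorted = [alignment.taxa[i] for i in order]
    arr = arr[order]
    for _ in range(n_reps):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        rep = Alignment.from_array(taxa_sorted, arr[:, cols])
        rep_tree = neighbor_joining(protein_distance(rep, model))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    leafsets = main.node_leafsets()
    leaves = main.leaf_labels
    ref = min(leaves)
    for node, ls in leafsets.items():
        if node.parent_node is None or node.is_leaf():
            continue
        side = leaves - ls if ref in ls else ls
        if frozenset(side) in counts:
            node.label = str(round(100.0 * counts[frozenset(side)] / n_reps))
    return main


# ---------------------------------------------------------------------------
# rooting


def root_at_outgroup(tree: PhyloTree, outgroup_taxa: Iterable[str]) -> PhyloTree:
    """Root on the edge separating the outgroup clade from the ingroup.

    The edge's length is split evenly across the new root (an explicit
    convention; the data carry no information about the split).  Errors if
    the outgroup cannot form a clade under any rooting.
    """
    og = frozenset(outgroup_taxa)
    leaves = tree.leaf_labels
    if not og or not og <= leaves:
        raise PhyloError(f"outgroup not a nonempty subset of leaves: {sorted(og)}")
    if og == leaves:
        raise PhyloError("outgroup cannot be all taxa")
    work = tree.clone()
    leafsets = work.node_leafsets()
    target = None
    for node, ls in leafsets.items():
        if node.parent_node is None:
            continue
        if ls == og or (leaves - ls) == og:
            target = node
            break
    if target is None:
        raise PhyloError("outgroup paraphyletic: no edge separates it")
    edge = target.edge
    half = (edge.length or 0.0) / 2.0
    work.tree.reroot_at_edge(edge, length1=half, length2=half)
    work.tree.suppress_unifurcations()
    work.tree.is_rooted = True
    return PhyloTree(work.tree, rooted=True)


# ---------------------------------------------------------------------------
# topology comparison


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions (unrooted)."""
    l1, l2 = t1.leaf_labels, t2.leaf_labels
    if l1 != l2:
        raise PhyloError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


@dataclass
class MonophylyResult:
    monophyletic: bool
    clade_taxa: frozenset[str]
    intruders: frozenset[str]

    @property
    def verdict(self) -> str:
        return "monophyletic" if self.monophyletic else "paraphyletic/nested"


def is_monophyletic(tree: PhyloTree, group_taxa: Iterable[str]) -> MonophylyResult:
    """Is ``group_taxa`` a complete clade of the rooted tree?

    Returns the smallest clade containing the group; when that clade holds
    additional taxa they are reported as intruders (supporting statements
    like "group III was contained within group II").
    """
    if not tree.rooted:
        raise PhyloError("monophyly requires a rooted tree (root via outgroup)")
    group = frozenset(group_taxa)
    leaves = tree.leaf_labels
    missing = group - leaves
    if missing:
        raise PhyloError(f"group taxa absent from tree: {sorted(missing)}")
    best: frozenset[str] | None = None
    for _, ls in tree.node_leafsets().items():
        if group <= ls and (best is None or len(ls) < len(best)):
            best = ls
    assert best is not None  # the root covers everything
    return MonophylyResult(best == group, best, best - group)


# ---------------------------------------------------------------------------
# branch-length outliers


@dataclass(frozen=True)
class FlaggedEdge:
    """One anomalously long branch.

    ``edge_id`` is the leaf label for external edges, else the subtended
    (child-side) clade of the internal edge.  ``root_proximal`` records
    whether the edge attaches below the tree's median node depth, the
    operational version of "diverged from near the root".
    """

    edge_id: str | frozenset[str]
    length: float
    z: float
    external: bool
    root_proximal: bool

    def covers(self, taxon: str) -> bool:
        if self.external:
            return self.edge_id == taxon
        return taxon in self.edge_id


@dataclass
class OutlierReport:
    scope: str
    k: float
    median: float
    mad: float
    flagged: list[FlaggedEdge]

    def flag_covering(self, taxon: str, max_clade: int = 2) -> FlaggedEdge | None:
        """Flagged external edge of ``taxon``, or a flagged internal edge
        subtending a clade of at most ``max_clade`` leaves that contains it
        (the paired-sister-species pattern)."""
        for fe in self.flagged:
            if fe.external and fe.edge_id == taxon:
                return fe
            if not fe.external and taxon in fe.edge_id and len(fe.edge_id) <= max_clade:
                return fe
        return None


def branch_length_outliers(
    tree: PhyloTree,
    k: float = 3.0,
    scope: str = "external",
) -> OutlierReport:
    """Robust z-score screen for anomalously long branches.

    For every edge in scope, z = (length - median) / (1.4826 * MAD) over the
    in-scope edge lengths; edges with z > k are flagged.  Each flag records
    whether the edge attaches root-proximally (its parent node's root
    distance is below the median node depth), the signature of a foreign
    homolog joining the tree near its base.
    """
    if scope not in ("external", "internal", "both"):
        raise PhyloError(f"bad scope {scope!r}")
    leafsets = tree.node_leafsets()
    leaves = tree.leaf_labels
    depths = tree.depths()
    node_depths = sorted(depths.values())
    median_depth = float(np.median(node_depths))

    edges: list[tuple[str | frozenset[str], float, bool, float]] = []
    for node, ls in leafsets.items():
        if node.parent_node is None:
            continue
        external = node.is_leaf()
        if scope == "external" and not external:
            continue
        if scope == "internal" and external:
            continue
        if external:
            eid: str | frozenset[str] = node.taxon.label
        else:
            if not (2 <= len(ls) <= len(leaves) - 2):
                continue  # trivial edge in the unrooted sense
            eid = frozenset(ls)  # the subtended clade
        edges.append(
            (eid, node.edge.length or 0.0, external, depths[node.parent_node])
        )
    if len(edges) < 4:
        raise PhyloError("need >= 4 edges in scope")
    lengths = np.array([e[1] for e in edges])
    med = float(np.median(lengths))
    mad = float(np.median(np.abs(lengths - med))) * 1.4826
    if mad == 0.0:
        # > half the branches identical: fall back to the mean absolute
        # deviation (Gaussian-consistent scaling) so a lone long branch in an
        # otherwise uniform tree is still detectable
        mad = float(np.mean(np.abs(lengths - med))) * 1.2533
    flagged: list[FlaggedEdge] = []
    if mad == 0.0:
        warnings.warn("all in-scope branch lengths equal; no outliers flaggable")
    else:
        for eid, length, external, parent_depth in edges:
            z = (length - med) / mad
            if z > k:
                flagged.append(
                    FlaggedEdge(
                        edge_id=eid,
                        length=float(length),
                        z=float(z),
                        external=external,
                        root_proximal=bool(parent_depth < median_depth),
                    )
                )
    flagged.sort(key=lambda fe: -fe.z)
    return OutlierReport(scope=scope, k=k, median=med, mad=mad, flagged=flagged)


# ---------------------------------------------------------------------------
# helpers


def restrict_bipartitions(
    bipartitions: Iterable[frozenset[str]], subset: Iterable[str]
) -> frozenset[frozenset[str]]:
    """Bipartitions induced on a leaf subset (= those of the pruned tree).

    Restricting each split to the subset, renormalizing, and dropping
    trivial ones yields exactly the split set of the induced subtree, so
    pruned-tree Robinson–Foulds distances can be computed without building
    the pruned trees.
    """
    subset = frozenset(subset)
    if len(subset) < 4:
        return frozenset()
    ref = min(subset)
    n = len(subset)
    out: set[frozenset[str]] = set()
    for bp in bipartitions:
        side = frozenset(bp & subset)
        if ref in side:
            side = subset - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def robinson_foulds_restricted(
    t1: PhyloTree | frozenset[frozenset[str]],
    t2: PhyloTree | frozenset[frozenset[str]],
    subset: Iterable[str],
) -> int:
    """RF distance between the two trees pruned to ``subset`` (computed on
    induced bipartition sets; precomputed bipartition sets are accepted)."""
    b1 = t1 if isinstance(t1, frozenset) else t1.bipartitions()
    b2 = t2 if isinstance(t2, frozenset) else t2.bipartitions()
    return len(
        restrict_bipartitions(b1, subset) ^ restrict_bipartitions(b2, subset)
    )


def first_diverging_clade(
    rooted_tree: PhyloTree, subset: Iterable[str] | None = None
) -> frozenset[str]:
    """Taxa of the earliest-diverging clade (optionally within a subset).

    Used to pick gene-tree outgroups the way the source analyses do: the
    lineage that split first from the rest of the group of interest.
    """
    if not rooted_tree.rooted:
        raise PhyloError("requires a rooted tree")
    subset = frozenset(subset) if subset is not None else rooted_tree.leaf_labels
    work = rooted_tree.prune_to(subset) if subset != rooted_tree.leaf_labels else rooted_tree
    children = work.tree.seed_node.child_nodes()
    leafsets = work.node_leafsets()
    sides = sorted(
        (leafsets[ch] for ch in children), key=lambda ls: (len(ls), sorted(ls))
    )
    return frozenset(sides[0])
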
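"""Ribosomal-MLST-style typing from marker-locus alignments.

A column of a marker alignment separates two clusters when each cluster is
fixed for a single allele in that column and the two alleles differ; any
within-cluster polymorphism disqualifies the column for that pair.  A locus
resolves the clusters it separates via at least one column; the unresolved
pairs of a locus are those no column separates.

Trees are built by standard neighbor joining on p-distances (fraction of
differing columns, gaps excluded pairwise) over the concatenated loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .delineation import ClusterPartition

__all__ = [
    "MarkerAlignment",
    "ColumnReport",
    "LocusReport",
    "diagnostic_positions",
    "concat_distance",
    "nj_tree",
    "cluster_monophyly",
]

GAP = "-"


@dataclass
class MarkerAlignment:
    """One locus: equal-length aligned sequences over {A, C, G, T, -}."""

    name: str
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate genome IDs in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must share one length")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, genome_id: str) -> str:
        return self.seqs[self.ids.index(genome_id)]

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "MarkerAlignment":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        import os

        return cls(name or os.path.splitext(os.path.basename(str(path)))[0], ids, seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid, seq in zip(self.ids, self.seqs):
                fh.write(f">{gid}\n{seq}\n")


@dataclass
class ColumnReport:
    """Resolution provided by one alignment column (1-based position)."""

    position: int
    separated_pairs: set[tuple[int, int]]


@dataclass
class LocusReport:
    """Locus-level cluster resolution summary."""

    locus: str
    columns: list[ColumnReport]
    unresolved_pairs: set[tuple[int, int]]

    @property
    def fully_resolving(self) -> bool:
        return not self.unresolved_pairs


def diagnostic_positions(
    aln: MarkerAlignment, labels: ClusterPartition | Mapping[str, int]
) -> LocusReport:
    """Per-column cluster separation report for one locus.

    Only columns where every cluster is fixed for one allele can separate
    cluster pairs; the locus' unresolved pairs are those separated by no
    column.  Positions are reported 1-based.
    """
    if aln.length == 0:
        raise ValueError("alignment has length 0")
    lab = labels.labels if isinstance(labels, ClusterPartition) else dict(labels)
    missing = [g for g in aln.ids if g not in lab]
    if missing:
        raise ValueError(f"labels missing for genomes: {missing}")
    clusters = sorted({lab[g] for g in aln.ids})
    by_cluster = {c: [i for i, g in enumerate(aln.ids) if lab[g] == c] for c in clusters}
    all_pairs = set(combinations(clusters, 2))

    columns: list[ColumnReport] = []
    resolved: set[tuple[int, int]] = set()
    for pos in range(aln.length):
        alleles: dict[int, str | None] = {}
        for c, idx in by_cluster.items():
            col = {aln.seqs[i][pos] for i in idx}
            alleles[c] = col.pop() if len(col) == 1 else None
        sep = {
            (a, b)
            for a, b in all_pairs
            if alleles[a] is not None
            and alleles[b] is not None
            and alleles[a] != alleles[b]
        }
        if sep:
            columns.append(ColumnReport(position=pos + 1, separated_pairs=sep))
            resolved |= sep
    return LocusReport(
        locus=aln.name, columns=columns, unresolved_pairs=all_pairs - resolved
    )


def concat_distance(alignments: Sequence[MarkerAlignment]) -> DistanceMatrix:
    """p-distance matrix on the concatenated loci (pairwise gap deletion)."""
    if not alignments:
        raise ValueError("no alignments given")
    ids = alignments[0].ids
    idset = set(ids)
    for aln in alignments[1:]:
        if set(aln.ids) != idset:
            raise ValueError(f"locus {aln.name!r} covers a different genome set")
    concat = {g: "".join(a.sequence(g) for a in alignments) for g in ids}
    n = len(ids)
    d = np.zeros((n, n))
    arrs = {g: np.frombuffer(concat[g].encode(), dtype="S1") for g in ids}
    gapb = GAP.encode()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            ok = (a != gapb) & (b != gapb)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no shared non-gap columns between {ids[i]} and {ids[j]}"
                )
            d[i, j] = d[j, i] = float((a[ok] != b[ok]).sum()) / total
    return DistanceMatrix(d, ids)


def nj_tree(d: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou-Nei agglomeration; ties in the Q-matrix are broken by
    the smallest (row, column) index pair, so trees are deterministic.  For
    an additive input the tree's path lengths reproduce the matrix exactly.
    Negative branch-length estimates are clamped to zero.  The returned
    tree is unrooted (trifurcating root).
    """
    if isinstance(d, DistanceMatrix):
        ids = list(d.ids)
        D = np.array(d.data, dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        if ids is None:
            ids = [f"t{i}" for i in range(D.shape[0])]
        ids = list(ids)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9) or np.any(np.diag(D) != 0) or D.min() < 0:
        raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")

    nodes: list[TreeNode] = [TreeNode(name=g) for g in ids]
    D = D.copy()
    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic argmin: smallest (row, col) among minima
        flat = np.argmin(Q)
        i, j = divmod(int(flat), r)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way join with closed-form branch lengths
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


def cluster_monophyly(
    tree: TreeNode, labels: ClusterPartition | Mapping[str, int]
) -> dict[int, bool]:
    """Whether each labeled cluster is monophyletic on the unrooted tree.

    A cluster is monophyletic iff some edge bipartition isolates exactly
    its members; on the (arbitrarily rooted) tree this means some node's
    leaf set equals the cluster or its complement.  Singleton clusters are
    trivially monophyletic.
    """
    lab = labels.labels if isinstance(labels, ClusterPartition) else dict(labels)
    leaves = {t.name for t in tree.tips()}
    if leaves != set(lab):
        raise ValueError("tree leaf set differs from the labeled genome set")
    subsets: set[frozenset[str]] = set()
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node._leafset = frozenset([node.name])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.children))
        subsets.add(node._leafset)
    out: dict[int, bool] = {}
    for cluster in sorted(set(lab.values())):
        members = frozenset(g for g, c in lab.items() if c == cluster)
        out[cluster] = (
            len(members) == 1
            or members in subsets
            or frozenset(leaves - members) in subsets
        )
    return out
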
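"""Species-level delineation and duplicate removal from similarity matrices.

Species clusters are the connected components of the graph that joins every
genome pair whose similarity is at or above the species threshold (95% ANI
or 70% dDDH by convention).  Duplicate genomes are collapsed within
clusters of more than three strains when a pair reaches >= 99% on *both*
measures; one representative is kept per duplicate group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score

from .similarity import SimilarityMatrix

__all__ = [
    "DelineationConfig",
    "ClusterPartition",
    "ExclusionLedger",
    "ThresholdClusterer",
    "cluster_by_threshold",
    "dedup",
    "consensus_check",
    "ConsensusReport",
    "ledger_tally",
]


@dataclass(frozen=True)
class DelineationConfig:
    """Thresholds for species delineation and duplicate collapse.

    ani_species_threshold / dddh_species_threshold : percent identity at or
        above which two genomes are conspecific (95 / 70 by convention).
    dup_threshold : percent at or above which, on both measures, a pair is
        a duplicate (99).
    dup_min_group_size : duplicates are only collapsed inside clusters of
        at least this many strains ("groups with more than three strains").
    """

    ani_species_threshold: float = 95.0
    dddh_species_threshold: float = 70.0
    dup_threshold: float = 99.0
    dup_min_group_size: int = 4

    def __post_init__(self) -> None:
        for t in (
            self.ani_species_threshold,
            self.dddh_species_threshold,
            self.dup_threshold,
        ):
            if not 0 < t <= 100:
                raise ValueError("thresholds must lie in (0, 100]")
        if self.dup_threshold <= self.ani_species_threshold:
            raise ValueError("dup_threshold must exceed the species threshold")


@dataclass
class ClusterPartition:
    """Assignment of genomes to clusters.

    Cluster indices are contiguous from 1, ordered by decreasing size and,
    among equal sizes, by the lexicographically smallest member.
    """

    labels: dict[str, int]
    method: str = "ANI"

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    @property
    def genome_ids(self) -> list[str]:
        return list(self.labels)

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return dict(sorted(sizes.items()))

    @classmethod
    def from_raw_labels(
        cls, ids: Sequence[str], raw: Sequence[int], method: str = "ANI"
    ) -> "ClusterPartition":
        """Canonicalize arbitrary component labels to the 1..k convention."""
        groups: dict[int, list[str]] = {}
        for g, r in zip(ids, raw):
            groups.setdefault(int(r), []).append(g)
        ordered = sorted(
            groups.values(), key=lambda ms: (-len(ms), min(ms))
        )
        labels = {g: i + 1 for i, ms in enumerate(ordered) for g in ms}
        return cls({g: labels[g] for g in ids}, method=method)

    def subset(self, keep: Sequence[str]) -> "ClusterPartition":
        kept = {g: self.labels[g] for g in keep}
        return ClusterPartition.from_raw_labels(
            list(kept), list(kept.values()), method=self.method
        )


class ThresholdClusterer(BaseEstimator, ClusterMixin):
    """Connected-component clustering of a similarity matrix at a threshold.

    sklearn-style estimator: ``fit(X)`` takes a square symmetric similarity
    matrix (percent, 100 on the diagonal) and exposes ``labels_`` with
    0-based component labels (size-then-lexicographic canonical order on
    row index when IDs are absent).

    Parameters
    ----------
    threshold : percent; an edge joins every pair with similarity >= it.
    """

    def __init__(self, threshold: float = 95.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square similarity matrix")
        if not np.allclose(X, X.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        adj = csr_matrix(X >= self.threshold)
        n, raw = connected_components(adj, directed=False)
        ids = [f"{i}" for i in range(X.shape[0])]
        part = ClusterPartition.from_raw_labels(ids, raw)
        self.labels_ = np.array([part.labels[g] - 1 for g in ids])
        self.n_clusters_ = n
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_by_threshold(
    matrix: SimilarityMatrix, threshold: float
) -> ClusterPartition:
    """Delineate clusters as components of the >=threshold similarity graph."""
    est = ThresholdClusterer(threshold=threshold).fit(matrix.values)
    return ClusterPartition.from_raw_labels(
        matrix.ids, est.labels_, method=matrix.measure
    )


@dataclass
class ExclusionLedger:
    """Ordered bookkeeping of genome removals, one stage at a time."""

    stages: list[tuple[str, list[tuple[str, str]]]] = field(default_factory=list)

    def add_stage(self, stage: str, removals: Sequence[tuple[str, str]]) -> None:
        seen = self.removed_ids()
        for gid, _ in removals:
            if gid in seen:
                raise ValueError(f"genome {gid!r} already removed in an earlier stage")
            seen.add(gid)
        self.stages.append((stage, [(g, r) for g, r in removals]))

    def removed_ids(self) -> set[str]:
        return {g for _, removals in self.stages for g, _ in removals}

    def counts(self) -> dict[str, int]:
        return {stage: len(removals) for stage, removals in self.stages}

    @property
    def total_removed(self) -> int:
        return sum(len(removals) for _, removals in self.stages)

    def to_rows(self) -> list[tuple[str, str, str]]:
        return [
            (stage, gid, reason)
            for stage, removals in self.stages
            for gid, reason in removals
        ]


def ledger_tally(ledger: ExclusionLedger, initial: int, added: int = 0) -> int:
    """Final genome count: initial - total removed + added."""
    final = initial - ledger.total_removed + added
    if final < 0:
        raise ValueError("ledger removes more genomes than were available")
    return final


def dedup(
    ani: SimilarityMatrix,
    dddh: SimilarityMatrix,
    partition: ClusterPartition,
    config: DelineationConfig | None = None,
    gene_counts: Mapping[str, int] | None = None,
) -> tuple[list[str], ExclusionLedger]:
    """Collapse duplicate genomes within large clusters.

    Within each cluster of size >= ``dup_min_group_size``, duplicate groups
    are the connected components of the graph with an edge wherever BOTH
    ANI and dDDH are >= ``dup_threshold``.  One representative is kept per
    group: the genome with the most gene families present (``gene_counts``)
    or, absent that / on ties, the lexicographically smallest ID.

    Returns the kept IDs (input order) and the exclusion ledger.
    """
    config = config or DelineationConfig()
    if set(ani.ids) != set(dddh.ids):
        raise ValueError("ANI and dDDH matrices cover different genome sets")
    if set(partition.labels) != set(ani.ids):
        raise ValueError("partition does not cover the matrix genome set")

    removed: list[tuple[str, str]] = []
    for cluster in sorted(set(partition.labels.values())):
        members = [g for g in ani.ids if partition.labels[g] == cluster]
        if len(members) < config.dup_min_group_size:
            continue
        a = ani.subset(members).values
        d = dddh.subset(members).values
        adj = (a >= config.dup_threshold) & (d >= config.dup_threshold)
        np.fill_diagonal(adj, True)
        _, raw = connected_components(csr_matrix(adj), directed=False)
        for comp in set(raw):
            group = [m for m, r in zip(members, raw) if r == comp]
            if len(group) < 2:
                continue
            rep = min(
                group,
                key=lambda g: (-(gene_counts or {}).get(g, 0), g),
            )
            removed.extend(
                (g, f"duplicate of {rep} (>= {config.dup_threshold}% ANI and dDDH)")
                for g in group
                if g != rep
            )

    ledger = ExclusionLedger()
    if removed:
        ledger.add_stage("duplicates", removed)
    gone = {g for g, _ in removed}
    kept = [g for g in ani.ids if g not in gone]
    return kept, ledger


@dataclass
class ConsensusReport:
    """Agreement between the ANI- and dDDH-based partitions."""

    ari: float
    discordant: list[str]

    @property
    def concordant(self) -> bool:
        return not self.discordant


def consensus_check(
    p_ani: ClusterPartition, p_dddh: ClusterPartition
) -> ConsensusReport:
    """Adjusted Rand index plus the genomes whose cluster differs.

    Cluster labels of the two partitions are matched by maximum overlap
    (Hungarian assignment); a genome is discordant when its matched labels
    disagree.
    """
    if set(p_ani.labels) != set(p_dddh.labels):
        raise ValueError("partitions cover different genome sets")
    ids = sorted(p_ani.labels)
    la = np.array([p_ani.labels[g] for g in ids])
    ld = np.array([p_dddh.labels[g] for g in ids])
    ari = float(adjusted_rand_score(la, ld))

    from scipy.optimize import linear_sum_assignment

    ca, cd = la.max(), ld.max()
    overlap = np.zeros((ca, cd), dtype=int)
    for x, y in zip(la, ld):
        overlap[x - 1, y - 1] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {c + 1: r + 1 for r, c in zip(rows, cols)}
    discordant = [
        g for g, x, y in zip(ids, la, ld) if mapping.get(y) != x
    ]
    return ConsensusReport(ari=ari, discordant=discordant)
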
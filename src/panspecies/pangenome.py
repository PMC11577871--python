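"""Pangenome partitioning, openness fitting, and core-set algebra.

Gene families are binned by the fraction of genomes carrying them into
core (>= 99%), soft-core (95-99%), shell (15-95%) and cloud (< 15%).
Fractions are converted to integer genome counts by flooring, which
reproduces the per-cluster integer criteria used in practice for cluster
sizes from 3 to 28; the shell band never dips below 2 genomes once a
cluster has more than 6 members (singleton families are cloud), and never
below 1 otherwise.

Pangenome openness follows the Heaps-law power model dn = kappa * N**(-alpha),
where dn is the number of new gene families contributed by the N-th genome
over random genome orderings.  alpha < 1 diagnoses an open pangenome,
alpha > 1 a closed one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresenceAbsenceMatrix",
    "PartitionThresholds",
    "PangenomePartition",
    "HeapsFit",
    "CoreSetFamily",
    "classify_genes",
    "accumulation_curves",
    "fit_heaps",
    "core_fraction",
    "type_core",
]

CLASSES = ("core", "soft_core", "shell", "cloud")


@dataclass
class PresenceAbsenceMatrix:
    """Boolean gene-family x genome matrix backed by a pandas DataFrame."""

    data: pd.DataFrame  # index = gene IDs, columns = genome IDs, dtype bool

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate genome ID {dup!r}")
        if self.data.shape[1] < 1:
            raise ValueError("need at least one genome")
        self.data = self.data.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genomes(self) -> int:
        return self.data.shape[1]

    def presence_counts(self) -> pd.Series:
        """Number of genomes each gene family is present in."""
        return self.data.sum(axis=1)

    def genes_per_genome(self) -> dict[str, int]:
        """Number of gene families present in each genome."""
        return self.data.sum(axis=0).astype(int).to_dict()

    def subset_genomes(self, keep: Sequence[str]) -> "PresenceAbsenceMatrix":
        missing = [g for g in keep if g not in self.data.columns]
        if missing:
            raise KeyError(f"unknown genomes: {missing}")
        return PresenceAbsenceMatrix(self.data.loc[:, list(keep)].copy())

    def drop_absent_genes(self) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(self.data.loc[self.data.any(axis=1)].copy())


@dataclass(frozen=True)
class PartitionThresholds:
    """Fractional presence boundaries between pangenome classes."""

    core_frac: float = 0.99
    soft_frac: float = 0.95
    shell_frac: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.shell_frac < self.soft_frac < self.core_frac <= 1:
            raise ValueError("need 0 < shell < soft < core <= 1")

    def integer_bounds(self, n_genomes: int) -> tuple[int, int, int]:
        """(c_core, c_soft, c_shell): minimum presence counts per band.

        A gene in m of n genomes is core if m >= c_core, soft-core if
        c_soft <= m < c_core, shell if c_shell <= m < c_soft, else cloud.
        The shell floor is 2 for n > 6 and 1 otherwise, so that singleton
        families in mid-size clusters fall in the cloud while tiny clusters
        keep a one-genome shell band.
        """
        c_core = math.floor(self.core_frac * n_genomes)
        c_soft = math.floor(self.soft_frac * n_genomes)
        shell_floor = 2 if n_genomes > 6 else 1
        c_shell = max(shell_floor, math.floor(self.shell_frac * n_genomes))
        return c_core, c_soft, c_shell


@dataclass
class PangenomePartition:
    """Gene-family assignment to {core, soft_core, shell, cloud}."""

    classes: dict[str, str]
    n_genomes: int
    bounds: tuple[int, int, int]
    merged_soft_core: bool = False  # soft-core band empty (tiny clusters)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for c in self.classes.values():
            out[c] += 1
        return out

    def genes_in(self, cls: str) -> set[str]:
        return {g for g, c in self.classes.items() if c == cls}

    @property
    def core_genes(self) -> set[str]:
        return self.genes_in("core")


def classify_genes(
    pam: PresenceAbsenceMatrix,
    thresholds: PartitionThresholds | None = None,
) -> PangenomePartition:
    """Bin every gene family into a pangenome class by presence count.

    Gene families present in zero genomes are excluded with a warning.
    """
    thresholds = thresholds or PartitionThresholds()
    n = pam.n_genomes
    c_core, c_soft, c_shell = thresholds.integer_bounds(n)
    counts = pam.presence_counts()
    absent = counts[counts == 0]
    if len(absent):
        warnings.warn(
            f"{len(absent)} gene families present in no genome were excluded",
            stacklevel=2,
        )
    classes: dict[str, str] = {}
    for gene, m in counts.items():
        if m == 0:
            continue
        if m >= c_core:
            classes[gene] = "core"
        elif m >= c_soft:
            classes[gene] = "soft_core"
        elif m >= c_shell:
            classes[gene] = "shell"
        else:
            classes[gene] = "cloud"
    return PangenomePartition(
        classes=classes,
        n_genomes=n,
        bounds=(c_core, c_soft, c_shell),
        merged_soft_core=(c_soft == c_core),
    )


def core_fraction(partition: PangenomePartition) -> float:
    """Percent of gene families in the core class."""
    counts = partition.counts
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty partition")
    return 100.0 * counts["core"] / total


def accumulation_curves(
    pam: PresenceAbsenceMatrix,
    n_permutations: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Gene-accumulation increments dn(N) over random genome orderings.

    Returns an (n_permutations, n_genomes) array where entry [p, N-1] is
    the number of gene families first observed at the N-th genome of the
    p-th permutation.  Every row sums to the total number of distinct
    families present in at least one genome.
    """
    if pam.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    present = pam.data.to_numpy()
    present = present[present.any(axis=1)]
    n = pam.n_genomes
    out = np.zeros((n_permutations, n), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n)
        first = present[:, order].argmax(axis=1)
        out[p] = np.bincount(first, minlength=n)
    return out


@dataclass
class HeapsFit:
    """Fitted Heaps-law parameters for one genome cluster.

    alpha is the decay exponent of dn = kappa * N**(-alpha) (positive when
    new-gene discovery decays); alpha < 1 calls the pangenome open.
    """

    kappa: float
    alpha: float
    alpha_sd: float
    n_permutations: int
    degenerate: bool = False

    @property
    def openness(self) -> str:
        return "open" if self.alpha < 1 else "closed"


def fit_heaps(curves: np.ndarray | Sequence[Sequence[float]]) -> HeapsFit:
    """Least-squares power-law fit of accumulation curves.

    For each permutation, ln dn is regressed on ln N over the points with
    N >= 2 and dn > 0 (zero increments have no log and are dropped from
    that permutation's fit); alpha-hat = -slope.  The reported alpha and
    alpha_sd are the mean and standard deviation over permutations, and
    kappa the geometric mean of the per-permutation intercepts.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim == 1:
        curves = curves[None, :]
    if curves.shape[1] < 3:
        raise ValueError("each curve must have length >= 3")
    alphas: list[float] = []
    log_kappas: list[float] = []
    for dn in curves:
        N = np.arange(1, len(dn) + 1)
        mask = (N >= 2) & (dn > 0)
        if mask.sum() < 2:
            continue
        x = np.log(N[mask])
        y = np.log(dn[mask])
        slope, intercept = np.polyfit(x, y, 1)
        alphas.append(-slope)
        log_kappas.append(intercept)
    if not alphas:
        warnings.warn("all increments beyond N=1 are zero; degenerate fit")
        return HeapsFit(
            kappa=float("nan"),
            alpha=float("inf"),
            alpha_sd=float("nan"),
            n_permutations=curves.shape[0],
            degenerate=True,
        )
    alpha = float(np.mean(alphas))
    alpha_sd = float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0
    kappa = float(np.exp(np.mean(log_kappas)))
    return HeapsFit(
        kappa=kappa,
        alpha=alpha,
        alpha_sd=alpha_sd,
        n_permutations=curves.shape[0],
    )


@dataclass
class CoreSetFamily:
    """Set algebra over per-cluster core genomes.

    common : gene families core in every cluster.
    type_core : per cluster, families core there and core nowhere else
        (they may still occur as accessory genes elsewhere).
    venn : region counts keyed by the sorted '&'-joined cluster labels,
        e.g. '1&3' counts families core in exactly clusters 1 and 3.
    """

    cores: dict[int, set[str]]
    common: set[str]
    type_core: dict[int, set[str]]
    venn: dict[str, int]


def type_core(cores: Mapping[int, set[str] | frozenset[str]]) -> CoreSetFamily:
    """Common core, type-core sets and all Venn region counts."""
    if len(cores) < 2:
        raise ValueError("need core sets for at least 2 clusters")
    keys = sorted(cores)
    sets = {k: set(cores[k]) for k in keys}
    common = set.intersection(*sets.values())
    tc = {
        k: sets[k] - set().union(*(sets[j] for j in keys if j != k))
        for k in keys
    }
    universe = set().union(*sets.values())
    membership: dict[str, tuple[int, ...]] = {}
    for gene in universe:
        membership[gene] = tuple(k for k in keys if gene in sets[k])
    venn: dict[str, int] = {}
    for combo in _nonempty_subsets(keys):
        venn["&".join(map(str, combo))] = 0
    for combo in membership.values():
        venn["&".join(map(str, combo))] += 1
    return CoreSetFamily(cores=sets, common=common, type_core=tc, venn=venn)


def _nonempty_subsets(keys: Sequence[int]) -> Iterable[tuple[int, ...]]:
    from itertools import combinations

    for r in range(1, len(keys) + 1):
        yield from combinations(keys, r)
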
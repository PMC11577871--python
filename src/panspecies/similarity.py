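"""Pairwise genome similarity: ANI estimation and similarity matrices.

Two alignment-free average-nucleotide-identity (ANI) estimators are
provided.  ``kmer_ani`` is a MinHash-sketch estimator in the style of Mash:
the Jaccard index ``J`` of the bottom-``s`` sketches of the two canonical
k-mer sets is converted to identity through

    ANI ~= 100 * (1 + (1/k) * ln(2J / (1 + J)))

``fragment_ani`` splits the query into fixed-length fragments, estimates
per-fragment identity from k-mer containment (``identity = c ** (1/k)``)
against the whole target, drops fragments whose shared-k-mer fraction is
below ``min_shared_fraction`` (unmapped), and averages reciprocally.

Both treat genomes as unphased contig bags: k-mers are strand-canonical
(the lexicographic/numeric minimum of a window and its reverse complement)
and any non-ACGT character splits the extraction window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AniParams",
    "AniEstimate",
    "SimilarityMatrix",
    "kmer_ani",
    "fragment_ani",
    "build_matrix",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    """Deterministic 64-bit mixer (splitmix64 finalizer)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _kmer_hashes(seq: str, k: int) -> set[int]:
    """Hashes of all canonical k-mers; non-ACGT characters split windows."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rev = 0
    valid = 0
    out: set[int] = set()
    for ch in seq.upper():
        code = _CODE.get(ch)
        if code is None:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | ((3 - code) << shift)
        valid += 1
        if valid >= k:
            out.add(_splitmix64(min(fwd, rev)))
    return out


@dataclass(frozen=True)
class AniParams:
    """Estimator tuning knobs.

    k : k-mer size, 11 <= k <= 31.
    sketch_size : bottom-sketch size for the MinHash estimator.
    fragment_length : query fragment size (bases) for the fragment
        estimator; must be >= 200.
    min_shared_fraction : fragments sharing fewer than this fraction of
        their k-mers with the target are treated as unmapped.
    """

    k: int = 16
    sketch_size: int = 5000
    fragment_length: int = 1000
    min_shared_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 11 <= self.k <= 31:
            raise ValueError(f"k must be in [11, 31], got {self.k}")
        if self.fragment_length < 200:
            raise ValueError("fragment_length must be >= 200")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be positive")
        if not 0.0 <= self.min_shared_fraction <= 1.0:
            raise ValueError("min_shared_fraction must be in [0, 1]")


class AniEstimate(float):
    """A percent-identity estimate; ``flagged`` marks lower-bound results.

    Behaves as a plain float.  ``flagged`` is True when the sketches share
    no k-mers (or no fragment maps), in which case the value is a lower
    bound on divergence, not a point estimate.
    """

    flagged: bool

    def __new__(cls, value: float, flagged: bool = False) -> "AniEstimate":
        obj = super().__new__(cls, value)
        obj.flagged = flagged
        return obj


def _check_pair(seq_a: str, seq_b: str, params: AniParams) -> None:
    if len(seq_a) < 10 * params.k or len(seq_b) < 10 * params.k:
        raise ValueError(
            f"sequences must be >= {10 * params.k} bases for k={params.k}"
        )


def kmer_ani(seq_a: str, seq_b: str, params: AniParams | None = None) -> AniEstimate:
    """MinHash-sketch ANI estimate between two genome sequences (percent).

    Symmetric in its arguments.  When the union sketch shares no hashes the
    Jaccard index is below the sketch resolution; a flagged lower bound
    (computed at J = 1 / (2 * sketch_size)) is returned instead of an error.
    """
    params = params or AniParams()
    _check_pair(seq_a, seq_b, params)
    ha = _kmer_hashes(seq_a, params.k)
    hb = _kmer_hashes(seq_b, params.k)
    s = params.sketch_size
    merged = sorted(ha | hb)[:s]
    shared = sum(1 for h in merged if h in ha and h in hb)
    if shared == 0:
        j = 1.0 / (2 * s)
        return AniEstimate(max(0.0, _mash_ani(j, params.k)), flagged=True)
    j = shared / len(merged)
    return AniEstimate(min(100.0, _mash_ani(j, params.k)))


def _mash_ani(j: float, k: int) -> float:
    return 100.0 * (1.0 + np.log(2.0 * j / (1.0 + j)) / k)


def _directional_fragment_identity(
    query: str, target_hashes: set[int], params: AniParams
) -> list[float]:
    L = params.fragment_length
    idents: list[float] = []
    for start in range(0, max(1, len(query) - L + 1), L):
        frag = query[start : start + L]
        if len(frag) < params.k:
            continue
        fh = _kmer_hashes(frag, params.k)
        if not fh:
            continue
        c = sum(1 for h in fh if h in target_hashes) / len(fh)
        if c < params.min_shared_fraction:
            continue  # unmapped fragment
        idents.append(100.0 * c ** (1.0 / params.k))
    return idents


def fragment_ani(seq_a: str, seq_b: str, params: AniParams | None = None) -> AniEstimate:
    """Fragment-containment ANI estimate (percent), reciprocally averaged.

    The query is cut into ``fragment_length`` pieces; each mapped fragment
    contributes ``100 * c**(1/k)`` where ``c`` is the fraction of its
    k-mers found in the target.  The estimate is the mean over mapped
    fragments, averaged over both directions.  If no fragment maps in
    either direction a flagged zero-identity result is returned.
    """
    params = params or AniParams()
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    _check_pair(seq_a, seq_b, params)
    ha = _kmer_hashes(seq_a, params.k)
    hb = _kmer_hashes(seq_b, params.k)
    fwd = _directional_fragment_identity(seq_a, hb, params)
    rev = _directional_fragment_identity(seq_b, ha, params)
    vals = fwd + rev
    if not vals:
        return AniEstimate(0.0, flagged=True)
    return AniEstimate(min(100.0, float(np.mean(vals))))


@dataclass
class SimilarityMatrix:
    """Symmetric percent-identity matrix (ANI or dDDH) over genome IDs."""

    ids: list[str]
    values: np.ndarray
    measure: str = "ANI"

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate genome IDs")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 100.0, atol=1e-9):
            raise ValueError("diagonal must equal 100")
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise ValueError("values must lie in [0, 100]")
        if self.measure not in ("ANI", "dDDH"):
            raise ValueError("measure must be 'ANI' or 'dDDH'")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, genome_id: str) -> int:
        return self.ids.index(genome_id)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, keep: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.index(g) for g in keep]
        return SimilarityMatrix(
            list(keep), self.values[np.ix_(idx, idx)], self.measure
        )

    def to_tsv(self, path) -> None:
        from .io import write_matrix_tsv

        write_matrix_tsv(self, path)

    @classmethod
    def from_tsv(cls, path, measure: str = "ANI") -> "SimilarityMatrix":
        from .io import read_matrix_tsv

        return read_matrix_tsv(path, measure=measure)


def build_matrix(
    genomes: Mapping[str, str] | Sequence[tuple[str, str]],
    params: AniParams | None = None,
    estimator: Callable[[str, str, AniParams], float] | str = "kmer",
    measure: str = "ANI",
) -> SimilarityMatrix:
    """All-against-all similarity matrix over a FASTA set.

    ``genomes`` maps genome ID to sequence (dict or (id, seq) pairs, order
    preserved).  ``estimator`` is 'kmer', 'fragment', or a callable.
    """
    if isinstance(genomes, Mapping):
        items = list(genomes.items())
    else:
        items = list(genomes)
    ids = [g for g, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome IDs")
    if len(ids) < 2:
        raise ValueError("need at least 2 genomes")
    params = params or AniParams()
    if estimator == "kmer":
        fn = kmer_ani
    elif estimator == "fragment":
        fn = fragment_ani
    elif callable(estimator):
        fn = estimator
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(fn(items[i][1], items[j][1], params))
            vals[i, j] = vals[j, i] = min(100.0, max(0.0, v))
    return SimilarityMatrix(ids, vals, measure)
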
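"""Synthetic genome-collection studies with planted cluster structure.

The generator emulates a bacterial genome collection that splits into a few
species-level clusters: within-cluster ANI/dDDH drawn above the species
thresholds and between-cluster values below them, a gene presence/absence
matrix with a universal core, cluster-specific type-core families and a
shared accessory pool, duplicate genome pairs (for the dedup rule),
marker-locus alignments with planted cluster-diagnostic columns, and a
strain x metabolite BGC count table with cluster-skewed producer
probabilities.  Everything is deterministic given the study seed; all
sub-generators derive child seeds from it.

Similarity values are drawn from normal distributions truncated to
[0, 100]; the defaults place within-cluster ANI at 97 +/- 0.5 and
between-cluster ANI at 90 +/- 0.5, well clear of the 95% species
threshold, and dDDH at 82 +/- 3 vs 45 +/- 4 around the 70% threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pangenome import PresenceAbsenceMatrix, PartitionThresholds
from .rmlst import MarkerAlignment
from .similarity import SimilarityMatrix

__all__ = [
    "MarkerColumnSpec",
    "MarkerLocusSpec",
    "StudyConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_marker_alignment",
    "generate_sequences",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MarkerColumnSpec:
    """One planted diagnostic column.

    position : 1-based column index in the locus alignment.
    groups : allele groups; clusters in the same group share an allele,
        clusters in different groups get distinct alleles.  Clusters not
        listed join the first group.
    """

    position: int
    groups: tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class MarkerLocusSpec:
    name: str
    length: int
    columns: tuple[MarkerColumnSpec, ...]


def _default_marker_loci() -> tuple[MarkerLocusSpec, ...]:
    # L13 analog: central columns fix a distinct allele per cluster, so the
    # locus discriminates all four clusters; L14/L35 analogs separate
    # clusters 1 and 2 but leave 3 and 4 with identical alleles.
    four_way = (((1,), (2,), (3,), (4,)),)
    one_two = (((1,), (2,), (3, 4)),)
    return (
        MarkerLocusSpec(
            "L13",
            120,
            tuple(
                MarkerColumnSpec(pos, four_way[0]) for pos in (55, 60, 65)
            ),
        ),
        MarkerLocusSpec(
            "L14",
            120,
            tuple(MarkerColumnSpec(pos, one_two[0]) for pos in (40, 80)),
        ),
        MarkerLocusSpec(
            "L35",
            90,
            (MarkerColumnSpec(45, one_two[0]),),
        ),
    )


def _default_bgc_metabolites() -> tuple[tuple[str, tuple[float, ...]], ...]:
    # producer probabilities per cluster; first two emulate strongly
    # cluster-skewed lantibiotic/polymyxin-like profiles, the third is
    # unskewed, the last is rare everywhere.
    return (
        ("paenilan_like", (0.37, 0.33, 0.83, 0.86)),
        ("polymyxin_like", (0.54, 0.0, 0.67, 0.93)),
        ("uniform_like", (0.5, 0.5, 0.5, 0.5)),
        ("rare_like", (0.05, 0.0, 0.05, 0.03)),
    )


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of a synthetic study (defaults mirror the study design)."""

    n_clusters: int = 4
    cluster_sizes: tuple[int, ...] = (24, 3, 7, 28)
    n_core_common: int = 2327
    n_type_core_per_cluster: tuple[int, ...] = (70, 164, 183, 82)
    accessory_pool_size: int = 6000
    accessory_presence_prob: float = 0.3
    accessory_spectrum_exponent: float = 1.5
    ani_within_mean: float = 97.0
    ani_within_sd: float = 0.5
    ani_between_mean: float = 90.0
    ani_between_sd: float = 0.5
    dddh_within_mean: float = 82.0
    dddh_within_sd: float = 3.0
    dddh_between_mean: float = 45.0
    dddh_between_sd: float = 4.0
    n_duplicate_pairs: int = 2
    marker_loci: tuple[MarkerLocusSpec, ...] = field(
        default_factory=_default_marker_loci
    )
    bgc_metabolites: tuple[tuple[str, tuple[float, ...]], ...] = field(
        default_factory=_default_bgc_metabolites
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must all be >= 1")
        if len(self.n_type_core_per_cluster) != self.n_clusters:
            raise ValueError("n_type_core_per_cluster length must equal n_clusters")
        if not 0 <= self.accessory_presence_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.ani_within_mean <= self.ani_between_mean:
            raise ValueError("within-ANI mean must exceed between-ANI mean")
        if self.dddh_within_mean <= self.dddh_between_mean:
            raise ValueError("within-dDDH mean must exceed between-dDDH mean")
        for _, probs in self.bgc_metabolites:
            if len(probs) != self.n_clusters or any(
                not 0 <= p <= 1 for p in probs
            ):
                raise ValueError("BGC producer probabilities invalid")


@dataclass
class SyntheticStudy:
    """A generated study with its ground truth."""

    config: StudyConfig
    genome_ids: list[str]
    latent_labels: dict[str, int]
    ani: SimilarityMatrix
    dddh: SimilarityMatrix
    pam_full: PresenceAbsenceMatrix
    marker_alignments: list[MarkerAlignment]
    bgc_table: pd.DataFrame
    truth: dict

    def write_all(self, outdir) -> None:
        """Write matrices, alignments, PAM, BGC table and truth record."""
        from .io import write_matrix_tsv, write_roary_pam

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix_tsv(self.ani, out / "ani.tsv")
        write_matrix_tsv(self.dddh, out / "dddh.tsv")
        write_roary_pam(self.pam_full, out / "gene_presence_absence.csv")
        self.bgc_table.to_csv(out / "bgc.tsv", sep="\t")
        (out / "loci").mkdir(exist_ok=True)
        for aln in self.marker_alignments:
            aln.to_fasta(out / "loci" / f"{aln.name}.fasta")
        with open(out / "labels.tsv", "w") as fh:
            fh.write("genome\tcluster\n")
            for g in self.genome_ids:
                fh.write(f"{g}\t{self.latent_labels[g]}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _child_rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _block_matrix(
    ids: Sequence[str],
    labels: Mapping[str, int],
    within: tuple[float, float],
    between: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mu, sd = within if labels[ids[i]] == labels[ids[j]] else between
            v = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
            vals[i, j] = vals[j, i] = v
    return vals


def generate_marker_alignment(
    labels: Mapping[str, int],
    length: int,
    spec: Sequence[MarkerColumnSpec],
    name: str = "locus",
    seed: int | None = None,
) -> MarkerAlignment:
    """Alignment with planted diagnostic columns; other columns invariant.

    Every planted column gives each allele group a distinct base; all
    remaining columns carry one base shared by every genome.
    """
    rng = np.random.default_rng(seed)
    positions = [c.position for c in spec]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate planted column positions")
    if len(spec) > length:
        raise ValueError("more diagnostic columns requested than the locus length")
    if any(not 1 <= p <= length for p in positions):
        raise ValueError("planted column position outside the locus")
    clusters = sorted(set(labels.values()))
    background = rng.choice(list(_BASES), size=length)
    columns = {g: background.copy() for g in labels}
    for col in spec:
        if len(col.groups) > len(_BASES):
            raise ValueError("more allele groups than available bases")
        allele_of: dict[int, str] = {}
        listed = [c for grp in col.groups for c in grp]
        if len(set(listed)) != len(listed):
            raise ValueError("cluster listed in two allele groups")
        for gi, grp in enumerate(col.groups):
            for c in grp:
                allele_of[c] = _BASES[gi]
        default = _BASES[0]
        for g, lab in labels.items():
            columns[g][col.position - 1] = allele_of.get(lab, default)
    ids = list(labels)
    return MarkerAlignment(name, ids, ["".join(columns[g]) for g in ids])


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study; deterministic given ``config.seed``."""
    config = config or StudyConfig()
    rngs = _child_rngs(
        config.seed, ["ani", "dddh", "pam", "markers", "bgc", "dups"]
    )
    clusters = list(range(1, config.n_clusters + 1))
    genome_ids: list[str] = []
    labels: dict[str, int] = {}
    for c, size in zip(clusters, config.cluster_sizes):
        for i in range(size):
            gid = f"C{c}-{i + 1:02d}"
            genome_ids.append(gid)
            labels[gid] = c

    truth: dict = {"latent_labels": dict(labels), "warnings": []}
    for measure, w_mu, w_sd, b_mu, b_sd, thr in (
        ("ANI", config.ani_within_mean, config.ani_within_sd,
         config.ani_between_mean, config.ani_between_sd, 95.0),
        ("dDDH", config.dddh_within_mean, config.dddh_within_sd,
         config.dddh_between_mean, config.dddh_between_sd, 70.0),
    ):
        if w_mu - 4 * w_sd < thr or b_mu + 4 * b_sd > thr:
            truth["warnings"].append(
                f"{measure} within/between distributions straddle the {thr}% "
                "threshold; delineation recovery is not guaranteed"
            )

    ani_vals = _block_matrix(
        genome_ids, labels,
        (config.ani_within_mean, config.ani_within_sd),
        (config.ani_between_mean, config.ani_between_sd),
        rngs["ani"],
    )
    dddh_vals = _block_matrix(
        genome_ids, labels,
        (config.dddh_within_mean, config.dddh_within_sd),
        (config.dddh_between_mean, config.dddh_between_sd),
        rngs["dddh"],
    )

    # --- choose duplicate pairs up front -----------------------------------
    # The second member of each pair will receive a verbatim copy of the
    # first member's gene content and similarity rows; gene counts are
    # therefore planted on the *unique* genomes only, with caps computed at
    # the post-dedup cluster sizes so that accessory and foreign type-core
    # genes stay strictly below every core threshold both before and after
    # duplicate removal.
    n_total = len(genome_ids)
    col_of = {g: k for k, g in enumerate(genome_ids)}
    members = {c: [g for g in genome_ids if labels[g] == c] for c in clusters}
    eligible = [c for c in clusters if len(members[c]) > 3]
    duplicates: list[tuple[str, str]] = []
    for k in range(config.n_duplicate_pairs):
        if not eligible:
            break
        c = eligible[k % len(eligible)]
        used = {g for pair in duplicates for g in pair}
        free = [g for g in members[c] if g not in used]
        if len(free) < 2:
            continue
        duplicates.append((free[0], free[-1]))
    dup_of = {b: a for a, b in duplicates}
    unique_members = {
        c: [g for g in members[c] if g not in dup_of] for c in clusters
    }
    bounds = {
        c: PartitionThresholds().integer_bounds(len(unique_members[c]))
        for c in clusters
    }
    rows: list[np.ndarray] = []
    gene_names: list[str] = []
    rng = rngs["pam"]

    for i in range(config.n_core_common):
        rows.append(np.ones(n_total, dtype=bool))
        gene_names.append(f"core_{i + 1:05d}")

    type_core_truth: dict[str, list[str]] = {}
    for c, n_tc in zip(clusters, config.n_type_core_per_cluster):
        names = []
        for i in range(n_tc):
            row = np.zeros(n_total, dtype=bool)
            for g in members[c]:
                row[col_of[g]] = True
            # sparse presence elsewhere, capped strictly below every other
            # cluster's core threshold so the family is core only in c
            for other in clusters:
                if other == c:
                    continue
                um = unique_members[other]
                cap = max(0, min(len(um) - 1, bounds[other][0] - 1))
                k = min(int(rng.binomial(len(um), 0.15)), cap)
                if k:
                    chosen = rng.choice(len(um), size=k, replace=False)
                    for idx in chosen:
                        row[col_of[um[idx]]] = True
            name = f"tc{c}_{i + 1:04d}"
            rows.append(row)
            names.append(name)
        type_core_truth[str(c)] = names

    # Accessory genes follow a power-law gene-frequency spectrum
    # (S_m ~ m**-gamma): each gene occurs in a cluster with probability
    # accessory_presence_prob, and within an occupied cluster its presence
    # count is drawn from the truncated power law on 1..(c_core - 1).  The
    # heavy singleton tail is what makes the simulated pangenomes open
    # (alpha < 1); counts stay strictly below every core threshold so
    # accessory genes never contaminate the planted core sets.
    gamma = config.accessory_spectrum_exponent
    spectrum: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for c in clusters:
        cap = max(1, min(len(unique_members[c]) - 1, bounds[c][0] - 1))
        ms = np.arange(1, cap + 1)
        w = ms.astype(float) ** -gamma
        spectrum[c] = (ms, w / w.sum())
    for i in range(config.accessory_pool_size):
        row = np.zeros(n_total, dtype=bool)
        for c in clusters:
            if rng.random() >= config.accessory_presence_prob:
                continue
            ms, w = spectrum[c]
            k = int(rng.choice(ms, p=w))
            um = unique_members[c]
            chosen = rng.choice(len(um), size=k, replace=False)
            for idx in chosen:
                row[col_of[um[idx]]] = True
        if row.any():
            rows.append(row)
            gene_names.append(f"acc_{i + 1:05d}")
    gene_names = (
        gene_names[: config.n_core_common]
        + [n for ns in type_core_truth.values() for n in ns]
        + gene_names[config.n_core_common:]
    )
    pam_matrix = np.vstack(rows)
    pam = PresenceAbsenceMatrix(
        pd.DataFrame(pam_matrix, index=gene_names, columns=genome_ids)
    )

    # --- apply the planted duplicate pairs ---------------------------------
    dup_rng = rngs["dups"]
    for a, b in duplicates:
        ia, ib = col_of[a], col_of[b]
        pam.data[b] = pam.data[a]
        for vals in (ani_vals, dddh_vals):
            vals[ib, :] = vals[ia, :]
            vals[:, ib] = vals[:, ia]
            pair_sim = float(dup_rng.uniform(99.2, 99.9))
            vals[ia, ib] = vals[ib, ia] = pair_sim
            vals[ib, ib] = 100.0
    truth["duplicates"] = [list(p) for p in duplicates]
    truth["expected_dedup_removed"] = sorted(max(p) for p in duplicates)
    truth["type_core"] = type_core_truth

    ani = SimilarityMatrix(genome_ids, ani_vals, "ANI")
    dddh = SimilarityMatrix(genome_ids, dddh_vals, "dDDH")

    # --- marker alignments -------------------------------------------------
    marker_rng = rngs["markers"]
    alignments = []
    diag_truth = {}
    for locus in config.marker_loci:
        aln = generate_marker_alignment(
            labels,
            locus.length,
            locus.columns,
            name=locus.name,
            seed=int(marker_rng.integers(0, 2**31 - 1)),
        )
        alignments.append(aln)
        diag_truth[locus.name] = [
            {"position": c.position, "groups": [list(g) for g in c.groups]}
            for c in locus.columns
        ]
    truth["marker_columns"] = diag_truth

    # --- BGC counts ---------------------------------------------------------
    bgc_rng = rngs["bgc"]
    bgc = pd.DataFrame(0, index=genome_ids, columns=[m for m, _ in config.bgc_metabolites])
    for met, probs in config.bgc_metabolites:
        for c, p in zip(clusters, probs):
            for g in members[c]:
                if bgc_rng.random() < p:
                    bgc.loc[g, met] = int(bgc_rng.integers(1, 4))
    truth["bgc_producer_probs"] = {
        m: list(p) for m, p in config.bgc_metabolites
    }

    return SyntheticStudy(
        config=config,
        genome_ids=genome_ids,
        latent_labels=labels,
        ani=ani,
        dddh=dddh,
        pam_full=pam,
        marker_alignments=alignments,
        bgc_table=bgc,
        truth=truth,
    )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute round(rate * L) random positions, each to a new base."""
    L = len(seq)
    n_sub = int(round(rate * L))
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.choice(L, size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub)
    out[pos] = (out[pos] + shift) % 4
    return out


def generate_sequences(
    study: SyntheticStudy,
    genome_length: int = 20_000,
    substitution_rates: Mapping[tuple[int, int], float] | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Genome sequences whose pairwise divergence tracks the target ANI.

    ``substitution_rates`` maps cluster pairs (i, j), i <= j, to the target
    pairwise substitution divergence (fraction); (i, i) is the
    within-cluster divergence.  Defaults derive from the study's ANI means:
    (100 - ANI) / 100.  Divergences are realized on a star phylogeny: tip
    rates carry the within-cluster divergence, cluster-centre rates are
    solved by least squares to approximate the between-cluster targets.
    Planted duplicate genomes receive their partner's exact sequence.
    """
    if genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    cfg = study.config
    clusters = sorted(set(study.latent_labels.values()))
    if substitution_rates is None:
        w = (100.0 - cfg.ani_within_mean) / 100.0
        b = (100.0 - cfg.ani_between_mean) / 100.0
        substitution_rates = {}
        for i in clusters:
            substitution_rates[(i, i)] = w
            for j in clusters:
                if i < j:
                    substitution_rates[(i, j)] = b
    rates = {tuple(sorted(k)): float(v) for k, v in substitution_rates.items()}
    if any(r > 0.3 for r in rates.values()):
        raise ValueError("substitution rate > 0.3 breaks the ANI estimator assumptions")
    if any(r < 0 for r in rates.values()):
        raise ValueError("substitution rates must be non-negative")

    tip = {c: rates.get((c, c), 0.0) / 2.0 for c in clusters}
    # centre rates: c_i + c_j ~ d_ij - g_i - g_j for every between pair
    pairs = [(i, j) for i in clusters for j in clusters if i < j and (i, j) in rates]
    if pairs:
        A = np.zeros((len(pairs), len(clusters)))
        y = np.zeros(len(pairs))
        idx = {c: k for k, c in enumerate(clusters)}
        for row, (i, j) in enumerate(pairs):
            A[row, idx[i]] = A[row, idx[j]] = 1.0
            y[row] = max(0.0, rates[(i, j)] - tip[i] - tip[j])
        centre_rates, *_ = np.linalg.lstsq(A, y, rcond=None)
        centre = {c: max(0.0, float(centre_rates[idx[c]])) for c in clusters}
    else:
        centre = {c: 0.0 for c in clusters}

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    root = rng.integers(0, 4, size=genome_length)
    centres = {c: _mutate(root, centre[c], rng) for c in clusters}
    seqs: dict[str, str] = {}
    lut = np.array(list(_BASES))
    for g in study.genome_ids:
        c = study.latent_labels[g]
        seqs[g] = "".join(lut[_mutate(centres[c], tip[c], rng)])
    for a, b2 in study.truth.get("duplicates", []):
        seqs[b2] = seqs[a]
    return seqs
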
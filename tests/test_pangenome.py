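"""Pangenome partitioning, Heaps fitting and core-set algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from panspecies import (
    PangenomePartition,
    PartitionThresholds,
    PresenceAbsenceMatrix,
    accumulation_curves,
    classify_genes,
    cluster_by_threshold,
    core_fraction,
    dedup,
    fit_heaps,
    type_core,
)


def _pam_with_counts(n_genomes: int, presence_counts: dict[str, int]):
    data = {}
    genomes = [f"s{i}" for i in range(n_genomes)]
    rows = {
        gene: [i < m for i in range(n_genomes)]
        for gene, m in presence_counts.items()
    }
    return PresenceAbsenceMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=genomes)
    )


class TestClassifyGenes:
    # Explicit per-cluster integer criteria for each study cluster size:
    # (n, m, expected class)
    CRITERIA = [
        # n = 24: core >= 23, soft core = 22, shell 3-21, cloud < 3
        (24, 24, "core"), (24, 23, "core"), (24, 22, "soft_core"),
        (24, 21, "shell"), (24, 3, "shell"), (24, 2, "cloud"), (24, 1, "cloud"),
        # n = 3: core (merged with soft core) >= 2, shell = 1, no cloud band
        (3, 3, "core"), (3, 2, "core"), (3, 1, "shell"),
        # n = 7: core (merged) >= 6, shell 2-5, cloud = 1
        (7, 7, "core"), (7, 6, "core"), (7, 5, "shell"),
        (7, 2, "shell"), (7, 1, "cloud"),
        # n = 28: core >= 27, soft core = 26, shell 4-25, cloud < 4
        (28, 28, "core"), (28, 27, "core"), (28, 26, "soft_core"),
        (28, 25, "shell"), (28, 4, "shell"), (28, 3, "cloud"), (28, 1, "cloud"),
    ]

    @pytest.mark.parametrize("n,m,expected", CRITERIA)
    def test_study_cluster_criteria(self, n, m, expected):
        pam = _pam_with_counts(n, {"g": m})
        part = classify_genes(pam)
        assert part.classes["g"] == expected

    def test_full_presence_is_core_any_n(self):
        for n in (1, 2, 5, 17):
            pam = _pam_with_counts(n, {"g": n})
            assert classify_genes(pam).classes["g"] == "core"

    def test_merged_soft_core_flagged_for_tiny_clusters(self):
        pam = _pam_with_counts(3, {"g": 3})
        assert classify_genes(pam).merged_soft_core

    def test_absent_gene_excluded_with_warning(self):
        pam = _pam_with_counts(4, {"g": 2, "absent": 0})
        with pytest.warns(UserWarning, match="no genome"):
            part = classify_genes(pam)
        assert "absent" not in part.classes

    @given(st.integers(0, 200))
    def test_matches_brute_force_band_derivation(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        counts = {f"g{i}": int(rng.integers(1, n + 1)) for i in range(50)}
        part = classify_genes(_pam_with_counts(n, counts))
        # independent re-derivation straight from the band definition
        c_core = math.floor(0.99 * n)
        c_soft = math.floor(0.95 * n)
        c_shell = max(2, math.floor(0.15 * n))  # n > 6
        for gene, m in counts.items():
            if m >= c_core:
                expected = "core"
            elif m >= c_soft:
                expected = "soft_core"
            elif m >= c_shell:
                expected = "shell"
            else:
                expected = "cloud"
            assert part.classes[gene] == expected

    def test_counts_sum_to_present_genes(self):
        rng = np.random.default_rng(1)
        counts = {f"g{i}": int(rng.integers(1, 13)) for i in range(80)}
        part = classify_genes(_pam_with_counts(12, counts))
        assert sum(part.counts.values()) == 80


class TestCoreFraction:
    def test_study_cluster_four_counts(self):
        # class counts printed for the largest, most homogeneous cluster
        classes = {}
        for cls, k in zip(("core", "soft_core", "shell", "cloud"),
                          (3731, 268, 1563, 5638)):
            for i in range(k):
                classes[f"{cls}_{i}"] = cls
        part = PangenomePartition(classes, n_genomes=28, bounds=(27, 26, 4))
        assert round(core_fraction(part), 1) == 33.3

    def test_all_core(self):
        part = PangenomePartition({"a": "core", "b": "core"}, 5, (5, 5, 1))
        assert core_fraction(part) == 100.0

    def test_uniform_quarters(self):
        part = PangenomePartition(
            {"a": "core", "b": "soft_core", "c": "shell", "d": "cloud"},
            24, (23, 22, 3),
        )
        assert core_fraction(part) == 25.0


class TestAccumulation:
    def test_identical_genomes_all_new_at_first(self):
        pam = _pam_with_counts(4, {f"g{i}": 4 for i in range(9)})
        curves = accumulation_curves(pam, 5, seed=0)
        assert np.array_equal(curves, np.tile([9, 0, 0, 0], (5, 1)))

    def test_three_genome_hand_enumeration(self):
        # A={g1,g2}, B={g2,g3}, C={g3}: order A,B,C gives dn=(2,1,0)
        data = pd.DataFrame(
            {"A": [True, True, False], "B": [False, True, True],
             "C": [False, False, True]},
            index=["g1", "g2", "g3"],
        )
        pam = PresenceAbsenceMatrix(data)
        valid = set()
        import itertools

        for order in itertools.permutations(range(3)):
            seen, dn = set(), []
            cols = data.to_numpy()
            for k in order:
                new = {i for i in range(3) if cols[i, k]} - seen
                dn.append(len(new))
                seen |= new
            valid.add(tuple(dn))
        assert (2, 1, 0) in valid
        curves = accumulation_curves(pam, 30, seed=3)
        for row in curves:
            assert tuple(row) in valid

    def test_conservation_across_permutations(self, small_study):
        pam = small_study.pam_full
        total = int(pam.data.any(axis=1).sum())
        curves = accumulation_curves(pam, 10, seed=1)
        assert np.all(curves.sum(axis=1) == total)

    def test_bad_arguments(self):
        pam = _pam_with_counts(4, {"g": 2})
        with pytest.raises(ValueError):
            accumulation_curves(pam, 0)
        with pytest.raises(ValueError):
            accumulation_curves(_pam_with_counts(1, {"g": 1}), 5)


class TestHeapsFit:
    def test_exact_power_law_recovered(self):
        N = np.arange(1, 21)
        fit = fit_heaps(100.0 * N ** -0.5)
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.kappa == pytest.approx(100.0, rel=1e-6)
        assert fit.openness == "open"

    def test_constant_curve_alpha_zero(self):
        fit = fit_heaps(np.full(15, 7.0))
        assert fit.alpha == pytest.approx(0.0, abs=1e-9)
        assert fit.openness == "open"

    def test_alpha_above_one_is_closed(self):
        N = np.arange(1, 21)
        fit = fit_heaps(50.0 * N ** -1.2)
        assert fit.alpha == pytest.approx(1.2, abs=1e-6)
        assert fit.openness == "closed"

    def test_degenerate_all_zero_tail_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_heaps(np.array([40.0, 0, 0, 0, 0]))
        assert fit.degenerate

    @pytest.mark.parametrize("alpha", [0.3, 0.7, 1.3])
    def test_noisy_recovery_within_tenth(self, alpha):
        """Multiplicative noise, 20 genomes x 50 permutations."""
        rng = np.random.default_rng(int(alpha * 10))
        N = np.arange(1, 21)
        curves = [
            50.0 * N ** -alpha * np.exp(rng.normal(0, 0.1, 20))
            for _ in range(50)
        ]
        fit = fit_heaps(np.array(curves))
        assert fit.alpha == pytest.approx(alpha, abs=0.1)
        assert fit.openness == ("open" if alpha < 1 else "closed")

    def test_study_clusters_are_open(self, study):
        part = cluster_by_threshold(study.ani, 95)
        for c in sorted(set(part.labels.values())):
            members = part.members(c)
            pam_c = study.pam_full.subset_genomes(members).drop_absent_genes()
            fit = fit_heaps(accumulation_curves(pam_c, 50, seed=c))
            assert fit.openness == "open"


class TestTypeCore:
    def test_identical_cores(self):
        fam = type_core({1: {"a", "b"}, 2: {"a", "b"}})
        assert fam.common == {"a", "b"}
        assert fam.type_core == {1: set(), 2: set()}

    def test_hand_enumeration(self):
        fam = type_core({1: {1, 2, 3}, 2: {2, 3, 4}})
        assert fam.common == {2, 3}
        assert fam.type_core == {1: {1}, 2: {4}}
        assert fam.venn == {"1": 1, "2": 1, "1&2": 2}

    def test_planted_type_cores_recovered_exactly(self, study):
        part = cluster_by_threshold(study.ani, 95)
        kept, _ = dedup(study.ani, study.dddh, part,
                        gene_counts=study.pam_full.genes_per_genome())
        part = part.subset(kept)
        cores = {}
        for c in sorted(set(part.labels.values())):
            members = part.members(c)
            latent = study.latent_labels[members[0]]
            pam_c = study.pam_full.subset_genomes(members).drop_absent_genes()
            cores[latent] = classify_genes(pam_c).core_genes
        fam = type_core(cores)
        for c in cores:
            assert fam.type_core[c] == set(study.truth["type_core"][str(c)])
        assert len(fam.common) == study.config.n_core_common

    @given(st.integers(0, 200))
    def test_venn_invariants_on_random_families(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        universe = list(range(40))
        cores = {
            i + 1: set(rng.choice(universe, size=rng.integers(1, 30),
                                  replace=False).tolist())
            for i in range(k)
        }
        fam = type_core(cores)
        union = set().union(*cores.values())
        assert sum(fam.venn.values()) == len(union)
        tc_sets = list(fam.type_core.values())
        for i in range(len(tc_sets)):
            for j in range(i + 1, len(tc_sets)):
                assert not (tc_sets[i] & tc_sets[j])
        for c, tc in fam.type_core.items():
            for other, core in cores.items():
                if other != c:
                    assert not (tc & core)

    def test_requires_two_clusters(self):
        with pytest.raises(ValueError):
            type_core({1: {"a"}})
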
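"""Threshold clustering, dedup and QC bookkeeping against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from panspecies import (
    ClusterPartition,
    DelineationConfig,
    ExclusionLedger,
    SimilarityMatrix,
    ThresholdClusterer,
    cluster_by_threshold,
    consensus_check,
    dedup,
    ledger_tally,
)


def _union_find_components(values: np.ndarray, threshold: float) -> list[set[int]]:
    """Brute-force all-pairs union-find oracle."""
    n = values.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] >= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def _random_similarity(n: int, seed: int) -> SimilarityMatrix:
    rng = np.random.default_rng(seed)
    v = rng.uniform(85, 100, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 100.0)
    return SimilarityMatrix([f"g{i:02d}" for i in range(n)], v)


class TestClusterByThreshold:
    def test_complete_graph_is_one_cluster(self):
        m = SimilarityMatrix(["a", "b", "c"],
                             [[100, 96, 97], [96, 100, 95], [97, 95, 100]])
        assert cluster_by_threshold(m, 95).n_clusters == 1

    def test_two_block_matrix(self):
        ids = ["a1", "a2", "b1", "b2", "b3"]
        v = np.full((5, 5), 90.0)
        for blk in ([0, 1], [2, 3, 4]):
            for i in blk:
                for j in blk:
                    v[i, j] = 97.0
        np.fill_diagonal(v, 100.0)
        part = cluster_by_threshold(SimilarityMatrix(ids, v), 95)
        assert part.n_clusters == 2
        # canonical order: bigger cluster is 1
        assert part.labels["b1"] == 1 and part.labels["a1"] == 2

    def test_synthetic_study_recovers_block_sizes(self, study):
        part = cluster_by_threshold(study.ani, 95)
        assert sorted(part.cluster_sizes().values()) == sorted(
            study.config.cluster_sizes
        )

    def test_nonsymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ThresholdClusterer(95).fit(np.array([[100.0, 96], [90, 100]]))

    @given(st.integers(0, 500), st.integers(4, 20))
    def test_matches_union_find_oracle(self, seed, n):
        m = _random_similarity(n, seed)
        threshold = 95.0
        part = cluster_by_threshold(m, threshold)
        oracle = _union_find_components(m.values, threshold)
        found = {}
        for comp in oracle:
            labels = {part.labels[m.ids[i]] for i in comp}
            assert len(labels) == 1  # component not split
            lab = labels.pop()
            assert lab not in found  # components not merged
            found[lab] = comp
        assert len(found) == part.n_clusters

    @given(st.integers(0, 200), st.integers(4, 15))
    def test_threshold_monotonicity(self, seed, n):
        m = _random_similarity(n, seed)
        counts = [
            cluster_by_threshold(m, t).n_clusters for t in (90.0, 94.0, 98.0)
        ]
        assert counts == sorted(counts)

    def test_partition_labels_contiguous_ordered(self):
        m = _random_similarity(12, 42)
        part = cluster_by_threshold(m, 96)
        sizes = part.cluster_sizes()
        assert list(sizes) == list(range(1, part.n_clusters + 1))
        assert list(sizes.values()) == sorted(sizes.values(), reverse=True) or all(
            sizes[c] >= sizes[c + 1]
            or min(part.members(c)) < min(part.members(c + 1))
            for c in range(1, part.n_clusters)
        )


def _pair_matrix(ids, pairs_at, base=90.0, high=99.5):
    n = len(ids)
    v = np.full((n, n), base)
    np.fill_diagonal(v, 100.0)
    idx = {g: i for i, g in enumerate(ids)}
    for a, b in pairs_at:
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = high
    return v


class TestDedup:
    def _study(self, ids, dup_pairs_ani, dup_pairs_dddh, labels=None):
        # cluster-internal base similarity 97 keeps everyone in one cluster
        ani = SimilarityMatrix(ids, _pair_matrix(ids, dup_pairs_ani, base=97.0))
        dddh = SimilarityMatrix(
            ids, _pair_matrix(ids, dup_pairs_dddh, base=80.0), "dDDH"
        )
        part = ClusterPartition({g: 1 for g in ids}) if labels is None else labels
        return ani, dddh, part

    def test_pair_above_threshold_collapses(self):
        ids = [f"g{i}" for i in range(5)]
        ani, dddh, part = self._study(ids, [("g1", "g3")], [("g1", "g3")])
        kept, ledger = dedup(ani, dddh, part)
        assert len(kept) == 4
        assert ledger.removed_ids() == {"g3"}  # lexicographic representative g1

    def test_small_cluster_untouched(self):
        ids = ["a", "b", "c"]
        ani, dddh, part = self._study(ids, [("a", "b")], [("a", "b")])
        kept, ledger = dedup(ani, dddh, part)
        assert kept == ids and ledger.total_removed == 0

    def test_requires_both_measures(self):
        ids = [f"g{i}" for i in range(5)]
        ani, dddh, part = self._study(ids, [("g1", "g3")], [])  # dDDH below 99
        kept, _ = dedup(ani, dddh, part)
        assert kept == ids

    def test_chain_collapses_to_single_representative(self):
        ids = ["A", "B", "C", "D", "E"]
        chain = [("A", "B"), ("B", "C")]  # A-C below threshold
        ani, dddh, part = self._study(ids, chain, chain)
        kept, ledger = dedup(ani, dddh, part)
        assert ledger.removed_ids() == {"B", "C"}
        assert "A" in kept

    def test_gene_rich_representative_preferred(self):
        ids = [f"g{i}" for i in range(5)]
        ani, dddh, part = self._study(ids, [("g1", "g3")], [("g1", "g3")])
        kept, ledger = dedup(
            ani, dddh, part, gene_counts={"g1": 10, "g3": 50}
        )
        assert ledger.removed_ids() == {"g1"}

    def test_idempotent(self, study):
        from panspecies import cluster_by_threshold

        part = cluster_by_threshold(study.ani, 95)
        kept1, _ = dedup(study.ani, study.dddh, part)
        ani2, dddh2 = study.ani.subset(kept1), study.dddh.subset(kept1)
        kept2, ledger2 = dedup(ani2, dddh2, part.subset(kept1))
        assert kept2 == kept1 and ledger2.total_removed == 0

    def test_mismatched_id_sets_rejected(self):
        ids = [f"g{i}" for i in range(4)]
        ani = SimilarityMatrix(ids, _pair_matrix(ids, []))
        dddh = SimilarityMatrix(ids[:3], _pair_matrix(ids[:3], []), "dDDH")
        with pytest.raises(ValueError):
            dedup(ani, dddh, ClusterPartition({g: 1 for g in ids}))

    def test_removes_exactly_planted_duplicates(self, study):
        part = cluster_by_threshold(study.ani, 95)
        kept, ledger = dedup(
            study.ani, study.dddh, part,
            gene_counts=study.pam_full.genes_per_genome(),
        )
        assert sorted(ledger.removed_ids()) == study.truth["expected_dedup_removed"]


def _pair_counting_ari(la, lb) -> float:
    """Brute-force adjusted Rand index from pair agreement counts."""
    from math import comb

    n = len(la)
    same_a = {(i, j) for i in range(n) for j in range(i + 1, n) if la[i] == la[j]}
    same_b = {(i, j) for i in range(n) for j in range(i + 1, n) if lb[i] == lb[j]}
    a = len(same_a & same_b)
    total = comb(n, 2)
    exp = len(same_a) * len(same_b) / total
    max_index = (len(same_a) + len(same_b)) / 2
    if max_index == exp:
        return 1.0
    return (a - exp) / (max_index - exp)


class TestConsensus:
    def test_identical_partitions(self):
        p = ClusterPartition({"a": 1, "b": 1, "c": 2})
        rep = consensus_check(p, p)
        assert rep.ari == pytest.approx(1.0)
        assert rep.discordant == []

    def test_one_moved_genome_listed(self):
        pa = ClusterPartition({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})
        pb = ClusterPartition({"a": 1, "b": 1, "c": 2, "d": 2, "e": 2, "f": 2})
        rep = consensus_check(pa, pb)
        assert rep.discordant == ["c"]

    @given(st.integers(0, 300))
    def test_ari_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(30)]
        la = rng.integers(1, 5, size=30)
        lb = rng.integers(1, 5, size=30)
        pa = ClusterPartition.from_raw_labels(ids, la)
        pb = ClusterPartition.from_raw_labels(ids, lb)
        rep = consensus_check(pa, pb)
        assert rep.ari == pytest.approx(
            _pair_counting_ari(list(la), list(lb)), abs=1e-9
        )


class TestLedger:
    def test_study_qc_arithmetic(self):
        """108 assemblies minus the staged exclusions plus 6 additions = 62."""
        ledger = ExclusionLedger()
        ledger.add_stage("abnormalities", [(f"anc{i}", "contamination/no RefSeq")
                                           for i in range(27)])
        ledger.add_stage("duplicates", [(f"dup{i}", "duplicate") for i in range(7)])
        ledger.add_stage("low_completeness", [(f"lc{i}", "low BUSCO")
                                              for i in range(3)])
        ledger.add_stage("reclassified", [("ISL-58", "closer to another species")])
        ledger.add_stage("ani_dddh_duplicates",
                         [(f"ad{i}", ">=99% ANI and dDDH") for i in range(14)])
        assert ledger_tally(ledger, initial=108, added=5 + 1) == 62

    def test_no_removals(self):
        assert ledger_tally(ExclusionLedger(), 10) == 10

    def test_double_removal_rejected(self):
        ledger = ExclusionLedger()
        ledger.add_stage("s1", [("x", "r")])
        with pytest.raises(ValueError, match="already removed"):
            ledger.add_stage("s2", [("x", "r")])
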
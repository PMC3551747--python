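import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osedax16s.core_io import SequenceRecord
from osedax16s.diversity import (
    cluster_ribospecies,
    distance_matrix,
    effective_length,
    group_divergence_matrix,
    nucleotide_diversity,
    p_distance,
    segregating_sites,
    watterson_theta,
)


def _records(seqs):
    return [SequenceRecord(id=f"s{i}", seq=s) for i, s in enumerate(seqs)]


class TestPDistance:
    def test_single_difference(self):
        a, b = _records(["ACGT", "ACGA"])
        assert p_distance(a, b) == (0.25, 1, 4)

    def test_identical(self):
        a, b = _records(["ACGT", "ACGT"])
        assert p_distance(a, b) == (0.0, 0, 4)

    def test_pairwise_deletion_of_n(self):
        a, b = _records(["ACNT", "ACGT"])
        assert p_distance(a, b) == (0.0, 0, 3)

    def test_ambiguity_sites_excluded(self):
        a, b = _records(["ACYT", "ACCA"])
        prop, raw, compared = p_distance(a, b)
        assert (raw, compared) == (1, 3)

    def test_length_mismatch(self):
        a, b = _records(["ACGT", "ACG"])
        with pytest.raises(ValueError, match="length"):
            p_distance(a, b)

    def test_no_comparable_sites(self):
        a, b = _records(["NNNN", "ACGT"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(a, b)

    @given(
        st.lists(st.sampled_from("ACGTN-"), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, chars, rnd):
        seq_a = "".join(chars)
        seq_b = "".join(rnd.choice("ACGTN-") for _ in chars)
        has_pair = any(
            x in "ACGT" and y in "ACGT" for x, y in zip(seq_a, seq_b)
        )
        if not (has_pair and set(seq_a) & set("ACGT")):
            return
        a = SequenceRecord(id="a", seq=seq_a)
        b = SequenceRecord(id="b", seq=seq_b)
        dab, dba = p_distance(a, b), p_distance(b, a)
        assert dab == dba
        assert 0.0 <= dab.proportion <= 1.0

    def test_matrix_agrees_with_scalar(self, small_pool):
        records = small_pool.records
        dm = distance_matrix(records)
        for i, j in itertools.combinations(range(len(records)), 2):
            scalar = p_distance(records[i], records[j])
            assert dm.proportions[i, j] == pytest.approx(scalar.proportion)
            assert dm.differences[i, j] == scalar.differences


class TestPolymorphismStats:
    def test_no_segregation_in_identical_pair(self):
        assert segregating_sites(_records(["ACGT", "ACGT"])) == 0

    def test_segregating_columns_by_inspection(self):
        assert segregating_sites(_records(["ACGT", "ACGA", "ATGA"])) == 2

    def test_ambiguous_bases_do_not_segregate(self):
        # Y vs C at a column is not two unambiguous states
        assert segregating_sites(_records(["ACYT", "ACCT"])) == 0

    def test_diversity_identical(self):
        result = nucleotide_diversity(_records(["ACGT", "ACGT"]))
        assert result.pi == 0.0
        assert result.mean_pairwise_differences == 0.0

    def test_diversity_single_difference(self):
        result = nucleotide_diversity(_records(["ACGT", "ACGA"]))
        assert result.pi == pytest.approx(0.25)
        assert result.mean_pairwise_differences == pytest.approx(1.0)

    def test_pi_times_length_equals_k_on_clean_alignment(self, small_pool):
        records = small_pool.records
        result = nucleotide_diversity(records)
        L = len(records[0].seq)
        assert result.pi * L == pytest.approx(result.mean_pairwise_differences)

    def test_watterson_closed_form(self):
        a4 = 1 + 1 / 2 + 1 / 3 + 1 / 4
        assert watterson_theta(5, 5, 100) == pytest.approx(5 / (a4 * 100))

    def test_watterson_trivial_cases(self):
        assert watterson_theta(0, 10, 672) == 0.0
        assert watterson_theta(7, 2, 100) == pytest.approx(7 / 100)

    def test_watterson_invalid_inputs(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 1, 100)
        with pytest.raises(ValueError):
            watterson_theta(5, 5, 0)

    def test_effective_length_excludes_masked_columns(self):
        records = _records(["ACGT", "ACNT", "ACGY"])
        assert effective_length(records) == 2


def close_groups_far_means():
    """Two tight ribotype groups whose closest inter-group pair is under 3%
    while the inter-group mean divergence is above it — the empirical
    configuration of the two dominant endosymbiont ribospecies (minimum 13
    substitutions across 672 bp, mean divergence 3.5%)."""
    L = 672
    base = "A" * L

    def mutated(positions):
        chars = list(base)
        for p in positions:
            chars[p] = "G"
        return "".join(chars)

    return [
        SequenceRecord(id="a1", seq=base),
        SequenceRecord(id="a2", seq=mutated(range(0, 8))),
        SequenceRecord(id="b1", seq=mutated(range(300, 313))),  # 13 steps from a1
        SequenceRecord(id="b2", seq=mutated([*range(300, 313), *range(400, 410)])),
    ]


def _brute_force_agglomerate(records, threshold, linkage):
    """Direct linkage evaluation over all partitions of the merge sequence."""
    dm = distance_matrix(records)
    clusters = [frozenset([i]) for i in range(len(records))]

    def linkage_distance(a, b):
        values = [dm.proportions[i, j] for i in a for j in b]
        if linkage == "average":
            return float(np.mean(values))
        return min(values) if linkage == "single" else max(values)

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = linkage_distance(a, b)
            key = tuple(
                sorted((min(dm.labels[i] for i in a), min(dm.labels[i] for i in b)))
            )
            cand = (d, key, a, b)
            if best is None or (d < best[0] - 1e-12) or (
                abs(d - best[0]) <= 1e-12 and key < best[1]
            ):
                best = cand
        if best[0] > threshold:
            break
        _, _, a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return {frozenset(dm.labels[i] for i in c) for c in clusters}


class TestRibospeciesClustering:
    def test_all_identical_collapse(self):
        records = [SequenceRecord(id=f"s{i}", seq="ACGTACGT") for i in range(4)]
        assert cluster_ribospecies(records).n_groups == 1

    def test_recovers_true_groups(self, small_pool):
        clustering = cluster_ribospecies(small_pool.records)
        truth = small_pool.true_assignment
        assert clustering.n_groups == len(small_pool.species)
        for group in clustering.groups.values():
            assert len({truth[r] for r in group}) == 1

    def test_average_linkage_separates_close_groups_single_would_merge(self):
        records = close_groups_far_means()
        group1, group2 = records[:2], records[2:]
        cross = [
            p_distance(a, b).proportion for a in group1 for b in group2
        ]
        assert min(cross) < 0.03 < np.mean(cross)

        average = cluster_ribospecies(records, threshold=0.03, linkage="average")
        single = cluster_ribospecies(records, threshold=0.03, linkage="single")
        assert average.n_groups == 2
        assert {frozenset(g) for g in average.groups.values()} == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
        }
        assert single.n_groups == 1

    def test_input_order_invariance(self, small_pool):
        records = list(small_pool.records)
        forward = cluster_ribospecies(records)
        backward = cluster_ribospecies(records[::-1])
        assert forward.assignment == backward.assignment

    @pytest.mark.parametrize("linkage", ["average", "single", "complete"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_oracle(self, linkage, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        records = [
            SequenceRecord(
                id=f"s{i}", seq="".join(rng.choice(list("ACGT"), size=30))
            )
            for i in range(n)
        ]
        threshold = float(rng.uniform(0.05, 0.5))
        mine = {
            frozenset(g)
            for g in cluster_ribospecies(records, threshold, linkage).groups.values()
        }
        assert mine == _brute_force_agglomerate(records, threshold, linkage)

    def test_scipy_linkage_cross_check(self, small_pool):
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        records = small_pool.records
        dm = distance_matrix(records)
        condensed = squareform(dm.proportions, checks=False)
        labels = fcluster(
            scipy_linkage(condensed, method="average"), t=0.03, criterion="distance"
        )
        scipy_groups = {}
        for rec, lab in zip(records, labels):
            scipy_groups.setdefault(lab, set()).add(rec.id)
        mine = {frozenset(g) for g in cluster_ribospecies(records).groups.values()}
        assert mine == {frozenset(g) for g in scipy_groups.values()}


class TestGroupDivergence:
    def test_two_clean_groups(self):
        records = [
            SequenceRecord(id="a1", seq="AAAA"),
            SequenceRecord(id="a2", seq="AAAA"),
            SequenceRecord(id="b1", seq="TTAA"),
            SequenceRecord(id="b2", seq="TTAA"),
        ]
        clustering = cluster_ribospecies(records, threshold=0.1)
        matrix = group_divergence_matrix(clustering, distance_matrix(records))
        groups = clustering.groups
        (g_a,) = [g for g, m in groups.items() if "a1" in m]
        (g_b,) = [g for g, m in groups.items() if "b1" in m]
        assert matrix.loc[g_a, g_a] == 0.0
        assert matrix.loc[g_a, g_b] == pytest.approx(0.5)

    def test_singleton_group_not_computable(self):
        records = [
            SequenceRecord(id="a1", seq="AAAAAAAAAA"),
            SequenceRecord(id="b1", seq="TTTTTAAAAA"),
        ]
        clustering = cluster_ribospecies(records, threshold=0.01)
        matrix = group_divergence_matrix(clustering, distance_matrix(records))
        assert np.isnan(np.diag(matrix)).all()  # singletons: within n/c

    def test_offdiagonal_symmetry(self, small_pool):
        clustering = cluster_ribospecies(small_pool.records)
        matrix = group_divergence_matrix(
            clustering, distance_matrix(small_pool.records)
        )
        values = matrix.to_numpy()
        assert np.allclose(values, values.T, equal_nan=True)
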
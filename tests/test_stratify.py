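"""K-means stratification, misclassification distance, stability test,
complete-linkage clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hyposig.io import ExpressionMatrix, normalize_chain
from hyposig.signature import Signature
from hyposig.stratify import (
    _lloyd,
    expected_chance_distance,
    hcluster_complete,
    kmeans2,
    label_prognosis,
    misclassification_distance,
    permutation_stability,
    prepare_cluster_matrix,
)


def exhaustive_best_wcss(M):
    """Minimum within-cluster SS over all 2-partitions (oracle)."""
    n = M.shape[0]
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all():
            continue
        w = ((M[mask] - M[mask].mean(0)) ** 2).sum() + ((M[~mask] - M[~mask].mean(0)) ** 2).sum()
        best = min(best, w)
    return best


class TestKmeans:
    def test_separated_blobs_split_perfectly_any_seed(self):
        rng = np.random.default_rng(0)
        M = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(10, 1, (20, 3))])
        for seed in (0, 1, 99):
            A = kmeans2(M, restarts=5, seed=seed)
            first = set(A.labels[:20])
            assert len(first) == 1 and set(A.labels[20:]) != first

    def test_duplicate_rows_co_assigned(self):
        rng = np.random.default_rng(1)
        M = rng.normal(0, 1, (8, 2))
        Md = np.vstack([M, M])
        A = kmeans2(Md, restarts=50, seed=3)
        assert (A.labels[:8] == A.labels[8:]).all()

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            kmeans2(np.ones((5, 2)), restarts=3, seed=0)

    def test_wcss_never_increases_within_lloyd_run(self):
        rng = np.random.default_rng(2)
        M = rng.normal(0, 1, (30, 4))
        trace: list = []
        _lloyd(M, M[[0, 1]].copy(), trace=trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        M = rng.normal(0, 1, (25, 5))
        a = kmeans2(M, restarts=10, seed=7)
        b = kmeans2(M, restarts=10, seed=7)
        assert (a.labels == b.labels).all() and a.inertia == b.inertia


class TestPrognosisLabels:
    def test_high_expression_cluster_is_poor(self):
        M = np.vstack([np.full((5, 3), 2.0), np.full((6, 3), 0.5)])
        M += np.random.default_rng(0).normal(0, 0.01, M.shape)
        A = kmeans2(M, restarts=10, seed=1)
        A = label_prognosis(A, M)
        poor = [c for c, l in A.prognosis.items() if l == "poor"][0]
        assert set(np.flatnonzero(A.labels == poor)) == set(range(5))

    def test_invariant_to_cluster_index_permutation(self):
        M = np.vstack([np.full((5, 2), 3.0), np.full((5, 2), 1.0)])
        M += np.random.default_rng(1).normal(0, 0.01, M.shape)
        ids = [f"s{i}" for i in range(10)]
        A = kmeans2(M, restarts=10, seed=0, sample_ids=ids)
        B = kmeans2(M, restarts=10, seed=0, sample_ids=ids)
        B.labels = 3 - B.labels  # swap cluster indices
        pa = set(label_prognosis(A, M).poor_samples())
        pb = set(label_prognosis(B, M).poor_samples())
        assert pa == pb

    def test_recovers_planted_hypoxic_patients(self, planted_cohort, sig62, evaluation_bundle):
        _, clin, H = planted_cohort
        poor = set(evaluation_bundle.assignment.poor_samples())
        hypoxic = {pid for pid, h in zip(clin.patient_ids, H) if h == 1}
        assert len(poor & hypoxic) / len(hypoxic) >= 0.9


class TestMisclassificationDistance:
    def test_equal_labelings(self):
        a = np.array([1, 1, 2, 2])
        assert misclassification_distance(a, a) == 0.0

    def test_swapped_cluster_indices(self):
        a = np.array([1, 1, 2, 2])
        assert misclassification_distance(a, 3 - a) == 0.0

    def test_maximally_discordant(self):
        assert misclassification_distance(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2])) == 0.5

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            a = rng.integers(1, 3, n)
            b = rng.integers(1, 3, n)
            brute = min(
                np.mean(perm[a - 1] != b) for perm in (np.array([1, 2]), np.array([2, 1]))
            )
            assert misclassification_distance(a, b) == pytest.approx(brute)

    @given(st.integers(0, 5000))
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 3, 12)
        b = rng.integers(1, 3, 12)
        d = misclassification_distance(a, b)
        assert d == misclassification_distance(b, a)
        assert 0.0 <= d <= 0.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            misclassification_distance(np.array([1, 2]), np.array([1, 2, 1]))


class TestChanceBaseline:
    def test_matches_monte_carlo(self):
        n, m_a, m_b = 40, 12, 20
        rng = np.random.default_rng(5)
        a = np.array([1] * m_a + [2] * (n - m_a))
        sims = []
        for _ in range(4000):
            b = np.full(n, 2)
            b[rng.choice(n, m_b, replace=False)] = 1
            sims.append(misclassification_distance(a, b))
        assert expected_chance_distance(n, m_a, m_b) == pytest.approx(np.mean(sims), abs=0.01)


class TestPermutationStability:
    def _structureless(self, seed, p=400, n=40):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            np.exp2(rng.normal(7, 1, (p, n))),
            index=[f"G{i}" for i in range(p)],
            columns=[f"S{i}" for i in range(n)],
        )
        return ExpressionMatrix(df, "linear")

    def test_records_exactly_n_perm_distances(self):
        E = self._structureless(0)
        res = permutation_stability(E, Signature("s", [f"G{i}" for i in range(8)]),
                                    n_perm=25, seed=1, restarts=5)
        assert res.n_perm == 25 and len(res.distances) == 25

    def test_pure_function_of_inputs(self):
        E = self._structureless(1)
        S = Signature("s", [f"G{i}" for i in range(8)])
        r1 = permutation_stability(E, S, n_perm=10, seed=9, restarts=5)
        r2 = permutation_stability(E, S, n_perm=10, seed=9, restarts=5)
        np.testing.assert_array_equal(r1.distances, r2.distances)
        assert r1.p_value == r2.p_value

    def test_strong_signature_effect_detected(self, planted_cohort, sig62):
        E, _, _ = planted_cohort
        res = permutation_stability(normalize_chain(E), sig62, n_perm=60, seed=2, restarts=15)
        assert res.p_value < 0.001
        # random signatures track the pervasive structure: distances shrink
        assert res.distances.mean() < res.baselines.mean()

    def test_too_few_permutations_rejected(self):
        E = self._structureless(2)
        with pytest.raises(ValueError):
            permutation_stability(E, Signature("s", ["G0"]), n_perm=1, seed=0)


def naive_complete_linkage(rows):
    """O(n^3) agglomeration oracle: returns merge heights and member sets."""
    clusters = {i: frozenset([i]) for i in range(len(rows))}
    dist = {
        (i, j): np.linalg.norm(rows[i] - rows[j])
        for i, j in itertools.combinations(range(len(rows)), 2)
    }

    def cdist(a, b):
        return max(dist[tuple(sorted((i, j)))] for i in a for j in b)

    merges = []
    while len(clusters) > 1:
        pairs = list(itertools.combinations(clusters.keys(), 2))
        key = min(pairs, key=lambda pr: cdist(clusters[pr[0]], clusters[pr[1]]))
        h = cdist(clusters[key[0]], clusters[key[1]])
        merged = clusters.pop(key[0]) | clusters.pop(key[1])
        nid = max(list(clusters.keys()) + [len(rows) + len(merges)]) + 1
        clusters[nid] = merged
        merges.append((h, merged))
    return merges


class TestHierarchicalClustering:
    def test_first_merge_joins_closest_pair(self):
        rows = np.array([[0.0], [1.0], [3.0]])  # pairwise distances 1, 2, 3
        order, Z = hcluster_complete(rows)
        assert sorted(Z[0, :2].astype(int)) == [0, 1]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(6)
        _, Z = hcluster_complete(rng.normal(0, 1, (15, 4)))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(7)
        rows = rng.normal(0, 1, (8, 3))
        _, Z = hcluster_complete(rows)
        oracle = naive_complete_linkage(rows)
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(h for h, _ in oracle), atol=1e-10)
        # reconstruct scipy's member sets and compare merge-by-merge
        members = {i: frozenset([i]) for i in range(8)}
        for k, (a, b, h, _) in enumerate(Z):
            members[8 + k] = members[int(a)] | members[int(b)]
        scipy_sets = {members[8 + k] for k in range(len(Z))}
        assert scipy_sets == {m for _, m in oracle}
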
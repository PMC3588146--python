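"""Dimension reduction, bootstrap, consensus clustering, and the full pipeline."""

from itertools import combinations

import numpy as np
import pytest

from sigdecipher import build_alphabet
from sigdecipher.catalog import CatalogMatrix
from sigdecipher.decipher import (
    DecipherConfig,
    bootstrap_catalog,
    cluster_signatures,
    cosine_similarity,
    decipher_signatures,
    reduce_dimensions,
    silhouette_widths,
)
from sigdecipher.evaluate import match_signatures
from sigdecipher.nmf import NMFConfig
from sigdecipher.simulate import SimulationSpec, simulate_catalogs, simulate_exposures, simulate_truth

from conftest import make_signatures

FAST_NMF = NMFConfig(max_iter=30_000, conv_window=2_000, conv_tol=1e-6, check_every=10)


def toy_catalog(counts, scheme="SBS6"):
    counts = np.asarray(counts)
    alpha = build_alphabet(scheme)
    assert counts.shape[0] == alpha.K
    return CatalogMatrix(
        alphabet=alpha,
        samples=[f"g{i}" for i in range(counts.shape[1])],
        counts=counts,
    )


class TestReduceDimensions:
    def test_only_affordable_row_removed(self):
        counts = np.array([[1], [4], [95]] + [[0]] * 3)
        # rows sum 1, 4, 95 and three zero rows; threshold 1% of 100 = 1
        red = reduce_dimensions(toy_catalog(counts), 0.01)
        removed_totals = counts[red.removed_rows, :].sum(axis=1)
        assert set(removed_totals.tolist()) == {0, 1}
        assert removed_totals.sum() <= 1

    def test_zero_rows_always_removed(self):
        counts = np.array([[0], [0], [50], [50], [0], [0]])
        red = reduce_dimensions(toy_catalog(counts), 0.01)
        assert len(red.removed_rows) == 4
        assert np.array_equal(red.M_dot, [[50], [50]])

    def test_greedy_matches_brute_force_on_small_candidates(self, rng):
        """Oracle: exhaustive search over subsets of the 10 smallest rows for
        the largest removal set within the 1% budget."""
        counts = rng.poisson(3, size=(96, 20))
        counts[rng.choice(96, size=30, replace=False), :] = rng.poisson(
            40, size=(30, 20)
        )
        M = toy_catalog(counts, "SBS96")
        red = reduce_dimensions(M, 0.01)
        row_totals = counts.sum(axis=1)
        budget = 0.01 * row_totals.sum()
        candidates = np.argsort(row_totals, kind="stable")[:10]
        best = 0
        for k in range(len(candidates) + 1):
            for subset in combinations(candidates, k):
                if row_totals[list(subset)].sum() <= budget:
                    best = max(best, k)
        assert len(red.removed_rows) == best
        assert row_totals[red.removed_rows].sum() <= budget

    def test_kept_rows_preserve_order(self, rng):
        counts = rng.poisson(10, size=(6, 4))
        red = reduce_dimensions(toy_catalog(counts), 0.0)
        assert np.array_equal(red.kept_rows, np.arange(6))

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            reduce_dimensions(toy_catalog(np.zeros((6, 2), int)), 0.01)


class TestBootstrap:
    def test_column_sums_preserved_exactly(self, rng):
        X = rng.poisson(20, size=(12, 7)).astype(float) + 1
        for _ in range(5):
            B = bootstrap_catalog(X, rng)
            assert np.array_equal(B.sum(axis=0), X.sum(axis=0))

    def test_degenerate_single_type_column_unchanged(self, rng):
        X = np.zeros((4, 1))
        X[2, 0] = 37
        assert np.array_equal(bootstrap_catalog(X, rng), X)

    def test_zero_total_column_rejected(self, rng):
        X = np.zeros((4, 2))
        X[0, 0] = 5
        with pytest.raises(ValueError):
            bootstrap_catalog(X, rng)

    def test_cellwise_mean_approaches_original(self, rng):
        X = rng.poisson(30, size=(6, 3)).astype(float) + 1
        mean = np.mean([bootstrap_catalog(X, rng) for _ in range(1000)], axis=0)
        assert np.allclose(mean, X, rtol=0.1, atol=1.5)


class TestCosine:
    def test_identical_vectors(self, rng):
        v = rng.random(10) + 0.1
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert cosine_similarity([1, 1, 0, 0], [0, 0, 2, 3]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestClusterSignatures:
    def test_identical_runs_up_to_permutation(self, rng):
        base = make_signatures(12, 3, rng).P
        perms = [np.array([0, 1, 2]), np.array([2, 0, 1]), np.array([1, 2, 0])]
        S_P = [base[:, p] for p in perms]
        S_E = [np.eye(3)[p, :] @ np.arange(12).reshape(3, 4) for p in perms]
        centroids, _, assign, converged = cluster_signatures(S_P, S_E, 3)
        # each cluster's members are a single true signature
        for run, p in enumerate(perms):
            for col in range(3):
                # column col of run `run` holds base signature p[col]
                mates = assign[run, col]
                sim = cosine_similarity(centroids[:, mates], base[:, p[col]])
                assert sim > 0.999

    def test_two_permuted_matrices_matching_recovers_permutation(self, rng):
        base = make_signatures(10, 3, rng).P
        perm = np.array([2, 0, 1])
        S_P = [base, base[:, perm]]
        S_E = [np.zeros((3, 2)), np.zeros((3, 2))]
        _, _, assign, _ = cluster_signatures(S_P, S_E, 3)
        # columns carrying the same signature land in the same cluster
        assert np.array_equal(assign[1, :], assign[0, perm])

    def test_perturbed_prototypes_recovered(self, rng):
        protos = make_signatures(20, 3, rng).P
        S_P, S_E = [], []
        for _ in range(10):
            noisy = protos + rng.normal(0, 0.002, size=protos.shape).clip(-protos, None)
            noisy /= noisy.sum(axis=0)
            perm = rng.permutation(3)
            S_P.append(noisy[:, perm])
            S_E.append(np.zeros((3, 4)))
        centroids, _, _, _ = cluster_signatures(S_P, S_E, 3)
        sims = np.array(
            [[cosine_similarity(centroids[:, i], protos[:, j]) for j in range(3)] for i in range(3)]
        )
        assert np.all(sims.max(axis=1) > 0.99)


class TestSilhouette:
    def test_tight_separated_clusters_score_near_one(self, rng):
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0, 0, 0, 1.0])
        pts = np.vstack([a + rng.uniform(0, 1e-4, 4) for _ in range(5)]
                        + [b + rng.uniform(0, 1e-4, 4) for _ in range(5)])
        labels = np.array([0] * 5 + [1] * 5)
        per_cluster, overall = silhouette_widths(pts, labels)
        assert overall > 0.999 and np.all(per_cluster > 0.999)

    def test_indistinguishable_clusters_score_zero(self):
        pts = np.tile([1.0, 2.0, 3.0], (6, 1))
        labels = np.array([0, 0, 0, 1, 1, 1])
        _, overall = silhouette_widths(pts, labels)
        assert overall == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_computed_six_point_instance(self):
        """Textbook formula s(i) = (b−a)/max(a,b) with 1−cosine distance,
        computed by hand (naive loops) for 6 points in 2 clusters."""
        pts = np.array(
            [
                [1.0, 0.1],
                [1.0, 0.2],
                [0.9, 0.15],
                [0.1, 1.0],
                [0.2, 1.0],
                [0.1, 0.9],
            ]
        )
        labels = np.array([0, 0, 0, 1, 1, 1])

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        expected = []
        for i in range(6):
            own = [1 - cos(pts[i], pts[j]) for j in range(6) if j != i and labels[j] == labels[i]]
            other = [1 - cos(pts[i], pts[j]) for j in range(6) if labels[j] != labels[i]]
            a, b = np.mean(own), np.mean(other)
            expected.append((b - a) / max(a, b))
        per_cluster, overall = silhouette_widths(pts, labels)
        assert overall == pytest.approx(np.mean(expected), abs=1e-9)
        assert per_cluster[0] == pytest.approx(np.mean(expected[:3]), abs=1e-9)
        assert per_cluster[1] == pytest.approx(np.mean(expected[3:]), abs=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_widths(np.eye(3), np.zeros(3, dtype=int))


class TestDecipherPipeline:
    def test_noiseless_well_separated_signatures_recovered(self, rng):
        """Exact-factorization input with distinct signatures: every matched
        cosine ≥ 0.99 and exposures recovered closely."""
        alpha = build_alphabet("SBS96")
        # orthogonal-ish sparse signatures: pairwise cosine < 0.3
        P = make_signatures(96, 4, rng, alphabet=alpha, concentration=0.1)
        spec = SimulationSpec(N=4, G=50, mutations_per_genome=("uniform", 2000, 20_000), seed=21)
        E = simulate_exposures(spec, rng)
        M = simulate_catalogs(P, E, noise_model="none", rng=rng)
        cfg = DecipherConfig(N=4, I=30, nmf=FAST_NMF, seed=5)
        res = decipher_signatures(M, cfg)
        match = match_signatures(res.P_bar, P)
        assert np.all(match.cosines >= 0.99)
        assert res.avg_silhouette > 0.9
        rel_err = np.linalg.norm(res.E_bar.E[np.argsort(match.pairing), :] - E.E) / np.linalg.norm(E.E)
        assert rel_err < 0.1

    def test_determinism_same_seed_same_result(self, rng):
        truth = simulate_truth(SimulationSpec(N=3, G=20, seed=31))
        cfg = DecipherConfig(N=3, I=10, nmf=FAST_NMF, seed=17)
        r1 = decipher_signatures(truth.M, cfg)
        r2 = decipher_signatures(truth.M, cfg)
        assert np.array_equal(r1.P_bar.P, r2.P_bar.P)
        assert r1.avg_silhouette == r2.avg_silhouette
        assert r1.reconstruction_error == r2.reconstruction_error

    def test_p_bar_columns_sum_to_one_with_zero_removed_rows(self, rng):
        counts = np.asarray(simulate_truth(SimulationSpec(N=3, G=15, seed=41)).M.counts).copy()
        counts[5, :] = 0  # force a removable row
        M = toy_catalog(counts, "SBS96")
        res = decipher_signatures(M, DecipherConfig(N=3, I=8, nmf=FAST_NMF, seed=3))
        assert np.allclose(res.P_bar.P.sum(axis=0), 1.0, atol=1e-8)
        assert np.all(res.P_bar.P[res.reduced.removed_rows, :] == 0)
        assert 5 in res.reduced.removed_rows

    def test_rank_one_convention(self, rng):
        truth = simulate_truth(SimulationSpec(N=2, G=10, seed=51))
        res = decipher_signatures(truth.M, DecipherConfig(N=1, I=5, nmf=FAST_NMF, seed=1))
        assert res.avg_silhouette == 1.0
        # single signature tracks the normalized pooled mutation spectrum
        pooled = truth.M.counts.sum(axis=1).astype(float)
        assert cosine_similarity(res.P_bar.P[:, 0], pooled) > 0.98

    def test_signatures_ordered_by_reproducibility(self, rng):
        truth = simulate_truth(SimulationSpec(N=4, G=25, seed=61))
        res = decipher_signatures(truth.M, DecipherConfig(N=4, I=12, nmf=FAST_NMF, seed=2))
        assert np.all(np.diff(res.per_cluster_silhouette) <= 1e-12)

    def test_auto_iterations_stop_when_consensus_stabilizes(self, rng):
        truth = simulate_truth(SimulationSpec(N=2, G=15, seed=71))
        cfg = DecipherConfig(N=2, I="auto", auto_I_batch=10, auto_I_tol=1e-3, nmf=FAST_NMF, seed=4)
        res = decipher_signatures(truth.M, cfg)
        assert res.I_used >= 20 and res.I_used % 10 == 0
        assert res.stable

    def test_infeasible_rank_rejected(self, rng):
        truth = simulate_truth(SimulationSpec(N=2, G=5, seed=81))
        with pytest.raises(ValueError):
            decipher_signatures(truth.M, DecipherConfig(N=50, I=5, nmf=FAST_NMF))
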
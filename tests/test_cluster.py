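import itertools

import numpy as np
import pytest

from wcms.cluster import (
    NoveltyIdentifier,
    SpectralClusterer,
    call_novelty,
    cut_dendrogram,
    mantel,
    pearson_binary,
    proximity,
    upgma,
)
from wcms.types import BinaryPeakMatrix, NoveltyCall, SimilarityMatrix


def random_similarity(n, rng):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix([f"s{i}" for i in range(n)], np.clip(v, -1, 1))


def binary_matrix(bits, window=(3500.0, 20000.0)):
    bits = np.asarray(bits)
    positions = np.linspace(4000, 19000, bits.shape[0])
    labels = [f"s{j}" for j in range(bits.shape[1])]
    return BinaryPeakMatrix(positions, labels, bits, mz_window=window)


class TestPearsonBinary:
    def test_self_correlation(self):
        x = np.array([1, 0, 1, 1, 0])
        assert pearson_binary(x, x) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        x = np.array([1, 1, 0, 0, 1])
        y = np.array([1, 0, 0, 0, 1])
        assert pearson_binary(x, y) == pytest.approx(2 / 3)

    def test_complement_anticorrelated(self):
        x = np.array([1, 0, 1, 0, 1])
        assert pearson_binary(x, 1 - x) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_binary(np.ones(5), np.array([1, 0, 1, 0, 1]))


class TestProximity:
    def test_duplicated_spectrum(self):
        bits = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 1], [0, 0, 0]])
        sim = proximity(binary_matrix(bits))
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        bits = (rng.random((30, 8)) > 0.5).astype(int)
        # guard against constant columns in the draw
        bits[0] = 1
        bits[1] = 0
        sim = proximity(binary_matrix(bits))
        n = bits.shape[1]
        for i in range(n):
            for j in range(n):
                x, y = bits[:, i].astype(float), bits[:, j].astype(float)
                expected = (np.mean((x - x.mean()) * (y - y.mean()))
                            / (x.std() * y.std())) if i != j else 1.0
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        bits = (rng.random((25, 6)) > 0.5).astype(int)
        bits[0] = 1
        bits[1] = 0
        base = proximity(binary_matrix(bits))
        perm = rng.permutation(6)
        m = binary_matrix(bits)
        permuted = BinaryPeakMatrix(m.positions, [m.labels[p] for p in perm],
                                    bits[:, perm], mz_window=m.mz_window)
        sim_p = proximity(permuted)
        np.testing.assert_allclose(sim_p.values,
                                   base.values[np.ix_(perm, perm)], atol=1e-12)

    def test_constant_column_names_offender(self):
        bits = np.array([[1, 0], [0, 0], [1, 0]])
        with pytest.raises(ValueError, match="s1"):
            proximity(binary_matrix(bits))


def upgma_oracle(d):
    """O(n^3) re-averaging UPGMA: clusters as explicit leaf sets, inter-
    cluster distance recomputed each step as the mean over member pairs."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0] - 1e-15:
                best = (dist, a, b)
        dist, a, b = best
        merges.append((a, b, dist / 2.0))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestUPGMA:
    def test_two_leaves_forced(self):
        sim = SimilarityMatrix(["A", "B"], np.array([[1.0, 0.8], [0.8, 1.0]]))
        tree = upgma(sim)
        assert tree.merges == [(0, 1, pytest.approx(0.1))]

    def test_hand_traced_three_leaves(self):
        # d(A,B)=0.2, d(A,C)=0.6, d(B,C)=0.8
        r = 1 - np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]])
        np.fill_diagonal(r, 1.0)
        tree = upgma(SimilarityMatrix(["A", "B", "C"], r))
        (a, b, h1), (c, d_, h2) = tree.merges
        assert {a, b} == {0, 1} and h1 == pytest.approx(0.1)
        assert h2 == pytest.approx(0.35)  # mean(0.6, 0.8) / 2

    def test_agrees_with_reaveraging_oracle(self):
        """Merge heights and cluster compositions match the brute-force
        O(n^3) group-average oracle on 50 random 6-leaf instances."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sim = random_similarity(6, rng)
            tree = upgma(sim)
            expected = upgma_oracle(sim.to_distance())
            got_heights = sorted(h for _, _, h in tree.merges)
            exp_heights = sorted(h for _, _, h in expected)
            np.testing.assert_allclose(got_heights, exp_heights, atol=1e-10)
            # same flat partitions at every cut level
            for k in (2, 3, 4):
                got = cut_dendrogram(tree, k)
                exp = _flat_from_merges(expected, 6, k)
                assert _same_partition(got, exp)

    def test_heights_non_decreasing(self, rng):
        tree = upgma(random_similarity(10, rng))
        heights = [h for _, _, h in tree.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))


def _flat_from_merges(merges, n, k):
    members = {i: [i] for i in range(n)}
    nid = n
    active = set(range(n))
    for a, b, _ in merges[: n - k]:
        members[nid] = members[a] + members[b]
        active -= {a, b}
        active.add(nid)
        nid += 1
    labels = np.empty(n, int)
    for ci, cid in enumerate(sorted(active)):
        labels[members[cid]] = ci
    return labels


def _same_partition(x, y):
    from sklearn.metrics import adjusted_rand_score
    return adjusted_rand_score(x, y) == 1.0


class TestNovelty:
    def test_identical_to_reference_assigned(self):
        bits = np.array([[1, 0], [0, 1], [1, 1], [0, 0], [1, 0]])
        call = call_novelty(bits[:, 0], bits, ["refA", "refB"], "q")
        assert call.verdict == "assigned"
        assert call.best_match == "refA"
        assert call.best_similarity == pytest.approx(1.0)

    @pytest.mark.parametrize("best,verdict", [
        (0.49, "candidate_novel"),
        (0.51, "assigned"),
        (0.50, "assigned"),  # strictly-less-than threshold semantics
    ])
    def test_threshold_semantics(self, best, verdict):
        assert NoveltyCall("q", "ref", best).verdict == verdict

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_novelty(np.array([1, 0]), np.empty((2, 0)), [])


def mantel_r(a, b):
    iu = np.triu_indices(a.shape[0], k=1)
    return np.corrcoef(a[iu], b[iu])[0, 1]


class TestMantel:
    def test_self_correlation(self, rng):
        a = random_similarity(8, rng)
        res = mantel(a, a, n_permutations=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000, abs=2e-3)

    def test_exhaustive_enumeration_oracle_4x4(self, rng):
        """Monte-Carlo p on a 4x4 instance matches the exact p from
        enumerating all 24 joint relabelings."""
        a = random_similarity(4, rng)
        b = random_similarity(4, rng)
        r_obs = mantel_r(a.values, b.values)
        count = sum(
            mantel_r(a.values, b.values[np.ix_(p, p)]) >= r_obs - 1e-12
            for p in map(list, itertools.permutations(range(4)))
        )
        exact = count / 24
        res = mantel(a, b, n_permutations=9999, seed=3)
        mc_se = np.sqrt(exact * (1 - exact) / 9999)
        assert res.p_value == pytest.approx(exact, abs=max(4 * mc_se, 1e-3))

    def test_cross_check_against_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        a = random_similarity(8, rng)
        b = random_similarity(8, rng)
        da, db = 1 - a.values, 1 - b.values
        np.fill_diagonal(da, 0)
        np.fill_diagonal(db, 0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(da, a.labels),
                                   DistanceMatrix(db, b.labels),
                                   method="pearson", permutations=0,
                                   alternative="greater")
        res = mantel(a, b, n_permutations=99, seed=0)
        # distances are 1 - similarity, so correlations coincide
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_seed_reproducibility(self, rng):
        a = random_similarity(6, rng)
        b = random_similarity(6, rng)
        r1 = mantel(a, b, 499, seed=42)
        r2 = mantel(a, b, 499, seed=42)
        assert r1.p_value == r2.p_value

    def test_label_mismatch_rejected(self, rng):
        a = random_similarity(5, rng)
        b = random_similarity(5, rng)
        b.labels[0] = "other"
        with pytest.raises(ValueError, match="label"):
            mantel(a, b)


class TestEstimators:
    def test_clusterer_on_binary_matrix(self, rng):
        bits = np.zeros((40, 6), int)
        bits[:20, :3] = (rng.random((20, 3)) > 0.2).astype(int)
        bits[20:, 3:] = (rng.random((20, 3)) > 0.2).astype(int)
        est = SpectralClusterer(n_clusters=2).fit(binary_matrix(bits))
        labels = est.labels_
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert est.similarity_.values.shape == (6, 6)
        assert len(est.dendrogram_.merges) == 5

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = SpectralClusterer(n_clusters=3, max_shift=10.0)
        cloned = clone(est)
        assert cloned.get_params()["max_shift"] == 10.0
        cloned.set_params(threshold_percent=7.5)
        assert cloned.threshold_percent == 7.5
        clone(NoveltyIdentifier(threshold=0.4))
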
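import itertools

import numpy as np
import pytest

import gcmap
from gcmap.mapping import MediolateralPattern
from gcmap.population import (
    CorrelationBiclustering,
    CorrelationMatrix,
    center_on_soma,
    correlation_matrix,
    median_patterns,
    pattern_correlation,
    shuffle_null,
    spectral_cocluster,
)
from gcmap.synth import planted_group_labels
from sklearn.metrics import adjusted_rand_score


def pat(values, start=0.0, soma=None, cell_id=None):
    values = np.asarray(values, dtype=float)
    return MediolateralPattern(
        positions_um=start + np.arange(values.size, dtype=float),
        values=values,
        soma_position_um=soma,
        cell_id=cell_id,
    )


def brute_force_bipartition(M):
    """Exhaustive 2-way partition maximising within-block mass."""
    n = M.shape[0]
    best, best_score = None, -np.inf
    for size in range(1, n // 2 + 1):
        for block in itertools.combinations(range(n), size):
            a = np.zeros(n, bool)
            a[list(block)] = True
            within = M[np.ix_(a, a)].sum() / a.sum() ** 2 + M[
                np.ix_(~a, ~a)
            ].sum() / (~a).sum() ** 2
            if within > best_score:
                best_score, best = within, a
    return best


class TestPatternCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        p = pat(rng.uniform(0, 5, 200))
        assert pattern_correlation(p, p) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 5, 200)
        assert pattern_correlation(pat(v), pat(-v)) == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        b = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        # patterns already on a common 10 µm-compatible support
        pa = pat(np.repeat(a, 10))
        pb = pat(np.repeat(b, 10))
        got = pattern_correlation(pa, pb)
        va, vb = pa.resample(np.arange(0.0, 50.0, 10.0)), pb.resample(
            np.arange(0.0, 50.0, 10.0)
        )
        cov = ((va - va.mean()) * (vb - vb.mean())).sum()
        expected = cov / np.sqrt(
            ((va - va.mean()) ** 2).sum() * ((vb - vb.mean()) ** 2).sum()
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_pattern_rejected(self):
        with pytest.raises(gcmap.UndefinedCorrelationError):
            pattern_correlation(pat(np.ones(100)), pat(np.arange(100.0)))

    def test_disjoint_supports_rejected(self):
        with pytest.raises(gcmap.UndefinedCorrelationError):
            pattern_correlation(pat(np.arange(50.0)), pat(np.arange(50.0), start=500.0))


class TestShuffleNull:
    def _population(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return [
            pat(rng.uniform(0, 5, 300), soma=float(200 * i), cell_id=f"c{i}")
            for i in range(n)
        ]

    def test_identical_patterns_give_r_one(self):
        v = np.sin(np.arange(300) / 20.0) + 2
        pats = [pat(v, soma=float(200 * i)) for i in range(5)]
        rs = shuffle_null(pats, 10, seed=0)
        np.testing.assert_allclose(rs, 1.0)

    def test_same_seed_reproducible(self):
        pats = self._population()
        a = shuffle_null(pats, 50, seed=3)
        b = shuffle_null(pats, 50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_independent_patterns_mean_near_zero(self):
        pats = self._population(n=30, seed=4)
        rs = shuffle_null(pats, 300, seed=5)
        se = rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean()) <= 3 * se + 0.01

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            shuffle_null(self._population(n=2), 10, seed=0)

    def test_neighbors_and_self_excluded(self):
        pats = self._population(n=6)
        # all somas identical -> every pairing is a neighbour pairing
        for p in pats:
            p.soma_position_um = 0.0
        with pytest.raises(ValueError, match="no admissible"):
            shuffle_null(
                [pat(np.random.default_rng(i).uniform(0, 5, 300), soma=0.0) for i in range(6)],
                10,
                seed=0,
            )


class TestMedianPatterns:
    def test_single_cell_is_its_own_median(self):
        rng = np.random.default_rng(7)
        p = pat(rng.uniform(0, 5, 200), soma=100.0, cell_id="only")
        groups = median_patterns([p], np.array([100.0]))
        assert groups
        for g in groups:
            assert abs(g.center_um - 100.0) <= 50.0
            np.testing.assert_allclose(
                g.pattern.resample(p.positions_um), p.values, atol=1e-9
            )
            assert g.member_ids == ("only",)

    def test_elementwise_median_of_three(self):
        pats = [
            pat(np.full(200, v), soma=50.0, cell_id=str(v)) for v in (1.0, 2.0, 9.0)
        ]
        groups = median_patterns(pats, np.array([50.0, 50.0, 50.0]))
        g = groups[len(groups) // 2]
        assert g.n_members == 3
        np.testing.assert_allclose(g.pattern.values, 2.0)
        # MAD of (1, 2, 9) is 1
        np.testing.assert_allclose(g.mad, 1.0)

    def test_window_membership(self, archetype_analysis):
        patterns, positions, _ = archetype_analysis
        groups = median_patterns(patterns, positions)
        for g in groups:
            for m in g.member_ids:
                i = next(
                    k for k, p in enumerate(patterns) if p.cell_id == m
                )
                assert abs(positions[i] - g.center_um) <= 50.0


class TestCorrelationMatrix:
    def test_identical_groups_all_ones(self):
        rng = np.random.default_rng(8)
        p = pat(rng.uniform(0, 5, 300), soma=10.0)
        groups = median_patterns([p, p, p], np.array([0.0, 10.0, 20.0]))
        R = correlation_matrix(groups)
        np.testing.assert_allclose(R.values, 1.0)

    def test_symmetric_unit_diagonal(self, archetype_analysis):
        patterns, positions, _ = archetype_analysis
        R = correlation_matrix(median_patterns(patterns, positions))
        np.testing.assert_allclose(R.values, R.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(R.values), 1.0)
        assert np.nanmax(np.abs(R.values)) <= 1.0 + 1e-12

    def test_orthogonal_patterns_near_zero(self):
        n = 300
        x = np.arange(n)
        v1 = np.sin(2 * np.pi * x / 50.0)
        v2 = np.cos(2 * np.pi * x / 50.0)
        p1, p2 = pat(v1 + 2, soma=0.0), pat(v2 + 2, soma=300.0)
        groups = median_patterns([p1, p2], np.array([0.0, 300.0]))
        R = correlation_matrix(groups)
        off = R.values[0, -1]
        assert abs(off) < 0.1

    def test_undefined_entries_are_nan_not_zero(self):
        flat = pat(np.ones(200), soma=0.0)
        varied = pat(np.arange(200.0), soma=300.0)
        groups = median_patterns([flat, varied], np.array([0.0, 300.0]))
        R = correlation_matrix(groups)
        assert np.isnan(R.values[0, -1])

    def test_affine_rescaling_invariance(self, archetype_analysis):
        patterns, positions, _ = archetype_analysis
        sub = patterns[:8]
        groups = median_patterns(sub, positions[:8])
        R1 = correlation_matrix(groups)
        scaled = [
            MediolateralPattern(p.positions_um, 3.0 * p.values + 7.0, cell_id=p.cell_id)
            for p in sub
        ]
        R2 = correlation_matrix(median_patterns(scaled, positions[:8]))
        np.testing.assert_allclose(R1.values, R2.values, atol=1e-9)


class TestCoclustering:
    def _block_matrix(self, sizes, rng):
        n = sum(sizes)
        M = np.full((n, n), -0.3)
        start = 0
        for s in sizes:
            M[start : start + s, start : start + s] = 1.0
            start += s
        perm = rng.permutation(n)
        return M[np.ix_(perm, perm)], perm

    def test_two_block_recovery_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for sizes in [(3, 5), (4, 4), (2, 6)]:
            M, _ = self._block_matrix(sizes, rng)
            assign = spectral_cocluster(M, k=2)
            oracle = brute_force_bipartition((M + 1) / 2)
            got = assign.labels == assign.labels[0]
            assert (got == oracle).all() or (got == ~oracle).all()

    def test_constant_matrix_rejected(self):
        with pytest.raises(gcmap.DegenerateStructureError):
            spectral_cocluster(np.ones((5, 5)), k=2)

    def test_k_larger_than_matrix_rejected(self):
        with pytest.raises(ValueError):
            spectral_cocluster(np.eye(3), k=5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        M, _ = self._block_matrix((3, 4, 5), rng)
        assign0 = spectral_cocluster(M, k=3)
        perm = rng.permutation(M.shape[0])
        assign1 = spectral_cocluster(M[np.ix_(perm, perm)], k=3)
        # permuting rows/columns permutes assignments identically
        assert (
            adjusted_rand_score(assign0.labels[perm], assign1.labels) == 1.0
        )

    def test_archetype_recovery_contiguous(self, archetype_analysis):
        patterns, positions, archetypes = archetype_analysis
        groups = median_patterns(patterns, positions)
        R = correlation_matrix(groups)
        est = CorrelationBiclustering(n_clusters=4).fit(R)
        truth = planted_group_labels(groups, archetypes)
        ok = truth >= 0
        assert adjusted_rand_score(truth[ok], est.row_labels_[ok]) >= 0.9
        assert all(est.contiguous_.values())
        # symmetric matrix: identical row and column partitions
        np.testing.assert_array_equal(est.row_labels_, est.column_labels_)


class TestCenterOnSoma:
    def test_single_pattern_translated(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(0, 5, 100)
        p = pat(v, start=200.0, soma=250.0)
        offsets, mean = center_on_soma([p], normalize=False)
        np.testing.assert_allclose(offsets, p.positions_um - 250.0)
        np.testing.assert_allclose(mean, v, atol=1e-9)

    def test_mirror_pair_symmetric_mean(self):
        v = np.concatenate([np.zeros(40), np.ones(20), np.zeros(140)])
        p1 = pat(v, soma=100.0)
        p2 = pat(v[::-1], soma=99.0)
        offsets, mean = center_on_soma([p1, p2], normalize=False)
        both = ~np.isnan(mean)
        o, m = offsets[both], mean[both]
        # symmetric within the jointly covered range
        lo, hi = max(o[0], -o[-1]), min(o[-1], -o[0])
        xs = np.arange(lo, hi + 1.0)
        np.testing.assert_allclose(
            np.interp(xs, o, m), np.interp(-xs, o, m), atol=1e-9
        )

    def test_centering_erases_distal_structure(self, archetype_analysis):
        # hotspots sit at absolute positions; aligning on somas keeps only
        # the local input aligned, so the mean shows one central peak and
        # the distal hotspots smear out instead of forming a secondary peak
        patterns, _, _ = archetype_analysis
        offsets, mean = center_on_soma(patterns)
        covered = ~np.isnan(mean)
        o, m = offsets[covered], mean[covered]
        peak = o[np.argmax(m)]
        assert abs(peak) <= 50.0
        distal = np.abs(o) > 150.0
        assert m[distal].max() < 0.6 * m.max()
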
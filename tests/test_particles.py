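"""Point-pattern segregation statistics and the particle mixing index."""

import numpy as np
import pytest

from micromix import (
    ParticleSet,
    PNNDistribution,
    SegregationSummary,
    default_XR,
    index_of_dispersion,
    index_of_dispersion_quadrat,
    max_striation_thickness,
    mixing_index_particles,
    pnn,
    quadrant_cov,
    sigma_fpp,
    spatial_resolution_SR,
    summarize,
)

from conftest import brute_force_pnn


def make_set(points, width=10.0, height=10.0):
    return ParticleSet(np.asarray(points, dtype=float), width=width, height=height)


class TestQuadrantCov:
    def test_perfectly_even_counts(self):
        ps = make_set([(2.5, 2.5), (7.5, 2.5), (2.5, 7.5), (7.5, 7.5)])
        assert quadrant_cov(ps, 2, 2) == pytest.approx(0.0)

    def test_all_in_one_quadrant(self):
        ps = make_set([(1, 1), (2, 2), (3, 3), (4, 4)])
        assert quadrant_cov(ps, 2, 2) == pytest.approx(2.0)

    def test_half_occupied(self):
        ps = make_set([(1, 1), (3, 3), (6, 1), (8, 3)])  # two left-top, two right-top
        assert quadrant_cov(ps, 2, 2) == pytest.approx(2 / np.sqrt(3))

    def test_matches_brute_force_on_random_patterns(self, rng):
        for _ in range(10):
            pts = rng.random((60, 2)) * [40, 30]
            ps = ParticleSet(pts, width=40, height=30)
            m, n = 3, 4
            # brute force: explicit rectangle membership per quadrant
            qw, qh = 40 / n, 30 / m
            conc = []
            for i in range(m):
                for j in range(n):
                    inside = (
                        (pts[:, 0] >= j * qw)
                        & (pts[:, 0] < (j + 1) * qw)
                        & (pts[:, 1] >= i * qh)
                        & (pts[:, 1] < (i + 1) * qh)
                    )
                    conc.append(inside.sum() / (qw * qh))
            conc = np.array(conc)
            c_mean = 60 / (40 * 30)
            expected = np.sqrt(((conc - c_mean) ** 2).sum() / (m * n - 1)) / c_mean
            assert quadrant_cov(ps, m, n) == pytest.approx(expected, abs=1e-10)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            quadrant_cov(make_set(np.empty((0, 2))), 2, 2)


class TestPNN:
    def test_unit_square_corners(self):
        d = pnn(make_set([(0, 0), (1, 0), (0, 1), (1, 1)], 2, 2))
        np.testing.assert_allclose(d.distances, 1.0)

    def test_collinear_points(self):
        d = pnn(make_set([(0, 0), (0, 3), (0, 4)], 5, 5))
        assert sorted(d.distances) == pytest.approx([1, 1, 3])

    def test_coincident_points_warn(self):
        with pytest.warns(UserWarning):
            d = pnn(make_set([(1, 1), (1, 1)], 2, 2))
        np.testing.assert_allclose(d.distances, 0.0)

    def test_single_particle_rejected(self):
        with pytest.raises(ValueError):
            pnn(make_set([(1, 1)], 2, 2))

    def test_matches_all_pairs_oracle(self, rng):
        for n in (5, 50, 300):
            pts = rng.random((n, 2)) * 100
            d = pnn(ParticleSet(pts, 100, 100))
            np.testing.assert_allclose(d.distances, brute_force_pnn(pts), atol=1e-10)

    def test_rigid_motion_invariance_and_dilation(self, rng):
        pts = rng.random((40, 2)) * 50 + 20
        base = pnn(ParticleSet(pts, 200, 200)).distances
        shifted = pnn(ParticleSet(pts + [30, 40], 200, 200)).distances
        np.testing.assert_allclose(np.sort(shifted), np.sort(base), atol=1e-9)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = pts @ rot.T
        rotated -= rotated.min(axis=0)
        np.testing.assert_allclose(
            np.sort(pnn(ParticleSet(rotated, 200, 200)).distances),
            np.sort(base),
            atol=1e-9,
        )
        dilated = pnn(ParticleSet(pts * 1.7, 200, 200)).distances
        np.testing.assert_allclose(np.sort(dilated), 1.7 * np.sort(base), atol=1e-9)


class TestSigmaFpp:
    def test_clipped_deviation(self):
        d = PNNDistribution(np.array([5.0, 10.0, 20.0]))
        assert sigma_fpp(d, 10.0) == pytest.approx(np.sqrt(50), abs=1e-9)

    def test_fully_clipped_is_zero(self):
        d = PNNDistribution(np.array([1.0, 2.0, 3.0]))
        assert sigma_fpp(d, 5.0) == 0.0

    def test_grid_perfect_is_zero(self):
        d = PNNDistribution(np.full(9, 4.0))
        assert sigma_fpp(d, 4.0) == 0.0

    def test_nonpositive_xr_rejected(self):
        with pytest.raises(ValueError):
            sigma_fpp(PNNDistribution(np.array([1.0, 2.0])), 0.0)


class TestDefaultXR:
    def test_uniform_grid_spacing(self):
        ps = ParticleSet(np.random.default_rng(0).random((100, 2)) * 100, 100, 100)
        assert default_XR(ps) == pytest.approx(10.0)

    def test_single_particle_unit_square(self):
        assert default_XR(make_set([(0.5, 0.5)], 1, 1)) == pytest.approx(1.0)

    def test_area_scaling_law(self):
        ps1 = make_set([(1, 1), (2, 2)], 10, 10)
        ps2 = make_set([(1, 1), (2, 2)], 20, 10)
        assert default_XR(ps2) == pytest.approx(np.sqrt(2) * default_XR(ps1))


class TestIndexOfDispersion:
    def test_lattice_has_zero_dispersion(self):
        assert index_of_dispersion(PNNDistribution(np.full(5, 2.0))) == 0.0

    def test_population_variance_over_mean(self):
        d = PNNDistribution(np.array([3.0, 1.0, 1.0]))
        assert index_of_dispersion(d) == pytest.approx(8 / 15, abs=1e-9)

    def test_all_coincident_rejected(self):
        with pytest.warns(UserWarning):
            d = pnn(make_set([(1, 1), (1, 1)], 2, 2))
        with pytest.raises(ValueError):
            index_of_dispersion(d)

    def test_quadrat_variant_near_one_for_csr(self, rng):
        # classical dimensionless index: ~1 under complete spatial randomness
        vals = []
        for _ in range(30):
            pts = rng.random((400, 2)) * 200
            vals.append(index_of_dispersion_quadrat(ParticleSet(pts, 200, 200), 5, 5))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)


class TestMaxStriationThickness:
    def test_single_occupied_bin(self):
        ps = make_set([(4.2, 1), (4.7, 5), (4.3, 9)], 100, 10)
        assert max_striation_thickness(ps, bin_px=1) == 1.0

    def test_full_band(self):
        pts = [(x + 0.5, 1.0) for x in range(100)]
        ps = ParticleSet(np.array(pts), 100, 10)
        assert max_striation_thickness(ps, bin_px=1) == 100.0

    def test_longest_run(self):
        xs = list(range(10)) + list(range(20, 25))
        ps = ParticleSet(np.array([(x + 0.5, 1.0) for x in xs]), 100, 10)
        assert max_striation_thickness(ps, bin_px=1) == 10.0

    def test_along_flow_axis(self):
        ps = make_set([(1, 2.5), (5, 3.5), (9, 4.5)], 10, 10)
        assert max_striation_thickness(ps, axis="along_flow", bin_px=1) == 3.0

    def test_min_count_threshold(self):
        ps = make_set([(1.5, 1), (1.6, 2), (3.5, 3)], 10, 10)
        assert max_striation_thickness(ps, bin_px=1, min_count=2) == 1.0


class TestSpatialResolution:
    def test_unit_square_corners(self):
        assert spatial_resolution_SR(pnn(make_set([(0, 0), (1, 0), (0, 1), (1, 1)], 2, 2))) == pytest.approx(1.0)

    def test_arithmetic_mean(self):
        assert spatial_resolution_SR(PNNDistribution(np.array([3.0, 1.0, 1.0]))) == pytest.approx(5 / 3)

    def test_homogeneous_under_dilation(self, rng):
        pts = rng.random((30, 2)) * 50
        sr1 = spatial_resolution_SR(pnn(ParticleSet(pts, 100, 100)))
        sr2 = spatial_resolution_SR(pnn(ParticleSet(pts * 2, 100, 100)))
        assert sr2 == pytest.approx(2 * sr1, rel=1e-9)


class TestMixingIndex:
    def test_self_reference_is_zero(self):
        s = SegregationSummary(idisp=529.6032, sr=64.2695, sigma_fpp=356.1561)
        assert mixing_index_particles(s, s).mp == 0.0

    def test_ratios_reported(self):
        ref = SegregationSummary(idisp=2.0, sr=4.0, sigma_fpp=8.0)
        cur = SegregationSummary(idisp=1.0, sr=1.0, sigma_fpp=2.0)
        r = mixing_index_particles(cur, ref)
        assert r.ratios == pytest.approx((0.5, 0.25, 0.25))
        assert r.mp == pytest.approx(1 - (0.5 + 0.25 + 0.25) / 3)

    def test_strictly_increases_as_components_shrink(self):
        ref = SegregationSummary(idisp=10.0, sr=10.0, sigma_fpp=10.0)
        previous = mixing_index_particles(ref, ref).mp
        for scale in (0.8, 0.5, 0.2, 0.05):
            cur = SegregationSummary(idisp=10 * scale, sr=10 * scale, sigma_fpp=10 * scale)
            mp = mixing_index_particles(cur, ref).mp
            assert mp > previous
            previous = mp

    def test_negative_when_segregation_worsens(self):
        ref = SegregationSummary(idisp=1.0, sr=1.0, sigma_fpp=1.0)
        cur = SegregationSummary(idisp=2.0, sr=2.0, sigma_fpp=2.0)
        assert mixing_index_particles(cur, ref).mp == pytest.approx(-1.0)

    def test_nonpositive_reference_rejected(self):
        ref = SegregationSummary(idisp=0.0, sr=1.0, sigma_fpp=1.0)
        cur = SegregationSummary(idisp=1.0, sr=1.0, sigma_fpp=1.0)
        with pytest.raises(ValueError):
            mixing_index_particles(cur, ref)


class TestSummarize:
    def test_summary_fields_are_consistent(self, rng):
        pts = rng.random((80, 2)) * [64, 64]
        ps = ParticleSet(pts, 64, 64)
        s = summarize(ps, grid=(4, 4))
        d = pnn(ps)
        assert s.count == 80
        assert s.idisp == pytest.approx(index_of_dispersion(d))
        assert s.sr == pytest.approx(spatial_resolution_SR(d))
        assert s.sigma_fpp == pytest.approx(sigma_fpp(d, default_XR(ps)))
        assert s.cov == pytest.approx(quadrant_cov(ps, 4, 4))
        assert s.mst == max_striation_thickness(ps)

    def test_xr_min_policy_reproduces_literal_reading(self, rng):
        pts = rng.random((50, 2)) * 100
        ps = ParticleSet(pts, 100, 100)
        d = pnn(ps)
        s = summarize(ps, xr="min")
        assert s.sigma_fpp == pytest.approx(sigma_fpp(d, float(d.distances.min())))

    def test_sigma_fpp_grows_with_jitter_from_grid(self):
        # grid -> CSR sweep: clipped deviation rises with jitter amplitude
        from micromix import PatternSpec, gen_points

        amplitudes = [0.0, 2.0, 5.0, 10.0, 20.0]
        means = []
        for amp in amplitudes:
            vals = []
            for seed in range(50):
                spec = PatternSpec(kind="grid", width=300, height=300, count=225, jitter=amp)
                ps = gen_points(spec, seed=seed)
                vals.append(summarize(ps).sigma_fpp)
            means.append(np.mean(vals))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
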
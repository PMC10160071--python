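import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from ramantda import (
    RamanSpectrum,
    brute_force_pd,
    diagrams_close,
    embed_spectrum,
    vietoris_rips_pd,
)

from conftest import random_cloud


class TestEmbedSpectrum:
    def test_cardinality_preserved(self, small_spectrum):
        cloud = embed_spectrum(small_spectrum)
        assert cloud.shape == (len(small_spectrum), 2)
        assert np.array_equal(cloud[:, 0], small_spectrum.wavenumbers)

    def test_index_mode_uses_sample_index(self):
        s = RamanSpectrum(np.array([400.0, 401.0, 402.0]), np.array([5.0, 6.0, 7.0]))
        cloud = embed_spectrum(s, mode="index_intensity")
        assert cloud[:, 0].tolist() == [0.0, 1.0, 2.0]

    def test_normalize_min_max_scales_each_axis(self):
        s = RamanSpectrum(np.array([400.0, 500.0, 600.0]), np.array([0.0, 5.0, 10.0]))
        cloud = embed_spectrum(s, normalize=True)
        assert cloud[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert cloud[:, 1].tolist() == [0.0, 0.5, 1.0]

    def test_unknown_mode(self, small_spectrum):
        with pytest.raises(ValueError):
            embed_spectrum(small_spectrum, mode="polar")


class TestVietorisRips:
    def test_single_point(self):
        d = vietoris_rips_pd(np.array([[0.3, 0.7]]))
        assert len(d.h0) == 0 and d.n_essential_h0 == 1
        assert len(d.h1) == 0

    def test_collinear_points_h0_are_gap_lengths(self):
        d = vietoris_rips_pd(np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]))
        assert np.allclose(np.sort(d.h0[:, 1]), [1.0, 2.0])
        assert np.allclose(d.h0[:, 0], 0.0)
        assert d.n_essential_h0 == 1
        assert len(d.h1) == 0

    def test_unit_square_single_loop(self):
        d = vietoris_rips_pd(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))
        assert d.h1.shape == (1, 2)
        assert np.allclose(d.h1[0], [1.0, np.sqrt(2.0)])

    def test_equilateral_triangle_has_no_loop(self):
        s = 2.0
        pts = np.array([[0.0, 0.0], [s, 0.0], [s / 2, s * np.sqrt(3) / 2]])
        d = vietoris_rips_pd(pts)
        assert len(d.h1) == 0

    def test_coincident_points_merge_at_zero(self):
        d = vietoris_rips_pd(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert np.allclose(d.h0, [[0.0, 0.0]])

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            vietoris_rips_pd(np.array([[0.0, np.inf]]))

    def test_h0_bar_count_equals_point_count(self, rng):
        for n in (2, 5, 9, 40):
            cloud = random_cloud(rng, n)
            d = vietoris_rips_pd(cloud)
            assert len(d.h0) + d.n_essential_h0 == n

    def test_h0_deaths_are_mst_edge_lengths(self, rng):
        # independent check via scipy's sparse-graph MST
        for _ in range(5):
            cloud = random_cloud(rng, 25)
            d = vietoris_rips_pd(cloud)
            mst = minimum_spanning_tree(squareform(pdist(cloud))).toarray()
            ref = np.sort(mst[mst > 0])
            assert np.allclose(np.sort(d.h0[:, 1]), ref, atol=1e-12)

    def test_translation_invariance(self, rng):
        cloud = random_cloud(rng, 15)
        a = vietoris_rips_pd(cloud)
        b = vietoris_rips_pd(cloud + np.array([13.0, -4.5]))
        assert diagrams_close(a, b, tol=1e-9)

    def test_scale_equivariance(self, rng):
        cloud = random_cloud(rng, 15)
        c = 3.7
        a = vietoris_rips_pd(cloud)
        b = vietoris_rips_pd(c * cloud)
        for dim in (0, 1):
            assert np.allclose(
                np.sort(b.intervals(dim), axis=0),
                c * np.sort(a.intervals(dim), axis=0),
                atol=1e-9,
            )


class TestBruteForceOracle:
    def test_size_limit(self, rng):
        with pytest.raises(ValueError, match="12"):
            brute_force_pd(random_cloud(rng, 13))

    def test_matches_main_implementation_on_random_clouds(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 11))
            cloud = random_cloud(rng, n)
            assert diagrams_close(vietoris_rips_pd(cloud), brute_force_pd(cloud), tol=1e-9)

    def test_agrees_on_shaped_clouds(self):
        square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        ring = np.column_stack([
            np.cos(np.linspace(0, 2 * np.pi, 9, endpoint=False)),
            np.sin(np.linspace(0, 2 * np.pi, 9, endpoint=False)),
        ])
        for cloud in (square, ring):
            assert diagrams_close(vietoris_rips_pd(cloud), brute_force_pd(cloud))

    def test_ring_has_one_dominant_loop(self):
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        d = brute_force_pd(np.column_stack([np.cos(theta), np.sin(theta)]))
        assert len(d.h1) >= 1
        # the dominant loop dies at the filling scale, near the diameter
        assert d.h1[:, 1].max() > 1.5
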
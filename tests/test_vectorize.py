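import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramantda import (
    PersistenceDiagram,
    VectorizationConfig,
    betti_curve,
    fit_value_range,
    persistence_image,
    persistence_landscape,
    persistence_silhouette,
    vectorize,
)

from conftest import toy_diagram


def intervals_strategy():
    pair = st.tuples(st.floats(0, 5), st.floats(0.01, 5)).map(
        lambda bd: (bd[0], bd[0] + bd[1])
    )
    return st.lists(pair, min_size=1, max_size=12).map(np.asarray)


class TestBettiCurve:
    def test_counts_covering_intervals(self):
        # grid over [0, 2] with n=5 hits t = 0, 0.5, 1, 1.5, 2
        out = betti_curve([(0, 1), (0, 2)], 5, (0, 2))
        assert out.tolist() == [2, 2, 1, 1, 0]

    def test_half_open_convention(self):
        out = betti_curve([(0, 2)], 5, (0, 2))
        assert out.tolist() == [1, 1, 1, 1, 0]

    def test_empty_diagram(self):
        assert betti_curve(np.empty((0, 2)), 7, (0, 1)).tolist() == [0] * 7

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            betti_curve([(0, 1)], 5, (1, 1))

    @settings(max_examples=40, deadline=None)
    @given(intervals_strategy())
    def test_entries_nonnegative_integers(self, intervals):
        out = betti_curve(intervals, 30, (0, 11))
        assert np.all(out >= 0)
        assert np.allclose(out, np.round(out))

    @settings(max_examples=30, deadline=None)
    @given(intervals_strategy(), intervals_strategy())
    def test_additive_over_diagram_union(self, a, b):
        rng_ = (0, 11)
        combined = betti_curve(np.vstack([a, b]), 40, rng_)
        assert np.allclose(combined, betti_curve(a, 40, rng_) + betti_curve(b, 40, rng_))


class TestLandscape:
    def test_single_tent(self):
        # grid over [0, 2], n=5: lambda_1 = (0, .5, 1, .5, 0); lambda_2 = 0
        out = persistence_landscape([(0, 2)], 5, 2, (0, 2))
        assert np.allclose(out[:5], [0, 0.5, 1.0, 0.5, 0])
        assert np.allclose(out[5:], 0.0)

    def test_second_landscape_from_overlap(self):
        # t = 1.5 is index 3 on the n=7 grid over [0, 3]
        out = persistence_landscape([(0, 2), (1, 3)], 7, 2, (0, 3))
        lam2 = out[7:]
        assert lam2[3] == pytest.approx(0.5)

    def test_empty_diagram(self):
        out = persistence_landscape(np.empty((0, 2)), 4, 3, (0, 1))
        assert out.shape == (12,)
        assert np.all(out == 0)

    @settings(max_examples=40, deadline=None)
    @given(intervals_strategy())
    def test_landscapes_pointwise_ordered(self, intervals):
        k, n = 4, 25
        out = persistence_landscape(intervals, n, k, (0, 11)).reshape(k, n)
        for j in range(k - 1):
            assert np.all(out[j] >= out[j + 1] - 1e-12)


class TestSilhouette:
    def test_single_interval_is_its_tent(self):
        for p in (0.5, 1.0, 3.0):
            out = persistence_silhouette([(0, 2)], 5, p, (0, 2))
            assert np.allclose(out, [0, 0.5, 1.0, 0.5, 0])

    def test_weighted_average_of_two_tents(self):
        # weights (2/3, 1/3) at p=1; at t=1 the tents give (1, 0)
        out = persistence_silhouette([(0, 2), (0, 1)], 5, 1.0, (0, 2))
        assert out[2] == pytest.approx(2.0 / 3.0)

    def test_zero_persistence_only_gives_zero_vector(self):
        out = persistence_silhouette([(1, 1), (2, 2)], 6, 1.0, (0, 3))
        assert np.all(out == 0)

    def test_large_power_approaches_dominant_tent(self):
        intervals = [(0, 4), (1, 2)]
        out = persistence_silhouette(intervals, 9, 8.0, (0, 4))
        dominant = persistence_silhouette([(0, 4)], 9, 1.0, (0, 4))
        assert np.allclose(out, dominant, atol=0.01)


class TestPersistenceImage:
    def test_empty_diagram(self):
        out = persistence_image(np.empty((0, 2)), 1.0, 5, (0, 1), (0, 1))
        assert np.all(out == 0)

    def test_argmax_pixel_contains_the_point(self):
        # (b, p) = (0, 2); 5x5 grid over b in [-1, 1], p in [1, 3]
        out = persistence_image([(0, 2)], 0.3, 5, (-1, 1), (1, 3)).reshape(5, 5)
        i, j = np.unravel_index(np.argmax(out), out.shape)
        assert j == 2  # birth 0 falls in the middle birth column
        assert i == 2  # persistence 2 falls in the middle persistence row

    def test_unit_mass_within_tolerance(self):
        # grid extends >= 4 sigma beyond the point, pixels smaller than sigma
        sigma = 0.5
        out = persistence_image([(0, 2)], sigma, 25, (-2.5, 2.5), (0, 4.5))
        # weight is persistence / fitted max = 2 / 4.5
        assert out.sum() == pytest.approx(2 / 4.5, abs=1e-3)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            persistence_image([(0, 1)], 0.0, 5, (0, 1), (0, 1))


class TestVectorizeAndFit:
    def test_unfitted_config_is_state_error(self):
        with pytest.raises(RuntimeError, match="fit"):
            vectorize(toy_diagram([1.0]), VectorizationConfig("BC", fusion="H0"))

    def test_fit_range_is_min_birth_max_death(self):
        d1 = toy_diagram([1.0])
        d2 = PersistenceDiagram(np.array([[2.0, 5.0]]), np.empty((0, 2)))
        cfg = fit_value_range([d1, d2], VectorizationConfig("BC", fusion="H0"))
        assert cfg.value_range == ((0.0, 5.0),)

    def test_empty_h1_block_vectorizes_to_zeros(self):
        train = toy_diagram([1.0], h1=[(0.5, 1.5)])
        cfg = fit_value_range([train], VectorizationConfig("BC", resolution=10, fusion="H1"))
        d = toy_diagram([1.0, 2.0])  # no loops
        assert np.all(vectorize(d, cfg).values == 0)

    def test_concat_doubles_length_and_fused_pools(self):
        d = toy_diagram([1.0, 2.0], h1=[(0.5, 1.5)])
        for method in ("BC", "PL", "PS", "PI"):
            c_h0 = fit_value_range([d], VectorizationConfig(method, resolution=5, fusion="H0"))
            c_cat = fit_value_range([d], VectorizationConfig(method, resolution=5, fusion="concat"))
            assert len(vectorize(d, c_cat)) == 2 * len(vectorize(d, c_h0))

    def test_fused_equals_h0_when_h1_empty(self):
        d = toy_diagram([1.0, 3.0])
        for method in ("BC", "PL", "PS", "PI"):
            ch0 = fit_value_range([d], VectorizationConfig(method, resolution=6, fusion="H0"))
            cfu = fit_value_range([d], VectorizationConfig(method, resolution=6, fusion="fused"))
            assert np.allclose(vectorize(d, ch0).values, vectorize(d, cfu).values)

    def test_out_of_range_test_diagram_is_clipped_not_an_error(self):
        train = toy_diagram([1.0])
        cfg = fit_value_range([train], VectorizationConfig("BC", resolution=8, fusion="H0"))
        wild = toy_diagram([50.0])
        out = vectorize(wild, cfg)
        assert np.all(np.isfinite(out.values))

    def test_fit_needs_some_interval_somewhere(self):
        empty = PersistenceDiagram(np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(ValueError, match="no finite intervals"):
            fit_value_range([empty], VectorizationConfig("BC", fusion="concat"))

    def test_permutation_invariance(self, rng):
        iv = np.column_stack([rng.uniform(0, 2, 8), rng.uniform(2, 4, 8)])
        d1 = PersistenceDiagram(iv, np.empty((0, 2)))
        d2 = PersistenceDiagram(iv[::-1].copy(), np.empty((0, 2)))
        for method in ("BC", "PL", "PS", "PI"):
            cfg = fit_value_range([d1], VectorizationConfig(method, resolution=7, fusion="H0"))
            assert np.allclose(vectorize(d1, cfg).values, vectorize(d2, cfg).values)

    @pytest.mark.parametrize("fusion,blocks", [("H0", 1), ("H1", 1), ("fused", 1), ("concat", 2)])
    def test_vector_lengths_across_grid(self, fusion, blocks):
        d = toy_diagram([1.0, 2.0], h1=[(0.5, 1.5)])
        k = 5
        for method, n in (("PI", 10), ("PL", 25), ("PS", 50), ("BC", 100)):
            cfg = fit_value_range(
                [d], VectorizationConfig(method, resolution=n, landscape_count=k, fusion=fusion)
            )
            expected_block = n * n if method == "PI" else (k * n if method == "PL" else n)
            assert len(vectorize(d, cfg)) == blocks * expected_block
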
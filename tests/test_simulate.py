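"""Unit and property tests for the AB-graph simulator."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scdetect.simulate import (
    ABGraph,
    GraphSpec,
    InvalidSpecError,
    apply_effect,
    apply_offset,
    apply_trend,
    generate_series,
    generate_test_dataset,
    generate_training_dataset,
)
from .conftest import StubRng

TAN30 = np.tan(np.deg2rad(30))


class TestGenerateSeries:
    def test_zero_noise_stable_is_flat_ten(self):
        spec = GraphSpec(n_a=3, n_b=5, autocorr=0.0, trend_deg=0, var_level="stable", smd=0)
        g = generate_series(spec, StubRng(np.zeros(8)))
        assert np.allclose(g.values, 10.0)
        assert g.label == 0

    def test_ar_recurrence_hand_computed(self):
        # x_t = 0.2 x_{t-1} + e_t with e = (1, 1, 1) -> (1, 1.2, 1.24)
        spec = GraphSpec(n_a=2, n_b=1, autocorr=0.2, var_level="stable")
        g = generate_series(spec, StubRng([1.0, 1.0, 1.0]))
        assert np.allclose(g.values - 10.0, [1.0, 1.2, 1.24])

    def test_zero_noise_effect_raises_phase_b_only(self):
        spec = GraphSpec(n_a=3, n_b=5, smd=3, var_level="stable")
        g = generate_series(spec, StubRng(np.zeros(8)))
        assert np.allclose(g.phase_a, 10.0)
        assert np.allclose(g.phase_b, 13.0)
        assert g.label == 1

    def test_invalid_phase_lengths_rejected(self):
        with pytest.raises(InvalidSpecError):
            GraphSpec(n_a=0, n_b=5)
        with pytest.raises(InvalidSpecError):
            GraphSpec(n_a=3, n_b=-1)

    def test_label_matches_smd(self):
        assert GraphSpec(n_a=3, n_b=5, smd=0).label == 0
        assert GraphSpec(n_a=3, n_b=5, smd=2).label == 1


class TestApplyTrend:
    def test_thirty_degrees_on_zero_series(self):
        out = apply_trend(np.zeros(5), 30)
        expected = TAN30 * (np.arange(5) - 2.0)
        assert np.allclose(out, expected)
        assert np.allclose(out, [-1.1547, -0.5774, 0, 0.5774, 1.1547], atol=1e-4)

    def test_zero_degrees_is_identity(self, rng):
        v = rng.standard_normal(8)
        assert np.array_equal(apply_trend(v, 0), v)

    def test_consecutive_increment_is_point_58(self):
        out = apply_trend(np.zeros(10), 30)
        diffs = np.diff(out)
        assert np.allclose(diffs, diffs[0])
        assert round(float(diffs[0]), 2) == 0.58

    @pytest.mark.parametrize("n", [5, 8, 13])
    def test_pivot_point_unchanged(self, rng, n):
        v = rng.standard_normal(n)
        out = apply_trend(v, 30)
        if n % 2:
            assert out[(n - 1) // 2] == v[(n - 1) // 2]
        else:
            # fractional pivot: the interpolated midpoint is invariant
            mid_in = (v[n // 2 - 1] + v[n // 2]) / 2
            mid_out = (out[n // 2 - 1] + out[n // 2]) / 2
            assert mid_out == pytest.approx(mid_in)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidSpecError):
            apply_trend(np.zeros(1), 30)


class TestApplyOffsetAndEffect:
    def test_offsets_match_variability_constants(self):
        assert np.allclose(apply_offset(np.zeros(4), "stable"), 10.0)
        assert np.allclose(apply_offset(np.zeros(4), "variable"), 4.0)

    def test_variability_coefficients(self):
        # unit-SD series shifted to mean 10 or 4 -> SD/mean of 0.10 / 0.25
        assert 1 / apply_offset(np.zeros(1), "stable")[0] == pytest.approx(0.10)
        assert 1 / apply_offset(np.zeros(1), "variable")[0] == pytest.approx(0.25)

    def test_unknown_level_rejected(self):
        with pytest.raises(InvalidSpecError):
            apply_offset(np.zeros(4), "wiggly")

    def test_effect_added_to_phase_b_only(self):
        out = apply_effect(np.zeros(8), 3, 2)
        assert np.array_equal(out, [0, 0, 0, 2, 2, 2, 2, 2])

    def test_zero_effect_is_identity(self, rng):
        v = rng.standard_normal(8)
        assert np.array_equal(apply_effect(v, 3, 0), v)

    def test_bad_phase_boundary_rejected(self):
        with pytest.raises(InvalidSpecError):
            apply_effect(np.zeros(5), 5, 1)
        with pytest.raises(InvalidSpecError):
            apply_effect(np.zeros(5), 0, 1)


class TestDatasetComposition:
    @pytest.mark.parametrize("seed", [0, 91])
    def test_test_scheme_counts(self, seed):
        manifest = generate_test_dataset(seed)
        assert len(manifest) == 1024
        smds = collections.Counter(g.spec.smd for g in manifest)
        assert smds[0] == 384
        assert all(smds[s] == 128 for s in range(1, 6))
        for attr, levels in [
            ("n_a", (3, 5)),
            ("n_b", (5, 10)),
            ("autocorr", (0.0, 0.2)),
            ("trend_deg", (0, 30)),
            ("var_level", ("stable", "variable")),
        ]:
            counts = collections.Counter(getattr(g.spec, attr) for g in manifest)
            assert all(counts[lev] == 512 for lev in levels), attr

    def test_training_scheme_small_total_brute_force(self):
        manifest = generate_training_dataset(5, total=320)
        assert len(manifest) == 320
        labels = manifest.labels
        assert labels.sum() == 160
        cells = collections.Counter(
            (g.spec.n_a, g.spec.n_b, g.spec.autocorr, g.spec.trend_deg,
             g.spec.var_level, g.spec.smd)
            for g in manifest
        )
        # 32 combos x smd 0 -> 5 each; 32 combos x smd 1..5 -> 1 each
        for cell, count in cells.items():
            assert count == (5 if cell[-1] == 0 else 1)

    def test_non_divisible_total_suggests_valid_size(self):
        with pytest.raises(InvalidSpecError, match="320"):
            generate_training_dataset(0, total=1000)

    def test_same_seed_reproduces_bit_identical_manifest(self):
        m1 = generate_test_dataset(42)
        m2 = generate_test_dataset(42)
        assert all(np.array_equal(a.values, b.values) for a, b in zip(m1, m2))
        assert [g.spec for g in m1] == [g.spec for g in m2]

    def test_different_seeds_differ(self):
        m1 = generate_test_dataset(1)
        m2 = generate_test_dataset(2)
        assert not all(np.array_equal(a.values, b.values) for a, b in zip(m1, m2))


class TestNoiseDistribution:
    def test_unit_normal_coverage_at_one_and_two_sd(self, rng):
        # no autocorrelation, no trend, no effect: points are N(level, 1)
        spec = GraphSpec(n_a=5, n_b=10, var_level="stable")
        points = np.concatenate(
            [generate_series(spec, rng).values for _ in range(8000)]
        )
        dev = np.abs(points - 10.0)
        assert (dev < 1).mean() == pytest.approx(0.6827, abs=0.01)
        assert (dev < 2).mean() == pytest.approx(0.9545, abs=0.01)


@settings(max_examples=30, deadline=None)
@given(
    n=st.integers(min_value=2, max_value=30),
    degrees=st.floats(min_value=1, max_value=60),
    data=st.lists(st.floats(-50, 50), min_size=30, max_size=30),
)
def test_trend_adds_constant_consecutive_difference(n, degrees, data):
    v = np.array(data[:n])
    out = apply_trend(v, degrees)
    added = np.diff(out) - np.diff(v)
    assert np.allclose(added, np.tan(np.deg2rad(degrees)), atol=1e-9)


def test_graph_length_invariant():
    with pytest.raises(InvalidSpecError):
        ABGraph(values=np.zeros(7), spec=GraphSpec(n_a=3, n_b=5))
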
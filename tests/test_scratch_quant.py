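"""Wound-healing quantification: structure maps, thresholds, rates."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_structure_map
from conftest import make_structure_map
from motilitykit import scratch
from motilitykit.errors import (
    BimodalityNotFound,
    InputError,
    InsufficientDataError,
    NormalizationError,
)
from motilitykit.scratch import (
    ScratchSeries,
    compute_structure_map,
    estimate_migration_rate,
    fit_structure_threshold,
    normalize_rates,
    quantify_stack,
    scratch_fraction,
)
from motilitykit.synthetic import ScratchSimParams, synthesize_scratch_timelapse


class TestStructureMap:
    def test_constant_frame_is_all_zero(self):
        smap = compute_structure_map(np.full((80, 80), 7.0), window=20, stride=4)
        assert np.all(smap.values == 0.0)

    def test_grid_arithmetic_default_window(self):
        smap = compute_structure_map(np.zeros((100, 100)), window=50, stride=5)
        assert smap.values.shape == (11, 11)

    def test_matches_brute_force_oracle(self, rng):
        frame = rng.uniform(0, 255, size=(200, 200))
        smap = compute_structure_map(frame, window=50, stride=5)
        oracle = brute_force_structure_map(frame, 50, 5)
        np.testing.assert_allclose(smap.values, oracle, rtol=1e-9)

    def test_matches_oracle_on_odd_geometry(self, rng):
        frame = rng.normal(120, 30, size=(73, 131))
        smap = compute_structure_map(frame, window=17, stride=3)
        oracle = brute_force_structure_map(frame, 17, 3)
        assert smap.values.shape == oracle.shape
        np.testing.assert_allclose(smap.values, oracle, rtol=1e-9, atol=1e-12)

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(InputError):
            compute_structure_map(np.zeros((40, 40)), window=50)

    def test_single_pixel_window_rejected(self):
        with pytest.raises(InputError):
            compute_structure_map(np.zeros((40, 40)), window=1)


class TestThreshold:
    @staticmethod
    def _bimodal_values(rng, m1=2.0, m2=30.0, sd=1.0, n=4000):
        return np.concatenate([
            np.abs(rng.normal(m1, sd, n // 2)),
            rng.normal(m2, sd, n - n // 2),
        ])

    def test_midpoint_of_well_separated_modes(self, rng):
        values = self._bimodal_values(rng)
        model = fit_structure_threshold(make_structure_map(values))
        bin_width = model.bin_edges[1] - model.bin_edges[0]
        assert model.threshold == pytest.approx(16.0, abs=2 * bin_width)
        assert model.peak_low < model.threshold < model.peak_high

    def test_mode_midpoint_recovery_monte_carlo(self, rng):
        """Fitted threshold lands within 2 bin widths of (m1+m2)/2 for >=95% of
        random well-separated mode pairs."""
        hits = 0
        n_trials = 50
        for _ in range(n_trials):
            m1 = rng.uniform(2, 8)
            m2 = rng.uniform(20, 40)
            values = self._bimodal_values(rng, m1=m1, m2=m2)
            model = fit_structure_threshold(make_structure_map(values))
            bin_width = model.bin_edges[1] - model.bin_edges[0]
            if abs(model.threshold - (m1 + m2) / 2) <= 2 * bin_width:
                hits += 1
        assert hits >= 0.95 * n_trials

    def test_unimodal_input_raises(self, rng):
        values = rng.normal(20, 1.0, 4000)
        with pytest.raises(BimodalityNotFound):
            fit_structure_threshold(make_structure_map(values))

    def test_constant_input_raises(self):
        with pytest.raises(BimodalityNotFound):
            fit_structure_threshold(make_structure_map(np.full(100, 4.0)))

    def test_shift_invariance_of_threshold(self, rng):
        """Adding a constant to every pixel leaves SDs, hence the threshold,
        unchanged."""
        frame = np.where(rng.random((120, 200)) < 0.5, 0, 1) * rng.normal(
            120, 30, (120, 200)
        )
        frame[:, 60:140] = rng.normal(120, 2, (120, 80))
        m1 = fit_structure_threshold(compute_structure_map(frame, 30, 5))
        m2 = fit_structure_threshold(compute_structure_map(frame + 37.0, 30, 5))
        assert m1.threshold == pytest.approx(m2.threshold, rel=1e-9)

    def test_intensity_scaling_scales_threshold(self, rng):
        frame = rng.normal(120, 30, (120, 200))
        frame[:, 60:140] = rng.normal(120, 2, (120, 80))
        m1 = fit_structure_threshold(compute_structure_map(frame, 30, 5))
        m2 = fit_structure_threshold(compute_structure_map(frame * 2.5, 30, 5))
        assert m2.threshold == pytest.approx(2.5 * m1.threshold, rel=1e-9)
        f1 = scratch_fraction(compute_structure_map(frame, 30, 5), m1.threshold)
        f2 = scratch_fraction(compute_structure_map(frame * 2.5, 30, 5), m2.threshold)
        assert f1 == f2


class TestScratchFraction:
    def test_everything_below(self):
        assert scratch_fraction(make_structure_map(np.zeros(20)), 5.0) == 1.0

    def test_counting(self):
        values = np.array([1.0, 1, 1, 9, 9, 9, 9, 9, 9, 9, 9, 9])
        assert scratch_fraction(make_structure_map(values), 5.0) == 0.25

    def test_matches_direct_enumeration(self, rng):
        values = rng.uniform(0, 50, size=(31, 41))
        thr = 17.3
        expected = sum(1 for v in values.ravel() if v < thr) / values.size
        assert scratch_fraction(make_structure_map(values), thr) == expected

    @given(thr_pair=st.tuples(st.floats(0.1, 50), st.floats(0.1, 50)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, thr_pair):
        values = np.random.default_rng(0).uniform(0, 50, 200)
        smap = make_structure_map(values)
        lo, hi = sorted(thr_pair)
        assert scratch_fraction(smap, lo) <= scratch_fraction(smap, hi)


class TestQuantifyStack:
    def test_constant_geometry_gives_flat_series(self):
        p = ScratchSimParams(image_width=400, image_height=200,
                             initial_scratch_width=150, closure_rate=0.0,
                             n_frames=10, seed=4)
        stack, _ = synthesize_scratch_timelapse(p)
        series, _ = quantify_stack(stack)
        assert series.fraction.std(ddof=1) <= 0.02

    def test_closed_scratch_reads_near_zero(self):
        # 150 px scratch at 50 px/h closes by t = 3 h (frame 6)
        p = ScratchSimParams(image_width=400, image_height=200,
                             initial_scratch_width=150, closure_rate=50.0,
                             n_frames=12, seed=4)
        stack, _ = synthesize_scratch_timelapse(p)
        series, _ = quantify_stack(stack)
        assert np.all(series.fraction[np.asarray(series.times) >= 3.5] <= 0.02)

    def test_first_frame_fraction_tracks_band_geometry(self):
        p = ScratchSimParams(seed=9, n_frames=2)
        stack, _ = synthesize_scratch_timelapse(p)
        series, _ = quantify_stack(stack)
        expected = p.initial_scratch_width / p.image_width
        assert series.fraction[0] == pytest.approx(expected, abs=0.05)

    def test_threshold_comes_from_first_frame_only(self, small_scratch_params):
        stack, _ = synthesize_scratch_timelapse(small_scratch_params)
        _, model = quantify_stack(stack)
        direct = fit_structure_threshold(compute_structure_map(stack.frames[0]))
        assert model.threshold == direct.threshold


class TestMigrationRate:
    @staticmethod
    def _line_series(intercept=0.30, slope=-0.01, t_max=24.0, dt=0.5):
        t = np.arange(0, t_max + dt / 2, dt)
        return ScratchSeries(times=t, fraction=intercept + slope * t)

    def test_exact_line_recovers_slope(self):
        fit = estimate_migration_rate(self._line_series())
        assert fit.rate == pytest.approx(0.01, rel=1e-12)
        assert fit.n_points == 13
        assert not fit.degenerate

    def test_constant_series_rate_zero(self):
        t = np.arange(0, 24.5, 0.5)
        with pytest.warns(UserWarning, match="closed"):
            fit = estimate_migration_rate(
                ScratchSeries(times=t, fraction=np.zeros_like(t))
            )
        assert fit.rate == pytest.approx(0.0, abs=1e-12)
        assert fit.degenerate

    def test_too_few_in_window_frames(self):
        series = ScratchSeries(times=np.array([0.0, 7.0, 20.0]),
                               fraction=np.array([0.3, 0.2, 0.1]))
        with pytest.raises(InsufficientDataError):
            estimate_migration_rate(series)

    def test_rate_recovery_on_simulated_wells(self):
        """Estimated rates track true closure rates and preserve their order."""
        from motilitykit.pipeline import quantify_simulated_well

        means = []
        for v in (10.0, 20.0):
            rates = [
                quantify_simulated_well(
                    ScratchSimParams(closure_rate=v, n_frames=27, seed=s)
                ).rate
                for s in range(3)
            ]
            true = v / 600
            assert abs(np.mean(rates) - true) / true <= 0.10
            means.append(np.mean(rates))
        assert means[0] < means[1]


class TestNormalizeRates:
    def test_simple_ratio(self):
        out = normalize_rates([0.01], [0.02, 0.02])
        assert out[0] == pytest.approx(0.5)

    def test_controls_self_normalize_to_mean_one(self, rng):
        controls = rng.uniform(0.01, 0.05, 8)
        assert normalize_rates(controls, controls).mean() == pytest.approx(1.0)

    def test_zero_mean_control_raises(self):
        with pytest.raises(NormalizationError):
            normalize_rates([0.01], [0.01, -0.01])

    def test_empty_controls_raise(self):
        with pytest.raises(InputError):
            normalize_rates([0.01], [])
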
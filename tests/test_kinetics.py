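"""ROI kinetics: trace extraction, filtering, normalization, rates, endpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paoximetry.exceptions import NormalizationError, StatisticsError, ValidationError
from paoximetry.kinetics import (
    PDTTimeline,
    RateSummary,
    ROIMask,
    StO2Trace,
    compare_group_rates,
    detect_active_pdt_end,
    inverse_severinghaus,
    mean_depletion_rate,
    median_filter_trace,
    moving_slope,
    normalize_trace,
    roi_mean_trace,
    severinghaus_so2,
)
from paoximetry.unmixing import OximetryMaps


def timeline(**kw):
    base = dict(t_baseline_start=0.0, t_light_on=300.0, t_light_off=1200.0, t_end=1800.0)
    base.update(kw)
    return PDTTimeline(**base)


def _maps(sto2, mask, t):
    return OximetryMaps(
        sto2=np.where(mask, sto2, 0.0),
        hbt=np.where(mask, 1.0, 0.0),
        mask=mask,
        t=t,
    )


class TestRoiMeanTrace:
    def test_masked_pixels_do_not_dilute_mean(self):
        roi = ROIMask(np.ones((6, 6), bool))
        mask = np.ones((6, 6), bool)
        mask[:3] = False  # half the ROI is below the noise floor
        seq = [_maps(np.full((6, 6), 80.0), mask, t) for t in (0.0, 4.0)]
        trace = roi_mean_trace(seq, roi, timeline())
        # zeros excluded: the mean is 80, not 40
        assert np.allclose(trace.raw, 80.0)

    def test_uniform_region_with_dropouts(self):
        roi = ROIMask(np.ones((5, 5), bool))
        rng = np.random.default_rng(7)
        seq = [
            _maps(np.full((5, 5), 60.0), rng.random((5, 5)) > 0.3, float(t))
            for t in range(5)
        ]
        trace = roi_mean_trace(seq, roi, timeline())
        assert np.allclose(trace.raw, 60.0)

    def test_matches_brute_force_per_pixel_average(self, rng):
        roi = ROIMask(rng.random((10, 12)) > 0.4)
        seq = []
        for t in range(4):
            sto2 = rng.uniform(10, 90, (10, 12))
            mask = rng.random((10, 12)) > 0.25
            seq.append(_maps(sto2, mask, float(t)))
        trace = roi_mean_trace(seq, roi, timeline())
        for i, m in enumerate(seq):
            vals = [
                m.sto2[r, c]
                for r in range(10)
                for c in range(12)
                if roi.mask[r, c] and m.mask[r, c]
            ]
            assert trace.raw[i] == pytest.approx(np.mean(vals))

    def test_frame_without_valid_pixels_is_nan(self):
        roi = ROIMask(np.ones((3, 3), bool))
        seq = [_maps(np.full((3, 3), 50.0), np.zeros((3, 3), bool), 0.0)]
        trace = roi_mean_trace(seq, roi, timeline())
        assert np.isnan(trace.raw[0])


class TestMedianFilter:
    def test_constant_series_unchanged(self):
        v = np.full(40, 7.0)
        assert np.array_equal(median_filter_trace(v), v)

    def test_spike_removed(self):
        v = np.full(40, 5.0)
        v[20] = 500.0
        out = median_filter_trace(v, 15)
        assert np.allclose(out, 5.0)

    def test_matches_brute_force_truncated_windows(self, rng):
        v = rng.normal(size=60)
        out = median_filter_trace(v, 15)
        for i in range(60):
            win = v[max(0, i - 7) : i + 8]
            assert out[i] == pytest.approx(np.median(win))

    def test_even_order_rejected(self):
        with pytest.raises(ValidationError):
            median_filter_trace(np.zeros(30), 14)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=15, max_size=60), st.sampled_from([3, 7, 15]))
    def test_output_stays_within_window_extremes(self, values, order):
        v = np.asarray(values)
        out = median_filter_trace(v, order)
        half = order // 2
        for i in range(v.size):
            win = v[max(0, i - half) : i + half + 1]
            assert win.min() - 1e-12 <= out[i] <= win.max() + 1e-12


class TestNormalize:
    def test_scale_factor_from_baseline(self):
        t = np.arange(0, 600, 4.0)
        v = np.full_like(t, 50.0)
        v[t >= 300] = 25.0
        out = normalize_trace(v, t, timeline())
        assert np.allclose(out[t < 300], 100.0)
        assert np.allclose(out[t >= 300], 50.0)

    def test_identity_when_baseline_is_100(self):
        t = np.arange(0, 600, 4.0)
        v = np.full_like(t, 100.0)
        assert np.allclose(normalize_trace(v, t, timeline()), v)

    def test_empty_or_nonpositive_baseline_rejected(self):
        t = np.arange(300, 600, 4.0)  # starts after light-on
        with pytest.raises(NormalizationError):
            normalize_trace(np.full_like(t, 50.0), t, timeline())
        t = np.arange(0, 600, 4.0)
        with pytest.raises(NormalizationError):
            normalize_trace(np.zeros_like(t), t, timeline())


class TestMovingSlope:
    def test_affine_series_recovers_slope_everywhere(self):
        t = np.arange(0, 400, 4.0)
        v = 90.0 - 5.0 * t / 60.0  # -5 %/min
        slopes = moving_slope(v, t, window=15)
        assert np.allclose(slopes, -5.0)

    def test_constant_series_zero_slope(self):
        t = np.arange(0, 200, 4.0)
        assert np.allclose(moving_slope(np.full_like(t, 3.0), t, 15), 0.0)

    def test_matches_per_window_ols(self, rng):
        t = np.arange(0, 240, 4.0)
        v = rng.normal(size=t.size)
        slopes = moving_slope(v, t, window=15)
        for i in range(t.size):
            lo, hi = max(0, i - 7), min(t.size, i + 8)
            coef = np.polyfit(t[lo:hi] / 60.0, v[lo:hi], 1)[0]
            assert slopes[i] == pytest.approx(coef)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValidationError):
            moving_slope(np.zeros(30), np.arange(30.0), window=1)


class TestDepletionRate:
    def _trace(self, t, normalized):
        return StO2Trace(
            t=t, raw=normalized.copy(), timeline=timeline(), normalized=normalized
        )

    def test_linear_depletion_recovered(self):
        t = np.arange(0, 1800, 4.0)
        v = np.full_like(t, 100.0)
        lit = t >= 300
        v[lit] = 100.0 - 5.0 * (t[lit] - 300.0) / 60.0
        rate = mean_depletion_rate(self._trace(t, v), window=15)
        assert rate == pytest.approx(-5.0, abs=0.15)  # window straddles light-on

    def test_flat_trace_rate_is_zero(self):
        t = np.arange(0, 1800, 4.0)
        rate = mean_depletion_rate(self._trace(t, np.full_like(t, 100.0)))
        assert rate == pytest.approx(0.0, abs=1e-12)


class TestActivePdtEnd:
    def _trace(self, t, normalized):
        return StO2Trace(
            t=t, raw=normalized.copy(), timeline=timeline(), normalized=normalized
        )

    def test_v_shaped_trough_found(self):
        t = np.arange(0, 1800, 4.0)
        v = 100.0 + np.abs(t - 720.0) / 60.0
        assert detect_active_pdt_end(self._trace(t, v)) == 720.0

    def test_monotone_decline_returns_light_off(self):
        t = np.arange(0, 1800, 4.0)
        v = 100.0 - t / 60.0
        assert detect_active_pdt_end(self._trace(t, v)) == 1200.0

    def test_invariant_to_positive_affine_rescaling(self, rng):
        t = np.arange(0, 1800, 4.0)
        v = 100.0 + np.abs(t - 900.0) / 60.0 + rng.normal(0, 0.1, t.size)
        t0 = detect_active_pdt_end(self._trace(t, v))
        t1 = detect_active_pdt_end(self._trace(t, 3.7 * v + 11.0))
        assert t0 == t1

    def test_plateau_rule_finds_sustained_non_decrease(self):
        t = np.arange(0, 1800, 4.0)
        v = np.where(t < 720.0, 100.0 - t / 60.0, 100.0 - 12.0)  # decline, then flat
        found = detect_active_pdt_end(
            self._trace(t, v), rule="plateau", plateau_delta=0.5, plateau_hold=15
        )
        # triggers once remaining decline is within delta: up to
        # delta/slope = 30 s before the kink at 720 s
        assert 680.0 <= found <= 740.0
        # still-declining trace: no plateau before light-off
        w = 100.0 - t / 60.0
        assert detect_active_pdt_end(
            self._trace(t, w), rule="plateau", plateau_delta=0.5, plateau_hold=15
        ) == 1200.0

    def test_unknown_rule_rejected(self):
        t = np.arange(0, 1800, 4.0)
        with pytest.raises(ValidationError):
            detect_active_pdt_end(
                self._trace(t, np.full_like(t, 50.0)), rule="bogus"
            )

    def test_tie_breaks_earliest(self):
        t = np.arange(0, 1800, 4.0)
        v = np.full_like(t, 100.0)
        v[(t >= 600) & (t <= 700)] = 90.0  # flat minimum
        assert detect_active_pdt_end(self._trace(t, v)) == 600.0


class TestSeveringhaus:
    def test_ten_mmhg_is_about_ten_percent(self):
        s = severinghaus_so2(10.0)
        assert round(s) == 10
        assert s == pytest.approx(100.0 / (23400.0 / 2500.0 + 1.0))

    def test_saturates_at_high_po2(self):
        assert severinghaus_so2(5000.0) > 99.9

    def test_strictly_monotone(self):
        p = np.linspace(1.0, 150.0, 400)
        s = severinghaus_so2(p)
        assert np.all(np.diff(s) > 0)

    @pytest.mark.parametrize("p", [5.0, 26.8, 100.0])
    def test_inverse_round_trips(self, p):
        assert inverse_severinghaus(severinghaus_so2(p)) == pytest.approx(p, abs=1e-6)

    def test_inverse_round_trips_across_range(self):
        p = np.linspace(1.0, 150.0, 100)
        assert np.allclose(inverse_severinghaus(severinghaus_so2(p)), p, atol=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            severinghaus_so2(0.0)
        with pytest.raises(ValidationError):
            inverse_severinghaus(100.0)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        g = (1.0, 2.0, 3.0, 4.0)
        res = compare_group_rates(
            [RateSummary("a", g), RateSummary("b", g), RateSummary("c", g)]
        )
        assert res.anova_f == pytest.approx(0.0, abs=1e-12)
        assert not res.table["significant"].any()
        assert (res.table["p_adj"] > 0.9).all()

    def test_fluence_rate_pattern(self, rng):
        # HFR strongly depleting, LFR mildly, light-only null; spread chosen so
        # only the HFR contrasts separate
        hfr = rng.normal(-20.0, 1.5, 5)
        lfr = rng.normal(-2.0, 1.5, 5)
        light = rng.normal(0.0, 1.5, 4)
        res = compare_group_rates(
            [
                RateSummary("HFR", tuple(hfr)),
                RateSummary("LFR", tuple(lfr)),
                RateSummary("light_only", tuple(light)),
            ]
        )
        tab = res.table.set_index(["group1", "group2"])

        def sig(a, b):
            key = (a, b) if (a, b) in tab.index else (b, a)
            return bool(tab.loc[key, "significant"])

        assert res.anova_p < 0.05
        assert sig("HFR", "LFR") and sig("HFR", "light_only")
        assert not sig("LFR", "light_only")

    def test_type_one_error_near_nominal(self):
        # identical null distributions: familywise rejection rate ~ alpha
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [RateSummary(g, tuple(rng.normal(size=5))) for g in "abc"]
            res = compare_group_rates(groups)
            rejections += bool(res.table["significant"].any())
        assert 0.02 <= rejections / reps <= 0.09

    def test_degenerate_group_rejected(self):
        with pytest.raises(StatisticsError):
            compare_group_rates(
                [RateSummary("a", (1.0,)), RateSummary("b", (1.0, 2.0))]
            )
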
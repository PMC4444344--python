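"""Plate-kinetics unit tests: background subtraction, exponential-window
detection, growth rate, synthesis rate and RPU."""

import numpy as np
import pytest

from luxrep.plate import (
    KineticSeries, NoExponentialWindow, PlateError, Window, compute_rpu,
    exponential_window, growth_rate, subtract_background, synthesis_rate,
)


def series(t, od, fluor, **kw):
    kw.setdefault("well_id", "w")
    return KineticSeries(time=np.asarray(t, float), od=np.asarray(od, float),
                        fluor=np.asarray(fluor, float), **kw)


T = np.arange(0.0, 601.0, 5.0)


class TestKineticSeriesContracts:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(PlateError, match="lengths differ"):
            series([0, 5, 10], [1, 1], [0, 0, 0])

    def test_rejects_non_increasing_time(self):
        with pytest.raises(PlateError, match="strictly increasing"):
            series([0, 5, 5], [1, 1, 1], [0, 0, 0])

    def test_rejects_nonpositive_gain(self):
        with pytest.raises(PlateError, match="gain"):
            series([0, 5], [1, 1], [0, 0], gain=0)


class TestSubtractBackground:
    def test_constant_offset_od(self):
        s = series(T, np.full_like(T, 0.30), np.zeros_like(T))
        b = series(T, np.full_like(T, 0.10), np.zeros_like(T),
                   well_id="b", role="medium_blank")
        out = subtract_background(s, [b])
        assert np.allclose(out.od, 0.20)
        assert out.background_subtracted

    def test_self_subtraction_zeroes_fluorescence(self):
        # sample fluorescence equals the control's at every OD -> corrected 0
        od = 0.1 + 0.001 * T
        fl = 50.0 * od
        s = series(T, od, fl)
        b = series(T, np.zeros_like(T), np.zeros_like(T),
                   well_id="b", role="medium_blank")
        c = series(T, od, fl, well_id="c", role="nonfluorescent_control")
        out = subtract_background(s, [b], c)
        assert np.allclose(out.fluor, 0.0, atol=1e-9)

    def test_blank_aggregation_is_per_timepoint_mean(self):
        s = series(T, np.full_like(T, 1.0), np.zeros_like(T))
        b1 = series(T, np.full_like(T, 0.10), np.zeros_like(T),
                    well_id="b1", role="medium_blank")
        b2 = series(T, np.full_like(T, 0.30), np.zeros_like(T),
                    well_id="b2", role="medium_blank")
        out = subtract_background(s, [b1, b2])
        assert np.allclose(out.od, 0.8)

    def test_negative_values_clip_to_zero_and_are_counted(self):
        s = series(T, np.full_like(T, 0.05), np.zeros_like(T))
        b = series(T, np.full_like(T, 0.10), np.zeros_like(T),
                   well_id="b", role="medium_blank")
        out = subtract_background(s, [b])
        assert np.all(out.od == 0.0)
        assert out.provenance["od_values_clipped"] == len(T)

    def test_empty_blank_set_rejected(self):
        s = series(T, np.full_like(T, 1.0), np.zeros_like(T))
        with pytest.raises(PlateError, match="empty blank"):
            subtract_background(s, [])

    def test_wrong_role_rejected(self):
        s = series(T, np.full_like(T, 1.0), np.zeros_like(T))
        b = series(T, np.full_like(T, 0.1), np.zeros_like(T), well_id="b")
        with pytest.raises(PlateError, match="role"):
            subtract_background(s, [b])

    def test_mismatched_time_grid_rejected(self):
        s = series(T, np.full_like(T, 1.0), np.zeros_like(T))
        t2 = T + 1.0
        b = series(t2, np.full_like(t2, 0.1), np.zeros_like(t2),
                   well_id="b", role="medium_blank")
        with pytest.raises(PlateError, match="time grid"):
            subtract_background(s, [b])


class TestExponentialWindow:
    def test_exponential_trace_matches_closed_form_crossings(self):
        # od = 0.01 e^{0.01 t}: crosses 0.05 at ln5/0.01 = 160.9 min and
        # 0.2 at ln20/0.01 = 299.6 min -> 5-min samples t = 165..295 in band
        od = 0.01 * np.exp(0.01 * T)
        w = exponential_window(series(T, od, np.zeros_like(T)))
        in_band_t = T[w.slice]
        assert in_band_t[0] == 165.0 and in_band_t[-1] == 295.0

    def test_constant_od_has_no_window(self):
        with pytest.raises(NoExponentialWindow, match="no exponential window"):
            exponential_window(series(T, np.full_like(T, 0.5), np.zeros_like(T)))

    def test_linear_ramp_matches_brute_force(self):
        t = np.arange(80.0)
        od = np.linspace(0.0, 0.4, 80)
        w = exponential_window(series(t, od, np.zeros_like(t)))
        brute = [i for i in range(80) if 0.05 <= od[i] <= 0.2]
        assert list(range(w.start, w.end)) == brute

    def test_first_maximal_run_wins_on_multiple_crossings(self):
        # dips out of band and re-enters: first maximal contiguous run is used
        od = np.array([0.01, 0.06, 0.1, 0.15, 0.3, 0.1, 0.12, 0.14, 0.16, 0.18])
        t = np.arange(10.0)
        w = exponential_window(series(t, od, np.zeros(10)), min_points=3)
        assert (w.start, w.end) == (5, 10)  # second run is longer -> maximal
        od2 = np.array([0.06, 0.1, 0.15, 0.19, 0.3, 0.1, 0.12, 0.14, 0.3, 0.3])
        w2 = exponential_window(series(t, od2, np.zeros(10)), min_points=3)
        assert (w2.start, w2.end) == (0, 4)  # equal-or-longer first run wins

    def test_min_points_enforced(self):
        od = np.array([0.01, 0.1, 0.1, 0.01])
        with pytest.raises(NoExponentialWindow):
            exponential_window(series(np.arange(4.0), od, np.zeros(4)))

    def test_brute_force_equivalence_on_random_traces(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 60))
            od = rng.uniform(0.0, 0.35, size=n)
            s = series(np.arange(float(n)), od, np.zeros(n))
            in_band = (od >= 0.05) & (od <= 0.2)
            runs = []
            i = 0
            while i < n:
                if in_band[i]:
                    j = i
                    while j < n and in_band[j]:
                        j += 1
                    runs.append((i, j))
                    i = j
                else:
                    i += 1
            best = max(runs, key=lambda r: r[1] - r[0], default=None)
            if best is None or best[1] - best[0] < 4:
                with pytest.raises(NoExponentialWindow):
                    exponential_window(s)
            else:
                w = exponential_window(s)
                assert (w.start, w.end) == best


class TestGrowthRate:
    def test_pure_exponential_recovered_exactly(self):
        od = 0.05 * 2 ** (T / 90.0)
        s = series(T, od, np.zeros_like(T))
        g = growth_rate(s, Window(0, len(T)))
        assert g.m == pytest.approx(np.log(2) / 90.0, rel=1e-9)
        assert g.doubling_time == pytest.approx(90.0, rel=1e-9)

    def test_doubling_time_definition(self):
        t = np.arange(0, 10.0, 0.5)
        od = 0.01 * np.exp(np.log(2) * t)
        g = growth_rate(series(t, od, np.zeros_like(t)), Window(0, len(t)))
        assert g.doubling_time == pytest.approx(1.0, rel=1e-9)

    def test_doubling_time_ratio_tracks_generated_rates(self):
        t = np.arange(0, 300.0, 5.0)
        m2 = np.log(2) / 120.0
        g1 = growth_rate(series(t, 0.05 * np.exp(2 * m2 * t), np.zeros_like(t)),
                         Window(0, len(t)))
        g2 = growth_rate(series(t, 0.05 * np.exp(m2 * t), np.zeros_like(t)),
                         Window(0, len(t)))
        assert g2.doubling_time / g1.doubling_time == pytest.approx(2.0, rel=1e-9)

    def test_nonpositive_od_rejected(self):
        s = series([0, 5, 10, 15], [0.1, 0.0, 0.1, 0.1], [0, 0, 0, 0])
        with pytest.raises(PlateError, match="non-positive OD"):
            growth_rate(s, Window(0, 4))

    def test_decay_flagged_non_growing(self):
        t = np.arange(0, 100.0, 5.0)
        s = series(t, 0.2 * np.exp(-0.01 * t), np.zeros_like(t))
        with pytest.raises(PlateError, match="non-growing"):
            growth_rate(s, Window(0, len(t)))


class TestSynthesisRate:
    def test_constant_fluorescence_gives_zero(self):
        s = series(T, 0.01 * np.exp(0.005 * T), np.full_like(T, 123.0))
        r = synthesis_rate(s, Window(5, 50))
        assert r.s_cell_mean == pytest.approx(0.0, abs=1e-12)

    def test_integral_construction_inverts_to_rate(self):
        # fluor = c * cumulative integral of od  =>  S_cell = c
        c = 700.0
        od = 0.01 * np.exp(np.log(2) / 90.0 * T)
        integral = np.concatenate(
            ([0.0], np.cumsum(np.diff(T) * (od[1:] + od[:-1]) / 2.0))
        )
        s = series(T, od, c * integral)
        r = synthesis_rate(s, Window(10, 80))
        assert r.s_cell_mean == pytest.approx(c, rel=0.01)

    def test_mean_equals_mean_of_series(self):
        od = 0.05 + 0.001 * T
        s = series(T, od, od ** 2)
        r = synthesis_rate(s, Window(3, 40))
        assert r.s_cell_mean == pytest.approx(float(np.mean(r.s_cell_series)))

    def test_zero_od_in_window_rejected(self):
        s = series([0, 5, 10, 15, 20], [0.1, 0.0, 0.1, 0.1, 0.1], np.arange(5.0))
        with pytest.raises(PlateError, match="zero OD"):
            synthesis_rate(s, Window(0, 5))


class TestRPU:
    def _pair(self, s_sample, s_ref, **ref_kw):
        od = 0.01 * np.exp(0.007 * T)
        integral = np.concatenate(
            ([0.0], np.cumsum(np.diff(T) * (od[1:] + od[:-1]) / 2.0))
        )
        sam = series(T, od, s_sample * integral, well_id="sam")
        ref = series(T, od, s_ref * integral, well_id="ref", **ref_kw)
        w = Window(10, 60)
        return (synthesis_rate(sam, w), synthesis_rate(ref, w), sam, ref)

    def test_self_ratio_is_one(self):
        rs, rr, sam, ref = self._pair(500.0, 500.0)
        assert compute_rpu(rs, rr, sam, ref).value == pytest.approx(1.0)

    def test_ratio(self):
        rs, rr, sam, ref = self._pair(500.0, 1000.0)
        assert compute_rpu(rs, rr, sam, ref).value == pytest.approx(0.5, rel=1e-9)

    def test_reporter_mismatch_names_key(self):
        rs, rr, sam, ref = self._pair(500.0, 1000.0, reporter="GFP")
        with pytest.raises(PlateError, match="reporter mismatch"):
            compute_rpu(rs, rr, sam, ref)

    def test_gain_linearity(self):
        # rescaling both fluorescence signals by the same constant leaves RPU fixed
        rs, rr, sam, ref = self._pair(500.0, 1000.0)
        k = 37.5
        rs2, rr2, sam2, ref2 = self._pair(500.0 * k, 1000.0 * k)
        v1 = compute_rpu(rs, rr, sam, ref).value
        v2 = compute_rpu(rs2, rr2, sam2, ref2).value
        assert v1 == pytest.approx(v2, rel=1e-12)
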
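import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sloshsim as ss
from sloshsim.errors import ValidationError
from sloshsim.stress import AT_SIGMA_MAX, PeakMap, StressProfile


def toy_profile(x, values):
    x = np.asarray(x, float)
    v = np.asarray(values, float)
    return StressProfile(
        x_mm=x,
        value_pa=v,
        region=np.full(len(x), "C"),
        filled=np.zeros(len(x), bool),
    )


class TestPeakMap:
    def test_constant_in_time_field_passes_through(self):
        hist = np.tile([1.0, 2.0, 3.0], (5, 1))
        pm = ss.peak_stress_map(hist, [0.0, 1.0, 2.0])
        assert np.array_equal(pm.peak_pa, [1.0, 2.0, 3.0])

    def test_peaks_at_different_times_all_retained(self):
        hist = np.array([[5.0, 0.0], [0.0, 7.0]])
        pm = ss.peak_stress_map(hist, [0.0, 1.0])
        assert np.array_equal(pm.peak_pa, [5.0, 7.0])

    def test_single_sample_is_identity(self):
        pm = ss.peak_stress_map(np.array([[4.0, 2.0]]), [0.0, 1.0])
        assert np.array_equal(pm.peak_pa, [4.0, 2.0])

    def test_empty_history_rejected(self):
        with pytest.raises(ValidationError):
            ss.peak_stress_map(np.empty((0, 0)), [])


class TestSliceMedians:
    def test_three_element_slice_takes_median(self):
        pm = PeakMap(x_mm=np.array([0.2, 0.5, 0.8]), peak_pa=np.array([1.0, 3.0, 2.0]))
        prof = ss.slice_medians(pm)
        assert prof.value_pa[0] == 2.0

    def test_one_element_per_slice_passes_through(self):
        pm = PeakMap(x_mm=np.arange(5) + 0.5, peak_pa=np.array([5.0, 1.0, 4.0, 2.0, 3.0]))
        prof = ss.slice_medians(pm)
        assert np.array_equal(prof.value_pa, pm.peak_pa)

    def test_matches_brute_force_median_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0.0, 10.0, size=50)
        v = rng.uniform(0.0, 100.0, size=50)
        prof = ss.slice_medians(PeakMap(x_mm=x, peak_pa=v))
        lo = x.min()
        for k, center in enumerate(prof.x_mm):
            left = lo + k * 1.0
            sel = (x >= left) & (x < left + 1.0)
            if k == len(prof.x_mm) - 1:
                sel |= x == x.max()
            if sel.any():
                assert prof.value_pa[k] == pytest.approx(float(np.median(v[sel])))

    def test_empty_slices_filled_and_flagged(self):
        pm = PeakMap(x_mm=np.array([0.5, 4.5]), peak_pa=np.array([0.0, 8.0]))
        prof = ss.slice_medians(pm)
        assert prof.filled.any()
        inner = prof.value_pa[prof.filled]
        assert np.all((inner >= 0.0) & (inner <= 8.0))

    def test_width_below_spacing_rejected(self):
        pm = PeakMap(x_mm=np.arange(5) * 2.0, peak_pa=np.ones(5))
        with pytest.raises(ValidationError):
            ss.slice_medians(pm, width_mm=1.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_medians_bounded_by_element_range(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 30, size=40))
        v = rng.uniform(0, 50, size=40)
        prof = ss.slice_medians(PeakMap(x_mm=x, peak_pa=v))
        assert prof.value_pa.min() >= v.min() - 1e-12
        assert prof.value_pa.max() <= v.max() + 1e-12


class TestSigmaMaxDelta:
    def test_flat_profile_ties_break_cranially(self):
        prof = toy_profile(np.arange(10) + 0.5, np.full(10, 7.0))
        val, x_at = ss.sigma_max(prof, (2.0, 6.0), margin_mm=1.0)
        assert val == 7.0
        assert x_at == 1.5  # window start

    def test_single_spike_found(self):
        v = np.zeros(20)
        v[12] = 9.0
        prof = toy_profile(np.arange(20) + 0.5, v)
        val, x_at = ss.sigma_max(prof, (10.0, 15.0))
        assert (val, x_at) == (9.0, 12.5)

    def test_delta_zero_for_identical_profiles(self):
        prof = toy_profile(np.arange(10) + 0.5, np.arange(10, dtype=float))
        assert ss.delta_sigma(prof, prof, (2.0, 6.0)) == 0.0

    def test_uniform_offset_recovered(self):
        base = toy_profile(np.arange(10) + 0.5, np.arange(10, dtype=float))
        prof = toy_profile(base.x_mm, base.value_pa + 100.0)
        assert ss.delta_sigma(prof, base, (2.0, 6.0)) == pytest.approx(100.0)

    def test_windowed_max_diff_matches_brute_force(self):
        rng = np.random.default_rng(7)
        x = np.arange(30) + 0.5
        base = toy_profile(x, rng.uniform(0, 10, 30))
        prof = toy_profile(x, rng.uniform(0, 10, 30))
        extent, margin = (8.0, 16.0), 5.0
        got = ss.delta_sigma(prof, base, extent, margin)
        sel = (x >= extent[0] - margin) & (x <= extent[1] + margin)
        assert got == pytest.approx(np.max(prof.value_pa[sel] - base.value_pa[sel]))

    def test_at_sigma_max_policy(self):
        x = np.arange(10) + 0.5
        base = toy_profile(x, np.full(10, 2.0))
        v = np.full(10, 3.0)
        v[4] = 10.0
        prof = toy_profile(x, v)
        got = ss.delta_sigma(prof, base, (3.0, 6.0), margin_mm=1.0, policy=AT_SIGMA_MAX)
        assert got == pytest.approx(8.0)

    def test_grid_mismatch_rejected(self):
        a = toy_profile(np.arange(10) + 0.5, np.zeros(10))
        b = toy_profile(np.arange(10) + 0.6, np.zeros(10))
        with pytest.raises(ValidationError):
            ss.delta_sigma(a, b, (2.0, 6.0))


class TestPercentIncrease:
    @pytest.mark.parametrize("delta,base,pct", [(100, 100, 100.0), (0, 50, 0.0), (54, 100, 54.0)])
    def test_arithmetic(self, delta, base, pct):
        assert ss.percent_increase(delta, base) == pytest.approx(pct)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            ss.percent_increase(10.0, 0.0)


class TestRegionalTable:
    def _summary(self, name, v=1.0):
        return ss.StressSummary(
            name=name,
            sigma_max_pa=v,
            x_at_max_mm=10.0,
            delta_sigma_pa=v / 2,
            percent_increase=50.0,
            region="C",
        )

    def test_row_count_and_order(self):
        names = [f"S{i}" for i in range(1, 29)]
        tab = ss.regional_table({n: self._summary(n) for n in names}, names)
        assert len(tab) == 28
        assert list(tab.name) == names

    def test_missing_config_listed_by_name(self):
        with pytest.raises(ValidationError, match="S7"):
            ss.regional_table({"S1": self._summary("S1")}, ["S1", "S7"])

    def test_spiked_row_differs(self):
        names = ["S1", "S2", "S3"]
        summaries = {n: self._summary(n) for n in names}
        summaries["S2"] = self._summary("S2", v=99.0)
        tab = ss.regional_table(summaries, names)
        assert tab.loc[tab.name == "S2", "sigma_max_pa"].item() == 99.0
        assert (tab.loc[tab.name != "S2", "sigma_max_pa"] == 1.0).all()
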
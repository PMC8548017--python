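"""DTOF measurands: background, moments, windows, contrasts, DNL, drift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdnirs.forward import DTOF
from tdnirs.metrics import (
    moment_series,
    BackgroundError,
    EARLY_WINDOW,
    LATE_WINDOW,
    Moments,
    TimeWindow,
    contrasts,
    drift_correct,
    epsilon_dnl,
    moments,
    rebin_time,
    subtract_background,
    temporal_fluctuations,
    window_counts,
)


def brute_force_moments(counts, bin_width, threshold_fraction, inclusive):
    """Independent oracle: explicit weighted sums over the contiguous
    above-threshold region containing the maximum."""
    counts = np.asarray(counts, dtype=float)
    level = threshold_fraction * counts.max()
    ok = counts >= level if inclusive else counts > level
    ipk = int(np.argmax(counts))
    i0 = ipk
    while i0 > 0 and ok[i0 - 1]:
        i0 -= 1
    i1 = ipk
    while i1 + 1 < counts.size and ok[i1 + 1]:
        i1 += 1
    t = (np.arange(counts.size) + 0.5) * bin_width
    c = counts[i0 : i1 + 1]
    tt = t[i0 : i1 + 1]
    n = c.sum()
    m1 = (tt * c).sum() / n
    var = (tt**2 * c).sum() / n - m1**2
    return n, m1, var


class TestMoments:
    def test_single_bin(self):
        d = DTOF(counts=np.array([0.0, 7.0, 0.0]), bin_width=800.0)
        m = moments(d, 0.01)
        assert m.m1 == pytest.approx(1200.0)  # center of bin 1
        assert m.var == pytest.approx(0.0)
        assert m.n == 7.0

    def test_two_point_distribution(self):
        # two equal bins 1000 ps apart: V = (separation/2)^2 = 250000 ps^2
        d = DTOF(counts=np.array([5.0, 5.0]), bin_width=1000.0)  # centers 500, 1500
        m = moments(d, 0.0, inclusive=True)
        assert m.n == 10.0
        assert m.m1 == pytest.approx(1000.0)
        assert m.var == pytest.approx(250000.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(
            1000 * np.exp(-0.5 * ((np.arange(512) - 200) / 40.0) ** 2)
        ).astype(float)
        d = DTOF(counts=counts, bin_width=9.77)
        m = moments(d, 0.01)
        n, m1, var = brute_force_moments(counts, 9.77, 0.01, inclusive=False)
        assert m.n == pytest.approx(n, rel=1e-12)
        assert m.m1 == pytest.approx(m1, rel=1e-9)
        assert m.var == pytest.approx(var, rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_oracle_property_random_dtofs(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 500, size=256)
        base[rng.integers(50, 200)] = 1000.0  # ensure a clear peak
        d = DTOF(counts=base, bin_width=9.77)
        m = moments(d, 0.01)
        n, m1, var = brute_force_moments(base, 9.77, 0.01, inclusive=False)
        assert m.n == pytest.approx(n, rel=1e-9)
        assert m.m1 == pytest.approx(m1, rel=1e-9)
        assert m.var >= 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(200, size=128).astype(float)
        counts[64] = 5000.0
        d = DTOF(counts=counts, bin_width=9.77)
        ns = [moments(d, f).n for f in (0.001, 0.01, 0.05, 0.2)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            moments(DTOF(counts=np.zeros(16), bin_width=9.77), 0.01)


class TestBackground:
    def test_zero_background_unchanged(self, dtof_factory):
        d = dtof_factory(background=0.0, seed=1)
        sub = subtract_background(d)
        assert abs(np.asarray(sub.counts).sum() - np.asarray(d.counts).sum()) < 0.01 * d.counts.sum()

    def test_uniform_background_removed(self, dtof_factory):
        clean = dtof_factory(background=0.0, seed=2)
        noisy = dtof_factory(background=10.0, seed=2)
        m_clean = moments(subtract_background(clean), 0.01)
        m_noisy = moments(subtract_background(noisy), 0.01)
        assert m_noisy.m1 == pytest.approx(m_clean.m1, abs=3.0)  # ps, Poisson tolerance
        assert m_noisy.n == pytest.approx(m_clean.n, rel=0.01)

    def test_background_only_input_raises(self):
        rng = np.random.default_rng(0)
        d = DTOF(counts=rng.poisson(50, 1024).astype(float), bin_width=9.77)
        with pytest.raises(BackgroundError):
            subtract_background(d)


class TestWindows:
    def test_full_window_equals_total(self, dtof_factory):
        d = dtof_factory(seed=3, background=0.0)
        total = moments(d, 0.0, inclusive=True).n
        w = TimeWindow(-1e5, 1e5)
        assert window_counts(d, w, irf_max_time=0.0) == pytest.approx(total)

    def test_empty_window_is_zero(self, dtof_factory):
        d = dtof_factory(seed=3)
        assert window_counts(d, TimeWindow(1000.0, 1000.0), 0.0) == 0.0

    def test_zero_shift_moves_selection(self):
        counts = np.arange(100, dtype=float)
        d = DTOF(counts=counts, bin_width=10.0)
        w = TimeWindow(100.0, 200.0)
        a = window_counts(d, w, irf_max_time=0.0)
        b = window_counts(d, w, irf_max_time=50.0)  # +5 bins
        t = d.times()
        sel_a = (t >= 100) & (t < 200)
        sel_b = (t - 50 >= 100) & (t - 50 < 200)
        assert a == counts[sel_a].sum()
        assert b == counts[sel_b].sum()

    def test_outside_support_raises(self, dtof_factory):
        d = dtof_factory(seed=3)
        with pytest.raises(ValueError):
            window_counts(d, TimeWindow(1e6, 2e6), 0.0)


class TestContrasts:
    def test_identical_inputs_give_zero(self, dtof_factory, irf_max_time):
        d = dtof_factory(seed=4, noiseless=True)
        rec = contrasts(d, d, irf_max_time)
        assert rec.dA_early == rec.dA_total == rec.dA_late == 0.0
        assert rec.dm1 == 0.0 and rec.dV == 0.0

    def test_half_counts_give_ln2(self, dtof_factory, irf_max_time):
        ref = dtof_factory(seed=5, noiseless=True, background=0.0)
        meas = DTOF(counts=np.asarray(ref.counts) / 2.0, bin_width=ref.bin_width)
        rec = contrasts(meas, ref, irf_max_time)
        assert rec.dA_total == pytest.approx(np.log(2), rel=1e-9)
        assert rec.dA_early == pytest.approx(np.log(2), rel=1e-9)
        assert rec.dm1 == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_under_swap(self, dtof_factory, irf_max_time):
        a = dtof_factory(mua=0.1, seed=6, noiseless=True)
        b = dtof_factory(mua=0.12, seed=6, noiseless=True)
        fwd = contrasts(a, b, irf_max_time)
        rev = contrasts(b, a, irf_max_time)
        assert fwd.dA_total == pytest.approx(-rev.dA_total, rel=1e-9)
        assert fwd.dm1 == pytest.approx(-rev.dm1, rel=1e-9)

    def test_binning_mismatch_raises(self, dtof_factory, irf_max_time):
        d = dtof_factory(seed=4)
        other = DTOF(counts=np.asarray(d.counts), bin_width=5.0)
        with pytest.raises(ValueError):
            contrasts(d, other, irf_max_time)


class TestEpsilonDNL:
    def test_constant_counts(self):
        assert epsilon_dnl(np.full(100, 42.0), (0, 1000), 9.77) == 0.0

    def test_alternating_pattern(self):
        c = np.tile([99.0, 101.0], 50)
        assert epsilon_dnl(c, (0, 1000), 9.77) == pytest.approx(0.02)

    def test_matches_formula_on_random_input(self):
        rng = np.random.default_rng(11)
        c = rng.uniform(50, 150, 200)
        t_range = (200.0, 1500.0)
        t = (np.arange(200) + 0.5) * 9.77
        sel = (t >= 200) & (t < 1500)
        expect = (c[sel].max() - c[sel].min()) / c[sel].mean()
        assert epsilon_dnl(c, t_range, 9.77) == pytest.approx(expect, rel=1e-12)

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            epsilon_dnl(np.ones(10), (1e6, 2e6), 9.77)


class TestFluctuations:
    def test_identical_records_zero(self):
        m = Moments(1e6, 1500.0, 2e5, 0.01, (0, 100))
        rep = temporal_fluctuations([m] * 10)
        assert rep.std_n_percent == 0.0 and rep.std_m1 == 0.0 and rep.std_var == 0.0

    def test_photon_noise_floor(self, dtof_factory):
        # std(m1) over repeats matches the delta-method prediction sqrt(V/N)
        # when the integration region is held fixed across frames
        dtofs = [
            dtof_factory(mua=0.07, musp=8.0, n_medium=1.55, seed=1000 + s,
                         background=0.0)
            for s in range(100)
        ]
        series = moment_series(dtofs, 0.01)
        rep = temporal_fluctuations(series)
        predicted = np.sqrt(np.mean([m.var / m.n for m in series]))
        assert rep.std_m1 == pytest.approx(predicted, rel=0.2)
        assert rep.std_m1 >= predicted * 0.8


class TestDrift:
    IRF0 = Moments(1e6, 1000.0, 5e4, 0.01, (0, 100))

    def test_identical_irfs_change_nothing(self):
        series = [Moments(5e5, 1500.0, 2e5, 0.01, (0, 100))] * 5
        out = drift_correct(series, np.linspace(0, 100, 5), self.IRF0, 0.0, self.IRF0, 100.0)
        assert all(o.m1 == s.m1 and o.n == s.n and o.var == s.var for o, s in zip(out, series))

    def test_linear_drift_removed(self):
        ts = np.linspace(0.0, 100.0, 11)
        drifted = [Moments(5e5, 1500.0 + 5.0 * t / 100.0, 2e5, 0.01, (0, 100)) for t in ts]
        irf_end = Moments(1e6, 1005.0, 5e4, 0.01, (0, 100))
        out = drift_correct(drifted, ts, self.IRF0, 0.0, irf_end, 100.0)
        m1s = np.array([o.m1 for o in out])
        assert np.allclose(m1s, 1500.0, atol=1e-9)

    def test_midpoint_gets_half_correction(self):
        irf_end = Moments(1e6, 1010.0, 5e4, 0.01, (0, 100))
        series = [Moments(5e5, 1500.0, 2e5, 0.01, (0, 100))]
        out = drift_correct(series, np.array([50.0]), self.IRF0, 0.0, irf_end, 100.0)
        assert out[0].m1 == pytest.approx(1500.0 - 5.0)

    def test_out_of_bracket_raises(self):
        series = [Moments(5e5, 1500.0, 2e5, 0.01, (0, 100))]
        with pytest.raises(ValueError):
            drift_correct(series, np.array([150.0]), self.IRF0, 0.0, self.IRF0, 100.0)


class TestRebin:
    def _series(self, n):
        return [
            DTOF(counts=np.full(16, float(i + 1)), bin_width=9.77, acquisition_time=0.3)
            for i in range(n)
        ]

    def test_identity_at_k1(self):
        s = self._series(4)
        assert rebin_time(s, 1) == s

    def test_three_frame_sum_gives_second_sampling(self):
        out = rebin_time(self._series(6), 3)
        assert len(out) == 2
        assert out[0].acquisition_time == pytest.approx(0.9)
        assert np.all(out[0].counts == 1.0 + 2.0 + 3.0)

    def test_total_counts_conserved(self):
        s = self._series(6)
        total = sum(d.counts.sum() for d in s)
        out = rebin_time(s, 3)
        assert sum(d.counts.sum() for d in out) == pytest.approx(total)

    def test_remainder_dropped(self):
        out = rebin_time(self._series(7), 3)
        assert len(out) == 2

    def test_bad_k_raises(self):
        with pytest.raises(ValueError):
            rebin_time(self._series(3), 0)
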
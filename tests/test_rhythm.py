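"""Chi-square periodogram and Morlet wavelet spectrum."""

import numpy as np
import pytest
from scipy.stats import chi2

from circabeam.rhythm import (
    InsufficientDataError,
    PeriodogramResult,
    chi_square_periodogram,
    daily_periods,
    daily_ridge,
    morlet_wavelet_spectrum,
    rhythmic_power,
)


def qp_oracle(x: np.ndarray, k: int) -> float:
    """Brute-force fold: Qp = sum_h n_h (M_h - Mbar)^2 / (SST / N)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    grand = x.mean()
    sst = ((x - grand) ** 2).sum()
    if sst == 0:
        return 0.0
    ssb = 0.0
    for h in range(k):
        col = x[h::k]
        ssb += len(col) * (col.mean() - grand) ** 2
    return n * ssb / sst


class TestPeriodogram:
    def test_constant_series_has_zero_qp_and_no_peak(self):
        res = chi_square_periodogram(np.full(720, 4.0), 20)
        assert np.all(res.qp == 0)
        assert res.peak_period_h is None
        assert res.rhythmic_power == 0.0

    def test_square_wave_peaks_at_24h_with_expected_grid_neighbours(self):
        t = np.arange(720) * 20 / 60.0
        x = ((t % 24) < 12).astype(float) * 5
        res = chi_square_periodogram(x, 20)
        assert res.peak_period_h == pytest.approx(24.0)
        i = int(np.argmin(np.abs(res.periods_h - 24.0)))
        assert res.periods_h[i - 1] == pytest.approx(23.0 + 2.0 / 3.0, abs=1e-9)
        assert res.periods_h[i + 1] == pytest.approx(24.0 + 1.0 / 3.0, abs=1e-9)

    def test_matches_brute_force_oracle_on_random_series(self, rng):
        for _ in range(10):
            n = int(rng.integers(300, 1000))
            x = rng.poisson(3.0, n).astype(float)
            res = chi_square_periodogram(x, 20, period_range_h=(16, 26))
            for period, qp in zip(res.periods_h, res.qp):
                k = round(period * 3)  # bins of 20 min
                assert qp == pytest.approx(qp_oracle(x, k), rel=1e-10)

    def test_significance_line_is_bonferroni_chi2(self):
        res = chi_square_periodogram(np.random.default_rng(0).normal(size=720), 20)
        g = len(res.periods_h)
        ks = np.round(res.periods_h * 3).astype(int)
        np.testing.assert_allclose(
            res.sig_line, chi2.isf(0.05 / g, ks - 1), rtol=1e-12
        )

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            chi_square_periodogram(np.zeros(200), 20)  # < 3 cycles of 32 h

    def test_period_recovery_within_one_grid_step(self, rng):
        for tau in (23.0, 24.5, 25.5):
            t = np.arange(720) * 20 / 60.0
            x = rng.poisson(3.0 + 2.0 * np.sin(2 * np.pi * t / tau))
            res = chi_square_periodogram(x.astype(float), 20)
            assert res.peak_period_h is not None
            assert abs(res.peak_period_h - tau) <= 1.0 / 3.0 + 1e-9


class TestRhythmicPower:
    def test_definition_is_peak_minus_sig(self):
        res = PeriodogramResult(
            periods_h=np.array([24.0]),
            qp=np.array([300.0]),
            sig_line=np.array([60.0]),
            alpha=0.05,
            bin_minutes=20,
            peak_period_h=24.0,
            rhythmic_power=240.0,
        )
        assert rhythmic_power(res) == 240.0

    def test_no_peak_gives_zero(self):
        res = chi_square_periodogram(np.full(720, 2.0), 20)
        assert rhythmic_power(res) == 0.0

    def test_strong_signal_outpowers_weak_signal(self, rng):
        t = np.arange(720) * 20 / 60.0
        base = 4.0
        strong = rng.poisson(base + 3.0 * np.sin(2 * np.pi * t / 24.0))
        weak = rng.poisson(base + 0.8 * np.sin(2 * np.pi * t / 24.0))
        p_strong = chi_square_periodogram(strong.astype(float), 20).rhythmic_power
        p_weak = chi_square_periodogram(weak.astype(float), 20).rhythmic_power
        assert p_strong > p_weak


class TestCorrelatedNull:
    def test_iid_lag_corr_reduces_to_chi2_line(self):
        x = np.random.default_rng(3).normal(size=720)
        plain = chi_square_periodogram(x, 20)
        corr = chi_square_periodogram(x, 20, lag_corr=np.array([1.0]))
        np.testing.assert_allclose(corr.sig_line, plain.sig_line, rtol=1e-9)

    def test_smoothed_noise_is_not_called_rhythmic(self, rng):
        from circabeam.smoothing import (
            PRESETS,
            savitzky_golay,
            smoothed_lag_correlation,
        )

        rho = smoothed_lag_correlation(PRESETS["entrainment_gate"], 20)
        hits = 0
        for _ in range(20):
            x = rng.poisson(2.0, 14400).astype(float)
            sm = savitzky_golay(x, PRESETS["entrainment_gate"])
            b = sm.reshape(-1, 20).mean(axis=1)
            res = chi_square_periodogram(b, 20, lag_corr=rho)
            hits += res.peak_period_h is not None
        assert hits <= 2


class TestWavelet:
    def test_sinusoid_ridge_within_two_percent(self):
        t = np.arange(9 * 96) * 0.25
        x = 2 + np.sin(2 * np.pi * t / 24.0)
        spec = morlet_wavelet_spectrum(x, 15)
        valid = spec.coi_mask()
        mid = len(t) // 2
        ridge = spec.periods_h[np.argmax(spec.power[valid[:, mid], mid])]
        assert abs(ridge - 24.0) / 24.0 < 0.02

    def test_constant_series_has_negligible_power(self):
        spec = morlet_wavelet_spectrum(np.full(9 * 96, 5.0), 15)
        assert spec.power.max() < 1e-12

    def test_daily_estimates_track_a_programmed_period_switch(self):
        t = np.arange(10 * 96) * 0.25
        x = np.where(
            t < 5 * 24,
            np.sin(2 * np.pi * t / 23.0),
            np.sin(2 * np.pi * t / 25.0),
        )
        spec = morlet_wavelet_spectrum(2 + x, 15)
        dailies = dict(daily_periods(spec))
        early = [p for d, p in dailies.items() if 1 <= d <= 3]
        late = [p for d, p in dailies.items() if 6 <= d <= 8]
        assert max(early) < 24.0
        assert min(late) > 24.0

    def test_25h_sinusoid_interior_days_above_band(self):
        t = np.arange(9 * 96) * 0.25
        spec = morlet_wavelet_spectrum(2 + np.sin(2 * np.pi * t / 25.0), 15)
        interior = [p for d, p in daily_periods(spec) if 2 <= d <= 6]
        assert interior and all(p > 24.5 for p in interior)

    def test_edge_day_fully_inside_coi_is_absent(self):
        t = np.arange(3 * 96) * 0.25
        x = 2 + np.sin(2 * np.pi * t / 24.0)
        spec = morlet_wavelet_spectrum(x, 15, period_range_h=(20.0, 32.0))
        cycles = [d for d, _ in daily_periods(spec)]
        assert 0 not in cycles  # first day has no coi-valid circadian row
        assert 1 in cycles

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            morlet_wavelet_spectrum(np.zeros(100), 15)

    def test_ridge_power_separates_rhythm_from_noise(self, rng):
        t = np.arange(9 * 96) * 0.25
        rhythmic = rng.poisson(10 + 3 * np.sin(2 * np.pi * t / 24.0)).astype(float)
        noise = rng.poisson(10, len(t)).astype(float)
        p_r = np.median([p for _, _, p in daily_ridge(morlet_wavelet_spectrum(rhythmic, 15))])
        p_n = np.median([p for _, _, p in daily_ridge(morlet_wavelet_spectrum(noise, 15))])
        assert p_r > 10 * p_n
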
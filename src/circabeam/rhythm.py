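"""Period estimation: chi-square periodogram and Morlet wavelet spectrum.

The chi-square (Sokolove-Bushell) periodogram folds a count series at every
trial period expressible as an integer number of bins and measures how much
of the total variance the folded daily profile explains:

    Qp(K) = sum_h n_h (M_h - Mbar)^2 / (SST / N)

with K columns of the fold, per-column counts ``n_h`` and means ``M_h``,
grand mean ``Mbar`` and total sum of squares ``SST`` over all N bins.  Under
the null of no rhythm Qp is asymptotically chi-square with K-1 degrees of
freedom, which supplies the per-period significance line; the test is
Bonferroni-corrected across the period grid by default.  The height of the
peak above its significance line is the rhythmic power, an index of rhythm
strength.

The continuous Morlet wavelet transform (centre frequency omega0 = 6)
provides time-resolved period estimates -- one ridge period per 24 h cycle --
used to judge whether a fly's period had stabilized under ramped light
cycles.  Edge effects are masked by the standard e-folding cone of
influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.stats import chi2

MINUTES_PER_HOUR = 60
HOURS_PER_DAY = 24.0

OMEGA0 = 6.0
#: Fourier period / wavelet scale for the omega0=6 Morlet (Torrence & Compo).
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))


class InsufficientDataError(ValueError):
    """The series is too short for the requested analysis."""


@dataclass
class PeriodogramResult:
    """Chi-square periodogram over a grid of integer-bin trial periods."""

    periods_h: np.ndarray
    qp: np.ndarray
    sig_line: np.ndarray
    alpha: float
    bin_minutes: int
    peak_period_h: float | None
    rhythmic_power: float
    bonferroni: bool = True

    def significant_periods(self) -> np.ndarray:
        return self.periods_h[self.qp > self.sig_line]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period_h": self.periods_h, "qp": self.qp, "sig": self.sig_line}
        )


def _correlated_null(ks: np.ndarray, lag_corr: np.ndarray, alpha_eff: float
                     ) -> np.ndarray:
    """Significance line for serially correlated (e.g. smoothed) series.

    Under an iid null the folded column means are uncorrelated and Qp is
    chi-square with K-1 df.  A known filter kernel induces a known
    autocorrelation ``lag_corr`` between bins; the column means of the fold
    then form a circulant-correlated Gaussian vector and Qp is a weighted
    sum of chi-square variables with weights equal to the non-constant
    circulant eigenvalues.  The line is the Satterthwaite (moment-matched
    scaled chi-square) upper quantile; with ``lag_corr = [1]`` it reduces
    exactly to the iid chi-square line.
    """
    sig = np.empty(len(ks))
    for j, k in enumerate(ks):
        c = np.zeros(k)
        for lag, rho in enumerate(lag_corr):
            c[lag % k] += rho
            if lag:
                c[(-lag) % k] += rho
        lam = np.fft.fft(c).real  # circulant eigenvalues
        lam = np.clip(lam, 0.0, None)
        lam = lam[1:]  # drop the constant eigenvector removed by centering
        e = lam.sum()
        v = 2.0 * (lam**2).sum()
        if e <= 0 or v <= 0:
            sig[j] = chi2.isf(alpha_eff, k - 1)
            continue
        scale = v / (2.0 * e)
        dof = 2.0 * e**2 / v
        sig[j] = scale * chi2.isf(alpha_eff, dof)
    return sig


def chi_square_periodogram(
    series,
    bin_minutes: int,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.05,
    bonferroni: bool = True,
    lag_corr: np.ndarray | None = None,
) -> PeriodogramResult:
    """Compute the chi-square periodogram of a binned count series.

    The trial-period grid holds every period that is a whole number of bins
    inside ``period_range_h`` (at the default 20-min bins this grid contains
    23.67, 24.00 and 24.33 h -- the two closest grid points to 24 h on either
    side, which define the entrainment window downstream).  The series must
    cover at least three cycles of the longest trial period.

    ``lag_corr`` supplies the known null autocorrelation per bin lag when the
    series has been filtered (see
    :func:`circabeam.smoothing.smoothed_lag_correlation`); the significance
    line is then moment-matched to the correlated null instead of assuming
    iid bins.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = len(x)
    lo, hi = period_range_h
    k_min = int(np.ceil(lo * MINUTES_PER_HOUR / bin_minutes))
    k_max = int(np.floor(hi * MINUTES_PER_HOUR / bin_minutes))
    if k_max < k_min:
        raise ValueError("period range contains no integer-bin trial period")
    if n < 3 * k_max:
        raise InsufficientDataError(
            f"need >= 3 cycles of the longest trial period "
            f"({3 * k_max} bins), got {n}"
        )
    ks = np.arange(k_min, k_max + 1)
    periods_h = ks * bin_minutes / MINUTES_PER_HOUR
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    alpha_eff = alpha / len(ks) if bonferroni else alpha
    if lag_corr is None:
        sig = chi2.isf(alpha_eff, ks - 1)
    else:
        sig = _correlated_null(ks, np.asarray(lag_corr, dtype=float), alpha_eff)
    qp = np.zeros(len(ks))
    if sst > 0:
        idx_all = np.arange(n)
        for j, k in enumerate(ks):
            col = idx_all % k
            n_h = np.bincount(col, minlength=k).astype(float)
            m_h = np.bincount(col, weights=x, minlength=k) / n_h
            ssb = float((n_h * (m_h - grand) ** 2).sum())
            qp[j] = n * ssb / sst
    peak: float | None = None
    power = 0.0
    above = qp - sig
    if sst > 0 and np.any(above > 0):
        j = int(np.argmax(above))
        peak = float(periods_h[j])
        power = float(above[j])
    return PeriodogramResult(
        periods_h=periods_h,
        qp=qp,
        sig_line=sig,
        alpha=alpha,
        bin_minutes=bin_minutes,
        peak_period_h=peak,
        rhythmic_power=power,
        bonferroni=bonferroni,
    )


def rhythmic_power(result: PeriodogramResult) -> float:
    """Peak Qp minus its significance line, or 0 without a significant peak."""
    return result.rhythmic_power


# -- wavelet spectrum ----------------------------------------------------------


@dataclass
class WaveletSpectrum:
    """Morlet wavelet power over (time, period) with a cone of influence.

    ``coi_period_h[t]`` is the longest period unaffected by edge effects at
    sample ``t``; power at longer periods is edge-contaminated there.
    """

    times_h: np.ndarray
    periods_h: np.ndarray
    power: np.ndarray  # shape (n_periods, n_times), variance-normalized
    coi_period_h: np.ndarray
    bin_minutes: int

    def coi_mask(self) -> np.ndarray:
        """Boolean (n_periods, n_times); True where inside the coi (valid)."""
        return self.periods_h[:, None] <= self.coi_period_h[None, :]


def morlet_wavelet_spectrum(
    series,
    bin_minutes: int,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    voices_per_octave: int = 50,
) -> WaveletSpectrum:
    """Continuous Morlet (omega0 = 6) wavelet power spectrum.

    Power is |W|^2 divided by the wavelet scale (the bias-rectified spectrum,
    which makes equal-amplitude sinusoids at different periods peak at equal
    height and at the correct scale) and normalized by the series variance,
    over a log2-spaced period grid with ``voices_per_octave`` periods per
    octave.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    dt_h = bin_minutes / MINUTES_PER_HOUR
    lo, hi = period_range_h
    if n * dt_h < 2 * hi:
        raise InsufficientDataError(
            f"series spans {n * dt_h:.1f} h; need >= {2 * hi:.1f} h"
        )
    var = x.var()
    n_voices = int(np.ceil(np.log2(hi / lo) * voices_per_octave))
    periods_h = lo * 2.0 ** (np.arange(n_voices + 1) / voices_per_octave)
    periods_h = periods_h[periods_h <= hi * (1 + 1e-12)]
    fc = OMEGA0 / (2 * np.pi)  # centre frequency of the cmor wavelet
    scales = fc * periods_h / dt_h
    wavelet = f"cmor2.0-{fc:.12f}"
    coeffs, _ = pywt.cwt(x - x.mean(), scales, wavelet, sampling_period=dt_h,
                         method="fft")
    power = np.abs(coeffs) ** 2 / scales[:, None]
    if var > 0:
        power /= var
    times_h = np.arange(n) * dt_h
    dist_h = np.minimum(np.arange(n), n - 1 - np.arange(n)) * dt_h
    coi = dist_h * FOURIER_FACTOR / np.sqrt(2.0)
    return WaveletSpectrum(
        times_h=times_h,
        periods_h=periods_h,
        power=power,
        coi_period_h=coi,
        bin_minutes=bin_minutes,
    )


def daily_ridge(
    spectrum: WaveletSpectrum, min_valid_frac: float = 0.25
) -> list[tuple[int, float, float]]:
    """Per-cycle ridge as (cycle_index, period_h, mean ridge power).

    For each complete 24 h cycle the wavelet power is averaged over the
    cycle's coi-valid samples; the ridge is the period of maximal average
    power.  Period rows with less than ``min_valid_frac`` valid coverage in
    the cycle are excluded; a cycle with no usable row yields no entry.
    """
    n_cycles = int(spectrum.times_h[-1] + spectrum.bin_minutes / 60) // 24
    valid = spectrum.coi_mask()
    out: list[tuple[int, float, float]] = []
    for d in range(n_cycles):
        cols = (spectrum.times_h >= d * 24) & (spectrum.times_h < (d + 1) * 24)
        if not np.any(cols):
            continue
        v = valid[:, cols]
        frac = v.mean(axis=1)
        rows = frac >= min_valid_frac
        if not np.any(rows):
            continue
        p = spectrum.power[:, cols]
        with np.errstate(invalid="ignore"):
            mean_power = np.where(v, p, np.nan)
        avg = np.nanmean(mean_power[rows], axis=1)
        j = int(np.nanargmax(avg))
        period = float(spectrum.periods_h[rows][j])
        out.append((d, period, float(avg[j])))
    return out


def daily_periods(spectrum: WaveletSpectrum) -> list[tuple[int, float]]:
    """Daily ridge period estimates, one per analysable 24 h cycle."""
    return [(d, per) for d, per, _ in daily_ridge(spectrum)]


def ridge_to_csv(spectrum: WaveletSpectrum, path) -> None:
    rows = daily_ridge(spectrum)
    pd.DataFrame(rows, columns=["cycle", "period_h", "power"]).to_csv(
        path, index=False
    )
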
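"""Entrainment verdicts: the skeleton-photoperiod period-window gate and the
four-way ramped-cycle classification.

Under skeleton photoperiods a fly is judged by a single quantitative gate:
the raw 1-min series is heavily SG-smoothed to suppress startle artifacts,
the chi-square periodogram is computed, and the fly is *entrained* if its
significant peak period falls in [23.67, 24.33] h (the two grid points
closest to 24 h on either side at 20-min periodogram bins), *free-running*
if the peak falls outside that window, and *arrhythmic* without a
significant peak.

Under ramped light cycles -- where entrainment may take several cycles and
can be partial -- the verdict is four-way, combining the periodogram with
daily wavelet period estimates and the cycle-to-cycle drift of the dominant
activity peak.  The qualitative actogram-inspection criteria are
operationalized as numeric thresholds (all configurable): period stability
band [23.5, 24.5] h for the wavelet dailies from the sixth cycle onward, a
maximum mean phase drift per cycle for stability, and monotone directional
drift for free-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damio import ActivityTable, MINUTES_PER_DAY, bin_activity, _split_series
from .phase import find_peaks
from .rhythm import (
    PeriodogramResult,
    chi_square_periodogram,
    daily_ridge,
    morlet_wavelet_spectrum,
)
from .smoothing import PRESETS, SGParams, savitzky_golay, smoothed_lag_correlation

VERDICTS = ("entrained", "relative_coordination", "free_running", "arrhythmic")

#: entrainment window on the periodogram peak (h); grid neighbours of 24 h
PERIOD_WINDOW_H = (23.67, 24.33)
#: wider stability band for the (more variable) wavelet daily estimates (h)
WAVELET_BAND_H = (23.5, 24.5)


@dataclass
class EntrainmentCall:
    """A categorical entrainment verdict with its supporting evidence."""

    verdict: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def _rebin_mean(series: np.ndarray, factor: int) -> np.ndarray:
    """Mean-rebin a (smoothed, float) series, dropping a partial tail bin."""
    n = len(series) // factor * factor
    return series[:n].reshape(-1, factor).mean(axis=1)


def classify_skeleton(
    table: ActivityTable,
    sg_params: SGParams = PRESETS["entrainment_gate"],
    periodogram_bin_minutes: int = 20,
    window_h: tuple[float, float] = PERIOD_WINDOW_H,
    alpha: float = 0.05,
    ch: int | None = None,
) -> EntrainmentCall:
    """Three-way period-window gate for step-function (skeleton/LD) data."""
    if table.duration_minutes < 6 * MINUTES_PER_DAY:
        raise ValueError("need at least 6 days of data")
    if table.bin_minutes != 1:
        raise ValueError("expects native 1-min tables (smoothing precedes binning)")
    sm = savitzky_golay(table.channel(ch), sg_params)
    binned = _rebin_mean(sm, periodogram_bin_minutes)
    # the significance line must reflect the autocorrelation the SG filter
    # induces, or smoothed noise reads as rhythmic
    rho = smoothed_lag_correlation(sg_params, rebin_factor=periodogram_bin_minutes)
    result = chi_square_periodogram(
        binned, periodogram_bin_minutes, alpha=alpha, lag_corr=rho
    )
    return _window_verdict(result, window_h)


def _window_verdict(
    result: PeriodogramResult, window_h: tuple[float, float]
) -> EntrainmentCall:
    peak = result.peak_period_h
    evidence = {
        "peak_period_h": peak,
        "rhythmic_power": result.rhythmic_power,
        "window_h": window_h,
    }
    if peak is None:
        verdict = "arrhythmic"
    elif window_h[0] <= peak <= window_h[1]:
        verdict = "entrained"
    else:
        verdict = "free_running"
    return EntrainmentCall(verdict=verdict, evidence=evidence)


@dataclass(frozen=True)
class RampCriteria:
    """Numeric thresholds operationalizing the ramped-cycle decision table."""

    period_window_h: tuple[float, float] = PERIOD_WINDOW_H
    wavelet_band_h: tuple[float, float] = WAVELET_BAND_H
    stable_from_cycle: int = 5  # 0-based: the sixth ramping cycle
    #: max |net peak-phase drift| per cycle for "stabilized"; ~2 sd of the
    #: slope estimator's noise for a locked fly at typical DAM count rates,
    #: and half the drift of a tau=25 h free-runner
    drift_max_min: float = 30.0
    ridge_power_min: float = 0.05  # variance-normalized wavelet ridge power
    alpha: float = 0.05


def _circ_diff_h(a: float, b: float) -> float:
    """Signed circular difference a - b in hours, in (-12, 12]."""
    d = (a - b) % 24.0
    return d - 24.0 if d > 12.0 else d


def _drift_slope_min(phases: list[float | None]) -> float:
    """Phase drift in min/cycle: OLS slope through unwrapped peak phases."""
    pts = [(i, p) for i, p in enumerate(phases) if p is not None]
    if len(pts) < 2:
        return float("nan")
    xs = np.array([i for i, _ in pts], dtype=float)
    unwrapped = [pts[0][1]]
    for (_, prev), (_, cur) in zip(pts[:-1], pts[1:]):
        unwrapped.append(unwrapped[-1] + _circ_diff_h(cur, prev))
    slope = np.polyfit(xs, np.array(unwrapped), 1)[0]
    return float(slope) * 60.0


def classify_ramp(
    table: ActivityTable,
    criteria: RampCriteria = RampCriteria(),
    sg_params: SGParams = PRESETS["ramp_peaks"],
    periodogram_bin_minutes: int = 20,
    wavelet_bin_minutes: int = 15,
    ch: int | None = None,
) -> EntrainmentCall:
    """Four-way ramped-cycle classification.

    Decision table (first match wins):

    1. *arrhythmic*: no significant periodogram peak AND no wavelet ridge
       (daily ridge power below threshold for most cycles);
    2. *entrained*: all daily wavelet periods from ``stable_from_cycle``
       onward inside the wavelet band, mean |peak-phase drift| over those
       cycles within ``drift_max_min``, and periodogram peak inside the
       period window;
    3. *free_running*: phase drift monotone in one direction (and larger
       than the stability threshold), or a significant periodogram peak
       outside the window;
    4. otherwise *relative_coordination*.
    """
    n_days = table.duration_minutes // MINUTES_PER_DAY
    if n_days < 9:
        raise ValueError("need at least 9 ramp cycles")
    series = table.channel(ch)

    binned20 = bin_activity(table, periodogram_bin_minutes).channel(ch)
    pgram = chi_square_periodogram(
        binned20, periodogram_bin_minutes, alpha=criteria.alpha
    )

    binned15 = bin_activity(table, wavelet_bin_minutes).channel(ch)
    spectrum = morlet_wavelet_spectrum(binned15, wavelet_bin_minutes)
    ridge = daily_ridge(spectrum)
    ridge_powers = [p for _, _, p in ridge]
    ridge_present = bool(ridge) and float(np.median(ridge_powers)) >= criteria.ridge_power_min

    # per-cycle dominant peak phases (15-min bins, SG(1,41), circular search)
    mat, _ = _split_series(binned15, wavelet_bin_minutes, table.zt0_offset,
                           int(table.timestamps[0]))
    phases: list[float | None] = []
    for day in mat:
        peaks = find_peaks(day, sg_params, bin_minutes=wavelet_bin_minutes,
                           circular=True)
        phases.append(peaks[0].zt_h if peaks else None)
    drifts = [
        _circ_diff_h(b, a)
        for a, b in zip(phases[:-1], phases[1:])
        if a is not None and b is not None
    ]
    # drift over the stabilized cycles: least-squares slope through the
    # unwrapped peak phases (robust to single-cycle peak jitter, unlike a
    # first-to-last difference)
    mean_late_drift_min = _drift_slope_min(phases[criteria.stable_from_cycle :])
    # drop the first inter-cycle drift (entrainment transients) before
    # judging directionality
    steady = drifts[1:]
    monotone = (
        len(steady) >= 3
        and (all(d > 0 for d in steady) or all(d < 0 for d in steady))
        and float(np.mean(np.abs(steady))) * 60.0 > criteria.drift_max_min
    )

    # the final daily estimate sits against the record edge, where the cone
    # of influence leaves little valid coverage at circadian periods; it is
    # excluded from the stability judgement
    last_daily = max((d for d, _, _ in ridge), default=-1)
    stable_dailies = [
        per for d, per, _ in ridge
        if criteria.stable_from_cycle <= d < last_daily
    ]
    band_ok = bool(stable_dailies) and all(
        criteria.wavelet_band_h[0] <= p <= criteria.wavelet_band_h[1]
        for p in stable_dailies
    )
    peak = pgram.peak_period_h
    peak_in_window = peak is not None and (
        criteria.period_window_h[0] <= peak <= criteria.period_window_h[1]
    )

    evidence = {
        "peak_period_h": peak,
        "rhythmic_power": pgram.rhythmic_power,
        "daily_periods_h": [(d, per) for d, per, _ in ridge],
        "ridge_power_median": float(np.median(ridge_powers)) if ridge_powers else 0.0,
        "ridge_present": ridge_present,
        "band_ok": band_ok,
        "mean_late_drift_min": mean_late_drift_min,
        "monotone_drift": bool(monotone),
        "n_peak_phases": sum(p is not None for p in phases),
    }

    if peak is None and not ridge_present:
        verdict = "arrhythmic"
    elif (
        band_ok
        and peak_in_window
        and np.isfinite(mean_late_drift_min)
        and abs(mean_late_drift_min) <= criteria.drift_max_min
    ):
        verdict = "entrained"
    elif monotone or (peak is not None and not peak_in_window):
        verdict = "free_running"
    else:
        verdict = "relative_coordination"
    return EntrainmentCall(verdict=verdict, evidence=evidence)


def is_rhythmic(call: EntrainmentCall) -> bool:
    """Clock-mutant reading: rhythmic = any periodogram peak or wavelet ridge."""
    ev = call.evidence
    return ev.get("peak_period_h") is not None or bool(ev.get("ridge_present"))


def cohort_summary(calls: list[EntrainmentCall]) -> dict[str, dict[str, float]]:
    """Verdict percentages (summing to 100 within rounding) with counts."""
    if not calls:
        raise ValueError("need at least one call")
    n = len(calls)
    out: dict[str, dict[str, float]] = {}
    for verdict in VERDICTS:
        count = sum(c.verdict == verdict for c in calls)
        if count:
            out[verdict] = {"count": count, "percent": 100.0 * count / n}
    return out


def calls_to_frame(calls: dict[int, EntrainmentCall]) -> pd.DataFrame:
    rows = []
    for fly, call in calls.items():
        ev = call.evidence
        rows.append(
            {
                "fly": fly,
                "verdict": call.verdict,
                "peak_period_h": ev.get("peak_period_h"),
                "rhythmic_power": ev.get("rhythmic_power"),
                "drift_min_per_cycle": ev.get("mean_late_drift_min"),
            }
        )
    return pd.DataFrame(rows)
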
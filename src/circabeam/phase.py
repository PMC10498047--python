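"""Activity-profile averaging and peak-phase extraction.

Entrained flies are summarized two ways: a cohort-average daily activity
profile (per-fly day-means first, then across-fly mean and s.e.m.), and
per-fly phases of activity peaks on smoothed data -- the evening peak under
skeleton photoperiods, the dominant peak under ramped cycles, and the
dominant peak on the first full day after release into constant conditions
(the phase-control measurement).

The evening peak is operationalized as the highest smoothed local maximum
inside a ZT06-ZT15 search window, with a startle guard excluding bins within
30 min after any discrete light transition; per-day phases over the last
five entrained days are combined by circular mean into one estimate per fly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _sp_find_peaks

from . import stats as cstats
from .damio import ActivityTable, MINUTES_PER_DAY, bin_activity, _split_series
from .light import LightRegime
from .smoothing import PRESETS, SGParams, savitzky_golay


@dataclass
class ActivityProfile:
    """Mean (+/- s.e.m.) daily activity profile across flies."""

    bin_minutes: int
    mean: np.ndarray
    sem: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        zt = np.arange(len(self.mean)) * self.bin_minutes
        return pd.DataFrame({"zt_min": zt, "mean": self.mean, "sem": self.sem})


@dataclass
class PhaseEstimate:
    """A peak phase in decimal ZT hours, [0, 24)."""

    zt_h: float
    height: float
    kind: str  # evening | dominant | release_day

    def __post_init__(self) -> None:
        self.zt_h = float(self.zt_h) % 24.0
        if self.height < 0:
            raise ValueError("height must be >= 0")


def average_profile(
    tables: list[ActivityTable],
    bin_minutes: int = 15,
    ch: int | None = None,
) -> ActivityProfile:
    """Cohort-mean daily profile: per-fly day-means, then across-fly stats."""
    if not tables:
        raise ValueError("need at least one fly")
    per_fly = []
    for t in tables:
        binned = bin_activity(t, bin_minutes) if t.bin_minutes != bin_minutes else t
        mat, _ = _split_series(
            binned.channel(ch), binned.bin_minutes, binned.zt0_offset,
            int(binned.timestamps[0]),
        )
        if mat.shape[0] == 0:
            raise ValueError("a table holds less than one complete ZT day")
        per_fly.append(mat.mean(axis=0))
    stack = np.vstack(per_fly)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(stack.shape[1])
    return ActivityProfile(
        bin_minutes=bin_minutes, mean=stack.mean(axis=0), sem=sem, n=n
    )


def find_peaks(
    series,
    sg_params: SGParams,
    bin_minutes: int = 1,
    start_zt_min: float = 0.0,
    kind: str = "dominant",
    prominence_frac: float = 0.05,
    circular: bool = False,
) -> list[PhaseEstimate]:
    """Local maxima of the SG-smoothed series, tallest first.

    Prominence must exceed ``prominence_frac`` of the smoothed range; a flat
    series yields no peaks.  With ``circular=True`` the series is treated as
    one wrapped 24 h cycle so boundary peaks are found.
    """
    x = np.asarray(series, dtype=float)
    if circular:
        sm_ext = savitzky_golay(np.tile(x, 3), sg_params)
        sm = sm_ext[len(x) : 2 * len(x)]
        search = sm_ext
        offset = len(x)
    else:
        sm = savitzky_golay(x, sg_params)
        search = sm
        offset = 0
    rng = float(np.ptp(sm))
    if rng == 0:
        return []
    idx, props = _sp_find_peaks(search, prominence=prominence_frac * rng)
    if circular:
        keep = (idx >= offset) & (idx < 2 * len(x))
        idx = idx[keep] - offset
    heights = sm[idx]
    order = np.argsort(-heights)
    out = []
    for i in order:
        zt_h = ((start_zt_min + idx[i] * bin_minutes) / 60.0) % 24.0
        out.append(PhaseEstimate(zt_h=zt_h, height=max(0.0, heights[i]), kind=kind))
    return out


def _guard_mask(day_zt_min: np.ndarray, regime: LightRegime | None,
                guard_min: float) -> np.ndarray:
    """True where a bin falls within ``guard_min`` after a discrete transition."""
    if regime is None:
        return np.zeros(len(day_zt_min), dtype=bool)
    mask = np.zeros(len(day_zt_min), dtype=bool)
    for zt, _ in regime.transitions():
        d = (day_zt_min - zt) % MINUTES_PER_DAY
        mask |= d < guard_min
    return mask


def evening_peak_phase(
    table: ActivityTable,
    regime: LightRegime | None = None,
    sg_params: SGParams = PRESETS["peak_finding"],
    window_h: tuple[float, float] = (6.0, 15.0),
    guard_min: float = 30.0,
    last_days: int = 5,
    ch: int | None = None,
) -> PhaseEstimate | None:
    """Per-fly evening peak phase under an entraining cycle.

    The raw series is SG-smoothed, split into complete ZT days, and for each
    of the last ``last_days`` days the tallest local maximum inside the
    evening window (excluding the post-transition startle guard) is taken;
    the per-day phases are circular-averaged.  Returns None when no day has
    a qualifying peak (e.g. an arrhythmic fly with a flat smoothed profile).
    """
    sm = savitzky_golay(table.channel(ch), sg_params)
    mat, _ = _split_series(sm, table.bin_minutes, table.zt0_offset,
                           int(table.timestamps[0]))
    if mat.shape[0] == 0:
        raise ValueError("need at least one complete ZT day")
    day_zt = np.arange(mat.shape[1]) * table.bin_minutes
    guarded = _guard_mask(day_zt.astype(float), regime, guard_min)
    in_window = (day_zt >= window_h[0] * 60) & (day_zt <= window_h[1] * 60)
    phases: list[float] = []
    heights: list[float] = []
    for day in mat[-last_days:]:
        rng = float(np.ptp(day))
        if rng == 0:
            continue
        idx, _ = _sp_find_peaks(day, prominence=0.05 * rng)
        idx = [i for i in idx if in_window[i] and not guarded[i]]
        if not idx:
            continue
        best = max(idx, key=lambda i: day[i])
        phases.append(day_zt[best] / 60.0)
        heights.append(float(day[best]))
    if not phases:
        return None
    mean_zt = cstats.angle_to_zt(cstats.circ_mean(cstats.zt_to_angle(phases)))
    return PhaseEstimate(zt_h=float(mean_zt), height=float(np.mean(heights)),
                         kind="evening")


def release_day_phase(
    table: ActivityTable,
    release_start_min: int,
    sg_params: SGParams = PRESETS["ramp_peaks"],
    bin_minutes: int = 15,
    ch: int | None = None,
) -> PhaseEstimate | None:
    """Dominant peak on the first full ZT cycle after release.

    The release-day data are binned (default 15 min), SG(1, 41)-smoothed and
    searched circularly for the dominant peak.  Returns None for a flat
    (arrhythmic) day.
    """
    if table.bin_minutes != 1:
        raise ValueError("expects native 1-min tables")
    lead = (table.zt0_offset - int(table.timestamps[0])) % MINUTES_PER_DAY
    first_zt00 = release_start_min + ((lead - release_start_min) % MINUTES_PER_DAY)
    if table.n_bins < first_zt00 + MINUTES_PER_DAY:
        raise ValueError("need at least one full day after release")
    day = table.channel(ch)[first_zt00 : first_zt00 + MINUTES_PER_DAY]
    binned = day.reshape(-1, bin_minutes).sum(axis=1)
    peaks = find_peaks(
        binned, sg_params, bin_minutes=bin_minutes, start_zt_min=0.0,
        kind="release_day", circular=True,
    )
    return peaks[0] if peaks else None


def phases_to_csv(estimates: dict[int, PhaseEstimate | None], path) -> None:
    """CSV of per-fly phases (fly id, kind, zt_h, height)."""
    rows = []
    for fly, est in estimates.items():
        if est is None:
            rows.append({"fly": fly, "kind": "absent", "zt_h": np.nan,
                         "height": np.nan})
        else:
            rows.append({"fly": fly, "kind": est.kind, "zt_h": est.zt_h,
                         "height": est.height})
    pd.DataFrame(rows).to_csv(path, index=False)
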
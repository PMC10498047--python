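"""Light regimes as piecewise intensity-vs-ZT functions.

Every schedule used in the analysis chain is represented here: full
photoperiods (LD12:12), skeleton photoperiods in which the photoperiod is
replaced by brief pulses marking dawn and dusk (SPP, and the asymmetric
aSPP-1 / aSPP-2 variants with a 6 h light block contiguous with dawn or
dusk), ramped cycles that rise linearly from a non-zero nadir at ZT00 to a
peak at ZT12 and fall back by ZT24, and the constant conditions LL and DD.

A regime is a tiling of the 1440-minute cycle by segments with constant or
linear intensity.  Discrete transitions (used by the startle model of the
simulator) are enumerable; a ramp has none by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

#: Display-only conversion for the broad-spectrum white source:
#: 400-500 lux corresponds to roughly 228-285 uW/cm^2, i.e. ~0.57 uW/cm^2
#: per lux.  Units are otherwise carried as labels and never converted.
UW_CM2_PER_LUX = 0.57

KINDS = ("LD", "SPP", "aSPP1", "aSPP2", "RAMP", "LL", "DD")


@dataclass(frozen=True)
class Segment:
    """One piece of the cycle; intensity is linear from start to end."""

    start_min: float
    end_min: float
    i_start: float
    i_end: float

    def intensity(self, zt_min):
        zt = np.asarray(zt_min, dtype=float)
        if self.i_start == self.i_end:
            return np.full_like(zt, self.i_start)
        frac = (zt - self.start_min) / (self.end_min - self.start_min)
        return self.i_start + frac * (self.i_end - self.i_start)


@dataclass(frozen=True)
class LightRegime:
    kind: str
    segments: tuple[Segment, ...]
    units: str = "uW_cm2"
    period_minutes: int = MINUTES_PER_DAY

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        pos = 0.0
        for seg in self.segments:
            if seg.start_min != pos:
                raise ValueError("segments must tile the cycle without gaps")
            if seg.end_min <= seg.start_min:
                raise ValueError("segments must have positive length")
            if min(seg.i_start, seg.i_end) < 0:
                raise ValueError("intensities must be >= 0")
            pos = seg.end_min
        if pos != self.period_minutes:
            raise ValueError("segments must cover the full cycle")
        if self.kind == "RAMP" and any(
            min(s.i_start, s.i_end) <= 0 for s in self.segments
        ):
            raise ValueError("a ramped cycle has no zero-intensity point")

    # -- evaluation ------------------------------------------------------------

    def intensity_at(self, zt_min):
        """Intensity at ZT minute(s), wrapped modulo the cycle."""
        zt = np.asarray(zt_min, dtype=float) % self.period_minutes
        out = np.empty_like(zt)
        for seg in self.segments:
            m = (zt >= seg.start_min) & (zt < seg.end_min)
            if np.any(m):
                out[m] = seg.intensity(zt[m])
        return float(out) if np.isscalar(zt_min) else out

    def transitions(self) -> list[tuple[float, float]]:
        """Discontinuities once per cycle as (zt_min, signed jump)."""
        out: list[tuple[float, float]] = []
        n = len(self.segments)
        for i, seg in enumerate(self.segments):
            prev = self.segments[(i - 1) % n]
            jump = seg.i_start - prev.i_end
            if jump != 0:
                out.append((seg.start_min % self.period_minutes, jump))
        return sorted(out)

    def mean_intensity(self) -> float:
        """Cycle-average intensity (exact trapezoid over the segments)."""
        area = sum(
            0.5 * (s.i_start + s.i_end) * (s.end_min - s.start_min)
            for s in self.segments
        )
        return area / self.period_minutes

    def min_intensity(self) -> float:
        return min(min(s.i_start, s.i_end) for s in self.segments)

    def max_intensity(self) -> float:
        return max(max(s.i_start, s.i_end) for s in self.segments)

    def intensity_trace(self, bin_minutes: int = 1) -> np.ndarray:
        """Intensity sampled at each bin start over one cycle."""
        zt = np.arange(0, self.period_minutes, bin_minutes, dtype=float)
        return self.intensity_at(zt)

    def to_csv(self, path, bin_minutes: int = 1) -> None:
        zt = np.arange(0, self.period_minutes, bin_minutes)
        pd.DataFrame(
            {"zt_min": zt, "intensity": self.intensity_trace(bin_minutes)}
        ).to_csv(path, index=False)


def _tile(light_windows: list[tuple[float, float]], intensity: float) -> tuple[Segment, ...]:
    """Constant-intensity pulses on a dark background."""
    segs: list[Segment] = []
    pos = 0.0
    for start, end in sorted(light_windows):
        if start > pos:
            segs.append(Segment(pos, start, 0.0, 0.0))
        segs.append(Segment(start, end, intensity, intensity))
        pos = end
    if pos < MINUTES_PER_DAY:
        segs.append(Segment(pos, MINUTES_PER_DAY, 0.0, 0.0))
    return tuple(segs)


def build_regime(kind: str, params: dict | None = None) -> LightRegime:
    """Construct a named regime.

    Parameters by kind (all intensities in the regime's unit label):

    - ``LD``: ``intensity`` (light ZT00-12).
    - ``SPP``: ``intensity``; 30 min pulses starting at dawn (ZT00:00-00:30)
      and ending at dusk (ZT11:30-12:00).
    - ``aSPP1``: ``intensity``; 6 h dawn block ZT00-06 plus the 30 min pulse
      ending at dusk.
    - ``aSPP2``: ``intensity``; 30 min pulse starting at dawn plus a 6 h dusk
      block ZT06-12.
    - ``RAMP``: ``i_min`` (> 0), ``i_max``; linear rise ZT00->ZT12 and fall
      ZT12->ZT24.  Optional ``steps`` quantizes the ramp into that many equal
      stairs per half-cycle (for incubators that approximate ramps).
    - ``LL``: ``intensity``; ``DD``: none.
    """
    params = dict(params or {})
    units = params.pop("units", "uW_cm2")
    if kind == "LD":
        segs = _tile([(0, 720)], float(params["intensity"]))
    elif kind == "SPP":
        i = float(params["intensity"])
        segs = _tile([(0, 30), (690, 720)], i)
    elif kind == "aSPP1":
        i = float(params["intensity"])
        segs = _tile([(0, 360), (690, 720)], i)
    elif kind == "aSPP2":
        i = float(params["intensity"])
        segs = _tile([(0, 30), (360, 720)], i)
    elif kind == "RAMP":
        i_min = float(params["i_min"])
        i_max = float(params["i_max"])
        if i_min <= 0:
            raise ValueError("RAMP requires i_min > 0 (no darkness in the cycle)")
        steps = params.get("steps")
        if steps:
            segs = _stepped_ramp(i_min, i_max, int(steps))
        else:
            segs = (
                Segment(0, 720, i_min, i_max),
                Segment(720, MINUTES_PER_DAY, i_max, i_min),
            )
    elif kind == "LL":
        i = float(params["intensity"])
        segs = (Segment(0, MINUTES_PER_DAY, i, i),)
    elif kind == "DD":
        segs = (Segment(0, MINUTES_PER_DAY, 0.0, 0.0),)
    else:
        raise ValueError(f"unknown regime kind {kind!r}")
    return LightRegime(kind=kind, segments=segs, units=units)


def _stepped_ramp(i_min: float, i_max: float, steps: int) -> tuple[Segment, ...]:
    """Stair-quantized approximation of the linear ramp (config option)."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    edges_up = np.linspace(0, 720, steps + 1)
    # step level = linear ramp value at the step midpoint, so the cycle mean
    # matches the continuous ramp
    segs: list[Segment] = []
    for a, b in zip(edges_up[:-1], edges_up[1:]):
        lev = i_min + (i_max - i_min) * ((a + b) / 2) / 720
        segs.append(Segment(a, b, lev, lev))
    edges_dn = np.linspace(720, MINUTES_PER_DAY, steps + 1)
    for a, b in zip(edges_dn[:-1], edges_dn[1:]):
        lev = i_max - (i_max - i_min) * ((a + b) / 2 - 720) / 720
        segs.append(Segment(a, b, lev, lev))
    return tuple(segs)


def intensity_at(regime: LightRegime, zt_min):
    """Module-level alias for :meth:`LightRegime.intensity_at`."""
    return regime.intensity_at(zt_min)


def transitions(regime: LightRegime):
    """Module-level alias for :meth:`LightRegime.transitions`."""
    return regime.transitions()
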
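"""Ground-truth simulator: a phase-oscillator fly with light action, masking,
startle and Poisson count emission.

Each simulated fly carries a circadian phase ``phi`` (hours on the 24 h
circle) advanced by a phase-only oscillator with intrinsic period ``tau``:

    dphi = dt * (24/tau) * (1 + eps_p * g(phi) * I_norm)

The velocity-response curve g(phi) = cos(2*pi*phi/24) encodes the continuous
(parametric) action of light: maximal clock acceleration at subjective dawn
(phi = 0), maximal deceleration at subjective dusk (phi = 12), zero mean.
Under constant light this yields the classic period lengthening
T = tau / sqrt(1 - (eps_p * I_norm)^2), monotone in both the parametric gain
and the intensity.  Discrete light-on transitions can additionally trigger
instantaneous (non-parametric) phase jumps through a delay-advance phase
response curve prc(phi) = sin(2*pi*(phi - 18)/24): delays in the early
subjective night, advances in the late subjective night and at dawn.

Activity counts are emitted as an inhomogeneous Poisson process at 1-min
resolution with rate

    rate = base_rate * waveform(phi) * exp(-mask_coeff * I_norm)
           + startle_amp * exp(-t_since_transition / startle_decay_min)

where the waveform is a two-bump (morning/evening) von Mises mixture, the
exponential masking term suppresses activity under bright light, and the
startle term fires within an hour of any discrete light transition.  Fly
categories are configured through :class:`FlySpec` presets: phase-locked
entrained flies, parametric oscillators, free-runners, relative coordination
(a gain too small to lock), arrhythmic flies and pure maskers whose activity
tracks light only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .damio import ActivityTable, MINUTES_PER_DAY, write_monitor_file
from .light import LightRegime

MODES = (
    "entrained_locked",
    "oscillator",
    "free_running",
    "relative_coordination",
    "arrhythmic",
    "masker",
)

#: window after a discrete transition during which the startle term applies
STARTLE_WINDOW_MIN = 60.0


@dataclass
class FlySpec:
    """Ground-truth parameters for one simulated fly."""

    mode: str = "entrained_locked"
    tau_h: float = 24.0
    psi0_h: float = 0.0
    eps_p: float = 0.0  # parametric (velocity-modulation) gain
    prc_amp_h: float = 0.0  # non-parametric transition-jump amplitude
    bump_centers_h: tuple[float, float] = (0.5, 11.0)
    bump_kappa: tuple[float, float] = (3.0, 5.0)
    bump_weights: tuple[float, float] = (0.5, 1.0)
    waveform_baseline: float = 0.15
    startle_amp: float = 8.0  # counts/min at the transition
    startle_decay_min: float = 4.0
    mask_coeff: float = 0.0
    base_rate: float = 2.0  # counts/min scale
    #: optional alternating intrinsic period: tau switches to ``tau_alt_h``
    #: every ``alt_every_cycles`` cycles (unstable, relatively coordinated
    #: rhythms with period segments on either side of 24 h)
    tau_alt_h: float | None = None
    alt_every_cycles: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be positive")
        if self.base_rate < 0 or min(self.bump_weights) < 0:
            raise ValueError("rates and weights must be >= 0")
        if self.mask_coeff < 0:
            raise ValueError("mask_coeff must be >= 0")


# -- spec presets (the simulated fly categories) -------------------------------


def entrained_locked_spec(seed: int = 0, psi0_h: float = 0.0, **kw) -> FlySpec:
    """A fly locked to the zeitgeber: exactly 24 h clock, no light action."""
    return FlySpec(mode="entrained_locked", tau_h=24.0, psi0_h=psi0_h,
                   seed=seed, **kw)


def free_running_spec(tau_h: float, seed: int = 0, **kw) -> FlySpec:
    """A clock blind to light: free-runs at its intrinsic period."""
    return FlySpec(mode="free_running", tau_h=tau_h, seed=seed, **kw)


def oscillator_spec(
    tau_h: float = 24.5, eps_p: float = 0.3, seed: int = 0, **kw
) -> FlySpec:
    """A parametric oscillator; with the default gain it locks to 24 h cycles."""
    return FlySpec(mode="oscillator", tau_h=tau_h, eps_p=eps_p, seed=seed, **kw)


def relative_coordination_spec(
    tau_h: float = 25.0, eps_p: float = 0.08, seed: int = 0, **kw
) -> FlySpec:
    """Gain too small to lock |tau - 24|: the period wavers around 24 h."""
    return FlySpec(mode="relative_coordination", tau_h=tau_h, eps_p=eps_p,
                   seed=seed, **kw)


def alternating_spec(
    tau_a_h: float = 23.5,
    tau_b_h: float = 24.6,
    every_cycles: int = 3,
    seed: int = 0,
    **kw,
) -> FlySpec:
    """Unstable rhythm whose period alternates across 24 h (relative
    coordination as period segments on either side of the zeitgeber)."""
    return FlySpec(
        mode="relative_coordination", tau_h=tau_a_h, tau_alt_h=tau_b_h,
        alt_every_cycles=every_cycles, seed=seed, **kw,
    )


def arrhythmic_spec(seed: int = 0, **kw) -> FlySpec:
    """No circadian modulation of activity (clock-output mutant-like)."""
    return FlySpec(mode="arrhythmic", seed=seed, **kw)


def masker_spec(mask_coeff: float = 1.5, seed: int = 0, **kw) -> FlySpec:
    """Activity tracks light only (bright-light avoidance; per01-like)."""
    return FlySpec(mode="masker", mask_coeff=mask_coeff, seed=seed, **kw)


# -- model primitives ----------------------------------------------------------


def velocity_response(phi_h):
    """g(phi): acceleration at subjective dawn, deceleration at dusk."""
    return np.cos(2 * np.pi * np.asarray(phi_h, dtype=float) / 24.0)


def phase_response(phi_h):
    """prc(phi): delay in early subjective night, advance in late night."""
    return np.sin(2 * np.pi * (np.asarray(phi_h, dtype=float) - 18.0) / 24.0)


def advance_phase(phi_h: float, i_norm: float, dt_min: float, spec: FlySpec) -> float:
    """Advance the oscillator phase by one step of ``dt_min`` minutes."""
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    dphi = (dt_min / 60.0) * (24.0 / spec.tau_h) * (
        1.0 + spec.eps_p * float(velocity_response(phi_h)) * i_norm
    )
    return (phi_h + dphi) % 24.0


def transition_jump(phi_h: float, d_intensity: float, spec: FlySpec) -> float:
    """Instantaneous phase jump at a discrete light transition.

    Only lights-on steps (positive jumps) reset the clock; the jump is
    ``prc_amp_h * prc(phi)`` hours.  A zero amplitude is a no-op.
    """
    if d_intensity == 0:
        raise ValueError("d_intensity must be non-zero at a transition")
    if spec.prc_amp_h == 0 or d_intensity < 0:
        return phi_h % 24.0
    return (phi_h + spec.prc_amp_h * float(phase_response(phi_h))) % 24.0


def activity_waveform(phi_h, spec: FlySpec):
    """Two-bump circadian activity waveform; flat for arrhythmic/masker."""
    phi = np.asarray(phi_h, dtype=float)
    if spec.mode in ("arrhythmic", "masker"):
        return np.ones_like(phi)
    out = np.full_like(phi, spec.waveform_baseline)
    for c, k, w in zip(spec.bump_centers_h, spec.bump_kappa, spec.bump_weights):
        out = out + w * np.exp(k * (np.cos(2 * np.pi * (phi - c) / 24.0) - 1.0))
    return out


def emission_rate(phi_h, i_norm, t_since_transition_min, spec: FlySpec):
    """Expected counts/min given phase, light and time since a transition."""
    rate = (
        spec.base_rate
        * activity_waveform(phi_h, spec)
        * np.exp(-spec.mask_coeff * np.asarray(i_norm, dtype=float))
    )
    tst = np.asarray(t_since_transition_min, dtype=float)
    startle = np.where(
        tst < STARTLE_WINDOW_MIN,
        spec.startle_amp * np.exp(-tst / spec.startle_decay_min),
        0.0,
    )
    return rate + startle


# -- simulation ----------------------------------------------------------------


def _intensity_minutes(
    regime: LightRegime, days: int, release_after: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute intensity and time-since-transition arrays.

    With ``release_after`` set, cycles from that index onward run at constant
    light equal to the regime's minimum (nadir-release protocol).
    """
    day_trace = regime.intensity_trace(1)
    n = days * MINUTES_PER_DAY
    intensity = np.tile(day_trace, days)[:n]
    trans = regime.transitions()
    if release_after is not None and release_after < days:
        nadir = regime.min_intensity()
        intensity[release_after * MINUTES_PER_DAY :] = nadir
    tst = np.full(n, np.inf)
    last = -np.inf
    trans_min = {int(zt): dI for zt, dI in trans}
    for t in range(n):
        day = t // MINUTES_PER_DAY
        if release_after is not None and day >= release_after:
            pass  # constant light: no further transitions
        elif (t % MINUTES_PER_DAY) in trans_min:
            last = t
        tst[t] = t - last
    return intensity, tst


def simulate_fly(
    spec: FlySpec,
    regime: LightRegime,
    days: int,
    seed: int | None = None,
    release_after: int | None = None,
    burnin_days: int = 0,
) -> tuple[ActivityTable, dict]:
    """Simulate one fly; returns its table and a ground-truth record.

    ``burnin_days`` advances the oscillator under the regime before counts
    are recorded, emulating rearing under the entraining cycle (so flies
    enter the recording at their steady-state phase relationship).
    ``release_after`` (in recorded cycles) switches the light to a constant
    at the regime's minimum -- the nadir-release protocol.  The truth record
    stores the mode, intrinsic period, seed and the realized clock phase at
    each recorded ZT00.  Identical seeds give bit-identical tables.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    total_days = burnin_days + days
    n_total = total_days * MINUTES_PER_DAY
    skip = burnin_days * MINUTES_PER_DAY
    release_total = None if release_after is None else burnin_days + release_after
    intensity, tst = _intensity_minutes(regime, total_days, release_total)
    i_max = float(intensity.max())
    i_norm = intensity / i_max if i_max > 0 else np.zeros(n_total)
    trans_min = {int(zt): dI for zt, dI in regime.transitions()}

    parametric = spec.eps_p != 0.0
    jumping = spec.prc_amp_h != 0.0 and bool(trans_min)
    alternating = spec.tau_alt_h is not None
    if not parametric and not jumping and not alternating:
        phases = (
            spec.psi0_h + np.arange(n_total) * (24.0 / spec.tau_h) / 60.0
        ) % 24.0
    else:
        spec_alt = replace(spec, tau_h=spec.tau_alt_h) if alternating else spec
        phases = np.empty(n_total)
        phi = spec.psi0_h % 24.0
        for t in range(n_total):
            day = t // MINUTES_PER_DAY
            released = release_total is not None and day >= release_total
            day_spec = (
                spec_alt
                if alternating and (day // spec.alt_every_cycles) % 2 == 1
                else spec
            )
            if jumping and not released and (t % MINUTES_PER_DAY) in trans_min:
                phi = transition_jump(phi, trans_min[t % MINUTES_PER_DAY], day_spec)
            phases[t] = phi
            phi = advance_phase(phi, float(i_norm[t]), 1.0, day_spec)
    phases = phases[skip:]
    i_norm = i_norm[skip:]
    tst = tst[skip:]
    rates = emission_rate(phases, i_norm, tst, spec)
    counts = rng.poisson(rates)
    table = ActivityTable(
        timestamps=np.arange(days * MINUTES_PER_DAY, dtype=np.int64),
        counts={1: counts},
        bin_minutes=1,
        zt0_offset=0,
    )
    truth = {
        "mode": spec.mode,
        "tau_h": spec.tau_h,
        "eps_p": spec.eps_p,
        "seed": int(seed),
        "phase_at_zt00": [float(phases[d * MINUTES_PER_DAY]) for d in range(days)],
    }
    return table, truth


@dataclass
class CohortSpec:
    """A cohort of fly specs recorded together under one regime."""

    flies: list[FlySpec]
    regime: LightRegime
    days: int = 10
    release_after: int | None = None
    burnin_days: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not self.flies:
            raise ValueError("flies must be non-empty")


def _fly_seed(base_seed: int, index: int) -> int:
    # deterministic per-fly seed, kept below 2**31 for portability
    return int((base_seed * 100_003 + 7919 * index + 1) % (2**31 - 1))


def simulate_cohort(
    cohort: CohortSpec,
    base_seed: int = 0,
    out_dir=None,
) -> dict:
    """Simulate a cohort; optionally serialize monitor files and a truth CSV.

    Monitor files hold up to 32 flies each (the DAM channel count); the truth
    table lists one row per fly (file, channel, mode, tau, seed).  Returns a
    dict with ``tables``, ``truths`` and, when ``out_dir`` is given,
    ``monitor_files`` and ``truth_csv`` paths.
    """
    tables: list[ActivityTable] = []
    truths: list[dict] = []
    for i, spec in enumerate(cohort.flies):
        seed = _fly_seed(base_seed, i)
        spec = replace(spec, seed=seed)
        table, truth = simulate_fly(
            spec, cohort.regime, cohort.days, seed=seed,
            release_after=cohort.release_after,
            burnin_days=cohort.burnin_days,
        )
        truth["fly"] = i
        truth["monitor"] = i // 32
        truth["channel"] = i % 32 + 1
        tables.append(table)
        truths.append(truth)
    result: dict = {"tables": tables, "truths": truths}
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for m in range(0, len(tables), 32):
            group = tables[m : m + 32]
            merged = ActivityTable(
                timestamps=group[0].timestamps,
                counts={j + 1: t.channel(1) for j, t in enumerate(group)},
                bin_minutes=1,
                zt0_offset=0,
            )
            path = out / f"Monitor{m // 32 + 1}.txt"
            write_monitor_file(merged, path)
            paths.append(path)
        truth_csv = out / "truth.csv"
        pd.DataFrame(
            [
                {k: v for k, v in t.items() if k != "phase_at_zt00"}
                for t in truths
            ]
        ).to_csv(truth_csv, index=False)
        result["monitor_files"] = paths
        result["truth_csv"] = truth_csv
    return result
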
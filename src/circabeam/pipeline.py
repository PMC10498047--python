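"""Config-driven orchestration of the three experiment analyses.

Three presets mirror the experimental designs the package serves:

- ``skeleton``: entrainment gate under step-function cycles (LD / skeleton
  photoperiods), entrained-only average profiles, evening-peak phases and
  Kruskal-Wallis comparisons across light regimes;
- ``ll_period``: free-running period and rhythmic power under constant
  conditions, DD-vs-LL Wilcoxon comparison and, with three or more
  intensities, the 4PL dose-response fit with its flat-line ANOVA;
- ``ramp``: four-way classification under ramped light cycles, entrained-only
  profiles, dominant-peak phases, and phase control (V-test) against
  release-day phases when a nadir release is part of the design.

A run consumes either recorded monitor files or a declarative simulation
spec, and writes a diffable directory bundle (CSV + JSON [+ PNG]); the full
resolved configuration, including every seed, is embedded in the bundle so a
rerun reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import stats as cstats
from .classify import (
    EntrainmentCall,
    calls_to_frame,
    classify_ramp,
    classify_skeleton,
    cohort_summary,
    is_rhythmic,
)
from .damio import ActivityTable, MINUTES_PER_DAY, read_monitor_file, split_days
from .light import LightRegime, build_regime
from .phase import (
    average_profile,
    evening_peak_phase,
    find_peaks,
    release_day_phase,
)
from .rhythm import chi_square_periodogram
from .smoothing import PRESETS
from .synth import (
    CohortSpec,
    FlySpec,
    alternating_spec,
    arrhythmic_spec,
    entrained_locked_spec,
    free_running_spec,
    masker_spec,
    oscillator_spec,
    relative_coordination_spec,
    simulate_cohort,
)

log = logging.getLogger("circabeam")

_FLY_PRESETS = {
    "entrained_locked": entrained_locked_spec,
    "oscillator": oscillator_spec,
    "free_running": free_running_spec,
    "relative_coordination": relative_coordination_spec,
    "alternating": alternating_spec,
    "arrhythmic": arrhythmic_spec,
    "masker": masker_spec,
}

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """One analysis run: exactly one input source plus a preset."""

    preset: str  # skeleton | ll_period | ramp
    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    monitor_files: list[str] | None = None
    zt0_offset: int = 0
    regime: dict | None = None  # for monitor-file input: {kind, params}
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset not in ("skeleton", "ll_period", "ramp"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if (self.simulate is None) == (self.monitor_files is None):
            raise ValueError("provide exactly one of simulate / monitor_files")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _build_flies(entries: list[dict]) -> list[FlySpec]:
    flies: list[FlySpec] = []
    for entry in entries:
        entry = dict(entry)
        preset = entry.pop("preset")
        n = int(entry.pop("n", 1))
        factory = _FLY_PRESETS[preset]
        for _ in range(n):
            flies.append(factory(**entry))
    return flies


def _load_cohorts(config: RunConfig) -> dict[str, dict]:
    """Label -> {tables, regime, truths?, release_after, days}."""
    cohorts: dict[str, dict] = {}
    if config.simulate is not None:
        for label, spec in config.simulate["cohorts"].items():
            regime = build_regime(
                spec["regime"]["kind"], spec["regime"].get("params")
            )
            cohort = CohortSpec(
                flies=_build_flies(spec["flies"]),
                regime=regime,
                days=int(spec.get("days", 10)),
                release_after=spec.get("release_after"),
                burnin_days=int(spec.get("burnin_days", 0)),
            )
            log.info("simulating cohort %s (%d flies)", label, len(cohort.flies))
            bundle = simulate_cohort(cohort, base_seed=config.seed)
            cohorts[label] = {
                "tables": bundle["tables"],
                "truths": bundle["truths"],
                "regime": regime,
                "release_after": spec.get("release_after"),
                "days": cohort.days,
            }
    else:
        regime = (
            build_regime(config.regime["kind"], config.regime.get("params"))
            if config.regime
            else None
        )
        tables: list[ActivityTable] = []
        for path in config.monitor_files:
            full = read_monitor_file(path, zt0_offset=config.zt0_offset)
            for ch in full.channels:
                arr = full.counts[ch]
                if arr.sum() == 0:
                    continue  # empty channel (no fly loaded)
                tables.append(
                    ActivityTable(
                        timestamps=full.timestamps,
                        counts={1: arr},
                        bin_minutes=1,
                        zt0_offset=config.zt0_offset,
                    )
                )
        cohorts["recorded"] = {
            "tables": tables,
            "truths": None,
            "regime": regime,
            "release_after": config.params.get("release_after"),
            "days": tables[0].duration_minutes // MINUTES_PER_DAY if tables else 0,
        }
    return cohorts


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pathlib.Path):
        return str(o)
    raise TypeError(f"cannot serialize {type(o)}")


def _prepare_out(config: RunConfig) -> pathlib.Path:
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(config.resolved(), out / "config.json")
    return out


# -- skeleton ------------------------------------------------------------------


def run_skeleton_analysis(config: RunConfig) -> dict:
    """Entrainment gate, entrained-only profiles, evening phases, KW letters."""
    out = _prepare_out(config)
    cohorts = _load_cohorts(config)
    report: dict = {"preset": "skeleton", "cohorts": {}, "warnings": []}
    phase_groups: dict[str, list[float]] = {}
    verdict_frames = []
    for label, data in cohorts.items():
        tables, regime = data["tables"], data["regime"]
        calls: dict[int, EntrainmentCall] = {}
        for i, t in enumerate(tables):
            calls[i] = classify_skeleton(t)
        summary = cohort_summary(list(calls.values()))
        entrained_idx = [i for i, c in calls.items() if c.verdict == "entrained"]
        log.info("%s: %d/%d entrained", label, len(entrained_idx), len(tables))
        frame = calls_to_frame(calls)
        frame.insert(0, "cohort", label)
        verdict_frames.append(frame)
        section: dict = {"summary": summary, "n": len(tables)}
        if entrained_idx:
            profile = average_profile([tables[i] for i in entrained_idx])
            pf = profile.to_frame()
            pf.insert(0, "cohort", label)
            section["profile_rows"] = len(pf)
            pf.to_csv(out / f"profile_{label}.csv", index=False,
                      float_format=_CSV_FLOAT)
            phases = []
            for i in entrained_idx:
                est = evening_peak_phase(tables[i], regime)
                if est is not None:
                    phases.append({"cohort": label, "fly": i, "zt_h": est.zt_h,
                                   "height": est.height})
            if phases:
                phase_groups[label] = [p["zt_h"] for p in phases]
                pd.DataFrame(phases).to_csv(
                    out / f"evening_phases_{label}.csv", index=False,
                    float_format=_CSV_FLOAT,
                )
                section["median_evening_phase_h"] = float(
                    np.median(phase_groups[label])
                )
        else:
            msg = f"cohort {label}: no entrained flies; profile section empty"
            log.warning(msg)
            report["warnings"].append(msg)
        report["cohorts"][label] = section
    pd.concat(verdict_frames, ignore_index=True).to_csv(
        out / "verdicts.csv", index=False, float_format=_CSV_FLOAT
    )
    if len(phase_groups) >= 2:
        h, p, letters = cstats.kruskal_with_letters(
            {k: np.asarray(v) for k, v in phase_groups.items()}
        )
        report["kruskal"] = {"H": h, "p": p, "letters": letters}
    _write_json(report, out / "summary.json")
    return report


# -- constant-light periods ----------------------------------------------------


def _fly_period_power(table: ActivityTable) -> tuple[float | None, float]:
    from .damio import bin_activity

    binned = bin_activity(table, 20).channel(None)
    res = chi_square_periodogram(binned, 20)
    return res.peak_period_h, res.rhythmic_power


def run_ll_period_analysis(config: RunConfig) -> dict:
    """Per-fly periods/powers, DD-vs-LL Wilcoxon, dose-response ANOVA."""
    out = _prepare_out(config)
    cohorts = _load_cohorts(config)
    report: dict = {"preset": "ll_period", "cohorts": {}, "warnings": []}
    rows = []
    for label, data in cohorts.items():
        if data["days"] < 10:
            raise ValueError(f"cohort {label}: need >= 10 days under constant conditions")
        periods, powers = [], []
        for i, t in enumerate(data["tables"]):
            per, pw = _fly_period_power(t)
            rows.append({"cohort": label, "fly": i, "period_h": per, "power": pw})
            if per is not None:
                periods.append(per)
                powers.append(pw)
        intensity = (
            data["regime"].max_intensity() if data["regime"] is not None else np.nan
        )
        report["cohorts"][label] = {
            "n": len(data["tables"]),
            "n_rhythmic": len(periods),
            "median_period_h": float(np.median(periods)) if periods else None,
            "median_power": float(np.median(powers)) if powers else None,
            "intensity": float(intensity),
        }
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "periods.csv", index=False, float_format=_CSV_FLOAT)

    by_label = {
        label: frame[(frame.cohort == label) & frame.period_h.notna()]
        .period_h.to_numpy()
        for label in report["cohorts"]
    }
    dd = config.params.get("dd_label", "DD")
    ll = config.params.get("ll_label")
    if ll is None:
        lls = [k for k in by_label if k != dd]
        ll = lls[0] if len(lls) == 1 else None
    if dd in by_label and ll in by_label and len(by_label[dd]) and len(by_label[ll]):
        w, p = cstats.wilcoxon_rank_sum(by_label[dd], by_label[ll])
        report["dd_vs_ll"] = {
            "dd": dd, "ll": ll, "W": w, "p": p,
            "median_shift_h": float(
                np.median(by_label[ll]) - np.median(by_label[dd])
            ),
        }
    dose_labels = [
        k for k, v in report["cohorts"].items()
        if np.isfinite(v["intensity"]) and v["intensity"] > 0 and by_label[k].size
    ]
    if len(dose_labels) >= 3:
        dose = np.concatenate(
            [np.full(len(by_label[k]), report["cohorts"][k]["intensity"])
             for k in dose_labels]
        )
        resp = np.concatenate([by_label[k] for k in dose_labels])
        fit = cstats.fit_logistic4(dose, resp, seed=config.seed)
        f, p = cstats.anova_vs_flat(fit, resp)
        report["dose_response"] = {
            "alpha_l": fit.alpha_l, "delta": fit.delta, "eta": fit.eta,
            "phi_m": fit.phi_m, "rss": fit.rss, "F": f, "p": p,
            "converged": fit.converged,
        }
        _write_json(report["dose_response"], out / "dose_response.json")
    else:
        msg = "fewer than 3 intensities: dose-response skipped"
        log.info(msg)
        report["warnings"].append(msg)
    _write_json(report, out / "summary.json")
    return report


# -- ramped cycles -------------------------------------------------------------


def _dominant_phase(table: ActivityTable, from_cycle: int = 5) -> float | None:
    """Circular-mean dominant peak phase over stabilized cycles."""
    from .damio import bin_activity, _split_series

    binned = bin_activity(table, 15)
    mat, _ = _split_series(binned.channel(None), 15, binned.zt0_offset,
                           int(binned.timestamps[0]))
    phases = []
    for day in mat[from_cycle:]:
        peaks = find_peaks(day, PRESETS["ramp_peaks"], bin_minutes=15,
                           circular=True)
        if peaks:
            phases.append(peaks[0].zt_h)
    if not phases:
        return None
    return float(cstats.angle_to_zt(cstats.circ_mean(cstats.zt_to_angle(phases))))


def run_ramp_analysis(config: RunConfig) -> dict:
    """Four-way verdicts, entrained profiles, phase control on release data."""
    out = _prepare_out(config)
    cohorts = _load_cohorts(config)
    report: dict = {"preset": "ramp", "cohorts": {}, "warnings": []}
    clock_mutant = bool(config.params.get("clock_mutant", False))
    for label, data in cohorts.items():
        tables = data["tables"]
        release_after = data["release_after"]
        n_entrain_cycles = (
            release_after if release_after is not None else data["days"]
        )
        if n_entrain_cycles < 9:
            raise ValueError(f"cohort {label}: need >= 9 ramp cycles")
        entrain_minutes = n_entrain_cycles * MINUTES_PER_DAY
        calls: dict[int, EntrainmentCall] = {}
        for i, t in enumerate(tables):
            sub = ActivityTable(
                timestamps=t.timestamps[:entrain_minutes],
                counts={1: t.channel(None)[:entrain_minutes]},
                bin_minutes=t.bin_minutes,
                zt0_offset=t.zt0_offset,
            )
            calls[i] = classify_ramp(sub)
        frame = calls_to_frame(calls)
        frame.insert(0, "cohort", label)
        frame.to_csv(out / f"verdicts_{label}.csv", index=False,
                     float_format=_CSV_FLOAT)
        section: dict = {
            "n": len(tables),
            "summary": cohort_summary(list(calls.values())),
        }
        if clock_mutant:
            n_r = sum(is_rhythmic(c) for c in calls.values())
            section["rhythmic_percent"] = 100.0 * n_r / len(tables)
        keep = (
            [i for i, c in calls.items() if is_rhythmic(c)]
            if clock_mutant
            else [i for i, c in calls.items() if c.verdict == "entrained"]
        )
        if not keep:
            msg = f"cohort {label}: no entrained flies"
            log.warning(msg)
            report["warnings"].append(msg)
            report["cohorts"][label] = section
            continue
        entrained_tables = [
            ActivityTable(
                timestamps=tables[i].timestamps[:entrain_minutes],
                counts={1: tables[i].channel(None)[:entrain_minutes]},
                bin_minutes=1,
                zt0_offset=tables[i].zt0_offset,
            )
            for i in keep
        ]
        profile = average_profile(entrained_tables)
        profile.to_frame().to_csv(out / f"profile_{label}.csv", index=False,
                                  float_format=_CSV_FLOAT)
        dom = {i: _dominant_phase(entrained_tables[j])
               for j, i in enumerate(keep)}
        dom = {i: v for i, v in dom.items() if v is not None}
        pd.DataFrame(
            [{"cohort": label, "fly": i, "zt_h": v} for i, v in dom.items()]
        ).to_csv(out / f"dominant_phases_{label}.csv", index=False,
                 float_format=_CSV_FLOAT)
        if dom:
            section["median_dominant_phase_h"] = float(
                cstats.angle_to_zt(
                    cstats.circ_median(cstats.zt_to_angle(list(dom.values())))
                )
            )
        if release_after is not None:
            release_start = release_after * MINUTES_PER_DAY
            rel = {}
            for i in keep:
                est = release_day_phase(tables[i], release_start)
                if est is not None:
                    rel[i] = est.zt_h
            if rel and dom:
                vt = cstats.assess_phase_control(
                    list(dom.values()), list(rel.values())
                )
                section["phase_control"] = {
                    "mu0_zt_h": float(cstats.angle_to_zt(vt.mu0_rad)),
                    "v": vt.v, "u": vt.u, "p": vt.p, "n": vt.n,
                }
                pd.DataFrame(
                    [{"cohort": label, "fly": i, "zt_h": v}
                     for i, v in rel.items()]
                ).to_csv(out / f"release_phases_{label}.csv", index=False,
                         float_format=_CSV_FLOAT)
        else:
            report["warnings"].append(
                f"cohort {label}: no release data; phase-control section absent"
            )
        report["cohorts"][label] = section
    _write_json(report, out / "summary.json")
    return report


# -- actograms -----------------------------------------------------------------


def render_actogram(
    table: ActivityTable,
    regime: LightRegime | None = None,
    double_plot: bool = False,
    path=None,
    bin_minutes: int = 15,
) -> np.ndarray:
    """Day-by-row activity raster with optional regime shading.

    Returns the underlying matrix (one row per plotted day; double plotting
    concatenates consecutive days into 48 h rows, giving n_days - 1 rows).
    A PNG is written when ``path`` is given.
    """
    from .damio import bin_activity

    binned = bin_activity(table, bin_minutes) if table.bin_minutes != bin_minutes else table
    dm = split_days(binned)
    if dm.n_days < 2:
        raise ValueError("need at least 2 complete days for an actogram")
    mat = dm.values
    if double_plot:
        mat = np.hstack([mat[:-1], mat[1:]])
    if path is not None:
        n_rows, n_cols = mat.shape
        hours = n_cols * bin_minutes / 60.0
        fig, axes = plt.subplots(
            n_rows, 1, sharex=True, figsize=(8, max(2, 0.45 * n_rows))
        )
        axes = np.atleast_1d(axes)
        xs = np.arange(n_cols) * bin_minutes / 60.0
        ymax = float(mat.max()) or 1.0
        for r, ax in enumerate(axes):
            if regime is not None and regime.max_intensity() > 0:
                zt = np.arange(0, hours * 60, bin_minutes)
                inten = regime.intensity_at(zt)
                ax.fill_between(
                    zt / 60.0, 0, ymax * inten / regime.max_intensity(),
                    color="gold", alpha=0.25, step="post", linewidth=0,
                )
            ax.bar(xs, mat[r], width=bin_minutes / 60.0, color="black",
                   align="edge")
            ax.set_ylim(0, ymax)
            ax.set_yticks([])
            ax.set_ylabel(str(r + 1), rotation=0, labelpad=12, fontsize=7,
                          va="center")
        axes[-1].set_xlabel("time (h)")
        axes[-1].set_xlim(0, hours)
        fig.suptitle("double-plotted actogram" if double_plot else "actogram")
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return mat


RUNNERS = {
    "skeleton": run_skeleton_analysis,
    "ll_period": run_ll_period_analysis,
    "ramp": run_ramp_analysis,
}


def run(config: RunConfig) -> dict:
    """Dispatch a config to its preset's runner."""
    return RUNNERS[config.preset](config)
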
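"""Experiment engine: stimulation scheduling, measurement cadence and the
96-channel computer-in-the-loop feedback loop.

Each well carries a stimulation protocol (a PWM intensity looping through ON
and OFF durations) and optionally a feedback policy that rewrites the
protocol from live measurements.  At every measurement epoch the engine
pauses the shaker, forces every stimulation LED dark, measures OD and then
fluorescence for all 96 wells, restores stimulation and resumes shaking, so
stimulation and measurement intervals never overlap.  Feedback is evaluated
immediately after the records of an epoch are written -- the only moments at
which new data exist.

Three built-in policy classes mirror the canonical feedback experiments:
constant open-loop light, stop-on-fluorescence (light latched off once a
fluorescence threshold is reached) and start-on-OD (light latched on once
the culture's reference-adjusted OD reaches a threshold).  Custom policies
are pure functions of (state, group records, protocol).

Simulated time is event-stepped; culture dynamics advance between epochs
using the period-averaged drive of each well's pulse train.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import recordsio
from .calibration import (CalibrationTable, calibrate_od_blank,
                          read_corrected)
from .culture import (DriveHistory, ExpressionCircuit, GrowthParams,
                      WellCulture, expression_step, growth_step,
                      induction_drive)
from .spectroscopy import ODTransform, adjust_od, compute_od
from .twin import PWM_MAX, PlateTwin
from .wells import N_WELLS, WELLS, well_index

POLICY_KINDS = ("constant", "stop_on_fluorescence", "start_on_od", "custom")


@dataclass
class StimProtocol:
    """Blue-light stimulation waveform: ``intensity`` for ``t_on`` seconds,
    dark for ``t_off`` seconds, looping continuously while ``active``."""

    intensity: int = 0
    t_on: float = 0.0
    t_off: float = 0.0
    active: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.intensity <= PWM_MAX:
            raise ValueError(f"intensity out of range 0..{PWM_MAX}")
        if self.t_on < 0 or self.t_off < 0:
            raise ValueError("t_on and t_off must be >= 0")
        if self.active and self.intensity > 0 and self.t_on + self.t_off == 0:
            raise ValueError("active protocol needs t_on + t_off > 0")


def led_state_at(protocol: StimProtocol, t: float) -> int:
    """Intensity commanded at time t (seconds) within the looping waveform;
    0 during OFF phases and for inactive protocols."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if not protocol.active or protocol.intensity == 0:
        return 0
    period = protocol.t_on + protocol.t_off
    if period == 0:
        return 0
    return protocol.intensity if (t % period) < protocol.t_on else 0


def duty_cycle(protocol: StimProtocol) -> float:
    """Percentage of each period the LED is on, 100 x t_on/(t_on + t_off)."""
    period = protocol.t_on + protocol.t_off
    if period == 0:
        raise ValueError("duty cycle undefined for zero period")
    return 100.0 * protocol.t_on / period


def on_fraction(protocol: StimProtocol) -> float:
    """Fraction of time the LED is lit (0 if inactive or dark)."""
    if not protocol.active or protocol.intensity == 0:
        return 0.0
    period = protocol.t_on + protocol.t_off
    return 1.0 if period == 0 else protocol.t_on / period


@dataclass
class MeasurementPlan:
    """Measurement cadence: OD and fluorescence periods (minutes), readings
    averaged per measurement, total duration (hours) and the nominal time a
    full-plate measurement occupies (seconds)."""

    od_period_min: float = 20.0
    fluor_period_min: float = 20.0
    n_avg: int = 100
    duration_h: float = 18.0
    measure_seconds: float = 60.0

    def __post_init__(self) -> None:
        if self.od_period_min <= 0 or self.fluor_period_min <= 0:
            raise ValueError("measurement periods must be > 0")
        if self.n_avg < 1:
            raise ValueError("n_avg must be >= 1")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if min(self.od_period_min, self.fluor_period_min) * 60 \
                <= self.measure_seconds:
            raise ValueError("measurement period shorter than a measurement")

    def epoch_times_h(self) -> np.ndarray:
        """Epoch start times in hours, including t = 0."""
        step = min(self.od_period_min, self.fluor_period_min) / 60.0
        n = int(np.floor(self.duration_h / step + 1e-9)) + 1
        return np.arange(n) * step


@dataclass
class FeedbackPolicy:
    """Rule updating a stimulation protocol from live measurements.

    ``wells`` lists the member wells whose latest records are averaged as
    the policy input (the replicate-grouping function); each well belongs to
    at most one policy.  Threshold kinds are latched: they flip the protocol
    at most once per run.
    """

    kind: str = "constant"
    threshold: float | None = None
    wells: tuple[str, ...] = ()
    latched: bool = True
    triggered: bool = False
    custom_fn: Callable | None = None
    state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind in ("stop_on_fluorescence", "start_on_od") \
                and self.threshold is None:
            raise ValueError(f"{self.kind} policy requires a threshold")
        if self.kind == "custom" and self.custom_fn is None:
            raise ValueError("custom policy requires custom_fn")
        self.wells = tuple(self.wells)
        for w in self.wells:
            well_index(w)  # validates


@dataclass
class MeasurementRecord:
    """One timestamped per-well measurement, the CSV-logged unit."""

    time_h: float
    well: str
    od_raw: float
    od_adjusted: float
    fluorescence: float


def schedule_epoch(plan: MeasurementPlan, protocols: dict[str, StimProtocol],
                   t_h: float) -> list[tuple]:
    """Ordered actions of one measurement epoch.

    The bracket guarantees stimulation/measurement exclusion: the shaker is
    paused and every stimulation LED forced dark before any reading, and
    stimulation resumes only after both channel sweeps complete.
    """
    actions: list[tuple] = [("pause_shaker",), ("stim_dark",)]
    if _due(t_h, plan.od_period_min):
        actions.append(("measure", "od", plan.n_avg))
    if _due(t_h, plan.fluor_period_min):
        actions.append(("measure", "fluorescence", plan.n_avg))
    actions += [("restore_stim",), ("resume_shaker",)]
    return actions


def _due(t_h: float, period_min: float) -> bool:
    period_h = period_min / 60.0
    return abs(t_h / period_h - round(t_h / period_h)) < 1e-6


def group_mean(records: dict[str, MeasurementRecord],
               wells: tuple[str, ...]) -> MeasurementRecord:
    """Arithmetic mean of the latest records of a policy's member wells."""
    missing = [w for w in wells if w not in records]
    if missing:
        raise KeyError(f"no records yet for policy wells {missing}")
    members = [records[w] for w in wells]
    return MeasurementRecord(
        time_h=members[0].time_h, well="+".join(wells),
        od_raw=float(np.mean([r.od_raw for r in members])),
        od_adjusted=float(np.mean([r.od_adjusted for r in members])),
        fluorescence=float(np.mean([r.fluorescence for r in members])))


def apply_feedback(policy: FeedbackPolicy, protocol: StimProtocol,
                   latest: dict[str, MeasurementRecord]) -> StimProtocol:
    """Update one protocol from the policy's group measurement.

    constant: unchanged.  stop_on_fluorescence: once mean group fluorescence
    reaches the threshold, intensity is set to 0 (latched off).
    start_on_od: the protocol stays inactive until the mean adjusted OD
    reaches the threshold, then activates (latched on).
    """
    if policy.kind == "constant":
        return protocol
    if policy.kind == "custom":
        new_state, new_protocol = policy.custom_fn(
            policy.state, {w: latest[w] for w in policy.wells}, protocol)
        policy.state = new_state
        return new_protocol
    obs = group_mean(latest, policy.wells)
    if policy.kind == "stop_on_fluorescence":
        crossed = obs.fluorescence >= policy.threshold
        if policy.latched:
            policy.triggered = policy.triggered or crossed
            crossed = policy.triggered
        return replace(protocol, intensity=0) if crossed else protocol
    # start_on_od
    if np.isnan(obs.od_adjusted):
        raise ValueError("start_on_od feedback needs an OD transform so "
                         "thresholds are on the reference OD scale")
    crossed = obs.od_adjusted >= policy.threshold
    if policy.latched:
        policy.triggered = policy.triggered or crossed
        crossed = policy.triggered
    return replace(protocol, active=crossed) if crossed != protocol.active \
        else protocol


@dataclass
class ExperimentResult:
    """Full run output: wide per-signal tables plus the record stream."""

    od_raw: pd.DataFrame
    od_adjusted: pd.DataFrame
    fluorescence: pd.DataFrame
    records: list[MeasurementRecord]
    blanks: np.ndarray
    od_table: CalibrationTable
    manifest: dict


def run_experiment(twin: PlateTwin,
                   cultures: dict[str, WellCulture],
                   circuits: dict[str, ExpressionCircuit],
                   protocols: dict[str, StimProtocol],
                   policies: list[FeedbackPolicy],
                   plan: MeasurementPlan,
                   *,
                   growth: GrowthParams | None = None,
                   pd_table: CalibrationTable | None = None,
                   blue_table: CalibrationTable | None = None,
                   uv_table: CalibrationTable | None = None,
                   od_transform: ODTransform | None = None,
                   inducer_wells: set[str] | frozenset[str] = frozenset(),
                   outdir: str | Path | None = None,
                   substep_h: float = 1.0 / 30.0) -> ExperimentResult:
    """Run a full simulated plate experiment.

    Requires prior photodiode and UV-LED calibration (``pd_table``,
    ``uv_table``); OD blanking is performed here at T=0 on the starting
    cultures, as the workflow prescribes.  Blue protocol intensities are
    corrected per well with ``blue_table`` factors when given.  Reproducible
    bit-for-bit for a twin built from the same seed.
    """
    if pd_table is None:
        raise RuntimeError(
            "photodiodes are uncalibrated: run calibrate_photodiodes (and "
            "LED calibration) before starting an experiment")
    if uv_table is None or uv_table.final_settings is None:
        raise RuntimeError(
            "UV LEDs are uncalibrated: run calibrate_led_iterative for "
            "uv_led before starting an experiment")
    growth = growth or GrowthParams()
    protocols = {w: replace(p) for w, p in protocols.items()}
    for w in list(cultures) + list(circuits) + list(protocols):
        well_index(w)
    assigned: set[str] = set()
    for pol in policies:
        overlap = assigned & set(pol.wells)
        if overlap:
            raise ValueError(f"wells in more than one policy: {sorted(overlap)}")
        assigned |= set(pol.wells)
        missing = [w for w in pol.wells if w not in protocols]
        if missing:
            raise ValueError(f"policy wells without protocols: {missing}")
        # start_on_od wells begin dark until triggered
        if pol.kind == "start_on_od":
            for w in pol.wells:
                protocols[w] = replace(protocols[w], active=False)

    pd_factors = pd_table.factors
    state = {w: cultures.get(w, WellCulture(turbidity=0.0)) for w in WELLS}
    circuits = {w: circuits.get(w, ExpressionCircuit(kind="none"))
                for w in WELLS}
    protocols = {w: protocols.get(w, StimProtocol()) for w in WELLS}
    blue_corr = (blue_table.factors if blue_table is not None
                 else np.ones(N_WELLS))

    def sync_sample() -> None:
        twin.sample.turbidity = np.array(
            [state[w].turbidity for w in WELLS])
        twin.sample.fluorophore_conc = np.array(
            [state[w].reporter for w in WELLS])

    # T=0 blank calibration on the actual starting liquid
    sync_sample()
    twin.set_intensity_array("uv_led", np.zeros(N_WELLS, dtype=int))
    blanks, od_cal = calibrate_od_blank(twin, pd_factors)

    histories = {w: DriveHistory(0.0) for w in WELLS}
    records: list[MeasurementRecord] = []
    latest: dict[str, MeasurementRecord] = {}
    epoch_rows: dict[str, list[dict]] = {
        "od_raw": [], "od_adjusted": [], "fluorescence": []}

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def realized_intensity(w: str) -> float:
        p = protocols[w]
        if not p.active or p.intensity == 0:
            return 0.0
        return p.intensity * blue_corr[well_index(w)]

    def record_drives(t_h: float) -> None:
        # the photoreceptor integrates light far more slowly than the
        # seconds-scale pulse train, so the circuit sees the duty-averaged
        # intensity of the waveform
        for w in WELLS:
            light_eff = on_fraction(protocols[w]) * realized_intensity(w)
            d = induction_drive(circuits[w], light_eff, w in inducer_wells)
            histories[w].record(t_h, d)

    epochs = plan.epoch_times_h()
    record_drives(0.0)
    for t_h in epochs:
        # --- measurement bracket: shaker paused, stimulation dark ---------
        actions = schedule_epoch(plan, protocols, t_h)
        twin.pause_shaker()
        saved_blue = twin.settings["blue_stim"].copy()
        twin.set_intensity_array("blue_stim", np.zeros(N_WELLS, dtype=int))
        sync_sample()
        od_vals = np.full(N_WELLS, np.nan)
        fl_vals = np.full(N_WELLS, np.nan)
        if ("measure", "od", plan.n_avg) in actions:
            counts = read_corrected(twin, "od", plan.n_avg, pd_factors)
            od_vals = compute_od(counts, blanks)
        if ("measure", "fluorescence", plan.n_avg) in actions:
            twin.set_intensity_array("uv_led", uv_table.final_settings)
            fl_vals = read_corrected(twin, "fluorescence", plan.n_avg,
                                     pd_factors)
            twin.set_intensity_array("uv_led", np.zeros(N_WELLS, dtype=int))
        twin.set_intensity_array("blue_stim", saved_blue)
        twin.resume_shaker()

        adj_vals = (adjust_od(od_vals, od_transform.slope,
                              od_transform.intercept)
                    if od_transform is not None
                    else np.full(N_WELLS, np.nan))
        for i, w in enumerate(WELLS):
            rec = MeasurementRecord(t_h, w, float(od_vals[i]),
                                    float(adj_vals[i]), float(fl_vals[i]))
            records.append(rec)
            latest[w] = rec
        for signal, vals in (("od_raw", od_vals), ("od_adjusted", adj_vals),
                             ("fluorescence", fl_vals)):
            epoch_rows[signal].append(
                {"time_h": t_h, **dict(zip(WELLS, vals))})
        if outdir is not None:
            for signal in epoch_rows:
                recordsio.append_epoch(outdir / f"{signal}.csv",
                                       epoch_rows[signal][-1])

        # --- feedback, then advance biology to the next epoch -------------
        for pol in policies:
            for w in pol.wells:
                protocols[w] = apply_feedback(pol, protocols[w], latest)
        record_drives(t_h)
        if t_h == epochs[-1]:
            break
        next_t = t_h + (epochs[1] - epochs[0])
        tt = t_h
        while tt < next_t - 1e-12:
            dt = min(substep_h, next_t - tt)
            for w in WELLS:
                c = growth_step(state[w], growth, dt, shaking=True, t=tt)
                state[w] = expression_step(c, circuits[w], histories[w],
                                           dt, t=tt)
            tt += dt

    frames = {k: pd.DataFrame(v) for k, v in epoch_rows.items()}
    manifest = {"seed": twin.seed, "n_epochs": len(epochs),
                "duration_h": plan.duration_h,
                "od_calibration_cv_history": od_cal.cv_history}
    if outdir is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExperimentResult(od_raw=frames["od_raw"],
                            od_adjusted=frames["od_adjusted"],
                            fluorescence=frames["fluorescence"],
                            records=records, blanks=blanks,
                            od_table=od_cal, manifest=manifest)
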
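"""Component calibration: CV-minimising normalisation of the 96 photodiodes
and the three LED arrays.

The workflow mirrors the instrument's: the photodiodes are calibrated first
against an external uniform light source (min-rule factors, averaged over
four irradiances), and the calibrated photodiodes then serve as the reference
for iterative LED calibration.  Photodiode factors are applied in software to
readings; LED factors are applied to the PWM settings, iterating
measure -> CV -> factors -> new settings until the CV drops below the target
or the round budget is spent.

Factor rules
------------
min-rule   c_i = min(r) / r_i   -- factors in (0, 1]; used where settings
                                   start at full scale and can only be
                                   reduced (photodiodes, UV LEDs)
mean-rule  c_i = mean(r) / r_i  -- factors spread around 1; used for the
                                   blue and OD LEDs
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .twin import PWM_MAX, PlateTwin
from .wells import N_WELLS, WELLS

#: Uniform-field irradiances (µW/cm^2) at which photodiode factors are
#: measured and averaged.
DEFAULT_IRRADIANCES = (31.0, 67.0, 74.0, 230.0)

#: Standard initial PWM settings for iterative LED calibration.
INITIAL_SETTINGS = {"blue_stim": 2000, "od_led": 500, "uv_led": PWM_MAX}

#: Which optical channel each LED role is calibrated through.
_CHANNEL_FOR_ROLE = {"blue_stim": "blue", "od_led": "od",
                     "uv_led": "fluorescence"}


def compute_cv(readings) -> float:
    """Coefficient of variation, sample SD / mean x 100 %.

    Uses the n-1 (sample) standard deviation.
    """
    r = np.asarray(readings, dtype=float)
    if r.size < 2:
        raise ValueError("CV needs at least 2 readings")
    mean = r.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean readings")
    return float(r.std(ddof=1) / mean * 100.0)


def factors_min(mean_readings) -> np.ndarray:
    """Normalisation factors c_i = min(r) / r_i (all in (0, 1])."""
    r = np.asarray(mean_readings, dtype=float)
    if np.any(r <= 0):
        raise ValueError("all readings must be > 0")
    return r.min() / r


def factors_mean(mean_readings) -> np.ndarray:
    """Normalisation factors c_i = mean(r) / r_i (r_i * c_i is constant)."""
    r = np.asarray(mean_readings, dtype=float)
    if np.any(r <= 0):
        raise ValueError("all readings must be > 0")
    return r.mean() / r


FACTOR_RULES = {"min": factors_min, "mean": factors_mean}


@dataclass
class CalibrationTable:
    """Per-well factors for one component class plus convergence metadata."""

    role: str
    factors: np.ndarray
    cv_history: list[float] = field(default_factory=list)
    rounds_used: int = 0
    converged: bool = False
    irradiances_used: tuple[float, ...] | None = None
    final_settings: np.ndarray | None = None
    clipped_wells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (N_WELLS,):
            raise ValueError(f"expected {N_WELLS} factors")
        if np.any(self.factors <= 0):
            raise ValueError("factors must be > 0")
        if not np.all(np.isfinite(self.cv_history)):
            raise ValueError("cv_history must be finite")

    def to_csv(self, path) -> None:
        """One row per well (A1..H12 row-major): well, factor, final_setting."""
        settings = (self.final_settings if self.final_settings is not None
                    else np.full(N_WELLS, np.nan))
        pd.DataFrame({"well": WELLS, "factor": self.factors,
                      "final_setting": settings}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, role: str = "unknown") -> "CalibrationTable":
        df = pd.read_csv(path)
        if list(df["well"]) != list(WELLS):
            raise ValueError(f"{path}: wells must be A1..H12 row-major")
        settings = None
        if df["final_setting"].notna().all():
            settings = df["final_setting"].to_numpy(dtype=float).round().astype(int)
        return cls(role=role, factors=df["factor"].to_numpy(dtype=float),
                   final_settings=settings)


def read_corrected(twin: PlateTwin, channel: str, n_avg: int = 100,
                   pd_factors: np.ndarray | None = None) -> np.ndarray:
    """Batch read with the software-side photodiode correction applied."""
    counts = twin.batch_read(channel, n_avg)
    if pd_factors is not None:
        counts = counts * pd_factors
    return counts


def calibrate_photodiodes(twin: PlateTwin,
                          irradiances=DEFAULT_IRRADIANCES,
                          n_readings: int = 100) -> CalibrationTable:
    """Calibrate the 96 photodiodes against a uniform external field.

    At each irradiance the bare array is illuminated uniformly, each well's
    reading is the average of ``n_readings`` single readings, and min-rule
    factors are computed; the final factor per well is the arithmetic mean of
    the per-irradiance factors (they should agree for a linear detector).
    The factors multiply all subsequent photodiode readings in software.
    """
    irradiances = tuple(float(v) for v in irradiances)
    if any(v <= 0 for v in irradiances):
        raise ValueError("irradiances must be > 0")
    factor_sets = []
    cv_history = []
    for irr in irradiances:
        twin.set_uniform_field(irr)
        readings = twin.batch_read("uniform", n_readings)
        cv_history.append(compute_cv(readings))
        factor_sets.append(factors_min(readings))
    factors = np.mean(factor_sets, axis=0)
    # verification read at the last irradiance with the correction applied
    corrected = twin.batch_read("uniform", n_readings) * factors
    cv_history.append(compute_cv(corrected))
    twin.set_uniform_field(None)
    return CalibrationTable(role="photodiode", factors=factors,
                            cv_history=cv_history, rounds_used=1,
                            converged=True, irradiances_used=irradiances)


def calibrate_led_iterative(twin: PlateTwin, role: str, initial_setting: int,
                            factor_rule: str,
                            pd_factors: np.ndarray,
                            target_cv: float = 1.0, max_rounds: int = 3,
                            n_readings: int = 100) -> CalibrationTable:
    """Iteratively equalise one LED array using the calibrated photodiodes.

    Each round: read (averaged, photodiode-corrected) -> compute CV ->
    compute factors -> new_setting_i = round(setting_i x c_i), clipped to
    0..4095.  Stops once the CV falls below ``target_cv`` or after
    ``max_rounds`` adjustment rounds.  cv_history[0] is the uncalibrated CV
    and cv_history[-1] the final verification CV.

    Photodiode calibration must come first: ``pd_factors`` is required so
    that LED factors correct the LEDs, not the detectors.
    """
    if role not in _CHANNEL_FOR_ROLE:
        raise ValueError(f"{role!r} is not an LED role")
    if not 0 < initial_setting <= PWM_MAX:
        raise ValueError(f"initial_setting out of range 1..{PWM_MAX}")
    pd_factors = np.asarray(pd_factors, dtype=float)
    if pd_factors.shape != (N_WELLS,):
        raise ValueError("pd_factors must have 96 entries")
    rule = FACTOR_RULES[factor_rule]
    channel = _CHANNEL_FOR_ROLE[role]

    settings = np.full(N_WELLS, int(initial_setting))
    twin.set_intensity_array(role, settings)
    cumulative = np.ones(N_WELLS)
    cv_history: list[float] = []
    clipped: set[str] = set()
    converged = False
    rounds = 0
    while True:
        readings = read_corrected(twin, channel, n_readings, pd_factors)
        if np.all(readings == 0):
            raise RuntimeError(f"{role}: all-dark readings; check the "
                               "sample/optical context for this role")
        cv_history.append(compute_cv(readings))
        if cv_history[-1] < target_cv:
            converged = True
            break
        if rounds >= max_rounds:
            break
        factors = rule(readings)
        cumulative *= factors
        raw = np.rint(initial_setting * cumulative)
        out_of_range = (raw > PWM_MAX) | (raw < 0)
        clipped.update(w for w, bad in zip(WELLS, out_of_range) if bad)
        settings = np.clip(raw, 0, PWM_MAX).astype(int)
        twin.set_intensity_array(role, settings)
        rounds += 1
    return CalibrationTable(role=role, factors=cumulative,
                            cv_history=cv_history, rounds_used=rounds,
                            converged=converged, final_settings=settings,
                            clipped_wells=sorted(clipped))


def calibrate_od_blank(twin: PlateTwin, pd_factors: np.ndarray,
                       initial_setting: int = INITIAL_SETTINGS["od_led"],
                       target_cv: float = 1.0, max_rounds: int = 3,
                       n_readings: int = 100
                       ) -> tuple[np.ndarray, CalibrationTable]:
    """Per-experiment OD calibration on the starting (T=0) sample.

    Runs the mean-rule iterative loop on the OD channel with the
    experiment's actual starting liquid loaded, then returns the per-well
    blank transmission counts (the maximum-transmission reference used by
    OD computation for the whole experiment) together with the table.

    Blanks are only valid for the liquid they were measured on: this must be
    called at T=0, before any growth, and repeated for every experiment.
    """
    table = calibrate_led_iterative(twin, "od_led", initial_setting, "mean",
                                    pd_factors, target_cv=target_cv,
                                    max_rounds=max_rounds,
                                    n_readings=n_readings)
    blanks = read_corrected(twin, "od", n_readings, pd_factors)
    return blanks, table
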
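"""End-to-end measurement workflows on a (simulated or real) instrument.

These functions chain the low-level pieces the way an operator would:
full component calibration in the prescribed order (photodiodes first, then
the three LED arrays), the dye dilution series that characterises
fluorescence detection, and the bead turbidity series that fits the
cross-instrument OD transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration as cal
from .spectroscopy import (DilutionSeriesResult, ODTransform,
                           characterize_dilution_series, compute_od,
                           fit_od_transform)
from .twin import PlateTwin, SamplePlate
from .wells import N_WELLS


@dataclass
class CalibrationState:
    """Tables for all four component classes of one instrument."""

    photodiode: cal.CalibrationTable
    blue: cal.CalibrationTable
    od: cal.CalibrationTable
    uv: cal.CalibrationTable

    @property
    def pd_factors(self) -> np.ndarray:
        return self.photodiode.factors


#: Dye concentration placed in every well during UV-LED calibration (µg/mL).
UV_CAL_DYE_CONC = 40.0


def full_calibration(twin: PlateTwin, *, target_cv: float = 1.0,
                     max_rounds: int = 3,
                     n_readings: int = 100) -> CalibrationState:
    """Calibrate photodiodes, then blue, OD and UV LEDs, in that order.

    Each LED role is calibrated in its prescribed optical context: blue
    through an empty plate, OD through a liquid-filled plate (the loop that
    is re-run at every experiment start), UV against a uniform dye plate.
    """
    pd_table = cal.calibrate_photodiodes(twin, n_readings=n_readings)
    pdf = pd_table.factors

    twin.load_sample(SamplePlate.uniform())  # empty plate for blue
    blue = cal.calibrate_led_iterative(
        twin, "blue_stim", cal.INITIAL_SETTINGS["blue_stim"], "mean", pdf,
        target_cv=target_cv, max_rounds=max_rounds, n_readings=n_readings)
    twin.set_intensity_array("blue_stim", np.zeros(N_WELLS, dtype=int))

    twin.load_sample(SamplePlate.uniform(turbidity=0.0))  # medium-filled
    od = cal.calibrate_led_iterative(
        twin, "od_led", cal.INITIAL_SETTINGS["od_led"], "mean", pdf,
        target_cv=target_cv, max_rounds=max_rounds, n_readings=n_readings)
    twin.set_intensity_array("od_led", np.zeros(N_WELLS, dtype=int))

    twin.load_sample(SamplePlate.uniform(fluorophore_conc=UV_CAL_DYE_CONC))
    uv = cal.calibrate_led_iterative(
        twin, "uv_led", cal.INITIAL_SETTINGS["uv_led"], "min", pdf,
        target_cv=target_cv, max_rounds=max_rounds, n_readings=n_readings)
    twin.load_sample(SamplePlate.uniform())
    return CalibrationState(photodiode=pd_table, blue=blue, od=od, uv=uv)


def simulate_dye_dilution_series(twin: PlateTwin, state: CalibrationState,
                                 concs, *, n_avg: int = 100,
                                 n_blank_readings: int = 100
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Measure a dye dilution series on a calibrated instrument.

    Returns (counts, blank_readings): ``counts`` is (k, 96) averaged
    fluorescence counts per concentration; ``blank_readings`` is
    (n_blank_readings, 96) single (unaveraged) readings of the blank, whose
    spread sets the single-reading detection limit.
    """
    twin.set_intensity_array("uv_led", state.uv.final_settings)
    pdf = state.pd_factors
    counts = np.empty((len(concs), N_WELLS))
    for j, conc in enumerate(concs):
        twin.load_sample(SamplePlate.uniform(fluorophore_conc=float(conc)))
        counts[j] = cal.read_corrected(twin, "fluorescence", n_avg, pdf)
    twin.load_sample(SamplePlate.uniform(fluorophore_conc=0.0))
    blanks = np.stack([
        cal.read_corrected(twin, "fluorescence", 1, pdf)
        for _ in range(n_blank_readings)])
    return counts, blanks


def characterize_fluorescence(twin: PlateTwin, state: CalibrationState,
                              concs, **kwargs) -> DilutionSeriesResult:
    """Dye dilution series plus per-well linear characterisation."""
    counts, blanks = simulate_dye_dilution_series(twin, state, concs,
                                                  **kwargs)
    return characterize_dilution_series(concs, counts, blanks)


def simulate_bead_od_series(twin: PlateTwin, state: CalibrationState,
                            reference_ods, *, n_avg: int = 100
                            ) -> np.ndarray:
    """Instrument OD readings (k, 96) of a bead turbidity dilution series.

    The blank is re-calibrated on the clear diluent first, as at the start
    of every experiment; ``reference_ods`` are the reference-instrument OD
    values of the same dilutions.
    """
    pdf = state.pd_factors
    twin.load_sample(SamplePlate.uniform(turbidity=0.0))
    blanks, _ = cal.calibrate_od_blank(twin, pdf)
    od_vals = np.empty((len(reference_ods), N_WELLS))
    for j, ref in enumerate(reference_ods):
        twin.load_sample(SamplePlate.uniform(turbidity=float(ref)))
        counts = cal.read_corrected(twin, "od", n_avg, pdf)
        od_vals[j] = compute_od(counts, blanks)
    twin.load_sample(SamplePlate.uniform())
    return od_vals


def fit_od_harmonization(twin: PlateTwin, state: CalibrationState,
                         reference_ods) -> ODTransform:
    """Fit the per-well instrument-to-reference OD transform on a freshly
    measured bead series."""
    od_vals = simulate_bead_od_series(twin, state, reference_ods)
    return fit_od_transform(od_vals, np.asarray(reference_ods, dtype=float))
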
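"""Digital twin of the 96-well LED/photodiode plate instrument.

The physical device pairs, for every well of a 96-well plate, a blue
stimulation LED (470 nm) and a red OD LED (600 nm) above the sample with a
photodiode and a near-UV excitation LED (395 nm) below it.  LED brightness is
set by 12-bit pulse-width modulation (settings 0..4095) and each photodiode is
digitised through a shared ADC; the software averages many single readings per
measurement.  Components of the same type differ in efficiency by up to ~20 %
after assembly, which is what the calibration workflow removes.

The twin reproduces that structure: each component class carries 96
multiplicative per-well gains (lognormal, mean 1, configurable CV), readings
add Gaussian noise and are rounded and clipped to the ADC range, and all
randomness flows from a single seed so simulated experiments are
bit-reproducible.

Default optical constants are chosen so that the default twin, once
calibrated, operates in the published instrument's regime: a fluorescence
sensitivity of ~12.5 counts per µg/mL of dye, a single-reading detection
limit of ~1 µg/mL, and OD readings about half the magnitude of a
reference-instrument OD (decadic absorbance with path-length factor 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wells import N_WELLS, well_index

PWM_MAX = 4095
DEFAULT_ADC_MAX = 1023

ROLES = ("blue_stim", "od_led", "uv_led", "photodiode")
LED_ROLES = ("blue_stim", "od_led", "uv_led")

#: Component-to-component variability (%) measured on the assembled
#: instrument before any calibration; used as the twin's default gain CVs.
DEFAULT_GAIN_CV = {
    "photodiode": 5.1,
    "blue_stim": 15.9,
    "od_led": 11.8,
    "uv_led": 9.8,
}
#: Per-well optical scatter of the OD light path (meniscus, alignment, liquid
#: refraction).  Combined with the OD-LED gain CV above it yields ~16.6 %
#: well-to-well variability of raw OD readings, the uncalibrated level seen
#: on the real light path.
DEFAULT_OD_SCATTER_CV = 11.7

#: Counts per µg/mL of dye per unit excitation drive.  Min-rule calibration
#: pins every UV drive (and the software photodiode correction) to the
#: dimmest component of its class, so the sensitivity of a calibrated
#: instrument is this constant times the expected minima of the two gain
#: samples (~0.686 for 96 wells at the default CVs), i.e. ~12.5 counts/µg/mL.
DEFAULT_FLUOR_GAIN = 18.2

#: Single-reading Gaussian read noise (counts).  With the 3-sigma blank
#: criterion this puts the single-reading detection limit near
#: 3 x 4.2 / 12.5 ~= 1 µg/mL.
DEFAULT_NOISE_SD = 4.2

#: Fraction of the excitation drive that reaches the detector through the
#: emission filter (times the UV channel scale); it is the dominant blank
#: level of the fluorescence channel.
DEFAULT_UV_BLEEDTHROUGH = 0.15

#: Scales sample turbidity (reference-instrument OD units) to the decadic
#: attenuation seen on the short vertical light path through the well; 0.5
#: reproduces OD readings at about half the reference magnitude.
DEFAULT_OD_PATHLENGTH_FACTOR = 0.5

# Counts per unit input at gain 1 for each channel.  LED channels are in
# detector-count equivalents at full PWM drive; the photodiode scale converts
# uniform-field irradiance (µW/cm^2) to counts.
_NOMINAL_SCALE = {
    "blue_stim": 1000.0,  # ~490 counts at the standard setting of 2000
    "od_led": 4915.2,     # ~600 blank counts at the standard setting of 500
    "uv_led": 1000.0,
    "photodiode": 3.5,
}


def lognormal_gains(cv_percent: float, n: int, rng: np.random.Generator,
                    mean: float = 1.0) -> np.ndarray:
    """Draw ``n`` positive gains with the requested mean and CV.

    Lognormal is used so gains stay positive even at CVs of 20 %.
    """
    if cv_percent < 0:
        raise ValueError("cv_percent must be >= 0")
    if cv_percent == 0:
        return np.full(n, float(mean))
    c = cv_percent / 100.0
    sigma2 = np.log1p(c * c)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


@dataclass
class ComponentArray:
    """One class of 96 matched components (an LED array or the photodiodes).

    gains are dimensionless per-well multipliers with mean ~1; noise_sd is
    the single-reading read noise in counts (only meaningful for the
    photodiode role); nominal_scale is counts per unit input at gain 1.
    """

    role: str
    gains: np.ndarray
    noise_sd: float = 0.0
    nominal_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (N_WELLS,):
            raise ValueError(f"{self.role}: expected {N_WELLS} gains, "
                             f"got shape {self.gains.shape}")
        if np.any(self.gains <= 0):
            raise ValueError(f"{self.role}: all gains must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_cv(cls, role: str, cv_percent: float, rng: np.random.Generator,
                *, noise_sd: float = 0.0,
                nominal_scale: float | None = None) -> "ComponentArray":
        if nominal_scale is None:
            nominal_scale = _NOMINAL_SCALE[role]
        return cls(role, lognormal_gains(cv_percent, N_WELLS, rng),
                   noise_sd=noise_sd, nominal_scale=nominal_scale)

    @property
    def sample_cv(self) -> float:
        """Sample CV (%) of the drawn gains."""
        return float(np.std(self.gains, ddof=1) / np.mean(self.gains) * 100.0)


@dataclass
class SamplePlate:
    """Optical state of the sample in each well.

    fluorophore_conc is in µg/mL-equivalents of the reference dye, turbidity
    in reference-instrument OD units, blank_level in counts of well/medium
    autofluorescence reaching the detector.
    """

    fluorophore_conc: np.ndarray = field(
        default_factory=lambda: np.zeros(N_WELLS))
    turbidity: np.ndarray = field(default_factory=lambda: np.zeros(N_WELLS))
    blank_level: np.ndarray = field(default_factory=lambda: np.zeros(N_WELLS))

    def __post_init__(self) -> None:
        for name in ("fluorophore_conc", "turbidity", "blank_level"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(N_WELLS, float(arr))
            if arr.shape != (N_WELLS,):
                raise ValueError(f"{name}: expected {N_WELLS} values")
            setattr(self, name, arr)
        if np.any(self.fluorophore_conc < 0) or np.any(self.turbidity < 0):
            raise ValueError("concentrations and turbidities must be >= 0")

    @classmethod
    def uniform(cls, *, fluorophore_conc: float = 0.0, turbidity: float = 0.0,
                blank_level: float = 0.0) -> "SamplePlate":
        return cls(np.full(N_WELLS, float(fluorophore_conc)),
                   np.full(N_WELLS, float(turbidity)),
                   np.full(N_WELLS, float(blank_level)))


class PlateTwin:
    """Simulated 96-well instrument implementing the hardware contract.

    The twin exposes exactly the operations a real device driver would:
    ``set_intensity`` / ``set_intensity_array`` for the three LED roles and
    ``batch_read`` returning 96 averaged photodiode counts for one optical
    channel, plus shaker pause/resume.  Everything above this contract
    (calibration, spectroscopy, the experiment engine) is hardware-agnostic.

    Channels
    --------
    ``uniform``       photodiodes exposed to an external uniform field
                      (photodiode calibration geometry; no plate, no filter)
    ``blue``          blue LEDs read through an empty plate, no filter
    ``od``            OD LEDs attenuated by sample turbidity and per-well
                      scatter
    ``fluorescence``  UV excitation driving dye emission plus filter
                      bleed-through and sample blank level
    """

    def __init__(self, *, seed: int = 0,
                 adc_max: int = DEFAULT_ADC_MAX,
                 noise_sd: float = DEFAULT_NOISE_SD,
                 gain_cv: dict[str, float] | None = None,
                 od_scatter_cv: float = DEFAULT_OD_SCATTER_CV,
                 uv_bleedthrough: float = DEFAULT_UV_BLEEDTHROUGH,
                 od_pathlength_factor: float = DEFAULT_OD_PATHLENGTH_FACTOR,
                 fluor_gain: float = DEFAULT_FLUOR_GAIN,
                 crosstalk: np.ndarray | None = None,
                 components: dict[str, ComponentArray] | None = None) -> None:
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.adc_max = int(adc_max)
        self.uv_bleedthrough = float(uv_bleedthrough)
        self.od_pathlength_factor = float(od_pathlength_factor)
        self.fluor_gain = float(fluor_gain)

        cvs = dict(DEFAULT_GAIN_CV)
        if gain_cv:
            unknown = set(gain_cv) - set(ROLES)
            if unknown:
                raise ValueError(f"unknown roles in gain_cv: {sorted(unknown)}")
            cvs.update(gain_cv)
        self.components: dict[str, ComponentArray] = {}
        for role in ROLES:
            if components and role in components:
                self.components[role] = components[role]
            else:
                ns = noise_sd if role == "photodiode" else 0.0
                self.components[role] = ComponentArray.from_cv(
                    role, cvs[role], self.rng, noise_sd=ns)
        self.od_scatter = lognormal_gains(od_scatter_cv, N_WELLS, self.rng)

        if crosstalk is not None:
            crosstalk = np.asarray(crosstalk, dtype=float)
            if crosstalk.shape != (N_WELLS, N_WELLS):
                raise ValueError("crosstalk must be 96x96")
            if np.any(crosstalk < 0):
                raise ValueError("crosstalk rows must be nonnegative")
        self.crosstalk = crosstalk  # None means perfect well insulation

        self.settings: dict[str, np.ndarray] = {
            role: np.zeros(N_WELLS, dtype=int) for role in LED_ROLES}
        self.sample = SamplePlate.uniform()
        self.uniform_field_irradiance: float | None = None
        self.shaking = False
        self.shaker_log: list[tuple[str, ...]] = []

    # ---------------------------------------------------------------- LEDs
    def set_intensity(self, role: str, well: str, pwm_setting: int) -> None:
        """Set one LED's PWM value (integer, 0..4095; 0 means dark)."""
        self._check_setting(role, pwm_setting)
        self.settings[role][well_index(well)] = int(pwm_setting)

    def set_intensity_array(self, role: str, pwm_settings: np.ndarray) -> None:
        settings = np.asarray(pwm_settings)
        if settings.shape != (N_WELLS,):
            raise ValueError(f"expected {N_WELLS} settings")
        for s in settings:
            self._check_setting(role, s)
        self.settings[role] = settings.astype(int)

    def _check_setting(self, role: str, s) -> None:
        if role not in LED_ROLES:
            raise ValueError(f"{role!r} is not an LED role")
        if not float(s).is_integer():
            raise ValueError(f"PWM setting must be an integer, got {s!r}")
        if not 0 <= int(s) <= PWM_MAX:
            raise ValueError(
                f"PWM setting {int(s)} out of range 0..{PWM_MAX}")

    def drive(self, role: str) -> np.ndarray:
        """Emitted output per well, proportional to setting x gain.

        PWM dimming averages linearly, so drive is linear in the setting;
        normalised to 1 at full scale and unit gain.
        """
        if role not in LED_ROLES:
            raise ValueError(f"{role!r} is not an LED role")
        return self.settings[role] / PWM_MAX * self.components[role].gains

    # ------------------------------------------------------------- shaker
    def pause_shaker(self) -> None:
        self.shaking = False
        self.shaker_log.append(("pause",))

    def resume_shaker(self) -> None:
        self.shaking = True
        self.shaker_log.append(("resume",))

    # ------------------------------------------------------------- optics
    def set_uniform_field(self, irradiance: float | None) -> None:
        """Expose the bare photodiode array to a uniform external field
        (µW/cm^2), as in the light-box calibration geometry; None exits the
        mode."""
        if irradiance is not None and irradiance <= 0:
            raise ValueError("irradiance must be > 0")
        self.uniform_field_irradiance = irradiance

    def load_sample(self, plate: SamplePlate) -> None:
        self.sample = plate

    def _incident(self, channel: str) -> np.ndarray:
        """Light reaching each photodiode, in count-equivalents."""
        if channel == "uniform":
            if self.uniform_field_irradiance is None:
                raise RuntimeError(
                    "uniform channel requires set_uniform_field(...) first")
            pd = self.components["photodiode"]
            return np.full(N_WELLS,
                           self.uniform_field_irradiance * pd.nominal_scale)
        if channel == "blue":
            c = self.components["blue_stim"]
            incident = c.nominal_scale * self.drive("blue_stim")
        elif channel == "od":
            c = self.components["od_led"]
            transmission = 10.0 ** (-self.od_pathlength_factor
                                    * self.sample.turbidity)
            incident = (c.nominal_scale * self.drive("od_led")
                        * self.od_scatter * transmission)
        elif channel == "fluorescence":
            c = self.components["uv_led"]
            uv = self.drive("uv_led")
            incident = (uv * (self.fluor_gain * self.sample.fluorophore_conc
                              + self.uv_bleedthrough * c.nominal_scale)
                        + self.sample.blank_level)
        else:
            raise ValueError(f"unknown channel {channel!r}")
        if self.crosstalk is not None:
            incident = self.crosstalk @ incident
        return incident

    def _single_readings(self, incident: np.ndarray, n: int) -> np.ndarray:
        """(n, 96) array of quantised single ADC readings."""
        if n < 1:
            raise ValueError("n_readings must be >= 1")
        pd = self.components["photodiode"]
        analog = pd.gains * np.maximum(incident, 0.0)
        raw = analog[None, :] + (
            self.rng.normal(0.0, pd.noise_sd, size=(n, N_WELLS))
            if pd.noise_sd > 0 else 0.0)
        return np.clip(np.rint(raw), 0, self.adc_max)

    def read_photodiode(self, well: str, incident_irradiance: float,
                        n_readings: int = 100) -> float:
        """Mean of n single readings of one photodiode under a given
        incident irradiance (µW/cm^2).  The standard error of the returned
        mean shrinks as 1/sqrt(n)."""
        if incident_irradiance < 0:
            raise ValueError("incident_irradiance must be >= 0")
        if n_readings < 1:
            raise ValueError("n_readings must be >= 1")
        i = well_index(well)
        pd = self.components["photodiode"]
        analog = pd.gains[i] * incident_irradiance * pd.nominal_scale
        raw = analog + (self.rng.normal(0.0, pd.noise_sd, size=n_readings)
                        if pd.noise_sd > 0 else 0.0)
        return float(np.clip(np.rint(raw), 0, self.adc_max).mean())

    def batch_read(self, channel: str, n_avg: int = 100) -> np.ndarray:
        """96 averaged raw counts (A1..H12 row-major) for one channel."""
        return self._single_readings(self._incident(channel), n_avg).mean(axis=0)

    def measure_fluorescence_raw(self, well: str, n_avg: int = 100) -> float:
        """Raw fluorescence counts of one well at the current UV settings."""
        return float(self.batch_read("fluorescence", n_avg)[well_index(well)])

    def measure_od_raw(self, well: str, n_avg: int = 100) -> float:
        """Raw OD-channel counts (transmitted 600 nm light) of one well."""
        return float(self.batch_read("od", n_avg)[well_index(well)])
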
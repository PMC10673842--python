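"""Bacterial growth and light-inducible reporter expression.

Each well holds an E. coli culture whose turbidity follows logistic growth
with a lag phase, and whose fluorescent reporter (an mAmetrine-like
long-Stokes-shift protein) is transcribed under one of three controllers:

* ``arabinose`` -- chemically induced, fully on when the inducer is present;
* ``pDawn``     -- blue light activates transcription (Hill function of
                   intensity), dark is off;
* ``pDusk``     -- blue light represses an otherwise constitutive promoter.

Activation is not instantaneous: an internal ``induced_fraction`` state
relaxes first-order toward the light drive evaluated ``switch_delay`` hours
in the past, modelling the transcriptional cassette's switching kinetics.
Reporter accumulates at ``k_prod x induced_fraction x turbidity`` per hour
(no degradation or bleaching by default), in µg/mL-equivalents of the
reference dye so the device twin can read it directly.

Integration is explicit Euler.  Because the photoreceptor responds far more
slowly than the seconds-scale stimulation pulses, the engine evaluates the
circuit response at the duty-averaged intensity of the pulse train rather
than resolving individual pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

CIRCUIT_KINDS = ("none", "arabinose", "pDawn", "pDusk")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth with lag.

    rate: 1/h intrinsic growth rate (static culture); carrying_capacity: OD
    units; lag: h before growth starts; shaking_multiplier: aeration factor
    on the rate while the plate is shaken (>= 1).
    """

    rate: float = 0.5
    carrying_capacity: float = 1.0
    lag: float = 1.0
    shaking_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.carrying_capacity <= 0:
            raise ValueError("rate and carrying_capacity must be > 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.shaking_multiplier < 1:
            raise ValueError("shaking_multiplier must be >= 1")


@dataclass(frozen=True)
class ExpressionCircuit:
    """Reporter controller and its kinetics.

    k_prod: µg/mL-equivalents per OD x h at full induction.
    half_max_light: PWM-equivalent intensity at half activation.
    hill_n: Hill coefficient (>= 1).
    switch_delay: h of transcriptional lag after the light condition changes;
    also the default first-order relaxation time of the activation state
    (override with relax_time).
    """

    kind: str = "none"
    k_prod: float = 8.0
    half_max_light: float = 30.0
    hill_n: float = 2.0
    switch_delay: float = 0.5
    relax_time: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in CIRCUIT_KINDS:
            raise ValueError(f"unknown circuit kind {self.kind!r}")
        if self.k_prod < 0 or self.switch_delay < 0:
            raise ValueError("k_prod and switch_delay must be >= 0")
        if self.half_max_light <= 0:
            raise ValueError("half_max_light must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.relax_time is not None and self.relax_time < 0:
            raise ValueError("relax_time must be >= 0")

    @property
    def tau(self) -> float:
        return self.switch_delay if self.relax_time is None else self.relax_time


@dataclass(frozen=True)
class WellCulture:
    """State of one culture: turbidity (OD units), reporter
    (fluorescence-equivalent µg/mL), induced_fraction in [0, 1]."""

    turbidity: float = 0.05
    reporter: float = 0.0
    induced_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.turbidity < 0 or self.reporter < 0:
            raise ValueError("turbidity and reporter must be >= 0")
        if not 0 <= self.induced_fraction <= 1:
            raise ValueError("induced_fraction must be in [0, 1]")


def growth_step(culture: WellCulture, params: GrowthParams, dt: float,
                shaking: bool = True, t: float = 0.0) -> WellCulture:
    """One Euler step of logistic growth, dN/dt = r_eff N (1 - N/K).

    ``t`` is the absolute time at the start of the step; growth only acts on
    the part of [t, t+dt] past the lag.  Turbidity never exceeds K.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    active = max(0.0, t + dt - max(t, params.lag))
    if active == 0.0:
        return culture
    r_eff = params.rate * (params.shaking_multiplier if shaking else 1.0)
    n = culture.turbidity
    k = params.carrying_capacity
    n_new = n + r_eff * n * (1.0 - n / k) * active
    n_new = min(max(n_new, 0.0), k)
    return replace(culture, turbidity=n_new)


def induction_drive(circuit: ExpressionCircuit, light_intensity: float,
                    inducer_present: bool = False) -> float:
    """Instantaneous transcriptional drive in [0, 1].

    arabinose: 1 iff the inducer is present; pDawn: Hill(light);
    pDusk: 1 - Hill(light); none: 0.
    """
    if light_intensity < 0:
        raise ValueError("light_intensity must be >= 0")
    kind = circuit.kind
    if kind == "none":
        return 0.0
    if kind == "arabinose":
        return 1.0 if inducer_present else 0.0
    ln = light_intensity ** circuit.hill_n
    hill = ln / (ln + circuit.half_max_light ** circuit.hill_n)
    if kind == "pDawn":
        return hill
    return 1.0 - hill  # pDusk


def expression_step(culture: WellCulture, circuit: ExpressionCircuit,
                    drive_history: "Callable[[float], float] | float",
                    dt: float, t: float = 0.0) -> WellCulture:
    """One Euler step of delayed activation and reporter accumulation.

    ``drive_history`` supplies the drive as a function of absolute time (or a
    constant); the activation state relaxes toward the drive evaluated at
    ``t - switch_delay`` with time constant ``circuit.tau``, and reporter
    accumulates at k_prod x induced_fraction x turbidity.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    delayed = (drive_history(t - circuit.switch_delay)
               if callable(drive_history) else float(drive_history))
    delayed = min(max(delayed, 0.0), 1.0)
    f = culture.induced_fraction
    if circuit.tau == 0:
        f_new = delayed
    else:
        f_new = f + (delayed - f) * min(dt / circuit.tau, 1.0)
    f_new = min(max(f_new, 0.0), 1.0)
    reporter = culture.reporter + circuit.k_prod * f * culture.turbidity * dt
    return replace(culture, reporter=reporter, induced_fraction=f_new)


class DriveHistory:
    """Piecewise-constant record of a well's transcriptional drive.

    ``value_at(t)`` returns the drive in force at time t; times before the
    first recorded segment return the initial value (default 0).
    """

    def __init__(self, initial: float = 0.0) -> None:
        self._times = [float("-inf")]
        self._values = [float(initial)]

    def record(self, t: float, value: float) -> None:
        if t < self._times[-1]:
            raise ValueError("drive history times must be nondecreasing")
        self._times.append(float(t))
        self._values.append(float(value))

    def value_at(self, t: float) -> float:
        idx = int(np.searchsorted(self._times, t, side="right")) - 1
        return self._values[max(idx, 0)]

    __call__ = value_at
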
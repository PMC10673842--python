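"""Ready-made plate layouts for the canonical experiments.

Three fixtures mirror the standard demonstrations on this class of
instrument: an arabinose-induction plate (48 induced / 48 uninduced wells),
an optogenetic half-plate (24 lit + 24 dark wells each of a pDawn and a
pDusk strain, pulsed 3 s ON / 7 s OFF), and the 96-channel feedback plate
(3 policy classes x 8 parameter values x 4 replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control import FeedbackPolicy, MeasurementPlan, StimProtocol
from .culture import ExpressionCircuit, WellCulture
from .wells import WELLS

#: Standard pulsed stimulation: ~25 % of maximum intensity, 30 % duty cycle.
PULSED_BLUE = StimProtocol(intensity=1000, t_on=3.0, t_off=7.0)

#: Open-loop intensity ladder spanning ~0.5 % to 10 % of full scale.
CONSTANT_LIGHT_INTENSITIES = (20, 31, 48, 73, 113, 174, 267, 410)

#: Fluorescence-halt thresholds (counts, including the channel blank).
FLUOR_THRESHOLDS = (150.0, 190.0, 230.0, 270.0, 310.0, 350.0, 390.0, 430.0)

#: OD-trigger thresholds on the reference-adjusted OD scale.
OD_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass
class PlateFixture:
    """A fully specified experiment: cultures, circuits, protocols,
    policies, plan and any chemical-inducer assignment."""

    name: str
    cultures: dict[str, WellCulture]
    circuits: dict[str, ExpressionCircuit]
    protocols: dict[str, StimProtocol]
    policies: list[FeedbackPolicy]
    plan: MeasurementPlan
    inducer_wells: frozenset[str] = frozenset()
    condition: dict[str, str] = field(default_factory=dict)


def _fresh(protocol: StimProtocol) -> StimProtocol:
    return StimProtocol(protocol.intensity, protocol.t_on, protocol.t_off,
                        protocol.active)


def arabinose_plate(initial_turbidity: float = 0.05) -> PlateFixture:
    """48 wells with arabinose, 48 without; no light; 20-min epochs, 18 h."""
    cultures, circuits, protocols, condition = {}, {}, {}, {}
    inducer = set()
    for i, w in enumerate(WELLS):
        cultures[w] = WellCulture(turbidity=initial_turbidity)
        circuits[w] = ExpressionCircuit(kind="arabinose")
        protocols[w] = StimProtocol(intensity=0)
        if i < 48:
            inducer.add(w)
            condition[w] = "+arabinose"
        else:
            condition[w] = "-arabinose"
    plan = MeasurementPlan(od_period_min=20, fluor_period_min=20,
                           duration_h=18)
    return PlateFixture("arabinose", cultures, circuits, protocols, [],
                        plan, frozenset(inducer), condition)


def optogenetic_half_plate(initial_turbidity: float = 0.05) -> PlateFixture:
    """pDawn/pDusk half-plate: per strain, 24 pulsed-light wells and 24
    dark wells; 30-min epochs, 10 h."""
    cultures, circuits, protocols, condition = {}, {}, {}, {}
    for i, w in enumerate(WELLS):
        cultures[w] = WellCulture(turbidity=initial_turbidity)
        kind = "pDawn" if i < 48 else "pDusk"
        circuits[w] = ExpressionCircuit(kind=kind)
        lit = (i % 48) < 24
        protocols[w] = _fresh(PULSED_BLUE) if lit else StimProtocol(0)
        condition[w] = f"{kind}_{'light' if lit else 'dark'}"
    plan = MeasurementPlan(od_period_min=30, fluor_period_min=30,
                           duration_h=10)
    return PlateFixture("optogenetic_half_plate", cultures, circuits,
                        protocols, [], plan, condition=condition)


def feedback_grid_plate(initial_turbidity: float = 0.05,
                        group_replicates: bool = True) -> PlateFixture:
    """The 96-channel feedback demonstration plate.

    One third of the plate per class: constant light at 8 intensities,
    stop-on-fluorescence at 8 thresholds, start-on-OD at 8 thresholds,
    each parameter set in biological quadruplicate (3 x 8 x 4 = 96 wells,
    24 policies).  Every well runs pDawn; with ``group_replicates`` (the
    default) each policy averages its 4 replicate wells as input, otherwise
    each well gets its own single-well policy.
    """
    cultures, circuits, protocols, condition = {}, {}, {}, {}
    policies: list[FeedbackPolicy] = []
    idx = 0

    def add_policies(kind: str, quad: list[str], threshold=None) -> None:
        groups = [tuple(quad)] if group_replicates \
            else [(w,) for w in quad]
        for g in groups:
            policies.append(FeedbackPolicy(kind=kind, threshold=threshold,
                                           wells=g))

    for param_i, intensity in enumerate(CONSTANT_LIGHT_INTENSITIES):
        quad = []
        for _ in range(4):
            w = WELLS[idx]
            protocols[w] = StimProtocol(intensity=int(intensity), t_on=3.0,
                                        t_off=7.0)
            condition[w] = f"constant_{param_i}"
            quad.append(w)
            idx += 1
        add_policies("constant", quad)
    for param_i, thr in enumerate(FLUOR_THRESHOLDS):
        quad = []
        for _ in range(4):
            w = WELLS[idx]
            protocols[w] = _fresh(PULSED_BLUE)
            condition[w] = f"fluor_halt_{param_i}"
            quad.append(w)
            idx += 1
        add_policies("stop_on_fluorescence", quad, float(thr))
    for param_i, thr in enumerate(OD_THRESHOLDS):
        quad = []
        for _ in range(4):
            w = WELLS[idx]
            protocols[w] = _fresh(PULSED_BLUE)
            condition[w] = f"od_start_{param_i}"
            quad.append(w)
            idx += 1
        add_policies("start_on_od", quad, float(thr))
    assert idx == 96
    for w in WELLS:
        cultures[w] = WellCulture(turbidity=initial_turbidity)
        circuits[w] = ExpressionCircuit(kind="pDawn")
    plan = MeasurementPlan(od_period_min=20, fluor_period_min=20,
                           duration_h=10)
    return PlateFixture("feedback_grid", cultures, circuits, protocols,
                        policies, plan, condition=condition)


FIXTURES = {
    "arabinose": arabinose_plate,
    "optogenetic-half-plate": optogenetic_half_plate,
    "feedback-grid": feedback_grid_plate,
}


def turbidity_series(reference_ods=(0.05, 0.1, 0.2, 0.4, 0.8)) -> np.ndarray:
    """Reference-instrument OD values of the standard bead dilution series."""
    return np.asarray(reference_ods, dtype=float)


def dye_series(concs=(2.0, 5.0, 10.0, 20.0, 30.0, 40.0)) -> np.ndarray:
    """Dye concentrations (µg/mL) of the standard fluorescence series."""
    return np.asarray(concs, dtype=float)
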
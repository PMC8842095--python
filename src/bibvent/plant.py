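"""Pneumatic bag-in-bottle plant coupled to a single-compartment lung.

The device drives inspiration by pressurising a sealed chamber ("bottle")
around a 1 L resuscitator bag; chamber pressure squeezes the bag and expels
gas into the patient airway.  Expiration is passive through a threshold
PEEP valve while the chamber exhausts and the bag self-refills.  The
patient (or test lung) is a linear single compartment with airway
resistance ``raw`` and respiratory-system compliance ``crs``; spontaneous
inspiratory effort is modelled as a half-sine muscle-pressure pulse
subtracted from the elastic recoil pressure.

State equations advanced by :func:`step_plant` (explicit Euler, default
dt = 1 ms):

* chamber pressure relaxes first-order toward ``drive * p_supply`` during
  inspiration and toward ambient during expiration, time constant
  ``tau_chamber``;
* inspiratory flow is pressure-driven through the bag-outlet and airway
  resistances in series, saturated at the bag's maximum outflow ``f_max``
  (which scales linearly with supply pressure and degrades with cycle
  count), and stops when the bag is empty;
* expiratory flow passes an ideal threshold PEEP valve:
  ``q = -max(0, p_alv - PEEP) / r_exp`` (plus an optional leak);
* airway pressure is ``p_aw = p_alv + raw * q`` at the sensing point.

Units: pressure cmH2O (supply pressure in bar, converted), volume mL,
flow mL/s, time s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .settings import VentSettings

__all__ = [
    "CMH2O_PER_BAR",
    "Phase",
    "PlantParams",
    "LungParams",
    "PlantState",
    "step_plant",
    "bag_refill",
    "effort_waveform",
    "initial_state",
]

CMH2O_PER_BAR = 1019.716

_MAX_DT = 0.005  # s; explicit Euler accuracy/stability guard


class Phase(str, Enum):
    INSPIRATION = "INSPIRATION"
    EXPIRATION = "EXPIRATION"


@dataclass(frozen=True, slots=True)
class PlantParams:
    """Physical constants of the bag-in-bottle pneumatics.

    ``f_max_nominal`` is the maximum bag outflow at the nominal 4.0 bar
    supply; the effective limit scales linearly with supply pressure and
    declines linearly with cycle count at ``degradation_rate`` (fraction
    of nominal per million cycles, used by the endurance harness).
    """

    supply_pressure: float = 4.0      # bar, nominal design point
    bag_volume_max: float = 1000.0    # mL, resuscitator bag volume
    f_max_nominal: float = 825.0      # mL/s at 4.0 bar
    r_bag: float = 0.0025             # cmH2O/(mL/s), bag outlet resistance
    tau_chamber: float = 0.01         # s, chamber pressurisation time constant
    chamber_relief: float = 60.0      # cmH2O, bottle relief-valve ceiling
    r_exp: float = 0.03               # cmH2O/(mL/s), expiratory circuit resistance
    tau_refill: float = 0.3           # s, bag self-refill time constant
    leak_conductance: float = 0.0     # mL/s per cmH2O; PEEP-valve leak (0 = ideal)
    degradation_rate: float = 0.0     # fraction of f_max per 1e6 cycles

    def f_max(self, supply_pressure: float | None = None, cycles: float = 0.0) -> float:
        """Effective maximum bag outflow (mL/s), clipped below at zero."""
        p = self.supply_pressure if supply_pressure is None else supply_pressure
        wear = 1.0 - self.degradation_rate * cycles / 1e6
        return max(0.0, self.f_max_nominal * (p / 4.0) * max(0.0, wear))


@dataclass(frozen=True, slots=True)
class LungParams:
    """Linear single-compartment respiratory mechanics plus optional effort."""

    raw: float = 20.0             # cmH2O/(L/s), airway resistance
    crs: float = 17.7             # mL/cmH2O, respiratory-system compliance
    effort_amplitude: float = 0.0  # cmH2O; 0 = passive patient
    effort_duration: float = 0.6   # s, half-sine pulse width
    effort_rate: float = 12.0      # efforts per minute

    def __post_init__(self) -> None:
        if self.raw <= 0 or self.crs <= 0:
            raise ValueError("raw and crs must be positive")
        if self.effort_amplitude < 0:
            raise ValueError("effort_amplitude must be non-negative")

    @property
    def raw_ml(self) -> float:
        """Airway resistance in cmH2O/(mL/s)."""
        return self.raw / 1000.0


@dataclass(frozen=True, slots=True)
class PlantState:
    """Instantaneous pneumatic and lung state.

    ``v_lung`` is volume above the relaxation volume, so the elastic
    recoil pressure is ``v_lung / crs``; at passive end-expiratory
    equilibrium on PEEP, ``v_lung = crs * peep_set``.
    """

    t: float = 0.0
    p_chamber: float = 0.0   # cmH2O
    v_bag: float = 1000.0    # mL
    v_lung: float = 0.0      # mL above relaxation volume
    q_aw: float = 0.0        # mL/s, positive into the patient
    p_aw: float = 0.0        # cmH2O at the airway sensing point
    phase: Phase = Phase.EXPIRATION


def initial_state(settings: VentSettings, plant: PlantParams, lung: LungParams,
                  phase: Phase = Phase.EXPIRATION) -> PlantState:
    """Passive equilibrium state on the set PEEP with a full bag."""
    v0 = lung.crs * settings.peep_set
    return PlantState(t=0.0, p_chamber=0.0, v_bag=plant.bag_volume_max,
                      v_lung=v0, q_aw=0.0, p_aw=settings.peep_set, phase=phase)


def effort_waveform(t: float, lung: LungParams) -> float:
    """Patient muscle pressure p_mus at time ``t`` (positive magnitude).

    A half-sine pulse of ``effort_amplitude`` and ``effort_duration``
    repeating at ``effort_rate`` per minute; identically zero for a
    passive patient.  The value is subtracted from elastic recoil in the
    alveolar pressure balance, so a pulse pulls airway pressure below
    PEEP — the signature the trigger detector looks for.
    """
    if lung.effort_amplitude <= 0.0 or lung.effort_rate <= 0.0 or lung.effort_duration <= 0.0:
        return 0.0
    period = 60.0 / lung.effort_rate
    t_in = t % period
    if t_in >= lung.effort_duration:
        return 0.0
    return lung.effort_amplitude * math.sin(math.pi * t_in / lung.effort_duration)


def _check_state(state: PlantState) -> None:
    for name in ("t", "p_chamber", "v_bag", "v_lung", "q_aw", "p_aw"):
        v = getattr(state, name)
        if math.isnan(v):
            raise ValueError(f"NaN in plant state field {name!r}")


def step_plant(state: PlantState, drive_command: float, settings: VentSettings,
               plant: PlantParams, lung: LungParams, dt: float,
               cycles: float = 0.0) -> PlantState:
    """Advance the plant by one Euler step of length ``dt``.

    ``drive_command`` is the fraction (0-1) of the supply pressure the
    chamber is driven toward; it is the single actuator the controller
    owns.  ``cycles`` feeds the endurance degradation model and is zero
    for ordinary runs.
    """
    if not (0.0 < dt <= _MAX_DT):
        raise ValueError(f"dt must be in (0, {_MAX_DT}] s, got {dt}")
    _check_state(state)

    p_supply = plant.supply_pressure * CMH2O_PER_BAR
    p_mus = effort_waveform(state.t, lung)
    p_alv = state.v_lung / lung.crs - p_mus

    if state.phase is Phase.INSPIRATION:
        # the bottle's relief valve caps the drive pressure it can hold
        target = min(max(0.0, min(1.0, drive_command)) * p_supply,
                     plant.chamber_relief)
        p_chamber = state.p_chamber + (target - state.p_chamber) / plant.tau_chamber * dt
        q = (p_chamber - p_alv) / (plant.r_bag + lung.raw_ml)
        q = min(max(q, 0.0), plant.f_max(cycles=cycles))
        if state.v_bag <= 0.0:
            q = 0.0
        v_bag = max(0.0, state.v_bag - q * dt)
        v_lung = max(0.0, state.v_lung + q * dt)
    else:
        p_chamber = state.p_chamber - state.p_chamber / plant.tau_chamber * dt
        q = -max(0.0, p_alv - settings.peep_set) / plant.r_exp
        if plant.leak_conductance > 0.0:
            q -= plant.leak_conductance * max(0.0, p_alv)
        v_bag = state.v_bag
        v_lung = max(0.0, state.v_lung + q * dt)

    p_aw = p_alv + lung.raw_ml * q
    return PlantState(t=state.t + dt, p_chamber=p_chamber, v_bag=v_bag,
                      v_lung=v_lung, q_aw=q, p_aw=p_aw, phase=state.phase)


def bag_refill(state: PlantState, dt: float, plant: PlantParams) -> PlantState:
    """Refill the resuscitator bag during expiration.

    First-order recovery toward ``bag_volume_max`` with time constant
    ``tau_refill``; never overshoots the bag volume.
    """
    if state.phase is not Phase.EXPIRATION:
        raise ValueError("bag_refill requires the EXPIRATION phase")
    deficit = plant.bag_volume_max - state.v_bag
    v = state.v_bag + deficit / plant.tau_refill * dt
    return replace(state, v_bag=min(plant.bag_volume_max, v))
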
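"""Design-verification harness: scripted bench experiments on the twin.

Three experiment families probe the envelope of the bag-in-bottle design:

* **maximum achievable therapy** — high-flow configurations (required
  inspiratory flow 750-900 mL/s and beyond) where the finite bag outflow
  limits delivery;
* **supply-pressure variation** — delivery as the compressed-air supply
  departs from the nominal 4.0 bar design point;
* **endurance** — continuous operation with a parametric degradation of
  the bag's maximum outflow, sampled every 24 simulated hours.

Bench experiments run at ZEEP (no PEEP valve fitted on the test lung) with
Plimit raised to 45 cmH2O under the engineering override so that pressure
limiting does not confound the flow-capability measurement.  The pass
criterion everywhere is delivered VT within +/-10% of target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .control import BreathRecord, run_ventilation
from .plant import LungParams, PlantParams
from .settings import VentSettings, compute_timing

__all__ = [
    "ExperimentResult",
    "run_to_steady",
    "run_max_therapy_sweep",
    "run_supply_pressure_test",
    "run_endurance",
    "run_step_response",
    "max_therapy_default_configs",
    "DECREASING_PRESSURE_SETTINGS",
    "INCREASING_PRESSURE_SETTINGS",
    "DECREASING_PRESSURES",
    "INCREASING_PRESSURES",
    "ENDURANCE_SETTINGS",
    "ENDURANCE_DEGRADATION_RATE",
    "ARDS_TEST_LUNG",
]

#: Standard adult test lung with ARDS-consistent mechanics.
ARDS_TEST_LUNG = LungParams(raw=20.0, crs=17.7)

#: Bench preset: decreasing-supply scenario (VT=600, RR=25, I:E=1:2).
DECREASING_PRESSURE_SETTINGS = VentSettings(
    vt_target=600.0, rr=25.0, insp_parts=1, exp_parts=2, peep_set=0.0,
    plimit=45.0, engineering_override=True)
DECREASING_PRESSURES = (4.0, 3.5, 3.0)

#: Bench preset: increasing-supply scenario (VT=450, RR=15, I:E=1:2).
INCREASING_PRESSURE_SETTINGS = VentSettings(
    vt_target=450.0, rr=15.0, insp_parts=1, exp_parts=2, peep_set=0.0,
    plimit=45.0, engineering_override=True)
INCREASING_PRESSURES = (4.0, 4.5, 5.0, 5.5, 6.0)

#: Endurance preset: continuous high-flow operation on PEEP 10.
ENDURANCE_SETTINGS = VentSettings(
    vt_target=600.0, rr=27.0, insp_parts=1, exp_parts=2, peep_set=10.0,
    plimit=45.0, engineering_override=True)

#: Bag-wear fixture for the endurance preset: fraction of nominal maximum
#: outflow lost per million cycles, calibrated so the effective outflow
#: crosses the preset's required flow between days 23 and 24 of continuous
#: operation.  This is a fixture describing the worn bag, not a prediction
#: of silicone-valve wear.
ENDURANCE_DEGRADATION_RATE = 0.1275


@dataclass(frozen=True, slots=True)
class ExperimentResult:
    """Per-configuration verification outcome over 10 settled cycles."""

    config_label: str
    set_vt: float
    delivered_vt_per_cycle: tuple[float, ...]
    mean_delivered: float
    worst_error_pct: float
    passed: bool
    required_flow: float
    supply_pressure: float
    steady_state_reached: bool


def _is_steady(records: list[BreathRecord], i: int, window: int, tol: float) -> bool:
    """True if the ``window`` cycles ending at index ``i`` changed by < tol each."""
    if i - window + 1 < 1:
        return False
    for j in range(i - window + 2, i + 1):
        prev = records[j - 1].vt_delivered
        cur = records[j].vt_delivered
        ref = max(abs(prev), 1.0)
        if abs(cur - prev) > tol * ref:
            return False
    return True


def run_to_steady(settings: VentSettings, plant: PlantParams, lung: LungParams,
                  *, n_record: int = 10, max_cycles: int = 50,
                  settle_window: int = 5, settle_tol: float = 0.01,
                  label: str | None = None) -> ExperimentResult:
    """Run until steady state, then score ``n_record`` consecutive cycles.

    Steady state is declared after ``settle_window`` consecutive cycles
    whose delivered VT changes by less than ``settle_tol`` (1%) between
    cycles.  If no steady state appears within ``max_cycles`` the last
    ``n_record`` cycles are scored and the result is flagged.
    """
    timing = compute_timing(settings)
    duration = (max_cycles + n_record + 1) * timing.t_cycle
    _, records = run_ventilation(settings, plant, lung, duration)

    steady_at: int | None = None
    for i in range(len(records) - n_record):
        if _is_steady(records, i, settle_window, settle_tol):
            steady_at = i
            break
    reached = steady_at is not None and steady_at < max_cycles
    start = steady_at + 1 if steady_at is not None else max(0, len(records) - n_record)
    chunk = records[start:start + n_record]
    delivered = tuple(r.vt_delivered for r in chunk)
    mean = sum(delivered) / len(delivered)
    worst = max(abs(v - settings.vt_target) / settings.vt_target * 100.0
                for v in delivered) if settings.vt_target > 0 else 0.0
    return ExperimentResult(
        config_label=label or (f"VT={settings.vt_target:g} RR={settings.rr:g} "
                               f"I:E={settings.insp_parts}:{settings.exp_parts}"),
        set_vt=settings.vt_target,
        delivered_vt_per_cycle=delivered,
        mean_delivered=mean,
        worst_error_pct=worst,
        passed=bool(reached and worst <= 10.0),
        required_flow=timing.required_flow,
        supply_pressure=plant.supply_pressure,
        steady_state_reached=bool(reached),
    )


def max_therapy_default_configs() -> list[VentSettings]:
    """High-flow configurations spanning the capability limit.

    Required flows run from comfortably attainable (675 mL/s) through the
    825 mL/s bag-outflow limit up to the unattainable 1200 mL/s corner of
    the RMVS envelope (VT=600, RR=30, I:E=1:3).
    """
    base = dict(peep_set=0.0, plimit=45.0, engineering_override=True)
    return [
        VentSettings(vt_target=450.0, rr=30.0, insp_parts=1, exp_parts=2, **base),  # 675
        VentSettings(vt_target=500.0, rr=30.0, insp_parts=1, exp_parts=2, **base),  # 750
        VentSettings(vt_target=600.0, rr=25.0, insp_parts=1, exp_parts=2, **base),  # 750
        VentSettings(vt_target=600.0, rr=27.0, insp_parts=1, exp_parts=2, **base),  # 810
        VentSettings(vt_target=600.0, rr=30.0, insp_parts=1, exp_parts=2, **base),  # 900
        VentSettings(vt_target=600.0, rr=30.0, insp_parts=1, exp_parts=3, **base),  # 1200
    ]


def run_max_therapy_sweep(configs: list[VentSettings], plant: PlantParams,
                          lung: LungParams) -> list[ExperimentResult]:
    """Score each high-flow configuration over 10 settled cycles."""
    return [run_to_steady(cfg, plant, lung) for cfg in configs]


def run_supply_pressure_test(pressures: list[float], settings: VentSettings,
                             plant: PlantParams, lung: LungParams
                             ) -> list[ExperimentResult]:
    """Repeat one configuration across supply pressures (bar)."""
    results = []
    for p in pressures:
        if p <= 0:
            raise ValueError(f"supply pressure must be positive, got {p}")
        results.append(run_to_steady(
            settings, replace(plant, supply_pressure=p), lung,
            label=f"{p:g} bar"))
    return results


def run_endurance(settings: VentSettings, plant: PlantParams,
                  simulated_days: int, surrogate: bool = True,
                  lung: LungParams = ARDS_TEST_LUNG,
                  n_sample: int = 10) -> tuple[int, int | None]:
    """Long-term run with bag degradation, sampled every 24 h.

    Returns ``(days_within_bounds, failure_day)`` where the failure day is
    the first daily 10-cycle sample with any cycle outside +/-10% of
    target (``None`` if none within ``simulated_days``).

    With ``surrogate=True`` (default) each sampled breath uses the
    flow-saturation closed form ``min(VT, f_max(cycles) * t_insp)``, which
    isolates the flow-capability wear mode and runs weeks of simulated
    operation in milliseconds.  ``surrogate=False`` integrates the full
    plant instead; use it only on configurations whose peak pressures stay
    below Plimit, since pressure limiting otherwise confounds the
    flow-capability measurement (the default endurance preset, VT=600 at
    810 mL/s on PEEP 10, is outside that capability for this plant).
    """
    timing = compute_timing(settings)
    cycles_per_day = settings.rr * 60.0 * 24.0
    days_within = 0
    failure_day: int | None = None
    for day in range(1, simulated_days + 1):
        cycles = day * cycles_per_day
        if surrogate:
            f_max = plant.f_max(cycles=cycles)
            delivered = [min(settings.vt_target, f_max * timing.t_insp,
                             plant.bag_volume_max)] * n_sample
        else:
            worn = replace(plant, f_max_nominal=plant.f_max_nominal
                           * max(0.0, 1.0 - plant.degradation_rate * cycles / 1e6),
                           degradation_rate=0.0)
            res = run_to_steady(settings, worn, lung, n_record=n_sample)
            delivered = list(res.delivered_vt_per_cycle)
        ok = all(abs(v - settings.vt_target) <= 0.10 * settings.vt_target
                 for v in delivered)
        if ok and failure_day is None:
            days_within = day
        elif failure_day is None:
            failure_day = day
    return days_within, failure_day


def run_step_response(plant: PlantParams, lung: LungParams = ARDS_TEST_LUNG, *,
                      vt_from: float = 400.0, vt_to: float = 600.0,
                      rr: float = 20.0, insp_parts: int = 1, exp_parts: int = 2,
                      peep: float = 5.0, settle_cycles: int = 30,
                      follow_cycles: int = 20, tol: float = 0.10,
                      hold: int = 3) -> tuple[int | None, list[BreathRecord]]:
    """Step the VT target and count cycles to re-enter the +/-10% band.

    Runs ``settle_cycles`` at ``vt_from``, steps the target to ``vt_to``,
    and returns the number of cycles (1 = first post-step cycle) until
    delivered VT first enters and remains within ``tol`` of the new target
    for ``hold`` consecutive cycles, together with the full breath log.
    Returns ``None`` for the count if the band is never held.
    """
    settings = VentSettings(vt_target=vt_from, rr=rr, insp_parts=insp_parts,
                            exp_parts=exp_parts, peep_set=peep, plimit=45.0,
                            engineering_override=True)
    timing = compute_timing(settings)
    t_step = settle_cycles * timing.t_cycle - timing.t_cycle / 2.0
    duration = (settle_cycles + follow_cycles) * timing.t_cycle
    _, records = run_ventilation(settings, plant, lung, duration,
                                 vt_schedule=[(t_step, vt_to)])
    step_idx = next((i for i, r in enumerate(records) if r.vt_target == vt_to),
                    None)
    if step_idx is None:
        return None, records
    in_band = [abs(r.vt_delivered - vt_to) <= tol * vt_to
               for r in records[step_idx:]]
    for k in range(len(in_band) - hold + 1):
        if all(in_band[k:k + hold]) and all(in_band[k:]):
            return k + 1, records
    return None, records
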
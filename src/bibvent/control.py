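"""Discrete-time re-implementation of the ventilator control firmware.

The firmware owns a single actuator — the drive command ``u`` (fraction of
supply pressure applied to the chamber) — and adjusts it **once per
breath** from the error between the integrated tidal volume delivered and
the set target.  Control is a velocity-form PID, deliberately overdamped
so that a step change in requested therapy settles without volume
overshoot, at the cost of a response time of several cycles.

Within each breath the firmware also:

* samples the pressure/flow sensors at a fixed rate (minimum 25 Hz),
* integrates flow to measure delivered tidal volume,
* estimates PEEP from the expiratory pressure waveform, discarding the
  first 75% of expiration so the estimate reflects the end-expiratory
  plateau (at 25 Hz and a 1 s expiration this leaves at least 5 readings),
* maintains an auto-regressive baseline PEEP,
  ``baseline(i+1) = beta*baseline(i) + (1-beta)*PEEP(i)`` with beta = 0.7,
  which balances noise rejection against responsiveness,
* in assisted-spontaneous mode, triggers a breath when airway pressure
  drops below ``baseline - trigger_delta``,
* enforces the inspiratory pressure limit by cutting inspiration short the
  moment a sampled pressure reaches Plimit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .plant import (LungParams, Phase, PlantParams, bag_refill,
                    initial_state, step_plant)
from .settings import Mode, VentSettings, compute_timing
from .wavio import WaveformSample

__all__ = [
    "Alarm",
    "PlimitAction",
    "PeepEstimatorState",
    "PidState",
    "BreathRecord",
    "update_pid",
    "estimate_peep",
    "update_baseline",
    "check_trigger",
    "enforce_plimit",
    "run_ventilation",
    "DEFAULT_REFRACTORY_S",
]

#: Lock-out after expiration onset before a trigger is accepted, so the
#: expiratory pressure transient cannot re-trigger a breath.
DEFAULT_REFRACTORY_S = 0.2


class Alarm(str, Enum):
    PLIMIT = "PLIMIT"
    VT_DEVIATION = "VT_DEVIATION"
    SUPPLY_LOW = "SUPPLY_LOW"


class PlimitAction(str, Enum):
    CONTINUE = "CONTINUE"
    CUT_INSPIRATION = "CUT_INSPIRATION"


@dataclass(slots=True)
class PeepEstimatorState:
    """Windowed PEEP measurement plus the auto-regressive baseline.

    ``baseline`` is ``None`` until the first cycle's PEEP seeds it.
    """

    beta: float = 0.7
    baseline: float | None = None
    window_fraction_discarded: float = 0.75
    sample_rate: float = 25.0   # Hz
    last_cycle_peep: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta < 1.0):
            raise ValueError("beta must lie in [0, 1)")
        if not (0.0 <= self.window_fraction_discarded < 1.0):
            raise ValueError("window_fraction_discarded must lie in [0, 1)")
        if self.sample_rate < 25.0:
            raise ValueError("sample_rate must be at least 25 Hz")


@dataclass(frozen=True, slots=True)
class PidState:
    """Velocity-form PID over the per-breath VT error (mL -> drive units)."""

    kp: float = 3e-6
    ki: float = 5e-6
    kd: float = 0.0
    e_prev: float = 0.0
    e_prev2: float = 0.0
    u: float = 0.005
    u_min: float = 0.0
    u_max: float = 1.0


@dataclass(slots=True)
class BreathRecord:
    """Per-cycle outcome log."""

    index: int
    vt_delivered: float          # mL, integrated from sampled flow
    vt_error: float              # mL, target - delivered
    vt_target: float             # mL, target in force for this breath
    peep_measured: float         # cmH2O
    baseline_peep: float         # cmH2O
    t_insp_actual: float         # s
    t_exp_actual: float          # s
    p_peak: float                # cmH2O
    triggered: bool = False
    plimit_hit: bool = False
    alarms: set[Alarm] = field(default_factory=set)


def update_pid(pid: PidState, vt_error: float) -> PidState:
    """One per-breath velocity-form PID update.

    ``u <- clamp(u + kp*(e - e_prev) + ki*e + kd*(e - 2*e_prev + e_prev2))``.
    Clamping the command to ``[u_min, u_max]`` provides anti-windup: the
    stored state is the clamped command itself.
    """
    if not math.isfinite(vt_error):
        raise ValueError("vt_error must be finite")
    e = vt_error
    du = (pid.kp * (e - pid.e_prev)
          + pid.ki * e
          + pid.kd * (e - 2.0 * pid.e_prev + pid.e_prev2))
    u = min(pid.u_max, max(pid.u_min, pid.u + du))
    return replace(pid, u=u, e_prev=e, e_prev2=pid.e_prev)


def estimate_peep(expiration_samples: list[tuple[float, float]], t_exp: float,
                  est: PeepEstimatorState) -> float:
    """Windowed PEEP estimate over one expiration.

    ``expiration_samples`` are ``(t, p_aw)`` pairs with ``t`` measured from
    expiration onset.  Readings during the first
    ``window_fraction_discarded`` (default 75%) of the expiration are
    discarded and the arithmetic mean of the remainder is returned and
    stored as ``last_cycle_peep``.
    """
    if t_exp <= 0:
        raise ValueError("t_exp must be positive")
    cutoff = est.window_fraction_discarded * t_exp
    window = [p for (t, p) in expiration_samples if t >= cutoff - 1e-12]
    if not window:
        raise ValueError(
            "PEEP window contains no samples; increase the sample rate or "
            "lengthen expiration")
    peep = sum(window) / len(window)
    est.last_cycle_peep = peep
    return peep


def update_baseline(est: PeepEstimatorState, peep_i: float) -> PeepEstimatorState:
    """Auto-regressive baseline update; first cycle seeds the baseline."""
    if est.baseline is None:
        baseline = peep_i
    else:
        baseline = est.beta * est.baseline + (1.0 - est.beta) * peep_i
    return PeepEstimatorState(
        beta=est.beta, baseline=baseline,
        window_fraction_discarded=est.window_fraction_discarded,
        sample_rate=est.sample_rate, last_cycle_peep=est.last_cycle_peep)


def check_trigger(p_aw_sample: float, est: PeepEstimatorState,
                  settings: VentSettings, phase: Phase, t_in_phase: float,
                  refractory_s: float = DEFAULT_REFRACTORY_S) -> bool:
    """Patient-trigger test for one expiratory pressure sample.

    True iff in ASV expiration, past the refractory period, with a
    baseline available, and the sampled pressure strictly below
    ``baseline - trigger_delta``.
    """
    if settings.mode is not Mode.ASV or phase is not Phase.EXPIRATION:
        return False
    if est.baseline is None or t_in_phase < refractory_s:
        return False
    return p_aw_sample < est.baseline - settings.trigger_delta


def enforce_plimit(p_aw: float, settings: VentSettings) -> PlimitAction:
    """Inspiratory pressure-limit check; the boundary itself trips the cut."""
    if p_aw >= settings.plimit:
        return PlimitAction.CUT_INSPIRATION
    return PlimitAction.CONTINUE


# ---------------------------------------------------------------------------
# Closed-loop orchestration


class _NoiseStreams:
    """Seeded, mutually independent sensor-noise streams.

    Streams are derived from one integer seed with fixed spawn keys so
    that adding a consumer never perturbs existing outputs.
    """

    PRESSURE_SD = 0.2  # cmH2O
    FLOW_SD = 5.0      # mL/s

    def __init__(self, seed: int | None, enabled: bool):
        self.enabled = enabled
        if enabled:
            base = 0 if seed is None else int(seed)
            self._p = np.random.default_rng(np.random.SeedSequence(base, spawn_key=(0,)))
            self._q = np.random.default_rng(np.random.SeedSequence(base, spawn_key=(1,)))

    def pressure(self, p: float) -> float:
        if not self.enabled:
            return p
        return p + self.PRESSURE_SD * self._p.standard_normal()

    def flow(self, q: float) -> float:
        if not self.enabled:
            return q
        return q + self.FLOW_SD * self._q.standard_normal()


def run_ventilation(settings: VentSettings, plant: PlantParams, lung: LungParams,
                    duration: float, seed: int | None = None, *,
                    noise_enabled: bool = False,
                    dt: float = 1e-3,
                    sample_rate: float = 25.0,
                    vt_schedule: list[tuple[float, float]] | None = None,
                    pid: PidState | None = None,
                    estimator: PeepEstimatorState | None = None,
                    refractory_s: float = DEFAULT_REFRACTORY_S,
                    ) -> tuple[list[WaveformSample], list[BreathRecord]]:
    """Closed-loop simulation of the ventilator on the given plant and lung.

    VCV runs timer-driven at the set RR and I:E; ASV waits for a patient
    trigger during expiration and falls back to a mandatory breath if a
    full set cycle elapses without one.  ``vt_schedule`` is an optional
    list of ``(time_s, new_target_mL)`` setpoint changes, applied at the
    next breath boundary.  All randomness (sensor noise only) derives from
    ``seed``; with ``noise_enabled=False`` the run is fully deterministic.

    Returns the sensor-rate waveform log and the per-breath records.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    timing = compute_timing(settings)
    pid = pid if pid is not None else PidState()
    est = estimator if estimator is not None else PeepEstimatorState()
    noise = _NoiseStreams(seed, noise_enabled)
    schedule = sorted(vt_schedule or [])
    sched_pos = 0
    vt_target = settings.vt_target

    n_sub = max(1, round(1.0 / (sample_rate * dt)))
    n_steps = round(duration / dt)

    samples: list[WaveformSample] = []
    breaths: list[BreathRecord] = []

    state = initial_state(settings, plant, lung, phase=Phase.INSPIRATION)
    supply_low = plant.f_max() < timing.required_flow

    # per-breath working variables
    breath_index = 1
    triggered = False
    plimit_hit = False
    vt_acc = 0.0
    p_peak = -math.inf
    prev_insp_sample: tuple[float, float] | None = None
    exp_samples: list[tuple[float, float]] = []
    phase_start = 0.0
    t_insp_actual = 0.0
    deviation_streak = 0

    def begin_expiration(now: float) -> None:
        nonlocal state, phase_start, t_insp_actual, exp_samples
        t_insp_actual = now - phase_start
        phase_start = now
        exp_samples = []
        state = replace(state, phase=Phase.EXPIRATION)

    def finish_breath(now: float, next_triggered: bool) -> None:
        """Close the current breath at expiration end and start the next."""
        nonlocal state, phase_start, pid, est, breath_index, triggered
        nonlocal plimit_hit, vt_acc, p_peak, prev_insp_sample, vt_target
        nonlocal deviation_streak, sched_pos
        t_exp_actual = now - phase_start
        # window against the expiration actually seen, so trigger-shortened
        # cycles still average mostly pre-effort plateau samples
        try:
            peep = estimate_peep(exp_samples, t_exp_actual, est)
        except ValueError:
            peep = est.last_cycle_peep if est.last_cycle_peep is not None \
                else settings.peep_set
        est = update_baseline(est, peep)

        vt_error = vt_target - vt_acc
        alarms: set[Alarm] = set()
        if plimit_hit:
            alarms.add(Alarm.PLIMIT)
        if supply_low:
            alarms.add(Alarm.SUPPLY_LOW)
        if abs(vt_error) > 0.10 * vt_target if vt_target > 0 else False:
            deviation_streak += 1
        else:
            deviation_streak = 0
        if deviation_streak >= 3:
            alarms.add(Alarm.VT_DEVIATION)

        breaths.append(BreathRecord(
            index=breath_index, vt_delivered=vt_acc, vt_error=vt_error,
            vt_target=vt_target, peep_measured=peep,
            baseline_peep=est.baseline if est.baseline is not None else peep,
            t_insp_actual=t_insp_actual, t_exp_actual=t_exp_actual,
            p_peak=p_peak, triggered=triggered, plimit_hit=plimit_hit,
            alarms=alarms))
        # conditional anti-windup: a pressure-limited breath under-delivers
        # by design, so its positive error must not wind the drive up
        if not (plimit_hit and vt_error > 0.0):
            pid = update_pid(pid, vt_error)

        while sched_pos < len(schedule) and schedule[sched_pos][0] <= now:
            vt_target = schedule[sched_pos][1]
            sched_pos += 1

        breath_index += 1
        triggered = next_triggered
        plimit_hit = False
        vt_acc = 0.0
        p_peak = -math.inf
        prev_insp_sample = None
        phase_start = now
        state = replace(state, phase=Phase.INSPIRATION)

    # All control decisions (phase changes, trigger, pressure limiting) are
    # made at sensor ticks, like the discrete firmware; the plant itself is
    # integrated at dt between ticks.  The sample taken at the tick that
    # closes an inspiration still carries inspiratory flow and forms the
    # right edge of the tidal-volume integral.
    half_tick = 0.5 * n_sub * dt
    for k in range(n_steps):
        if k % n_sub == 0:
            now = state.t
            p_s = noise.pressure(state.p_aw)
            q_s = noise.flow(state.q_aw)
            t_in_phase = now - phase_start

            if state.phase is Phase.INSPIRATION:
                cut = enforce_plimit(p_s, settings) is PlimitAction.CUT_INSPIRATION
                if cut or t_in_phase >= timing.t_insp - half_tick:
                    if prev_insp_sample is not None:
                        t0, q0 = prev_insp_sample
                        vt_acc += 0.5 * (q0 + q_s) * (now - t0)
                    p_peak = max(p_peak, p_s)
                    plimit_hit = plimit_hit or cut
                    begin_expiration(now)
            else:
                # keep the set RR: a pressure-limited (shortened)
                # inspiration lengthens the expiration that follows it
                timeout = (timing.t_cycle - t_insp_actual
                           if settings.mode is Mode.VCV else timing.t_cycle)
                if t_in_phase >= timeout - half_tick:
                    finish_breath(now, next_triggered=False)
                elif check_trigger(p_s, est, settings, state.phase, t_in_phase,
                                   refractory_s):
                    finish_breath(now, next_triggered=True)

            t_in_phase = now - phase_start
            samples.append(WaveformSample(
                t=now, p_aw=p_s, q_aw=q_s, v_lung=state.v_lung,
                p_chamber=state.p_chamber, phase=state.phase.value,
                drive_u=pid.u))
            if state.phase is Phase.INSPIRATION:
                if prev_insp_sample is not None:
                    t0, q0 = prev_insp_sample
                    vt_acc += 0.5 * (q0 + q_s) * (now - t0)
                prev_insp_sample = (now, q_s)
                p_peak = max(p_peak, p_s)
            else:
                exp_samples.append((t_in_phase, p_s))

        drive = pid.u if state.phase is Phase.INSPIRATION else 0.0
        state = step_plant(state, drive, settings, plant, lung, dt)
        if state.phase is Phase.EXPIRATION:
            state = bag_refill(state, dt, plant)

    return samples, breaths
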
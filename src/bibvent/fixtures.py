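"""Seeded synthetic-waveform generator.

Every fixture is a deterministic function of ``(kind, params, seed)``;
they exercise the PEEP estimator, the trigger detector and the closed
loop without any recorded data.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np

from .plant import LungParams, PlantParams
from .settings import Mode, VentSettings
from .wavio import WaveformSample

__all__ = ["generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("square_peep", "noisy_peep", "effort_train", "step_target")


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(0 if seed is None else int(seed),
                                                        spawn_key=(2,)))


def _plateau(params: dict[str, Any], noise_sd: float, seed: int | None,
             effort: dict[str, float] | None = None) -> list[WaveformSample]:
    peep = float(params.get("peep", 5.0))
    duration = float(params.get("duration", 4.0))
    rate = float(params.get("sample_rate", 25.0))
    rng = _rng(seed)
    n = int(round(duration * rate))
    out = []
    for k in range(n):
        t = k / rate
        p = peep
        if effort:
            period = effort["period"]
            tp = t % period
            if tp < effort["duration"]:
                p -= effort["amplitude"] * math.sin(math.pi * tp / effort["duration"])
        if noise_sd > 0:
            p += noise_sd * rng.standard_normal()
        out.append(WaveformSample(t=t, p_aw=p, q_aw=0.0, v_lung=0.0,
                                  p_chamber=0.0, phase="EXPIRATION", drive_u=0.0))
    return out


def generate_fixture(kind: str, params: dict[str, Any] | None = None,
                     seed: int | None = None) -> list[WaveformSample]:
    """Generate a synthetic waveform of the requested kind.

    Kinds:

    * ``square_peep`` — ideal expiratory plateau at ``peep``;
    * ``noisy_peep`` — the same plateau with seeded Gaussian noise
      (``sigma``, default 0.2 cmH2O);
    * ``effort_train`` — plateau with half-sine sub-PEEP deflections of
      ``amplitude`` and ``effort_duration`` at ``effort_rate`` per minute;
    * ``step_target`` — full closed-loop run with a mid-run VT setpoint
      change (``vt_from`` -> ``vt_to`` at ``t_step``).
    """
    params = dict(params or {})
    if kind == "square_peep":
        return _plateau(params, noise_sd=0.0, seed=seed)
    if kind == "noisy_peep":
        return _plateau(params, noise_sd=float(params.get("sigma", 0.2)), seed=seed)
    if kind == "effort_train":
        effort = {
            "amplitude": float(params.get("amplitude", 3.0)),
            "duration": float(params.get("effort_duration", 0.6)),
            "period": 60.0 / float(params.get("effort_rate", 12.0)),
        }
        return _plateau(params, noise_sd=float(params.get("sigma", 0.0)),
                        seed=seed, effort=effort)
    if kind == "step_target":
        from .control import run_ventilation  # deferred: heavier import
        settings = VentSettings(
            vt_target=float(params.get("vt_from", 400.0)),
            rr=float(params.get("rr", 20.0)),
            peep_set=float(params.get("peep", 5.0)),
            plimit=float(params.get("plimit", 45.0)),
            mode=Mode.VCV, engineering_override=True)
        duration = float(params.get("duration", 90.0))
        t_step = float(params.get("t_step", duration / 2.0))
        samples, _ = run_ventilation(
            settings, PlantParams(), LungParams(), duration, seed=seed,
            noise_enabled=bool(params.get("noise", False)),
            vt_schedule=[(t_step, float(params.get("vt_to", 600.0)))])
        return samples
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
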
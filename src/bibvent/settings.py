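"""Therapy settings and their validation against the RMVS envelope.

The RMVS (Rapidly Manufactured Ventilator System) specification defines the
minimum acceptable therapy ranges for an emergency-use ventilator: tidal
volume, respiratory rate, I:E ratio, inspiratory pressure limit, PEEP,
trigger pressure and FiO2.  :func:`validate_settings` checks a
:class:`VentSettings` against that envelope; :func:`compute_timing` derives
the per-breath timing quantities used by both the controller and the
verification harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Any

__all__ = [
    "Mode",
    "VentSettings",
    "BreathTiming",
    "Finding",
    "RMVS_LIMITS",
    "IE_RATIO_LIMITS",
    "validate_settings",
    "compute_timing",
    "settings_from_dict",
]


class Mode(str, Enum):
    """Ventilation mode: mandatory volume control or patient-triggered assist."""

    VCV = "VCV"
    ASV = "ASV"


#: RMVS envelope: field name -> (low, high), in the field's native units.
RMVS_LIMITS: dict[str, tuple[float, float]] = {
    "vt_target": (250.0, 600.0),       # mL
    "rr": (10.0, 30.0),                # breaths/min
    "plimit": (15.0, 40.0),            # cmH2O
    "peep_set": (5.0, 20.0),           # cmH2O
    "trigger_delta": (1.0, 10.0),      # cmH2O below baseline PEEP
    "fio2": (0.30, 1.00),              # fraction
}

#: I:E envelope 2:1 .. 1:3, expressed as the ratio insp/exp.
IE_RATIO_LIMITS: tuple[float, float] = (1.0 / 3.0, 2.0)

# Fields that must be strictly positive for the machine to operate at all;
# a non-positive value here is a hard error regardless of any override.
_STRICTLY_POSITIVE = ("rr", "insp_parts", "exp_parts", "plimit", "fio2", "trigger_delta")
# peep_set and vt_target may legitimately be zero (ZEEP bench runs; flow-zero
# edge cases) but never negative.
_NON_NEGATIVE = ("vt_target", "peep_set")


@dataclass(frozen=True, slots=True)
class VentSettings:
    """Clinician-facing therapy request.

    The I:E ratio is stored as an integer pair (``insp_parts`` :
    ``exp_parts``) rather than a float so that timing arithmetic is exact.
    ``trigger_delta`` is the positive magnitude of the airway-pressure drop
    below baseline PEEP that triggers an assisted breath; the sign
    convention (a drop *below* baseline) is applied at the comparison site.
    ``engineering_override`` permits out-of-envelope values for bench
    verification experiments (e.g. Plimit = 45 cmH2O to avoid
    pressure-limiting behaviour) and downgrades range violations to
    warnings.
    """

    vt_target: float = 400.0          # mL
    rr: float = 20.0                  # breaths/min
    insp_parts: int = 1
    exp_parts: int = 2
    peep_set: float = 5.0             # cmH2O
    plimit: float = 40.0              # cmH2O
    trigger_delta: float = 2.0        # cmH2O, positive magnitude
    fio2: float = 0.5                 # fraction 0-1
    mode: Mode = Mode.VCV
    engineering_override: bool = False

    @property
    def ie_ratio(self) -> float:
        """Inspiratory-to-expiratory time ratio as a float (insp/exp)."""
        return self.insp_parts / self.exp_parts


@dataclass(frozen=True, slots=True)
class BreathTiming:
    """Derived per-breath timing under the constant-flow assumption."""

    t_cycle: float        # s
    t_insp: float         # s
    t_exp: float          # s
    required_flow: float  # mL/s


@dataclass(frozen=True, slots=True)
class Finding:
    """One validation finding; ``severity`` is 'violation' or 'warning'."""

    field: str
    value: Any
    limits: tuple[float, float] | None
    message: str
    severity: str = "violation"


def _check_numeric(settings: VentSettings) -> None:
    for name in (
        "vt_target", "rr", "peep_set", "plimit", "trigger_delta", "fio2",
    ):
        v = getattr(settings, name)
        if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
            raise ValueError(f"{name} must be a finite number, got {v!r}")
    for name in ("insp_parts", "exp_parts"):
        v = getattr(settings, name)
        if not isinstance(v, int) or isinstance(v, bool):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    for name in _STRICTLY_POSITIVE:
        v = getattr(settings, name)
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    for name in _NON_NEGATIVE:
        v = getattr(settings, name)
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")


def validate_settings(settings: VentSettings) -> list[Finding]:
    """Validate a :class:`VentSettings` against the RMVS envelope.

    Returns one :class:`Finding` per field outside its envelope range; an
    empty list means the request is fully within the specification.  With
    ``engineering_override`` set, findings are reported with severity
    ``"warning"`` instead of ``"violation"``.  Non-positive or non-numeric
    fields raise :class:`ValueError` regardless of the override.
    """
    _check_numeric(settings)
    severity = "warning" if settings.engineering_override else "violation"
    findings: list[Finding] = []
    for name, (lo, hi) in RMVS_LIMITS.items():
        if name == "trigger_delta" and settings.mode is not Mode.ASV:
            continue  # trigger pressure pertains to assisted ventilation only
        v = getattr(settings, name)
        if not (lo <= v <= hi):
            findings.append(Finding(
                field=name, value=v, limits=(lo, hi),
                message=f"{name}={v:g} outside RMVS range [{lo:g}, {hi:g}]",
                severity=severity,
            ))
    lo, hi = IE_RATIO_LIMITS
    r = settings.ie_ratio
    if not (lo - 1e-12 <= r <= hi + 1e-12):
        findings.append(Finding(
            field="ie_ratio", value=r, limits=(lo, hi),
            message=(f"I:E ratio {settings.insp_parts}:{settings.exp_parts} "
                     f"outside RMVS range 2:1 to 1:3"),
            severity=severity,
        ))
    return findings


def compute_timing(settings: VentSettings) -> BreathTiming:
    """Derive cycle, inspiratory and expiratory times and the constant
    inspiratory flow implied by the settings.

    ``t_cycle = 60/RR``; the cycle is split in the ratio
    ``insp_parts : exp_parts``; ``required_flow = VT / t_insp``.
    """
    if settings.rr <= 0:
        raise ValueError("rr must be positive")
    if settings.insp_parts <= 0 or settings.exp_parts <= 0:
        raise ValueError("I:E parts must be positive")
    t_cycle = 60.0 / settings.rr
    total = settings.insp_parts + settings.exp_parts
    t_insp = t_cycle * settings.insp_parts / total
    t_exp = t_cycle - t_insp
    return BreathTiming(
        t_cycle=t_cycle,
        t_insp=t_insp,
        t_exp=t_exp,
        required_flow=settings.vt_target / t_insp,
    )


def _parse_ie(value: Any) -> tuple[int, int]:
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) != 2:
            raise ValueError(f"ie_ratio must look like '1:2', got {value!r}")
        return int(parts[0]), int(parts[1])
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return int(value[0]), int(value[1])
    raise ValueError(f"cannot parse I:E ratio from {value!r}")


def _parse_fraction(value: Any) -> float:
    """Accept 0.5, 50, or '50%' as the same FiO2."""
    if isinstance(value, str):
        value = value.strip()
        if value.endswith("%"):
            return float(value[:-1]) / 100.0
        value = float(value)
    if value > 1.0:  # bare number above 1 is taken as percent
        return float(value) / 100.0
    return float(value)


def settings_from_dict(d: dict[str, Any]) -> VentSettings:
    """Build :class:`VentSettings` from a JSON-style mapping.

    Accepts ``ie_ratio`` (string ``"1:2"`` or pair) as an alternative to
    explicit ``insp_parts``/``exp_parts``, and percent-style ``fio2``.
    """
    d = dict(d)
    kwargs: dict[str, Any] = {}
    if "ie_ratio" in d:
        kwargs["insp_parts"], kwargs["exp_parts"] = _parse_ie(d.pop("ie_ratio"))
    if "fio2" in d:
        kwargs["fio2"] = _parse_fraction(d.pop("fio2"))
    if "mode" in d:
        kwargs["mode"] = Mode(d.pop("mode"))
    allowed = {f for f in VentSettings.__dataclass_fields__}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown settings keys: {sorted(unknown)}")
    kwargs.update(d)
    return VentSettings(**kwargs)
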
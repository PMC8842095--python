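"""Waveform records, CSV serialization and run configuration.

Waveforms are written as plain CSV (RFC 4180, '.' decimal, UTF-8) with
unit-annotated column names so that files are inspectable with any tool;
configs and verdicts are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable

from .plant import LungParams, PlantParams
from .settings import VentSettings, settings_from_dict

__all__ = [
    "WaveformSample",
    "RunConfig",
    "WAVEFORM_COLUMNS",
    "write_waveform_csv",
    "read_waveform_csv",
    "WaveformParseError",
]

WAVEFORM_COLUMNS = ("t_s", "paw_cmH2O", "q_mLps", "vlung_mL", "pch_cmH2O",
                    "phase", "drive_u")


@dataclass(frozen=True, slots=True)
class WaveformSample:
    """One sensor-rate sample of the simulated (or recorded) run."""

    t: float          # s
    p_aw: float       # cmH2O
    q_aw: float       # mL/s, positive into the patient
    v_lung: float     # mL above relaxation volume
    p_chamber: float  # cmH2O
    phase: str        # INSPIRATION / EXPIRATION
    drive_u: float    # fraction 0-1


class WaveformParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


def _fmt(x: float) -> str:
    return format(x, ".8g")


def write_waveform_csv(samples: Iterable[WaveformSample], path: str | Path) -> None:
    """Write samples as CSV; values carry 8 significant digits."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(WAVEFORM_COLUMNS) + "\n")
        for s in samples:
            fh.write(",".join((_fmt(s.t), _fmt(s.p_aw), _fmt(s.q_aw),
                               _fmt(s.v_lung), _fmt(s.p_chamber), s.phase,
                               _fmt(s.drive_u))) + "\n")


def read_waveform_csv(path: str | Path) -> list[WaveformSample]:
    """Read a waveform CSV, checking header, time monotonicity and spacing.

    Raises :class:`WaveformParseError` with the offending line number on a
    missing column, non-monotone time, or mixed sample spacing.
    """
    path = Path(path)
    samples: list[WaveformSample] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = tuple(header.split(","))
        if cols != WAVEFORM_COLUMNS:
            missing = set(WAVEFORM_COLUMNS) - set(cols)
            raise WaveformParseError(
                f"bad header: missing column(s) {sorted(missing)}" if missing
                else f"bad header: {header!r}", line=1)
        prev_t: float | None = None
        spacing: float | None = None
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) != len(WAVEFORM_COLUMNS):
                raise WaveformParseError(
                    f"expected {len(WAVEFORM_COLUMNS)} fields, got {len(parts)}",
                    line=lineno)
            try:
                t = float(parts[0])
                vals = [float(parts[i]) for i in (1, 2, 3, 4)]
                drive = float(parts[6])
            except ValueError as exc:
                raise WaveformParseError(f"non-numeric field: {exc}", line=lineno)
            if prev_t is not None:
                dt = t - prev_t
                if dt <= 0:
                    raise WaveformParseError(
                        f"time not strictly increasing (t={t:g} after {prev_t:g})",
                        line=lineno)
                if spacing is None:
                    spacing = dt
                elif abs(dt - spacing) > 1e-6 * max(1.0, spacing):
                    raise WaveformParseError(
                        f"mixed sample spacing ({dt:g} vs {spacing:g})",
                        line=lineno)
            prev_t = t
            samples.append(WaveformSample(
                t=t, p_aw=vals[0], q_aw=vals[1], v_lung=vals[2],
                p_chamber=vals[3], phase=parts[5], drive_u=drive))
    return samples


@dataclass(frozen=True, slots=True)
class RunConfig:
    """Complete, serializable description of one simulation run."""

    settings: VentSettings = field(default_factory=VentSettings)
    plant: PlantParams = field(default_factory=PlantParams)
    lung: LungParams = field(default_factory=LungParams)
    controller: dict[str, Any] = field(default_factory=dict)
    duration: float = 60.0
    seed: int = 0
    noise_enabled: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = {
            "settings": asdict(self.settings),
            "plant": asdict(self.plant),
            "lung": asdict(self.lung),
            "controller": dict(self.controller),
            "duration": self.duration,
            "seed": self.seed,
            "noise_enabled": self.noise_enabled,
        }
        d["settings"]["mode"] = self.settings.mode.value
        return d

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            settings=settings_from_dict(d.get("settings", {})),
            plant=PlantParams(**d.get("plant", {})),
            lung=LungParams(**d.get("lung", {})),
            controller=dict(d.get("controller", {})),
            duration=float(d.get("duration", 60.0)),
            seed=int(d.get("seed", 0)),
            noise_enabled=bool(d.get("noise_enabled", False)),
        )

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
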
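"""Agreement and summary statistics for bench and pre-clinical comparisons.

Bland-Altman analysis quantifies agreement between a parameter set on the
ventilator and the same parameter measured by independent spirometry: the
mean of the paired differences (bias) and the 95% limits of agreement,
``mean +/- 1.96 * SD`` of the differences (SD with the n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .control import PeepEstimatorState, estimate_peep

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "loa_halfwidth_pct",
    "post_pre_ratio_pct",
    "BreathSummary",
    "breath_metrics",
]


@dataclass(frozen=True, slots=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(set_values: Sequence[float],
                 measured_values: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of measured against set values.

    Differences are ``measured - set``; limits of agreement use exactly
    1.96 standard deviations (n-1 denominator).
    """
    if len(set_values) != len(measured_values):
        raise ValueError("set and measured lists must have equal length")
    n = len(set_values)
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 paired values")
    d = np.asarray(measured_values, dtype=float) - np.asarray(set_values, dtype=float)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd,
                             loa_lower=mean - 1.96 * sd,
                             loa_upper=mean + 1.96 * sd, n=n)


def loa_halfwidth_pct(result: BlandAltmanResult, reference: float) -> float:
    """Half-width of the limits of agreement as a percent of ``reference``.

    E.g. VT limits of (-90, +88) mL against a 6 mL/kg breath for a 30 kg
    subject (180 mL) give 89/180 = 49.4%.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return (result.loa_upper - result.loa_lower) / 2.0 / reference * 100.0


def post_pre_ratio_pct(pre_median: float, post_median: float) -> int:
    """Post-condition median as an integer percent of the pre-condition one.

    Reported in the style "post value at X% of baseline"; note that prose
    of the form "X% lower" sometimes labels this same arithmetic.
    """
    if pre_median <= 0:
        raise ValueError("pre_median must be positive")
    return round(post_median / pre_median * 100.0)


@dataclass(frozen=True, slots=True)
class BreathSummary:
    """Per-breath metrics extracted from a waveform, independent of the
    controller's own books."""

    index: int
    vt: float        # mL, trapezoidal integral of inspiratory flow
    t_insp: float    # s
    t_exp: float     # s
    peep: float      # cmH2O, same tail-window rule as the controller
    p_peak: float    # cmH2O


def breath_metrics(waveform: Sequence) -> list[BreathSummary]:
    """Segment a phase-annotated waveform into breaths and summarise each.

    A breath spans one INSPIRATION run followed by one EXPIRATION run;
    incomplete leading/trailing fragments are dropped.  VT is the
    trapezoidal integral of flow over the inspiratory samples; PEEP is the
    mean of expiratory pressure after discarding the first 75% of the
    expiration (the controller's windowing rule).
    """
    # group consecutive samples by phase
    runs: list[tuple[str, list]] = []
    for s in waveform:
        if runs and runs[-1][0] == s.phase:
            runs[-1][1].append(s)
        else:
            runs.append((s.phase, [s]))
    out: list[BreathSummary] = []
    est = PeepEstimatorState()
    idx = 0
    for i in range(len(runs) - 1):
        phase, insp = runs[i]
        nphase, exp = runs[i + 1]
        if phase != "INSPIRATION" or nphase != "EXPIRATION":
            continue
        idx += 1
        # the first expiratory sample is taken at the tick that closed the
        # inspiration and still carries inspiratory flow: include it as the
        # right edge of the integral (the controller's own convention)
        t = np.array([s.t for s in insp] + [exp[0].t])
        q = np.array([s.q_aw for s in insp] + [exp[0].q_aw])
        vt = float(np.trapezoid(q, t)) if len(t) > 1 else 0.0
        # phase durations from the boundaries of the runs
        t_insp = exp[0].t - insp[0].t
        t_end = runs[i + 2][1][0].t if i + 2 < len(runs) else exp[-1].t
        t_exp = t_end - exp[0].t
        exp_samples = [(s.t - exp[0].t, s.p_aw) for s in exp]
        try:
            peep = estimate_peep(exp_samples, t_exp, est)
        except ValueError:
            peep = float("nan")
        out.append(BreathSummary(
            index=idx, vt=vt, t_insp=t_insp, t_exp=t_exp, peep=peep,
            p_peak=float(np.max([s.p_aw for s in insp]))))
    return out
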
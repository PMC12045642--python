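"""Intermittent-flow respirometry: oxygen slopes to mass-specific Ṁ_O2.

For each measurement cycle, ordinary least squares is fitted to dissolved
oxygen (mg O₂ l⁻¹) against time (h) over the last 15 minutes of the sealed
measurement phase.  The background slope — the mean of fish-free runs
before and after the trial — is subtracted, and the mass-specific oxygen
consumption rate follows as

    Ṁ_O2 = −S_net · V_resp / M_b    (mg O₂ kg⁻¹ h⁻¹),

positive when oxygen declines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .types import CycleSchedule, OxygenTrace, RespirometerConfig

__all__ = [
    "extract_window",
    "o2_slope",
    "background_correct",
    "mo2",
    "RespirometryResult",
    "analyze_cycle",
]

#: regression window, minutes before the end of the measurement phase
REGRESSION_WINDOW_MIN = 15.0


@dataclass
class RespirometryResult:
    """Per-cycle slope and mass-specific oxygen consumption rate."""

    cycle_id: str
    U: float
    condition: str
    replicate: int
    S: float  # raw slope, mg O2 l^-1 h^-1
    r2: float
    S_bg: float  # background slope subtracted
    mo2: float  # mg O2 kg^-1 h^-1


def extract_window(trace: OxygenTrace, cycle: CycleSchedule) -> OxygenTrace:
    """Samples from the last 15 min of the cycle's measurement phase."""
    t_end = cycle.measure_end_h
    t_start = t_end - REGRESSION_WINDOW_MIN / 60.0
    if trace.t[-1] < t_end - 1e-9:
        raise InsufficientDataError(
            f"cycle {cycle.cycle_id}: trace ends at {trace.t[-1]:.4f} h, "
            f"before measurement end {t_end:.4f} h"
        )
    sel = (trace.t >= t_start - 1e-12) & (trace.t <= t_end + 1e-12)
    if int(sel.sum()) < 3:
        raise InsufficientDataError(
            f"cycle {cycle.cycle_id}: only {int(sel.sum())} samples in regression window"
        )
    temp = trace.temp[sel] if trace.temp is not None else None
    return OxygenTrace(t=trace.t[sel], o2=trace.o2[sel], temp=temp)


def o2_slope(segment: OxygenTrace) -> tuple[float, float]:
    """OLS slope (mg O₂ l⁻¹ h⁻¹) and r² of oxygen against time."""
    if len(segment) < 3:
        raise InsufficientDataError("oxygen regression needs >= 3 samples")
    if np.ptp(segment.t) <= 0:
        raise ValidationError("degenerate time axis in oxygen regression")
    res = stats.linregress(segment.t, segment.o2)
    return float(res.slope), float(res.rvalue**2)


def background_correct(S: float, S_bg_pre: float | None, S_bg_post: float | None) -> float:
    """Subtract the mean fish-free background slope from a raw slope.

    A single background (pre or post) is accepted with a warning; with
    neither, the slope is returned unchanged (and a warning issued).
    """
    bgs = [b for b in (S_bg_pre, S_bg_post) if b is not None]
    if len(bgs) < 2:
        warnings.warn(f"background correction uses {len(bgs)} of 2 fish-free runs")
    if not bgs:
        return S
    return S - float(np.mean(bgs))


def mo2(S_net: float, config: RespirometerConfig) -> float:
    """Mass-specific oxygen consumption rate from a net slope.

    Positive for declining oxygen; a clearly positive net slope (oxygen
    rising) triggers a warning since it indicates a leak or supersaturation.
    """
    if S_net > 1e-6:
        warnings.warn(f"net oxygen slope is positive ({S_net:.3g}): leak or supersaturation?")
    return -S_net * config.effective_volume_l / config.fish.mass_kg


def analyze_cycle(
    trace: OxygenTrace,
    cycle: CycleSchedule,
    config: RespirometerConfig,
    S_bg_pre: float | None = None,
    S_bg_post: float | None = None,
) -> RespirometryResult:
    """Window → slope → background correction → Ṁ_O2 for one cycle."""
    segment = extract_window(trace, cycle)
    S, r2 = o2_slope(segment)
    bgs = [b for b in (S_bg_pre, S_bg_post) if b is not None]
    S_bg = float(np.mean(bgs)) if bgs else 0.0
    S_net = background_correct(S, S_bg_pre, S_bg_post)
    return RespirometryResult(
        cycle_id=cycle.cycle_id,
        U=cycle.U,
        condition=cycle.condition,
        replicate=cycle.replicate,
        S=S,
        r2=r2,
        S_bg=S_bg,
        mo2=mo2(S_net, config),
    )
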
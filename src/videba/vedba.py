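"""Dynamic body acceleration from a 3D trajectory.

Acceleration is obtained per axis with the second-order-accurate forward
finite-difference stencil for the second derivative,

    a_i = (2 x_i − 5 x_{i+1} + 4 x_{i+2} − x_{i+3}) / Δt²,

which is exact on polynomials of degree ≤ 3.  Because the trajectory is in
the Earth frame, raw acceleration already excludes gravity, so VeDBA is
simply the Euclidean norm of the three components.  Interval means apply
boundary-inclusive exclusion bounds (default keep 0.001 g ≤ VeDBA ≤ 1 g):
values above 1 g are residual tracking jumps, values below 0.001 g are
intervals where the animal was effectively not tracked.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .types import G_CM_S2, CycleSchedule, Trajectory3D, VeDBASeries, VeDBASummary

__all__ = ["finite_diff_accel", "vedba", "summarize_vedba", "pair_replicates"]

#: second-order forward stencil for the second derivative
_FORWARD_STENCIL = np.array([2.0, -5.0, 4.0, -1.0])


def finite_diff_accel(traj: Trajectory3D, scheme: str = "forward") -> VeDBASeries:
    """Differentiate a 3D trajectory (cm) twice; components returned in g.

    ``scheme="forward"`` is the default 4-point forward stencil applied
    directly to position; ``scheme="central"`` (3-point) is available for
    sensitivity checks.  Any stencil window touching an invalid sample is
    invalid, as are the trailing samples the stencil cannot reach.
    """
    dt = 1.0 / traj.fps
    n = len(traj)
    comps = {}
    if scheme == "forward":
        taps, offset0 = _FORWARD_STENCIL, 0
        width = 4
    elif scheme == "central":
        taps, offset0 = np.array([1.0, -2.0, 1.0]), -1
        width = 3
    else:
        raise ValidationError(f"unknown differentiation scheme {scheme!r}")

    valid = traj.valid.astype(bool)
    base = np.arange(n)
    ok = np.ones(n, dtype=bool)
    for j in range(width):
        idx = base + offset0 + j
        in_range = (idx >= 0) & (idx < n)
        ok &= in_range & valid[np.clip(idx, 0, n - 1)] & in_range
    for axis, series in (("a_x", traj.x), ("a_y", traj.y), ("a_z", traj.z)):
        acc = np.full(n, np.nan)
        acc_core = np.zeros(n)
        for j, c in enumerate(taps):
            idx = np.clip(base + offset0 + j, 0, n - 1)
            acc_core = acc_core + c * np.nan_to_num(series[idx], nan=0.0)
        acc[ok] = acc_core[ok] / dt**2 / G_CM_S2
        comps[axis] = acc
    if not ok.any():
        warnings.warn("fewer than 4 valid consecutive samples: acceleration is all-invalid")
    return VeDBASeries(
        t=traj.t.copy(),
        a_x=comps["a_x"],
        a_y=comps["a_y"],
        a_z=comps["a_z"],
        vedba=np.full(n, np.nan),
        valid=ok,
    )


def vedba(series: VeDBASeries) -> VeDBASeries:
    """Fill the VeDBA magnitude: the vectorial sum √(a_x² + a_y² + a_z²)."""
    mag = np.sqrt(series.a_x**2 + series.a_y**2 + series.a_z**2)
    series.vedba = mag
    return series


def summarize_vedba(
    series: VeDBASeries,
    lower: float = 0.001,
    upper: float = 1.0,
    window_id: str = "",
) -> VeDBASummary:
    """Mean VeDBA over a measurement window after the exclusion rules.

    Keeping is boundary-inclusive: samples with lower ≤ VeDBA ≤ upper enter
    the mean; values above ``upper`` (1 g default, residual jumps) and below
    ``lower`` (0.001 g default, lost tracking) are counted as excluded.
    """
    if not 0 < lower < upper:
        raise ValidationError(f"exclusion bounds must satisfy 0 < lower < upper, got {lower}, {upper}")
    valid = series.valid & np.isfinite(series.vedba)
    high = valid & (series.vedba > upper)
    low = valid & (series.vedba < lower)
    include = valid & ~high & ~low
    series.include = include
    n_inc = int(include.sum())
    if n_inc == 0:
        raise InsufficientDataError("no VeDBA samples inside the exclusion bounds; mean undefined")
    return VeDBASummary(
        mean_vedba=float(series.vedba[include].mean()),
        n_included=n_inc,
        n_excluded_high=int(high.sum()),
        n_excluded_low=int(low.sum()),
        n_invalid=int(len(series) - valid.sum()),
        window_id=window_id,
    )


def pair_replicates(
    summaries: dict[str, VeDBASummary | None],
    schedule: list[CycleSchedule],
) -> dict[tuple[float, str], dict]:
    """Average the two replicate mean-VeDBA values per (U, condition).

    ``summaries`` maps cycle_id → VeDBASummary (or None for a lost
    recording).  A single surviving replicate passes through as the
    representative; zero replicates raise.
    """
    grouped: dict[tuple[float, str], list[float]] = {}
    for cyc in schedule:
        key = (cyc.U, cyc.condition)
        grouped.setdefault(key, [])
        summ = summaries.get(cyc.cycle_id)
        if summ is not None:
            grouped[key].append(summ.mean_vedba)
    out = {}
    for key, vals in grouped.items():
        if not vals:
            raise InsufficientDataError(
                f"no usable replicate for condition U={key[0]}, {key[1]}"
            )
        out[key] = {"mean_vedba": float(np.mean(vals)), "n_replicates": len(vals)}
    return out
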
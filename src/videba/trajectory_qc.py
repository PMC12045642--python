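"""Cleaning of marker-less 2D pose tracks.

The chain mirrors the standard post-processing of CNN tracker output for
kinematic analysis: samples with low tracker likelihood are removed and
refilled with a cubic spline; temporal outliers ("jumps" the tracker makes
because it treats each frame independently) are flagged with a Hampel
filter, removed and refilled the same way; finally the series is smoothed
with a short centered running mean.  Windows are expressed in samples and
shrink at the series edges — no padding, no extrapolation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline

from .errors import ValidationError
from .types import (
    EDGE_DROPPED,
    HAMPEL_REMOVED,
    INTERPOLATED,
    KEPT,
    LIKELIHOOD_REMOVED,
    CleanTrack,
    PoseTrackSet,
    QCParams,
)

__all__ = [
    "filter_by_likelihood",
    "hampel_flag",
    "spline_interpolate",
    "running_mean",
    "qc_pipeline",
]


def filter_by_likelihood(pose: PoseTrackSet, body_point: str, threshold: float) -> CleanTrack:
    """Null out samples whose tracker likelihood falls below ``threshold``.

    Removal is strict (``likelihood < threshold`` goes); densified frames
    carry likelihood 0 and are therefore removed for any threshold > 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"likelihood threshold outside [0, 1]: {threshold}")
    pt = pose.points[body_point]
    u = pt.u.astype(float).copy()
    v = pt.v.astype(float).copy()
    flags = np.full(len(u), KEPT, dtype=np.uint8)
    bad = pt.likelihood < threshold
    u[bad] = np.nan
    v[bad] = np.nan
    flags[bad] = LIKELIHOOD_REMOVED
    return CleanTrack(u=u, v=v, flags=flags)


def hampel_flag(series: np.ndarray, window: int = 29, k: float = 1.0) -> np.ndarray:
    """Flag outliers: |x_i − median(W_i)| > k · sd(W_i).

    ``W_i`` is the centered window of ``window`` samples around i; NaN
    samples are ignored within the window and never flagged themselves.
    ``sd`` is the ordinary (population) standard deviation.  The inequality
    is strict, so a constant series flags nothing.

    The first and last half-window samples are never flagged: there the
    window is one-sided, the tested sample sits at its extreme rather than
    its centre, and any trending signal would be flagged spuriously
    (|x − median| ≈ 1.6·sd for a pure ramp).  Those edge frames are
    trimmed later in the chain anyway.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValidationError(f"hampel window must be odd and >= 3, got {window}")
    if window > len(series):
        raise ValidationError(
            f"hampel window ({window}) larger than series ({len(series)})"
        )
    half = window // 2
    padded = np.concatenate([np.full(half, np.nan), series, np.full(half, np.nan)])
    win = sliding_window_view(padded, window)  # (n, window)
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(win, axis=1)
        sd = np.nanstd(win, axis=1)
        flags = np.abs(series - med) > k * sd
    flags &= np.isfinite(series)
    flags[:half] = False
    flags[len(series) - half:] = False
    return flags


def spline_interpolate(track: CleanTrack, removed_flag: int | None = None) -> CleanTrack:
    """Refill interior gaps with a natural cubic spline through valid samples.

    Leading and trailing gaps are never extrapolated — they become
    ``edge_dropped``.  Refilled samples are flagged ``interpolated``.
    """
    valid = np.isfinite(track.u) & np.isfinite(track.v)
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise ValidationError(f"spline interpolation needs >= 4 valid samples, got {n_valid}")
    idx = np.arange(len(track))
    first, last = idx[valid][0], idx[valid][-1]
    u = track.u.copy()
    v = track.v.copy()
    flags = track.flags.copy()
    gaps = ~valid & (idx >= first) & (idx <= last)
    if gaps.any():
        for coord, arr in (("u", u), ("v", v)):
            cs = CubicSpline(idx[valid], arr[valid])
            arr[gaps] = cs(idx[gaps])
        flags[gaps] = INTERPOLATED
    edges = ~valid & ((idx < first) | (idx > last))
    flags[edges] = EDGE_DROPPED
    return CleanTrack(u=u, v=v, flags=flags)


def running_mean(track: CleanTrack, window: int = 5) -> CleanTrack:
    """Centered moving average per coordinate; shrunken windows at the edges.

    NaN samples (edge drops) are excluded from every window.  Provenance
    flags are preserved.
    """
    if window % 2 == 0 or window < 1:
        raise ValidationError(f"running-mean window must be odd, got {window}")
    u = _nan_running_mean(track.u, window)
    v = _nan_running_mean(track.v, window)
    # never resurrect coordinates at frames that have none
    u[~np.isfinite(track.u)] = np.nan
    v[~np.isfinite(track.v)] = np.nan
    return CleanTrack(u=u, v=v, flags=track.flags.copy())


def _nan_running_mean(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.concatenate([np.full(half, np.nan), x, np.full(half, np.nan)])
    win = sliding_window_view(padded, window)
    with np.errstate(invalid="ignore"):
        return np.nanmean(win, axis=1)


def qc_pipeline(
    pose: PoseTrackSet, params: QCParams | None = None
) -> tuple[dict[str, CleanTrack], dict]:
    """Run the full cleaning chain on every body point of one camera.

    Order: likelihood cut → spline → Hampel → spline → running mean.
    Returns the cleaned tracks and a QC report with per-stage event counts
    and final provenance-flag counts (which sum to the series length).
    """
    params = params or QCParams()
    threshold = params.threshold_for(pose.camera_id)
    clean: dict[str, CleanTrack] = {}
    report: dict = {"camera_id": pose.camera_id, "threshold": threshold, "points": {}}
    for bp in pose.body_points:
        track = filter_by_likelihood(pose, bp, threshold)
        n_lik = int(np.sum(track.flags == LIKELIHOOD_REMOVED))
        track = spline_interpolate(track)
        ham_u = hampel_flag(track.u, params.hampel_window, params.hampel_k)
        ham_v = hampel_flag(track.v, params.hampel_window, params.hampel_k)
        ham = ham_u | ham_v
        n_ham = int(ham.sum())
        if ham.any():
            track.u[ham] = np.nan
            track.v[ham] = np.nan
            track.flags[ham] = HAMPEL_REMOVED
            track = spline_interpolate(track)
        track = running_mean(track, params.smooth_window)
        counts = track.flag_counts()
        report["points"][bp] = {
            "n_frames": len(track),
            "likelihood_removed": n_lik,
            "hampel_flagged": n_ham,
            "final_flags": counts,
        }
        clean[bp] = track
    return clean, report
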
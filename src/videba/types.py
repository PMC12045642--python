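"""Domain containers shared across the pipeline.

All time-series containers hold plain numpy arrays; tabular results are
pandas DataFrames.  Conventions:

* pixel coordinates ``u`` (rightward) and ``v`` (downward), origin top-left;
* world frame in cm, ``x`` streamwise along the flow, ``y`` crosswise,
  ``z`` vertical up;
* oxygen time in hours, kinematic time in seconds;
* accelerations in g (1 g = 9.8067 m s⁻²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: standard gravity, cm s⁻²
G_CM_S2 = 980.67

#: provenance flags for cleaned tracks
KEPT = 0
LIKELIHOOD_REMOVED = 1
HAMPEL_REMOVED = 2
INTERPOLATED = 3
EDGE_DROPPED = 4

FLAG_NAMES = {
    KEPT: "kept",
    LIKELIHOOD_REMOVED: "likelihood_removed",
    HAMPEL_REMOVED: "hampel_removed",
    INTERPOLATED: "interpolated",
    EDGE_DROPPED: "edge_dropped",
}


@dataclass
class PointTrack:
    """One body point in one camera: pixel coordinates plus tracker likelihood."""

    u: np.ndarray
    v: np.ndarray
    likelihood: np.ndarray

    def __len__(self) -> int:
        return len(self.u)


@dataclass
class PoseTrackSet:
    """Raw marker-less tracker output for one camera.

    ``frames`` is gap-free and 0-based after reading (absent frames are
    densified with likelihood 0 and NaN coordinates); all body points share
    the frame axis.
    """

    camera_id: str
    frames: np.ndarray
    points: dict[str, PointTrack]
    fps: float = 90.0

    def __post_init__(self) -> None:
        d = np.diff(self.frames)
        if len(d) and not np.all(d == 1):
            raise ValidationError(
                f"camera {self.camera_id}: frame axis must be gap-free and increasing"
            )
        for name, pt in self.points.items():
            if len(pt) != len(self.frames):
                raise ValidationError(
                    f"camera {self.camera_id}, point {name}: length mismatch"
                )
            lk = pt.likelihood
            if np.any((lk < 0) | (lk > 1)):
                raise ValidationError(
                    f"camera {self.camera_id}, point {name}: likelihood outside [0, 1]"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def body_points(self) -> list[str]:
        return list(self.points)


@dataclass
class CleanTrack:
    """QC'd 2D pixel track with per-frame provenance flags."""

    u: np.ndarray
    v: np.ndarray
    flags: np.ndarray  # uint8, one of the provenance constants

    def __len__(self) -> int:
        return len(self.u)

    @property
    def valid(self) -> np.ndarray:
        """Frames with usable coordinates (kept or interpolated)."""
        return np.isin(self.flags, (KEPT, INTERPOLATED)) & np.isfinite(self.u) & np.isfinite(self.v)

    def flag_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.flags == code)) for code, name in FLAG_NAMES.items()}


@dataclass
class CameraModel:
    """11-coefficient direct linear transformation camera.

    u = (L1·X + L2·Y + L3·Z + L4) / D,  v = (L5·X + L6·Y + L7·Z + L8) / D,
    D = L9·X + L10·Y + L11·Z + 1.
    """

    L: np.ndarray  # shape (11,)
    camera_id: str = ""
    image_size: tuple[int, int] | None = None  # (width, height), px

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (11,):
            raise ValidationError("CameraModel requires exactly 11 DLT coefficients")


@dataclass
class Trajectory3D:
    """Evenly sampled world-frame positions (cm) of one body point."""

    t: np.ndarray  # seconds
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    fps: float
    body_point: str = ""
    residual: np.ndarray | None = None  # rms reprojection per frame, px

    def __len__(self) -> int:
        return len(self.t)

    def coords(self) -> np.ndarray:
        """(n, 3) array; invalid rows are NaN."""
        out = np.column_stack([self.x, self.y, self.z])
        out[~self.valid] = np.nan
        return out


@dataclass
class VeDBASeries:
    """Per-frame dynamic body acceleration in g."""

    t: np.ndarray
    a_x: np.ndarray
    a_y: np.ndarray
    a_z: np.ndarray
    vedba: np.ndarray
    valid: np.ndarray
    include: np.ndarray | None = None  # after exclusion bounds

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class VeDBASummary:
    """Windowed mean VeDBA after the exclusion rules."""

    mean_vedba: float
    n_included: int
    n_excluded_high: int
    n_excluded_low: int
    n_invalid: int
    window_id: str = ""

    @property
    def n_total(self) -> int:
        return self.n_included + self.n_excluded_high + self.n_excluded_low + self.n_invalid


@dataclass
class OxygenTrace:
    """Dissolved-oxygen time series; t in hours since trial start, o2 in mg l⁻¹."""

    t: np.ndarray
    o2: np.ndarray
    temp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("oxygen trace time must be strictly increasing")
        if np.any(self.o2 < 0):
            raise ValidationError("oxygen concentration must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class CycleSchedule:
    """One intermittent-flow measurement cycle."""

    cycle_id: str
    U: float  # flow speed, cm s⁻¹
    replicate: int = 1
    condition: str = "steady"  # steady | feeding
    flush_min: float = 5.0
    equil_min: float = 2.0
    measure_min: float = 20.0
    start_h: float = 0.0  # absolute start of the flush phase

    def __post_init__(self) -> None:
        if min(self.flush_min, self.equil_min, self.measure_min) < 0:
            raise ValidationError(f"cycle {self.cycle_id}: phase durations must be non-negative")

    @property
    def measure_start_h(self) -> float:
        return self.start_h + (self.flush_min + self.equil_min) / 60.0

    @property
    def measure_end_h(self) -> float:
        return self.measure_start_h + self.measure_min / 60.0

    @property
    def duration_h(self) -> float:
        return (self.flush_min + self.equil_min + self.measure_min) / 60.0


@dataclass
class FishMeta:
    """Identity and body mass of one individual."""

    individual_id: str
    mass_kg: float

    def __post_init__(self) -> None:
        if not self.mass_kg > 0:
            raise ValidationError(f"fish {self.individual_id}: mass must be positive")


@dataclass
class QCParams:
    """Parameters of the 2D track-cleaning chain.

    Defaults follow the tracking protocol for a two-camera flume rig:
    likelihood cutoffs 0.6 (top camera, rare occlusion) and 0.9 (side
    camera), Hampel window 29 samples with a median ± 1 s.d. threshold,
    and a 5-sample running mean (0.056 s at 90 fps).
    """

    likelihood_threshold: dict[str, float] = field(
        default_factory=lambda: {"top": 0.6, "side": 0.9}
    )
    default_likelihood_threshold: float = 0.9
    hampel_window: int = 29
    hampel_k: float = 1.0
    smooth_window: int = 5

    def __post_init__(self) -> None:
        for w, name in ((self.hampel_window, "hampel_window"), (self.smooth_window, "smooth_window")):
            if w < 3 or w % 2 == 0:
                raise ValidationError(f"{name} must be odd and >= 3, got {w}")
        if not self.hampel_k > 0:
            raise ValidationError("hampel_k must be positive")
        for cam, thr in self.likelihood_threshold.items():
            if not 0.0 <= thr <= 1.0:
                raise ValidationError(f"likelihood threshold for {cam!r} outside [0, 1]")

    def threshold_for(self, camera_id: str) -> float:
        return self.likelihood_threshold.get(camera_id, self.default_likelihood_threshold)


@dataclass
class RespirometerConfig:
    """Respirometer geometry and the fish inside it."""

    fish: FishMeta
    V_resp_l: float = 10.0
    fish_volume_l: float = 0.0  # optional body-volume correction, default off

    def __post_init__(self) -> None:
        if not self.V_resp_l > 0:
            raise ValidationError("respirometer volume must be positive")

    @property
    def effective_volume_l(self) -> float:
        return self.V_resp_l - self.fish_volume_l
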
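"""Ground-truthed synthetic studies: a virtual swim-flume with two cameras.

The generator emulates the full measurement chain so that every pipeline
stage can be tested against known truth without any recorded data:

* a station-holding fish whose eye traces a C² path — smooth bounded drift
  (random-phase low-frequency Fourier modes, an Ornstein–Uhlenbeck-like
  spectrum that stays twice differentiable) plus sinusoidal swimming beats
  whose amplitude A(U) and frequency f(U) grow with flow speed, and, in
  feeding bouts, Gaussian-envelope strike transients.  The analytic second
  derivative of this path is the ground-truth acceleration;
* a two-camera DLT rig (top + side) that projects the path to pixels and
  adds tracker-like defects: a small white jitter, a slower correlated
  localization wander (CNN trackers err almost identically on adjacent,
  near-identical frames, so their error is far from white), confident
  spikes, and low-likelihood dropouts;
* an intermittent-flow respirometer whose sealed-phase oxygen decline
  encodes Ṁ_O2 = SMR_individual + κ·VeDBA_true plus cycle-to-cycle
  metabolic noise, with fish-free background traces.

All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .types import (
    G_CM_S2,
    CameraModel,
    CycleSchedule,
    FishMeta,
    OxygenTrace,
    PointTrack,
    PoseTrackSet,
    Trajectory3D,
)
from . import io_formats

__all__ = [
    "SwimScenario",
    "CameraRig",
    "EnergeticsTruth",
    "simulate_trajectory",
    "simulate_cameras",
    "simulate_oxygen",
    "make_study",
    "true_mean_vedba",
]

#: masses (g) of the five study individuals
DEFAULT_MASSES_G = (6.59, 6.58, 5.17, 8.87, 9.32)
DEFAULT_IDS = ("A", "B", "C", "D", "E")


@dataclass
class SwimScenario:
    """Flow-speed ladder and kinematic maps of the virtual swimmer.

    The beat amplitude and frequency increase linearly from (A_lo, f_lo) at
    U_lo to (A_hi, f_hi) at U_hi, giving ground-truth VeDBA that is
    monotone in flow speed by construction.
    """

    U_ladder: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    n_replicates: int = 2
    fps: float = 90.0
    video_s: float = 30.0  # tracked window at the end of each measurement phase
    U_lo: float = 5.0
    U_hi: float = 30.0
    A_lo: float = 0.2  # cm, lateral beat amplitude
    A_hi: float = 0.8
    f_lo: float = 2.0  # Hz, beat frequency
    f_hi: float = 6.0
    z_amp_frac: float = 0.2  # vertical beat, fraction of A
    x_amp_frac: float = 0.05  # surge at twice the beat frequency
    drift_amp_cm: float = 1.5
    drift_modes: int = 4
    drift_max_hz: float = 0.4
    strike_rate_hz: float = 0.8  # feeding strikes (~1000 prey / 20 min)
    strike_disp_cm: float = 1.2
    strike_tau_s: float = 0.06
    section_cm: tuple[float, float, float] = (38.0, 10.0, 10.0)

    def amplitude(self, U: float) -> float:
        frac = np.clip((U - self.U_lo) / (self.U_hi - self.U_lo), 0.0, 1.0)
        return self.A_lo + (self.A_hi - self.A_lo) * frac

    def frequency(self, U: float) -> float:
        frac = np.clip((U - self.U_lo) / (self.U_hi - self.U_lo), 0.0, 1.0)
        return self.f_lo + (self.f_hi - self.f_lo) * frac


@dataclass
class CameraRig:
    """Two-camera DLT rig plus a tracker-defect model."""

    cameras: dict[str, CameraModel]
    image_size: tuple[int, int] = (1920, 1080)
    sigma_px_white: float = 0.1  # frame-to-frame jitter
    sigma_px_slow: float = 0.5  # correlated localization wander
    tau_slow_s: float = 0.5
    dropout_p: float = 0.02
    spike_p: float = 0.01
    spike_px: float = 40.0

    def __post_init__(self) -> None:
        for p in (self.dropout_p, self.spike_p):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("defect probabilities must lie in [0, 1]")

    @classmethod
    def default(cls, **kwargs) -> "CameraRig":
        """Top + side cameras over a 38×10×10 cm test section.

        25 mm lenses on 1920×1080 sensors (5.5 µm pixels → f ≈ 4545 px) at
        90 cm from the section centre; ~0.02 cm per pixel.
        """
        f_px = 4545.0
        cx, cy = 960.0, 540.0
        centre = np.array([19.0, 5.0, 5.0])
        # top camera: above, looking straight down (-z)
        R_top = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
        C_top = centre + np.array([0.0, 0.0, 90.0])
        # side camera: beside, looking along +y
        R_side = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        C_side = centre + np.array([0.0, -90.0, 0.0])
        cams = {
            "top": pinhole_to_dlt(C_top, R_top, f_px, cx, cy, "top"),
            "side": pinhole_to_dlt(C_side, R_side, f_px, cx, cy, "side"),
        }
        return cls(cameras=cams, **kwargs)


@dataclass
class EnergeticsTruth:
    """Energetic ground truth coupling Ṁ_O2 linearly to true VeDBA."""

    smr_mean: float = 152.15  # mg O2 kg^-1 h^-1 at U=0
    smr_sd: float = 25.0  # between-individual spread (random intercepts)
    kappa: float = 250.0  # mg O2 kg^-1 h^-1 per g of VeDBA
    sigma_resid: float = 10.0  # cycle-to-cycle metabolic noise
    sigma_o2: float = 0.02  # trace noise, mg l^-1
    background_slope: float = -0.05  # fish-free decline, mg l^-1 h^-1
    o2_saturation: float = 8.0  # mg l^-1
    V_resp_l: float = 10.0
    nonlinearity: float = 0.0  # optional quadratic term for robustness tests

    def __post_init__(self) -> None:
        if self.smr_mean <= 0 or self.kappa <= 0:
            raise ValidationError("SMR and kappa must be positive")

    def mo2_of(self, smr_i: float, vedba_true: float) -> float:
        return smr_i + self.kappa * vedba_true + self.nonlinearity * vedba_true**2


def pinhole_to_dlt(C: np.ndarray, R: np.ndarray, f_px: float, cx: float, cy: float, camera_id: str = "") -> CameraModel:
    """Convert a pinhole camera (centre C, rotation R, focal f_px) to 11 DLT coefficients."""
    K = np.array([[f_px, 0, cx], [0, f_px, cy], [0, 0, 1.0]])
    P = K @ np.hstack([R, (-R @ np.asarray(C, float)).reshape(3, 1)])
    if abs(P[2, 3]) < 1e-12:
        raise ValidationError("camera centre projects at infinity; cannot normalize DLT")
    P = P / P[2, 3]
    L = np.concatenate([P[0], P[1], P[2, :3]])
    return CameraModel(L=L, camera_id=camera_id)


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _drift_modes(scenario: SwimScenario, rng: np.random.Generator):
    """Random-phase Fourier drift per axis: amplitudes, frequencies, phases."""
    m = scenario.drift_modes
    amps = np.empty((3, m))
    freqs = np.empty((3, m))
    phases = np.empty((3, m))
    for ax in range(3):
        # 1/f-flavoured amplitudes, normalized so the peak drift is bounded
        raw = 1.0 / np.arange(1, m + 1)
        amps[ax] = scenario.drift_amp_cm * raw / raw.sum()
        freqs[ax] = rng.uniform(0.02, scenario.drift_max_hz, m)
        phases[ax] = rng.uniform(0, 2 * np.pi, m)
    return amps, freqs, phases


def simulate_trajectory(
    scenario: SwimScenario,
    U: float,
    duration_s: float | None = None,
    seed: int | np.random.Generator = 0,
    feeding: bool = False,
) -> tuple[Trajectory3D, np.ndarray]:
    """Simulate the eye path at flow speed ``U``; returns (trajectory, true accel).

    The true acceleration (n, 3) is analytic, in g.  Deterministic given
    the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_s = scenario.video_s if duration_s is None else duration_s
    n = int(round(duration_s * scenario.fps))
    if n < 4:
        raise ValidationError("trajectory must span at least 4 frames")
    t = np.arange(n) / scenario.fps

    centre = np.array(scenario.section_cm) / 2.0
    A = scenario.amplitude(U)
    f = scenario.frequency(U)
    w = 2 * np.pi * f

    pos = np.tile(centre, (n, 1)).astype(float)
    acc = np.zeros((n, 3))

    # swimming beats: lateral (y), a weaker vertical component, surge at 2f
    beats = (
        (1, A, w, rng.uniform(0, 2 * np.pi)),
        (2, scenario.z_amp_frac * A, w, rng.uniform(0, 2 * np.pi)),
        (0, scenario.x_amp_frac * A, 2 * w, rng.uniform(0, 2 * np.pi)),
    )
    for ax, amp, omega, phi in beats:
        pos[:, ax] += amp * np.sin(omega * t + phi)
        acc[:, ax] += -amp * omega**2 * np.sin(omega * t + phi)

    amps, freqs, phases = _drift_modes(scenario, rng)
    for ax in range(3):
        for a_j, nu_j, phi_j in zip(amps[ax], freqs[ax], phases[ax]):
            wj = 2 * np.pi * nu_j
            pos[:, ax] += a_j * np.sin(wj * t + phi_j)
            acc[:, ax] += -a_j * wj**2 * np.sin(wj * t + phi_j)

    if feeding:
        n_strikes = rng.poisson(scenario.strike_rate_hz * duration_s)
        tau = scenario.strike_tau_s
        for _ in range(n_strikes):
            t0 = rng.uniform(0, duration_s)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            D = scenario.strike_disp_cm * rng.uniform(0.5, 1.5)
            dt = t - t0
            env = np.exp(-(dt**2) / (2 * tau**2))
            pos += np.outer(D * env, direction)
            acc += np.outer(D * env * (dt**2 / tau**4 - 1.0 / tau**2), direction)

    traj = Trajectory3D(
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        z=pos[:, 2],
        valid=np.ones(n, dtype=bool),
        fps=scenario.fps,
        body_point="eye",
    )
    return traj, acc / G_CM_S2


def true_mean_vedba(accel_g: np.ndarray, lower: float = 0.001, upper: float = 1.0) -> float:
    """Mean of the analytic VeDBA under the estimator's exclusion bounds.

    This is the estimand the averaging rule targets: samples outside
    [lower, upper] g are excluded exactly as the pipeline excludes them.
    """
    mag = np.linalg.norm(accel_g, axis=1)
    sel = (mag >= lower) & (mag <= upper)
    if not sel.any():
        return 0.0
    return float(mag[sel].mean())


# ---------------------------------------------------------------------------
# cameras
# ---------------------------------------------------------------------------

def simulate_cameras(
    traj: Trajectory3D,
    rig: CameraRig,
    seed: int | np.random.Generator = 0,
    body_point: str = "eye",
) -> tuple[dict[str, PoseTrackSet], dict]:
    """Project the trajectory through the rig and add tracker defects.

    Returns the per-camera pose tracks and a ground-truth defect record
    (spike and dropout frame indices per camera) for QC recall scoring.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(traj)
    W, H = rig.image_size
    pts3 = np.column_stack([traj.x, traj.y, traj.z])
    out: dict[str, PoseTrackSet] = {}
    defects: dict[str, dict] = {}
    dt = 1.0 / traj.fps
    rho = float(np.exp(-dt / rig.tau_slow_s)) if rig.tau_slow_s > 0 else 0.0
    for cam_id, cam in rig.cameras.items():
        L = cam.L
        denom = pts3 @ L[8:11] + 1.0
        u = (pts3 @ L[0:3] + L[3]) / denom
        v = (pts3 @ L[4:7] + L[7]) / denom

        # correlated localization wander (AR(1)) + white jitter
        for arr in (u, v):
            slow = np.empty(n)
            slow[0] = rng.normal(0, rig.sigma_px_slow)
            innov = rng.normal(0, rig.sigma_px_slow * np.sqrt(1 - rho**2), n)
            for k in range(1, n):
                slow[k] = rho * slow[k - 1] + innov[k]
            arr += slow + rng.normal(0, rig.sigma_px_white, n)

        likelihood = rng.uniform(0.95, 1.0, n)

        drop = rng.random(n) < rig.dropout_p
        out_of_frame = (u < 0) | (u > W) | (v < 0) | (v > H)
        drop |= out_of_frame
        # dropouts: the tracker wanders far off with low confidence
        u[drop] += rng.normal(0, 30.0, int(drop.sum()))
        v[drop] += rng.normal(0, 30.0, int(drop.sum()))
        likelihood[drop] = rng.uniform(0.0, 0.3, int(drop.sum()))

        spike = (rng.random(n) < rig.spike_p) & ~drop
        ns = int(spike.sum())
        theta = rng.uniform(0, 2 * np.pi, ns)
        u[spike] += rig.spike_px * np.cos(theta)
        v[spike] += rig.spike_px * np.sin(theta)
        # spikes keep high likelihood: the failure mode the Hampel stage must catch

        out[cam_id] = PoseTrackSet(
            camera_id=cam_id,
            frames=np.arange(n),
            points={body_point: PointTrack(u=u, v=v, likelihood=likelihood)},
            fps=traj.fps,
        )
        defects[cam_id] = {
            "spike_frames": np.flatnonzero(spike).tolist(),
            "dropout_frames": np.flatnonzero(drop).tolist(),
        }
    return out, defects


# ---------------------------------------------------------------------------
# oxygen
# ---------------------------------------------------------------------------

def simulate_oxygen(
    cycles: list[CycleSchedule],
    mo2_true: dict[str, float],
    mass_kg: float,
    truth: EnergeticsTruth,
    seed: int | np.random.Generator = 0,
    sample_hz: float = 1.0,
) -> OxygenTrace:
    """Build an intermittent-flow oxygen trace for a sequence of cycles.

    During sealed phases (equilibration + measurement) oxygen declines at
    −(Ṁ_O2·M_b/V + |background|); flush phases relax back to saturation
    with a ~1 min time constant.  Gaussian noise σ_o2 is added throughout.
    Passing ``mo2_true`` values of 0 yields a fish-free background trace.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end_h = max(c.measure_end_h for c in cycles)
    dt_h = 1.0 / sample_hz / 3600.0
    t = np.arange(0.0, t_end_h + dt_h / 2, dt_h)
    o2 = np.full(len(t), truth.o2_saturation)
    level = truth.o2_saturation
    tau_flush_h = 60.0 / 3600.0
    bg = abs(truth.background_slope)
    # walk the samples through the phases
    idx = 0
    for cyc in cycles:
        flush_end = cyc.start_h + cyc.flush_min / 60.0
        seal_end = cyc.measure_end_h
        slope = -(mo2_true.get(cyc.cycle_id, 0.0) * mass_kg / truth.V_resp_l + bg)
        sel_flush = (t >= cyc.start_h) & (t < flush_end)
        if sel_flush.any():
            tf = t[sel_flush] - cyc.start_h
            o2[sel_flush] = truth.o2_saturation + (level - truth.o2_saturation) * np.exp(-tf / tau_flush_h)
            level = float(o2[sel_flush][-1])
        sel_seal = (t >= flush_end) & (t <= seal_end)
        if sel_seal.any():
            ts = t[sel_seal] - t[sel_seal][0]
            o2[sel_seal] = level + slope * ts
            level = float(o2[sel_seal][-1])
    o2 = o2 + rng.normal(0, truth.sigma_o2, len(t))
    return OxygenTrace(t=t, o2=np.clip(o2, 0.0, None))


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------

def _steady_schedule(scenario: SwimScenario) -> list[CycleSchedule]:
    cycles = []
    t0 = 0.0
    k = 0
    for U in scenario.U_ladder:
        for rep in range(1, scenario.n_replicates + 1):
            k += 1
            cyc = CycleSchedule(cycle_id=f"c{k:02d}", U=U, replicate=rep, start_h=t0)
            cycles.append(cyc)
            t0 += cyc.duration_h
    return cycles


def _feeding_schedule(ladder=(10.0, 20.0, 30.0)) -> list[CycleSchedule]:
    """Feeding follow-up design: at each speed, one steady then one feeding cycle."""
    cycles = []
    t0 = 0.0
    k = 0
    for U in ladder:
        for rep, cond in ((1, "steady"), (2, "feeding")):
            k += 1
            cyc = CycleSchedule(cycle_id=f"f{k:02d}", U=U, replicate=rep, condition=cond, start_h=t0)
            cycles.append(cyc)
            t0 += cyc.duration_h
    return cycles


def make_study(
    out_dir: str | Path,
    seed: int = 0,
    n_individuals: int = 5,
    scenario: SwimScenario | None = None,
    rig: CameraRig | None = None,
    truth: EnergeticsTruth | None = None,
    feeding: bool = False,
) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Layout: ``fish.csv``, ``dlt_coefficients.csv``, per-individual
    ``schedule_<id>.csv`` and ``oxygen_<id>.csv``, fish-free
    ``background_pre.csv`` / ``background_post.csv`` (+ their schedule),
    per-cycle pose tables under ``pose/``, and a ``truth.json`` sidecar
    with every generator parameter and per-cycle ground truth.

    The default is the 5-individual, 6-speed × 2-replicate steady-swimming
    design; ``feeding=True`` instead builds the 3-individual feeding
    follow-up at 10/20/30 cm s⁻¹ with and without prey.
    """
    out_dir = Path(out_dir)
    (out_dir / "pose").mkdir(parents=True, exist_ok=True)
    scenario = scenario or SwimScenario()
    rig = rig or CameraRig.default()
    truth = truth or EnergeticsTruth()
    root_rng = np.random.default_rng(seed)

    if feeding:
        n_individuals = min(n_individuals, 3)
    ids = DEFAULT_IDS[:n_individuals]
    masses = DEFAULT_MASSES_G[:n_individuals]
    fish = [FishMeta(individual_id=i, mass_kg=m / 1000.0) for i, m in zip(ids, masses)]
    io_formats.write_fish_table(fish, out_dir / "fish.csv")
    io_formats.write_dlt_coefficients(list(rig.cameras.values()), out_dir / "dlt_coefficients.csv")

    sidecar: dict = {
        "seed": seed,
        "scenario": asdict(scenario),
        "truth": asdict(truth),
        "rig": {
            "sigma_px_white": rig.sigma_px_white,
            "sigma_px_slow": rig.sigma_px_slow,
            "tau_slow_s": rig.tau_slow_s,
            "dropout_p": rig.dropout_p,
            "spike_p": rig.spike_p,
            "spike_px": rig.spike_px,
        },
        "individuals": {},
    }

    for fm in fish:
        rng = np.random.default_rng(root_rng.integers(0, 2**31 - 1))
        smr_i = float(max(truth.smr_mean + truth.smr_sd * rng.normal(), 1.0))
        cycles = _feeding_schedule() if feeding else _steady_schedule(scenario)
        io_formats.write_cycle_schedule(cycles, out_dir / f"schedule_{fm.individual_id}.csv")
        cyc_truth = {}
        mo2_true: dict[str, float] = {}
        for cyc in cycles:
            traj, acc_g = simulate_trajectory(
                scenario, cyc.U, scenario.video_s, rng, feeding=(cyc.condition == "feeding")
            )
            v_true = true_mean_vedba(acc_g)
            m_true = float(truth.mo2_of(smr_i, v_true) + truth.sigma_resid * rng.normal())
            mo2_true[cyc.cycle_id] = m_true
            tracks, defects = simulate_cameras(traj, rig, rng)
            for cam_id, pose in tracks.items():
                io_formats.write_pose_tracks(
                    pose,
                    out_dir / "pose" / f"{fm.individual_id}_{cyc.cycle_id}_{cam_id}.csv",
                    dialect="dlc",
                )
            cyc_truth[cyc.cycle_id] = {
                "U": cyc.U,
                "condition": cyc.condition,
                "replicate": cyc.replicate,
                "vedba_true": v_true,
                "mo2_true": m_true,
                "defects": defects,
            }
        trace = simulate_oxygen(cycles, mo2_true, fm.mass_kg, truth, rng)
        io_formats.write_oxygen_trace(trace, out_dir / f"oxygen_{fm.individual_id}.csv")
        sidecar["individuals"][fm.individual_id] = {
            "mass_kg": fm.mass_kg,
            "smr_true": smr_i,
            "kappa": truth.kappa,
            "cycles": cyc_truth,
        }

    # fish-free background runs (pre and post)
    bg_cycles = [CycleSchedule(cycle_id="bg", U=0.0, start_h=0.0)]
    io_formats.write_cycle_schedule(bg_cycles, out_dir / "background_schedule.csv")
    for name in ("pre", "post"):
        bg_rng = np.random.default_rng(root_rng.integers(0, 2**31 - 1))
        bg_trace = simulate_oxygen(bg_cycles, {}, 0.0, truth, bg_rng)
        io_formats.write_oxygen_trace(bg_trace, out_dir / f"background_{name}.csv")

    with open(out_dir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return sidecar
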
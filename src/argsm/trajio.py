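"""Trajectory-ensemble I/O, preprocessing, and synthetic fixture presets.

File conventions follow tracker output: positions in pixels with the image
convention (origin top-left, x rightward, y downward), velocities as first
differences in pixels/frame.  CSV columns are (trajectory_id, frame, u, v)
for velocities and (trajectory_id, frame, x, y) for positions; an HDF5
container stores the raw arrays with shape and metadata.

Preprocessing mirrors standard practice for ensembles of tracked points:
subtract the pooled ensemble mean from each velocity component, rotate the
two components slightly to zero their pooled cross-correlation (per-
trajectory means are deliberately NOT removed — doing so injects artificial
anticorrelation at long lags), and discard trajectories that linger below a
speed threshold (0.1 pixels/frame for 16 or more frames by default), since
those are dominated by tracker noise on static background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ar import ARParams
from .dynamic import ARGSMParams, LatentState, TrajectoryEnsemble, simulate_argsm

__all__ = [
    "PositionEnsemble",
    "PreprocessReport",
    "differentiate",
    "center_and_rotate",
    "speed_filter",
    "make_fixture",
    "preset_params",
    "read_ensemble",
    "write_ensemble",
    "read_positions",
    "PRESETS",
]


@dataclass
class PositionEnsemble:
    """N tracked point trajectories of P frames, pixel coordinates."""

    positions: np.ndarray  # (N, P, 2)
    trajectory_ids: np.ndarray | None = None
    frame_rate: float = 60.0
    resolution: tuple | None = None

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 3 or p.shape[2] != 2 or p.shape[1] < 2:
            raise ValueError(f"positions must be (N, P>=2, 2), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("positions contain non-finite values")
        self.positions = p
        if self.trajectory_ids is None:
            self.trajectory_ids = np.arange(p.shape[0])
        if self.resolution is not None:
            w, h = self.resolution
            if p[..., 0].min() < 0 or p[..., 0].max() > w or p[..., 1].min() < 0 or p[..., 1].max() > h:
                import warnings

                warnings.warn("positions outside stated resolution bounds")


@dataclass
class PreprocessReport:
    """Bookkeeping for preprocessing: what was removed and by how much."""

    mean_removed: np.ndarray | None = None
    rotation_angle: float | None = None
    n_input: int = 0
    n_kept: int = 0
    discarded_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_kept


def differentiate(positions: PositionEnsemble) -> TrajectoryEnsemble:
    """Velocities as first differences of point positions (T = P - 1)."""
    vel = np.diff(positions.positions, axis=1)
    return TrajectoryEnsemble(
        velocities=vel,
        trajectory_ids=positions.trajectory_ids,
        frame_rate=positions.frame_rate,
    )


def center_and_rotate(ensemble: TrajectoryEnsemble):
    """Remove the pooled ensemble mean per component, then rotate (u, v) by
    the diagonalizing angle closest to zero so the pooled cross-correlation
    vanishes.  Rotation preserves every speed magnitude.  Per-trajectory
    means are not touched.  Returns (ensemble, PreprocessReport)."""
    vel = ensemble.velocities
    mean = vel.reshape(-1, 2).mean(axis=0)
    centered = vel - mean
    u = centered[..., 0].ravel()
    v = centered[..., 1].ravel()
    cuu, cvv, cuv = u @ u, v @ v, u @ v
    denom = np.hypot(cuu - cvv, 2 * cuv)
    if denom < 1e-12 * max(cuu + cvv, 1.0):
        report = PreprocessReport(
            mean_removed=mean, rotation_angle=None,
            n_input=ensemble.n_traj, n_kept=ensemble.n_traj,
        )
        return (
            TrajectoryEnsemble(centered, ensemble.trajectory_ids, ensemble.frame_rate),
            report,
        )
    theta = 0.5 * np.arctan2(2 * cuv, cuu - cvv)
    # of the two diagonalizing angles theta and theta - pi/2, keep the one
    # closest to zero ("slightly rotate")
    if abs(theta) > np.pi / 4:
        theta -= np.sign(theta) * np.pi / 2
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    rotated = centered @ rot.T
    report = PreprocessReport(
        mean_removed=mean,
        rotation_angle=float(theta),
        n_input=ensemble.n_traj,
        n_kept=ensemble.n_traj,
    )
    return (
        TrajectoryEnsemble(rotated, ensemble.trajectory_ids, ensemble.frame_rate),
        report,
    )


def speed_filter(
    ensemble: TrajectoryEnsemble, threshold: float = 0.1, max_slow_steps: int = 16
):
    """Discard trajectories with ``max_slow_steps`` or more frames of speed
    (velocity magnitude) below ``threshold`` pixels/frame.  Values of kept
    trajectories are untouched.  Returns (ensemble, PreprocessReport)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    speed = np.hypot(ensemble.u, ensemble.v)
    slow = (speed < threshold).sum(axis=1)
    keep = slow < max_slow_steps
    report = PreprocessReport(
        n_input=ensemble.n_traj,
        n_kept=int(keep.sum()),
        discarded_ids=np.asarray(ensemble.trajectory_ids)[~keep],
    )
    if not np.any(keep):
        raise ValueError("speed filter discarded every trajectory")
    kept = TrajectoryEnsemble(
        velocities=ensemble.velocities[keep],
        trajectory_ids=np.asarray(ensemble.trajectory_ids)[keep],
        frame_rate=ensemble.frame_rate,
    )
    return kept, report


# ---------------------------------------------------------------------------
# synthetic presets

def _ar2(phi1: float, phi2: float, stat_sd: float) -> ARParams:
    """AR(2) with coefficients (phi1, phi2) and noise scaled to a target
    stationary standard deviation."""
    p = ARParams(order=2, phi=np.array([phi1, phi2]), noise_var=1.0)
    return ARParams(
        order=2,
        phi=np.array([phi1, phi2]),
        noise_var=stat_sd**2 / p.stationary_var,
    )


#: Category presets emulating the qualitative differences across scene types:
#: animal scenes have short velocity correlation times and heavy tails, plant
#: scenes long-lived velocity correlations with heavy tails, water scenes are
#: closer to Gaussian.  Velocity stationary sd in pixels/frame.
PRESETS: dict[str, ARGSMParams] = {
    "animal": ARGSMParams(
        y1=_ar2(0.55, 0.05, 1.0),
        y2=_ar2(0.55, 0.05, 0.8),
        z=_ar2(0.92, 0.0, 0.6),
    ),
    "plant": ARGSMParams(
        y1=_ar2(1.25, -0.30, 1.0),
        y2=_ar2(1.25, -0.30, 0.8),
        z=_ar2(0.92, 0.0, 0.5),
    ),
    "water": ARGSMParams(
        y1=_ar2(0.85, 0.0, 1.0),
        y2=_ar2(0.85, 0.0, 0.9),
        z=_ar2(0.90, 0.0, 0.15),
    ),
}


def preset_params(preset: str | ARGSMParams) -> ARGSMParams:
    if isinstance(preset, ARGSMParams):
        return preset
    try:
        return PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")


def make_fixture(preset, N: int = 512, T: int = 64, seed=None):
    """Simulate a category-preset ensemble; returns (ensemble, ground truth).

    ``preset`` is one of "animal" / "plant" / "water" or an explicit
    ARGSMParams.  Ground truth is the LatentState of the generating scale
    process, for recovery tests.
    """
    params = preset_params(preset)
    return simulate_argsm(params, N=N, T=T, seed=seed)


def make_filter_fixture(T: int = 64, seed: int = 0):
    """Deterministic 10-trajectory fixture for exercising the speed filter:
    slow-step counts (0, 3, 5, 8, 10, 15, 16, 17, 30, 63), so exactly six
    trajectories survive the (0.1 pix/frame, >=16 slow steps) rule."""
    slow_counts = [0, 3, 5, 8, 10, 15, 16, 17, 30, 63]
    rng = np.random.default_rng(seed)
    vel = np.empty((10, T, 2))
    for i, c in enumerate(slow_counts):
        fast = 0.5 + 0.1 * rng.random(T)
        speeds = fast
        speeds[:c] = 0.05  # below the 0.1 pix/frame threshold
        angle = rng.uniform(0, 2 * np.pi, T)
        vel[i, :, 0] = speeds * np.cos(angle)
        vel[i, :, 1] = speeds * np.sin(angle)
    return TrajectoryEnsemble(velocities=vel), np.array(slow_counts)


# ---------------------------------------------------------------------------
# file I/O

_VEL_COLS = ["trajectory_id", "frame", "u", "v"]
_POS_COLS = ["trajectory_id", "frame", "x", "y"]


def _frame_to_array(df: pd.DataFrame, value_cols, path):
    ids = df["trajectory_id"].to_numpy()
    uniq, first = np.unique(ids, return_index=True)
    uniq = uniq[np.argsort(first)]  # preserve file order
    lengths = {i: int((ids == i).sum()) for i in uniq}
    T = lengths[uniq[0]]
    bad = [i for i, ln in lengths.items() if ln != T]
    if bad:
        raise ValueError(
            f"{path}: ragged trajectory lengths; trajectory_id {bad[0]} has "
            f"{lengths[bad[0]]} rows, expected {T}"
        )
    arr = np.empty((len(uniq), T, 2))
    for j, i in enumerate(uniq):
        sub = df[ids == i].sort_values("frame")
        arr[j] = sub[value_cols].to_numpy()
    return arr, uniq


def read_ensemble(path) -> TrajectoryEnsemble:
    """Read a velocity ensemble from CSV (trajectory_id, frame, u, v) or from
    an HDF5 container written by :func:`write_ensemble`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            return TrajectoryEnsemble(
                velocities=f["velocities"][...],
                trajectory_ids=f["trajectory_ids"][...],
                frame_rate=float(f.attrs.get("frame_rate", 60.0)),
            )
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in _VEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in ("frame", "u", "v"):
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df[~pd.to_numeric(df[c], errors="coerce").notna()].index
            raise ValueError(f"{path}: non-numeric {c!r} at line {bad[0] + 2}")
    arr, ids = _frame_to_array(df, ["u", "v"], path)
    return TrajectoryEnsemble(velocities=arr, trajectory_ids=ids)


def write_ensemble(ensemble: TrajectoryEnsemble, path) -> None:
    """Write an ensemble losslessly; format chosen by extension (.csv / .h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("velocities", data=ensemble.velocities)
            f.create_dataset("trajectory_ids", data=np.asarray(ensemble.trajectory_ids))
            f.attrs["frame_rate"] = ensemble.frame_rate
        return
    N, T = ensemble.n_traj, ensemble.n_frames
    df = pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.asarray(ensemble.trajectory_ids), T),
            "frame": np.tile(np.arange(T), N),
            "u": ensemble.u.ravel(),
            "v": ensemble.v.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(
            "# point-trajectory velocities, pixels/frame; image convention "
            "(x right, y down); frame_rate=%g Hz\n" % ensemble.frame_rate
        )
        df.to_csv(fh, index=False)  # shortest-roundtrip float repr, lossless


def read_positions(path) -> PositionEnsemble:
    """Read a position ensemble from CSV (trajectory_id, frame, x, y)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in _POS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    arr, ids = _frame_to_array(df, ["x", "y"], path)
    return PositionEnsemble(positions=arr, trajectory_ids=ids)
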
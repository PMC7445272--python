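"""Reading, writing and validation of open-field sessions.

A session couples one behavioural trajectory (time-stamped position and
head direction of an animal or agent exploring a square arena) with the
spike-time tables of simultaneously recorded cells.  On load, every spike
is annotated with the position, head direction and running speed of the
animal at the moment it fired, obtained by interpolating the video-rate
trajectory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "SpikeTrain",
    "Session",
    "read_session",
    "write_session",
    "split_halves",
    "interp_circular_deg",
]

#: Tracking gaps longer than this (s) are flagged rather than interpolated.
MAX_INTERP_GAP_S = 0.5

#: Width of the boxcar used to smooth running speed (s).
SPEED_SMOOTH_S = 0.25


def _wrap_deg(a):
    """Wrap angles (degrees) into [0, 360)."""
    return np.mod(a, 360.0)


def circ_diff_deg(a, b):
    """Signed circular difference a - b in degrees, in (-180, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d)


def interp_circular_deg(t_query, t, hd_deg):
    """Circular-linear interpolation of head direction (degrees).

    Unwraps the angle time series, interpolates linearly, and wraps back,
    so a spike midway between samples at 350 deg and 10 deg maps to 0 deg.
    """
    unwrapped = np.unwrap(np.deg2rad(np.asarray(hd_deg, dtype=float)))
    return _wrap_deg(np.rad2deg(np.interp(t_query, t, unwrapped)))


@dataclass
class Trajectory:
    """Video-rate path of the animal through the arena.

    Attributes
    ----------
    time : array of float
        Sample times in seconds; strictly increasing.
    x, y : array of float
        Position in cm, clipped to ``[0, arena_size]``.
    hd : array of float
        Head direction in degrees, wrapped to ``[0, 360)``.
    frame_rate : float
        Sampling rate in Hz; occupancy time per sample is ``1/frame_rate``.
    arena_size : float
        Side length of the square arena in cm.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: np.ndarray
    frame_rate: float = 30.0
    arena_size: float = 100.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd = _wrap_deg(np.asarray(self.hd, dtype=float))
        if len(self.time) and np.any(np.diff(self.time) <= 0):
            raise ValueError("non-monotone time in trajectory")

    def __len__(self):
        return len(self.time)

    @property
    def duration(self) -> float:
        """Total occupancy time in seconds (frames / frame_rate)."""
        return len(self.time) / self.frame_rate

    def speed(self) -> np.ndarray:
        """Running speed (cm/s) from central differences, boxcar smoothed."""
        n = len(self.time)
        if n < 2:
            return np.zeros(n)
        vx = np.gradient(self.x, self.time)
        vy = np.gradient(self.y, self.time)
        sp = np.hypot(vx, vy)
        win = max(1, int(round(SPEED_SMOOTH_S * self.frame_rate)))
        if win > 1:
            from scipy.ndimage import uniform_filter1d
            sp = uniform_filter1d(sp, size=win, mode="nearest")
        return sp


@dataclass
class SpikeTrain:
    """Spike times of one cell with per-spike kinematics attached."""

    cell_id: str
    spike_times: np.ndarray
    spike_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_hd: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_speed: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def __len__(self):
        return len(self.spike_times)


@dataclass
class Session:
    """One open-field session: a trajectory plus the cells recorded on it."""

    trajectory: Trajectory
    cells: list[SpikeTrain]

    @property
    def arena_size(self) -> float:
        return self.trajectory.arena_size

    def cell(self, cell_id: str) -> SpikeTrain:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(f"no cell {cell_id!r} in session")


def attach_kinematics(trajectory: Trajectory, cell_id: str,
                      spike_times: np.ndarray) -> SpikeTrain:
    """Annotate spike times with interpolated position, hd and speed.

    Position is interpolated linearly, head direction circular-linearly.
    Spikes outside the trajectory's time range are rejected.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    t = trajectory.time
    if len(st) and len(t) and (st[0] < t[0] or st[-1] > t[-1]):
        raise ValueError(
            f"cell {cell_id!r}: spikes outside trajectory time range"
        )
    if len(t) == 0 or len(st) == 0:
        return SpikeTrain(cell_id, st, np.empty(0), np.empty(0),
                          np.empty(0), np.empty(0))
    sx = np.interp(st, t, trajectory.x)
    sy = np.interp(st, t, trajectory.y)
    shd = interp_circular_deg(st, t, trajectory.hd)
    ssp = np.interp(st, t, trajectory.speed())
    return SpikeTrain(cell_id, st, sx, sy, shd, ssp)


def clean_trajectory(df: pd.DataFrame, frame_rate: float,
                     arena_size: float) -> Trajectory:
    """Apply the cleaning rules: clip out-of-bounds samples, fill short gaps.

    Samples outside the arena are clipped to its bounds.  Missing samples
    (NaN) bridged by gaps shorter than :data:`MAX_INTERP_GAP_S` are linearly
    interpolated (circularly for hd); longer gaps raise a ``ValueError`` so
    the caller can decide how to segment the session.
    """
    t = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    hd = df["hd"].to_numpy(dtype=float)

    bad = ~(np.isfinite(x) & np.isfinite(y) & np.isfinite(hd))
    if bad.any():
        if bad.all():
            raise ValueError("no valid tracking samples")
        # longest run of consecutive missing samples, in seconds
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))
        longest = runs[::2].max() if len(runs) else 0
        if longest / frame_rate > MAX_INTERP_GAP_S:
            raise ValueError(
                f"tracking gap of {longest / frame_rate:.2f} s exceeds "
                f"{MAX_INTERP_GAP_S} s; segment the session first"
            )
        good = ~bad
        x[bad] = np.interp(t[bad], t[good], x[good])
        y[bad] = np.interp(t[bad], t[good], y[good])
        hd[bad] = interp_circular_deg(t[bad], t[good], hd[good])
    x = np.clip(x, 0.0, arena_size)
    y = np.clip(y, 0.0, arena_size)
    return Trajectory(t, x, y, hd, frame_rate=frame_rate,
                      arena_size=arena_size)


_META_RE = re.compile(r"#\s*frame_rate=(?P<fr>[\d.]+)\s+arena=(?P<ar>[\d.]+)")


def read_session(trajectory_path, spike_paths: Sequence | None = None,
                 frame_rate: float | None = None,
                 arena_size: float | None = None) -> Session:
    """Read a session from delimited text files.

    The trajectory file is CSV/TSV with columns ``time,x,y,hd`` and an
    optional metadata comment line ``# frame_rate=<Hz> arena=<cm>``.
    Each spike file holds either a single ``time`` column (cell id taken
    from the file stem) or long format ``cell_id,time``.
    """
    trajectory_path = Path(trajectory_path)
    meta_fr, meta_ar = None, None
    with open(trajectory_path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = _META_RE.search(line)
                if m:
                    meta_fr = float(m.group("fr"))
                    meta_ar = float(m.group("ar"))
            else:
                break
    frame_rate = frame_rate if frame_rate is not None else (meta_fr or 30.0)
    arena_size = arena_size if arena_size is not None else (meta_ar or 100.0)

    sep = "\t" if trajectory_path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(trajectory_path, sep=sep, comment="#")
    missing = {"time", "x", "y", "hd"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    traj = clean_trajectory(df, frame_rate, arena_size)

    cells: list[SpikeTrain] = []
    for sp in spike_paths or []:
        sp = Path(sp)
        ssep = "\t" if sp.suffix in (".tsv", ".txt") else ","
        sdf = pd.read_csv(sp, sep=ssep, comment="#")
        if "time" not in sdf.columns:
            raise ValueError(f"spike file {sp.name} missing 'time' column")
        if "cell_id" in sdf.columns:
            for cid, grp in sdf.groupby("cell_id", sort=True):
                cells.append(attach_kinematics(
                    traj, str(cid), grp["time"].to_numpy()))
        else:
            cid = sp.stem
            if cid.startswith("spikes_"):
                cid = cid[len("spikes_"):]
            cells.append(attach_kinematics(
                traj, cid, sdf["time"].to_numpy()))
    return Session(traj, cells)


def write_session(session: Session, out_dir, fmt: str = "tsv") -> Path:
    """Write a session to ``out_dir`` in the delimited-text layout.

    Produces ``trajectory.tsv`` plus one ``spikes_<cell_id>.tsv`` per cell.
    Round-trips through :func:`read_session` to float precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    traj = session.trajectory
    tpath = out_dir / f"trajectory.{fmt}"
    with open(tpath, "w") as fh:
        fh.write(f"# frame_rate={traj.frame_rate:g} arena={traj.arena_size:g}\n")
        pd.DataFrame({"time": traj.time, "x": traj.x,
                      "y": traj.y, "hd": traj.hd}).to_csv(
            fh, sep=sep, index=False, float_format="%.6f")
    for cell in session.cells:
        pd.DataFrame({"time": cell.spike_times}).to_csv(
            out_dir / f"spikes_{cell.cell_id}.{fmt}", sep=sep,
            index=False, float_format="%.6f")
    return tpath


def split_halves(session: Session) -> tuple[Session, Session]:
    """Split a session at its temporal midpoint.

    Trajectory samples and spikes strictly before the midpoint go to the
    first half; samples and spikes at or after it go to the second half.
    """
    traj = session.trajectory
    if len(traj) == 0:
        raise ValueError("cannot split an empty session")
    t_mid = traj.time[0] + (traj.time[-1] - traj.time[0]) / 2.0
    first = traj.time < t_mid

    def sub_traj(mask):
        return Trajectory(traj.time[mask], traj.x[mask], traj.y[mask],
                          traj.hd[mask], frame_rate=traj.frame_rate,
                          arena_size=traj.arena_size)

    def sub_cells(lo, hi):
        out = []
        for c in session.cells:
            m = (c.spike_times >= lo) & (c.spike_times < hi)
            out.append(SpikeTrain(c.cell_id, c.spike_times[m],
                                  c.spike_x[m] if len(c.spike_x) else c.spike_x,
                                  c.spike_y[m] if len(c.spike_y) else c.spike_y,
                                  c.spike_hd[m] if len(c.spike_hd) else c.spike_hd,
                                  c.spike_speed[m] if len(c.spike_speed) else c.spike_speed))
        return out

    s1 = Session(sub_traj(first), sub_cells(-np.inf, t_mid))
    s2 = Session(sub_traj(~first), sub_cells(t_mid, np.inf))
    return s1, s2
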
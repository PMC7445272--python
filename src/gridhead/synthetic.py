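"""Synthetic open-field sessions with known ground truth.

Generates (i) smooth random-walk trajectories confined to a square arena,
with an autocorrelated heading and a noisy head direction, and (ii) spike
trains from cells whose true tuning is known exactly: omnidirectional grid
cells, unidirectional conjunctive cells, and multidirectional grid cells
whose individual fields each carry their own mixture of preferred head
directions.  Every downstream analysis stage can therefore be tested
against ground truth without recorded data.

The trajectory model is deliberately minimal: speed follows an
Ornstein-Uhlenbeck process around a mean running speed, heading performs a
circular random walk whose circular autocorrelation decays exponentially
with a controllable persistence time, and walls reflect the path.  Head
direction equals heading plus wrapped Gaussian noise, mirroring the
imperfect alignment of head and movement direction in real animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session_io import SpikeTrain, Trajectory, attach_kinematics, \
    interp_circular_deg

__all__ = [
    "MotionParams",
    "TruthCell",
    "simulate_trajectory",
    "truth_rate",
    "generate_spikes",
    "hex_lattice_centres",
    "make_grid_cell",
    "make_conjunctive_cell",
    "make_multidirectional_cell",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MotionParams:
    """Parameters of the random-walk motion model.

    Defaults emulate a rodent actively foraging in a 1 m x 1 m arena:
    mean running speed 25 cm/s, heading persistence 2 s, and a 15 deg SD
    offset between head direction and movement direction.  With these
    values a 25-min session visits every bin of the 42 x 42 occupancy
    grid with an occupancy coefficient of variation well below 1.
    """

    mean_speed: float = 25.0       # cm/s
    speed_sd: float = 8.0          # cm/s
    speed_tau: float = 1.0         # s, relaxation time of the speed OU
    heading_persistence: float = 2.0   # s, circular autocorrelation time
    hd_offset_noise_sd: float = 15.0   # deg, head vs movement direction

    def validate(self, duration_s: float):
        if min(self.mean_speed, self.speed_sd, self.speed_tau,
               self.heading_persistence) <= 0:
            raise ValueError("motion parameters must be positive")
        if duration_s > 0 and self.heading_persistence >= duration_s:
            raise ValueError("heading persistence must be < session duration")


@dataclass
class TruthCell:
    """Ground-truth tuning of a synthetic cell.

    The firing rate is ``baseline + sum_f peak_f * G(|r - c_f|) * H_f(hd)``
    where G is a circular (isotropic) Gaussian parameterised by its spatial
    FWHM and H_f is a per-field directional gain: identically 1 for
    omnidirectional fields, a single Gaussian bump of head direction for
    conjunctive cells, or a mixture of bumps for multidirectional cells.

    ``hd_prefs_per_field`` holds, per field, a list of
    ``(preferred_direction_deg, fwhm_deg, weight)`` tuples; an empty list
    means the field is omnidirectional.  Directional gains are normalised
    so each field's maximum gain is 1, keeping ``peak_f`` interpretable as
    the field's true peak rate.
    """

    kind: str
    field_centres: np.ndarray            # (n_fields, 2) cm
    field_peak_rates: np.ndarray         # Hz per field
    spatial_fwhm: float                  # cm
    hd_prefs_per_field: list = field(default_factory=list)
    baseline_rate: float = 0.0           # Hz
    cell_id: str = "truth"

    def __post_init__(self):
        self.field_centres = np.atleast_2d(
            np.asarray(self.field_centres, dtype=float))
        self.field_peak_rates = np.atleast_1d(
            np.asarray(self.field_peak_rates, dtype=float))
        if np.any(self.field_peak_rates < 0) or self.baseline_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.kind == "omnidirectional_grid" and any(
                len(p) for p in self.hd_prefs_per_field):
            raise ValueError("omnidirectional cells take no hd preferences")
        if not self.hd_prefs_per_field:
            self.hd_prefs_per_field = [[] for _ in self.field_centres]


def _bounce(p: float, lo: float, hi: float) -> tuple[float, bool]:
    """Reflect a scalar into [lo, hi]; returns (value, was_reflected)."""
    hit = False
    span = hi - lo
    # at most a couple of bounces per frame at realistic speeds
    while p < lo or p > hi:
        hit = True
        p = 2 * lo - p if p < lo else 2 * hi - p
        p = np.clip(p, lo - span, hi + span)
    return p, hit


def simulate_trajectory(duration_s: float, arena_cm: float = 100.0,
                        motion: MotionParams | None = None,
                        seed=0, frame_rate: float = 30.0,
                        wall_mode: str = "reflect") -> Trajectory:
    """Simulate a random-walk trajectory confined to a square arena.

    Heading performs a Brownian rotation scaled so that the circular
    autocorrelation of heading decays as ``exp(-dt/heading_persistence)``.
    Walls reflect both position and heading (``wall_mode="slide"``
    instead clips the step to the arena so the agent hugs the wall until
    its heading turns away, a crude thigmotaxis analogue that strongly
    over-samples borders).  Head direction is heading plus wrapped
    Gaussian noise.
    """
    if arena_cm <= 0:
        raise ValueError("arena size must be positive")
    motion = motion or MotionParams()
    motion.validate(duration_s)
    n = int(round(duration_s * frame_rate))
    if n == 0:
        return Trajectory(np.empty(0), np.empty(0), np.empty(0), np.empty(0),
                          frame_rate=frame_rate, arena_size=arena_cm)
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate

    # Brownian heading: E[cos(theta_t - theta_0)] = exp(-D t / 2), so the
    # circular autocorrelation time equals persistence when D = 2/tau.
    sigma_step = np.sqrt(2.0 * dt / motion.heading_persistence)
    dtheta = rng.normal(0.0, sigma_step, n)
    # speed: OU around the mean, clipped at zero
    sp = np.empty(n)
    sp[0] = max(motion.mean_speed, 0.0)
    a = np.exp(-dt / motion.speed_tau)
    noise = rng.normal(0.0, motion.speed_sd * np.sqrt(1 - a * a), n)

    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)
    x[0] = y[0] = arena_cm / 2.0
    heading[0] = rng.uniform(0, 2 * np.pi)
    slide = wall_mode == "slide"
    for i in range(1, n):
        sp[i] = max(0.0, motion.mean_speed
                    + a * (sp[i - 1] - motion.mean_speed) + noise[i])
        th = heading[i - 1] + dtheta[i]
        px = x[i - 1] + sp[i] * dt * np.cos(th)
        py = y[i - 1] + sp[i] * dt * np.sin(th)
        if slide:
            px = min(max(px, 0.0), arena_cm)
            py = min(max(py, 0.0), arena_cm)
        else:
            px, hx = _bounce(px, 0.0, arena_cm)
            py, hy = _bounce(py, 0.0, arena_cm)
            if hx:
                th = np.pi - th
            if hy:
                th = -th
        x[i], y[i], heading[i] = px, py, th

    hd = np.rad2deg(heading) + rng.normal(0.0, motion.hd_offset_noise_sd, n)
    time = np.arange(n) * dt
    return Trajectory(time, x, y, np.mod(hd, 360.0),
                      frame_rate=frame_rate, arena_size=arena_cm)


def _gauss_fwhm(dist_sq, fwhm):
    """Gaussian of squared distance parameterised by its FWHM."""
    return np.exp(-4.0 * np.log(2.0) * dist_sq / (fwhm * fwhm))


def directional_gain(hd_deg, prefs) -> np.ndarray:
    """Directional gain of one field: Gaussian-bump mixture of hd.

    Each bump is a Gaussian of the minimal circular difference to its
    preferred direction, parameterised by FWHM; the mixture is normalised
    to a maximum of 1.  An empty preference list gives gain 1 everywhere.
    """
    hd_deg = np.asarray(hd_deg, dtype=float)
    if not len(prefs):
        return np.ones_like(hd_deg)
    total = np.zeros_like(hd_deg)
    for mu, fwhm, w in prefs:
        d = np.mod(hd_deg - mu + 180.0, 360.0) - 180.0
        total += w * _gauss_fwhm(d * d, fwhm)
    # normalise so the field's best direction has gain 1
    grid = np.arange(0.0, 360.0)
    peak = np.zeros_like(grid)
    for mu, fwhm, w in prefs:
        d = np.mod(grid - mu + 180.0, 360.0) - 180.0
        peak += w * _gauss_fwhm(d * d, fwhm)
    return total / peak.max()


def truth_rate(cell: TruthCell, x, y, hd) -> np.ndarray:
    """True firing rate (Hz) of a synthetic cell at position and hd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hd = np.asarray(hd, dtype=float)
    rate = np.full(np.broadcast(x, y, hd).shape, cell.baseline_rate,
                   dtype=float)
    for (cx, cy), peak, prefs in zip(cell.field_centres,
                                     cell.field_peak_rates,
                                     cell.hd_prefs_per_field):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        rate += peak * _gauss_fwhm(d2, cell.spatial_fwhm) \
            * directional_gain(hd, prefs)
    return rate


def generate_spikes(trajectory: Trajectory, cell: TruthCell,
                    seed=0, dt_ms: float = 1.0) -> SpikeTrain:
    """Bernoulli spiking on a 1 ms grid driven by the cell's true rate.

    The trajectory is upsampled to the spiking grid by linear (position)
    and circular-linear (hd) interpolation; at each step the cell fires
    with probability ``rate * dt``.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    rng = np.random.default_rng(seed)
    t0, t1 = trajectory.time[0], trajectory.time[-1]
    dt = dt_ms / 1000.0
    tq = np.arange(t0, t1, dt)
    xq = np.interp(tq, trajectory.time, trajectory.x)
    yq = np.interp(tq, trajectory.time, trajectory.y)
    hq = interp_circular_deg(tq, trajectory.time, trajectory.hd)
    p = truth_rate(cell, xq, yq, hq) * dt
    if np.any(p > 1.0):
        raise ValueError("rate * dt exceeds 1; invalid parameterization")
    spikes = tq[rng.random(len(tq)) < p]
    return attach_kinematics(trajectory, cell.cell_id, spikes)


# ---------------------------------------------------------------------------
# convenience constructors


def hex_lattice_centres(spacing: float, arena_cm: float,
                        phase=(0.0, 0.0), orientation_deg: float = 0.0,
                        margin: float | None = None) -> np.ndarray:
    """Vertices of an equilateral triangular lattice covering the arena.

    Returns all lattice points within ``margin`` (default: one spacing) of
    the arena so that fields truncated by the walls are still represented.
    """
    if margin is None:
        margin = spacing
    a1 = np.array([spacing, 0.0])
    a2 = np.array([spacing / 2.0, spacing * np.sqrt(3.0) / 2.0])
    th = np.deg2rad(orientation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    a1, a2 = rot @ a1, rot @ a2
    k = int(np.ceil((arena_cm + 2 * margin) / spacing)) + 2
    ij = np.mgrid[-k:k + 1, -k:k + 1].reshape(2, -1).T
    pts = ij[:, :1] * a1 + ij[:, 1:] * a2 + np.asarray(phase, dtype=float)
    keep = ((pts[:, 0] >= -margin) & (pts[:, 0] <= arena_cm + margin)
            & (pts[:, 1] >= -margin) & (pts[:, 1] <= arena_cm + margin))
    return pts[keep]


def make_grid_cell(spacing: float = 50.0, arena_cm: float = 100.0,
                   peak_rate: float = 12.0, spatial_fwhm: float = 20.0,
                   phase=(25.0, 25.0), cell_id: str = "grid") -> TruthCell:
    """Omnidirectional grid cell on a hexagonal lattice."""
    centres = hex_lattice_centres(spacing, arena_cm, phase)
    return TruthCell("omnidirectional_grid", centres,
                     np.full(len(centres), peak_rate), spatial_fwhm,
                     cell_id=cell_id)


def make_conjunctive_cell(hd_pref: float = 0.0, hd_fwhm: float = 141.0,
                          spacing: float = 50.0, arena_cm: float = 100.0,
                          peak_rate: float = 12.0, spatial_fwhm: float = 20.0,
                          phase=(25.0, 25.0),
                          cell_id: str = "conj") -> TruthCell:
    """Unidirectional conjunctive cell: every field shares one hd bump."""
    centres = hex_lattice_centres(spacing, arena_cm, phase)
    prefs = [[(hd_pref, hd_fwhm, 1.0)] for _ in centres]
    return TruthCell("conjunctive", centres,
                     np.full(len(centres), peak_rate), spatial_fwhm,
                     hd_prefs_per_field=prefs, cell_id=cell_id)


def make_multidirectional_cell(seed=0, n_modes=(1, 3),
                               hd_fwhm: float = 60.0, spacing: float = 50.0,
                               arena_cm: float = 100.0,
                               peak_rate: float = 12.0,
                               spatial_fwhm: float = 20.0,
                               phase=(25.0, 25.0),
                               cell_id: str = "multi") -> TruthCell:
    """Grid cell whose fields carry independent hd-preference mixtures."""
    rng = np.random.default_rng(seed)
    centres = hex_lattice_centres(spacing, arena_cm, phase)
    prefs = []
    for _ in centres:
        k = rng.integers(n_modes[0], n_modes[1] + 1)
        prefs.append([(rng.uniform(0, 360), hd_fwhm, rng.uniform(0.5, 1.0))
                      for _ in range(k)])
    return TruthCell("multidirectional_grid", centres,
                     np.full(len(centres), peak_rate), spatial_fwhm,
                     hd_prefs_per_field=prefs, cell_id=cell_id)
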
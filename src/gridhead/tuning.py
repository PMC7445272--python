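"""Spatial rate maps, autocorrelograms, and cell-classification scores.

Implements the standard open-field characterisation of medial entorhinal
cells: a binned, Gaussian-smoothed spatial firing-rate map; its spatial
autocorrelogram; a grid score based on the six-fold rotational symmetry
of the autocorrelogram; a head-direction score measuring unimodal
directional bias; and a speed score.  Cells are labelled grid, head
direction, conjunctive or other from fixed score thresholds
(grid >= 0.4, hd >= 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .session_io import Session, SpikeTrain, Trajectory

__all__ = [
    "RateMap",
    "Autocorrelogram",
    "CellScores",
    "compute_rate_map",
    "compute_autocorrelogram",
    "grid_score",
    "hd_score",
    "speed_score",
    "classify_cell",
    "GRID_SCORE_THRESHOLD",
    "HD_SCORE_THRESHOLD",
    "SPEED_SCORE_THRESHOLD",
]

GRID_SCORE_THRESHOLD = 0.4
HD_SCORE_THRESHOLD = 0.5
SPEED_SCORE_THRESHOLD = 0.1

N_BINS_DEFAULT = 42
SMOOTH_SIGMA_BINS = 1.0   # Gaussian e^{-x^2/2} centred on each bin
SMOOTH_TRUNCATE = 3.0     # kernel truncated at 3 sigma
MIN_OVERLAP_BINS = 20     # bins required for a valid autocorrelation shift
HD_SMOOTH_WINDOW_DEG = 23


@dataclass
class RateMap:
    """Binned, smoothed spatial firing-rate surface.

    ``rate_hz`` is smoothed spike counts over smoothed occupancy; bins the
    animal never visited (zero smoothed occupancy) are NaN and carried in
    ``mask``.  Row index 0 corresponds to minimum y.
    """

    spike_counts: np.ndarray
    occupancy_s: np.ndarray
    rate_hz: np.ndarray
    bin_size: float
    smoothing_sigma: float
    arena_size: float

    @property
    def n_bins(self) -> int:
        return self.rate_hz.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """True where the rate is undefined (unvisited)."""
        return ~np.isfinite(self.rate_hz)

    def bin_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) bin indices of positions; row 0 = minimum y."""
        n = self.n_bins
        col = np.clip((np.asarray(x) / self.bin_size).astype(int), 0, n - 1)
        row = np.clip((np.asarray(y) / self.bin_size).astype(int), 0, n - 1)
        return row, col


def _smooth(surface: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return surface
    return ndimage.gaussian_filter(surface, sigma=sigma, mode="constant",
                                   cval=0.0, truncate=SMOOTH_TRUNCATE)


def compute_rate_map(trajectory: Trajectory, cell: SpikeTrain,
                     n_bins: int = N_BINS_DEFAULT,
                     smoothing_sigma: float = SMOOTH_SIGMA_BINS) -> RateMap:
    """Spatial firing-rate map: smoothed spikes over smoothed occupancy.

    Spike counts and occupancy time are binned on an ``n_bins x n_bins``
    grid over the arena, each surface is smoothed with a Gaussian kernel
    of ``smoothing_sigma`` bins, and the rate is their ratio.  Bins with
    zero smoothed occupancy are NaN.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    arena = trajectory.arena_size
    bin_size = arena / n_bins
    edges = np.linspace(0.0, arena, n_bins + 1)
    occ_counts, _, _ = np.histogram2d(trajectory.y, trajectory.x,
                                      bins=[edges, edges])
    occupancy = occ_counts / trajectory.frame_rate
    spikes, _, _ = np.histogram2d(cell.spike_y, cell.spike_x,
                                  bins=[edges, edges])
    occ_s = _smooth(occupancy, smoothing_sigma)
    spk_s = _smooth(spikes, smoothing_sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 0, spk_s / np.where(occ_s > 0, occ_s, 1.0),
                        np.nan)
    # a bin never entered stays undefined even if smoothing leaks into it
    rate[occ_counts == 0] = np.nan
    return RateMap(spikes, occupancy, rate, bin_size, smoothing_sigma, arena)


@dataclass
class Autocorrelogram:
    """Spatial autocorrelation of a rate map over all integer bin shifts."""

    values: np.ndarray        # (2n-1, 2n-1); NaN where overlap too small
    n_overlap: np.ndarray     # valid overlapping bins per shift

    @property
    def centre(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2


def compute_autocorrelogram(rate_map: RateMap) -> Autocorrelogram:
    """Pearson autocorrelation of the rate map at every integer shift.

    At each shift the unmasked overlapping bins of the map and its shifted
    copy are correlated; shifts with fewer than 20 overlapping valid bins
    are undefined (NaN).
    """
    r = rate_map.rate_hz
    if not np.isfinite(r).any():
        raise ValueError("rate map is entirely masked")
    n = r.shape[0]
    valid = np.isfinite(r)
    out = np.full((2 * n - 1, 2 * n - 1), np.nan)
    nov = np.zeros((2 * n - 1, 2 * n - 1), dtype=int)
    for dr in range(-(n - 1), n):
        r0lo, r0hi = max(0, dr), min(n, n + dr)
        r1lo, r1hi = max(0, -dr), min(n, n - dr)
        for dc in range(-(n - 1), n):
            c0lo, c0hi = max(0, dc), min(n, n + dc)
            c1lo, c1hi = max(0, -dc), min(n, n - dc)
            a = r[r0lo:r0hi, c0lo:c0hi]
            b = r[r1lo:r1hi, c1lo:c1hi]
            m = valid[r0lo:r0hi, c0lo:c0hi] & valid[r1lo:r1hi, c1lo:c1hi]
            k = int(m.sum())
            nov[dr + n - 1, dc + n - 1] = k
            if k < MIN_OVERLAP_BINS:
                continue
            av, bv = a[m], b[m]
            sa, sb = av.std(), bv.std()
            if sa == 0 or sb == 0:
                continue
            out[dr + n - 1, dc + n - 1] = (
                np.mean((av - av.mean()) * (bv - bv.mean())) / (sa * sb))
    return Autocorrelogram(out, nov)


def _binary_field_maxima(binary: np.ndarray,
                         values: np.ndarray) -> np.ndarray:
    """One representative peak per connected component of a binary array.

    Components use 8-connectivity; the representative is the bin with the
    highest underlying value (first in row-major order on ties).
    Returns an (n, 2) array of (row, col).
    """
    labels, n_lab = ndimage.label(binary,
                                  structure=np.ones((3, 3), dtype=int))
    peaks = []
    vals = np.where(np.isfinite(values), values, -np.inf)
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        best = idx[np.argmax(vals[idx[:, 0], idx[:, 1]])]
        peaks.append(best)
    return np.asarray(peaks, dtype=int).reshape(-1, 2)


def grid_score(acg: Autocorrelogram) -> float:
    """Six-fold rotational-symmetry score of the autocorrelogram.

    The autocorrelogram is normalised to its peak and binarised at 20% of
    the peak correlation; if the binary array has more than seven local
    maxima (connected components),
    the annulus spanning the ring of the six maxima closest to the centre
    (radii 0.25 and 1.25 times their mean distance) is correlated against
    rotated copies of itself.  The score is
    ``min(r60, r120) - max(r30, r90, r150)``; NaN when undefined.
    """
    vals = acg.values
    finite = np.isfinite(vals)
    if not finite.any():
        return np.nan
    vmax = np.nanmax(vals)
    if vmax <= 0:
        return np.nan
    # 20% threshold on peak-normalised correlations; a min-max rescaling
    # would put the cut below r = 0 and fuse the whole surface into one
    # component, leaving the score undefined even for an ideal lattice
    binary = np.where(finite, vals / vmax, 0.0) > 0.2
    maxima = _binary_field_maxima(binary, vals)
    if len(maxima) <= 7:
        return np.nan
    cr, cc = acg.centre
    d = np.hypot(maxima[:, 0] - cr, maxima[:, 1] - cc)
    off_centre = maxima[d > 0]
    d = d[d > 0]
    if len(off_centre) < 6:
        return np.nan
    order = np.argsort(d)
    ring_d = d[order[:6]]
    d_mean = ring_d.mean()
    inner, outer = 0.25 * d_mean, 1.25 * d_mean

    rr, cc_idx = np.indices(vals.shape)
    radius = np.hypot(rr - cr, cc_idx - cc)
    annulus = (radius >= inner) & (radius <= outer)
    base = np.where(finite, vals, 0.0)

    correlations = {}
    for angle in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(base, angle, reshape=False, order=1,
                             mode="constant", cval=np.nan, prefilter=False)
        m = annulus & finite & np.isfinite(rot)
        if m.sum() < MIN_OVERLAP_BINS:
            return np.nan
        a, b = base[m], rot[m]
        if a.std() == 0 or b.std() == 0:
            return np.nan
        correlations[angle] = pearsonr(a, b).statistic
    return (min(correlations[60], correlations[120])
            - max(correlations[30], correlations[90], correlations[150]))


def hd_histogram(hds_deg: np.ndarray,
                 smooth_window_deg: int = HD_SMOOTH_WINDOW_DEG) -> np.ndarray:
    """360-bin (1 deg) histogram with a circular rolling-sum window."""
    hist, _ = np.histogram(np.mod(hds_deg, 360.0), bins=360,
                           range=(0.0, 360.0))
    if smooth_window_deg <= 1:
        return hist.astype(float)
    w = smooth_window_deg
    kernel = np.ones(w)
    padded = np.r_[hist[-(w // 2):], hist, hist[:w // 2]]
    return np.convolve(padded, kernel, mode="valid")[:360].astype(float)


def hd_score(spike_hds_deg) -> float:
    """Unimodal directional-bias score of a cell's spike head directions.

    The 360-bin spike-direction histogram is smoothed with a 23 deg
    rolling sum; the score is the length of its mean vector,
    ``sqrt(x_total^2 + y_total^2)`` with
    ``x_total = sum(cos(angle) * hist) / sum(hist)`` and likewise for y.
    """
    spike_hds_deg = np.asarray(spike_hds_deg, dtype=float)
    if len(spike_hds_deg) == 0:
        raise ValueError("hd score needs at least one spike")
    hist = hd_histogram(spike_hds_deg)
    angles = np.deg2rad(np.arange(360) + 0.5)
    total = hist.sum()
    x_total = np.sum(np.cos(angles) * hist) / total
    y_total = np.sum(np.sin(angles) * hist) / total
    return float(np.hypot(x_total, y_total))


INSTANT_RATE_SIGMA_S = 0.25  # Gaussian width for instantaneous firing rate


def instantaneous_rate(trajectory: Trajectory,
                       cell: SpikeTrain) -> np.ndarray:
    """Frame-rate firing-rate estimate: binned spikes, Gaussian smoothed."""
    edges = np.r_[trajectory.time, trajectory.time[-1]
                  + 1.0 / trajectory.frame_rate]
    counts, _ = np.histogram(cell.spike_times, bins=edges)
    sigma_frames = INSTANT_RATE_SIGMA_S * trajectory.frame_rate
    return ndimage.gaussian_filter1d(
        counts.astype(float), sigma_frames) * trajectory.frame_rate


def speed_score(trajectory: Trajectory, cell: SpikeTrain) -> float:
    """Pearson correlation of instantaneous firing rate with running speed."""
    if trajectory.duration < 60.0:
        raise ValueError("speed score needs at least one minute of data")
    speed = trajectory.speed()
    rate = instantaneous_rate(trajectory, cell)
    if speed.std() == 0:
        raise ValueError("speed score undefined for constant speed")
    if rate.std() == 0:
        return np.nan
    return pearsonr(rate, speed).statistic


@dataclass
class CellScores:
    """Classification scores and label of one cell."""

    grid_score: float
    hd_score: float
    speed_score: float = np.nan
    label: str = "other"


def classify_cell(grid: float, hd: float,
                  speed: float = np.nan) -> CellScores:
    """Label a cell from its scores.

    grid: grid score >= 0.4 and hd score < 0.5; head_direction: hd >= 0.5
    without the grid criterion; conjunctive: both criteria; otherwise
    other.  An undefined (NaN) grid score fails the grid criterion.
    """
    is_grid = np.isfinite(grid) and grid >= GRID_SCORE_THRESHOLD
    is_hd = np.isfinite(hd) and hd >= HD_SCORE_THRESHOLD
    if is_grid and is_hd:
        label = "conjunctive"
    elif is_grid:
        label = "grid"
    elif is_hd:
        label = "head_direction"
    else:
        label = "other"
    return CellScores(grid, hd, speed, label)


def score_session(session: Session) -> list[CellScores]:
    """Score and label every cell of a session."""
    out = []
    for cell in session.cells:
        rm = compute_rate_map(session.trajectory, cell)
        try:
            g = grid_score(compute_autocorrelogram(rm))
        except ValueError:
            g = np.nan
        h = hd_score(cell.spike_hd) if len(cell) else np.nan
        try:
            s = speed_score(session.trajectory, cell)
        except ValueError:
            s = np.nan
        out.append(classify_cell(g, h, s))
    return out
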
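"""Circular statistics for head-direction analysis.

Provides the two directional firing-rate curves used throughout the
analysis (a 1-degree, 23-degree-smoothed "classic" curve and a 20-bin,
18-degree "distributive" curve); the rate-map-conditioned spike shuffle
that implements the distributive-hypothesis null; per-bin significance
with Benjamini-Hochberg correction and the >97.5-percentile
directionality verdict; the two-sample Watson U^2 test; Pearson
correlations between directional curves; and half-session stability
scored against the shuffle-pair null.

The distributive-hypothesis null asks whether apparent directional
tuning could arise purely from uneven directional sampling across a
location-tuned firing field: shuffled spikes are drawn from the
trajectory with probability proportional to the spatial firing rate at
each sample, so they inherit the cell's spatial tuning but carry no
directional information beyond what the behaviour imposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, percentileofscore
from statsmodels.stats.multitest import multipletests

from .fields import FiringField
from .session_io import Session, SpikeTrain, Trajectory, split_halves
from .tuning import RateMap, hd_histogram

__all__ = [
    "DirectionalCurve",
    "ShuffleEnsemble",
    "BinSignificance",
    "classic_hd_curve",
    "distributive_curve",
    "shuffle_spike_locations",
    "significant_bins",
    "watson_u2",
    "watson_u2_permutation_p",
    "hd_curve_correlation",
    "field_correlation_analysis",
    "stability_percentile",
    "N_DISTRIBUTIVE_BINS",
    "DIRECTIONAL_PERCENTILE",
]

N_DISTRIBUTIVE_BINS = 20          # 18-degree bins
DIRECTIONAL_PERCENTILE = 97.5     # verdict threshold on the null percentile
BH_ALPHA = 0.05
MAX_MASKED_FRACTION = 0.25        # curves more masked than this are excluded

# Classical asymptotic critical values for the two-sample Watson U^2 test
WATSON_CRITICAL = [(0.385, "p < 0.001"), (0.268, "p < 0.01"),
                   (0.187, "p < 0.05"), (0.152, "p < 0.1")]


@dataclass
class DirectionalCurve:
    """Binned firing rate (Hz) as a function of head direction."""

    kind: str                 # "classic" or "distributive"
    bin_centres: np.ndarray   # degrees
    rate_hz: np.ndarray       # NaN where occupancy is zero
    n_spikes: int
    occupancy_s: np.ndarray   # seconds per bin (unsmoothed)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centres)

    @property
    def masked_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.rate_hz)))


def classic_hd_curve(spike_hds, traj_hds, frame_rate: float,
                     smooth_window_deg: int = 23) -> DirectionalCurve:
    """Classic head-direction polar curve: 1-degree bins, 23-degree smoothing.

    Both the spike and the trajectory head-direction histograms are
    smoothed with a circular rolling sum before division; the ratio is
    scaled by the frame rate to give Hz.
    """
    spike_hds = np.asarray(spike_hds, dtype=float)
    traj_hds = np.asarray(traj_hds, dtype=float)
    spike_hist = hd_histogram(spike_hds, smooth_window_deg)
    occ_hist = hd_histogram(traj_hds, smooth_window_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_hist > 0, spike_hist / occ_hist * frame_rate,
                        np.nan)
    occupancy, _ = np.histogram(np.mod(traj_hds, 360.0), bins=360,
                                range=(0, 360))
    return DirectionalCurve("classic", np.arange(360) + 0.5, rate,
                            len(spike_hds), occupancy / frame_rate)


def distributive_curve(spike_hds, traj_hds,
                       frame_rate: float) -> DirectionalCurve:
    """Distributive plot: 20 bins of 18 degrees, no smoothing."""
    spike_hds = np.asarray(spike_hds, dtype=float)
    traj_hds = np.asarray(traj_hds, dtype=float)
    nb = N_DISTRIBUTIVE_BINS
    spike_hist, _ = np.histogram(np.mod(spike_hds, 360.0), bins=nb,
                                 range=(0, 360))
    occ_hist, _ = np.histogram(np.mod(traj_hds, 360.0), bins=nb,
                               range=(0, 360))
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_hist > 0,
                        spike_hist / occ_hist * frame_rate, np.nan)
    centres = (np.arange(nb) + 0.5) * (360.0 / nb)
    return DirectionalCurve("distributive", centres, rate,
                            len(spike_hds), occ_hist / frame_rate)


@dataclass
class ShuffleEnsemble:
    """Rate-map-conditioned shuffle null for a distributive curve.

    ``curves`` holds one 20-bin distributive rate curve per shuffle
    (NaN where the trajectory never sampled a direction bin); the median
    and 90% interval (5th and 95th percentile) summarise each bin.
    """

    curves: np.ndarray        # (n_shuffles, 20)
    occ_hist: np.ndarray      # trajectory direction counts (20,)
    n_spikes: int
    seed: object

    @property
    def n_shuffles(self) -> int:
        return self.curves.shape[0]

    @property
    def median(self) -> np.ndarray:
        return np.nanmedian(self.curves, axis=0)

    @property
    def interval_90(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.nanpercentile(self.curves, 5, axis=0),
                np.nanpercentile(self.curves, 95, axis=0))


def shuffle_spike_locations(rate_map: RateMap, trajectory: Trajectory,
                            n_spikes: int, n_shuffles: int = 1000,
                            seed=0,
                            sample_indices=None) -> ShuffleEnsemble:
    """Draw shuffled spike locations under the distributive hypothesis.

    Each trajectory sample is allocated a probability proportional to the
    firing rate in its rate-map bin (total probability one); each shuffle
    draws ``n_spikes`` samples with replacement and bins their head
    directions into the 20-bin distributive curve.  Restricting
    ``sample_indices`` to the samples of a single field produces the
    per-field null.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(len(trajectory)) if sample_indices is None \
        else np.asarray(sample_indices, dtype=int)
    if len(idx) == 0:
        raise ValueError("no trajectory samples to shuffle over")
    rows, cols = rate_map.bin_of(trajectory.x[idx], trajectory.y[idx])
    weights = rate_map.rate_hz[rows, cols]
    weights = np.where(np.isfinite(weights), weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("rate map is zero over the shuffle region")
    probs = weights / total

    hds = np.mod(trajectory.hd[idx], 360.0)
    hd_bin = np.minimum((hds / 18.0).astype(int), N_DISTRIBUTIVE_BINS - 1)
    occ_hist = np.bincount(hd_bin, minlength=N_DISTRIBUTIVE_BINS)

    # vectorised categorical sampling: inverse-CDF on uniform draws
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    draws = rng.random((n_shuffles, n_spikes))
    chosen = np.searchsorted(cdf, draws)
    chosen_bins = hd_bin[chosen]
    flat = chosen_bins + N_DISTRIBUTIVE_BINS * np.arange(n_shuffles)[:, None]
    counts = np.bincount(
        flat.ravel(), minlength=n_shuffles * N_DISTRIBUTIVE_BINS
    ).reshape(n_shuffles, N_DISTRIBUTIVE_BINS).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        curves = np.where(occ_hist > 0,
                          counts / occ_hist * trajectory.frame_rate, np.nan)
    return ShuffleEnsemble(curves, occ_hist, n_spikes, seed)


@dataclass
class BinSignificance:
    """Per-bin shuffle test of a distributive curve plus the verdict."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    n_significant: int
    null_n_significant: np.ndarray
    percentile: float
    directional: bool


def _two_tailed_p(observed: np.ndarray, ensemble: np.ndarray) -> np.ndarray:
    """Two-tailed rank p-values of observed bins within shuffle columns.

    Uses the (r + 1)/(n + 1) convention so p is never zero; NaN bins
    (directions the trajectory never sampled) get p = 1.
    """
    n = ensemble.shape[0]
    le = np.nansum(ensemble <= observed[None, :], axis=0)
    ge = np.nansum(ensemble >= observed[None, :], axis=0)
    p = 2.0 * (np.minimum(le, ge) + 1.0) / (n + 1.0)
    p = np.minimum(p, 1.0)
    return np.where(np.isfinite(observed), p, 1.0)


def _count_significant(p_raw: np.ndarray, alpha: float = BH_ALPHA):
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def _bh_reject_counts(p_rows: np.ndarray, alpha: float = BH_ALPHA):
    """Benjamini-Hochberg rejection counts, one row of p-values at a time.

    Vectorised over rows (used for the 1000-shuffle null); agrees exactly
    with ``statsmodels`` ``multipletests(method="fdr_bh")`` per row.
    """
    n, m = p_rows.shape
    ps = np.sort(p_rows, axis=1)
    crit = alpha * np.arange(1, m + 1) / m
    below = ps <= crit[None, :]
    # BH rejects everything up to the largest index under its threshold
    idx = np.where(below.any(axis=1), m - np.argmax(below[:, ::-1], axis=1),
                   0)
    return idx


def significant_bins(observed: DirectionalCurve,
                     ensemble: ShuffleEnsemble,
                     leave_one_out: bool = False) -> BinSignificance:
    """Shuffle test of a distributive curve with the directionality verdict.

    Per bin, a two-tailed p-value places the observed rate within the
    shuffle distribution; Benjamini-Hochberg correction across the 20
    bins gives the count of significant bins (adjusted p < 0.05).  The
    null distribution of that count is obtained by scoring each shuffle
    against the ensemble in the same way; the curve is called directional
    when the observed count exceeds the 97.5th percentile of the null.
    """
    if observed.n_bins != ensemble.curves.shape[1]:
        raise ValueError("observed curve and ensemble bin grids differ")
    obs = observed.rate_hz
    p_raw = _two_tailed_p(obs, ensemble.curves)
    reject, p_adj = _count_significant(p_raw)
    n_sig = int(reject.sum())

    # null: each shuffle treated like the observed data, scored against
    # the full ensemble (leave-in by default, matching the procedure of
    # ranking every shuffle within all 1000 shuffles)
    curves = ensemble.curves
    n, nb = curves.shape
    n_le = np.zeros((n, nb))
    n_ge = np.zeros((n, nb))
    for b in range(nb):
        col = curves[:, b]
        if not np.isfinite(col).any():
            continue
        sc = np.sort(col)
        # ties handled exactly: counts of ensemble values <= / >= each value
        n_le[:, b] = np.searchsorted(sc, col, side="right")
        n_ge[:, b] = n - np.searchsorted(sc, col, side="left")
    if leave_one_out:
        # each shuffle scored against the other n-1, like external data
        p_null = 2.0 * np.minimum(n_le - 1 + 1, n_ge - 1 + 1) / n
    else:
        # leave-in: the scored shuffle is part of its own null ensemble,
        # so its self-comparison plays the role of the +1 pseudo-count
        p_null = 2.0 * np.minimum(n_le, n_ge) / (n + 1.0)
    p_null = np.minimum(np.where(np.isfinite(curves), p_null, 1.0), 1.0)
    null_counts = _bh_reject_counts(p_null)
    pct = percentileofscore(null_counts, n_sig, kind="mean")
    return BinSignificance(p_raw, p_adj, reject, n_sig, null_counts,
                           float(pct), bool(pct > DIRECTIONAL_PERCENTILE))


# ---------------------------------------------------------------------------
# Watson two-sample U^2


def watson_u2(sample_a_deg, sample_b_deg) -> tuple[float, str]:
    """Two-sample Watson U^2 test for homogeneity of circular samples.

    Returns the U^2 statistic and a p-value band from the classical
    asymptotic critical values (0.1 / 0.05 / 0.01 / 0.001).  Ties between
    the two samples are handled by averaging the cumulative fractions
    over tied blocks.
    """
    a = np.sort(np.mod(np.asarray(sample_a_deg, dtype=float), 360.0))
    b = np.sort(np.mod(np.asarray(sample_b_deg, dtype=float), 360.0))
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    u2 = _watson_u2_stat(a, b)
    band = "p >= 0.1"
    for crit, label in WATSON_CRITICAL:
        if u2 > crit:
            band = label
            break
    return u2, band


def _watson_u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """U^2 from the cumulative-fraction difference over the pooled sample."""
    n, m = len(a), len(b)
    total = np.concatenate([a, b])
    order = np.argsort(total, kind="stable")
    from_a = order < n
    ca = np.cumsum(from_a) / n
    cb = np.cumsum(~from_a) / m
    d = ca - cb
    pooled = total[order]
    # average d over blocks of tied pooled values
    if len(np.unique(pooled)) != len(pooled):
        _, inv, counts = np.unique(pooled, return_inverse=True,
                                   return_counts=True)
        last_idx = np.cumsum(counts) - 1
        d = d[last_idx][inv]
    nm = n + m
    dbar = d.mean()
    return float(n * m / nm**2 * np.sum((d - dbar) ** 2))


def watson_u2_permutation_p(sample_a_deg, sample_b_deg,
                            n_permutations: int = 10000,
                            seed=0) -> float:
    """Exact-style permutation p-value for the Watson U^2 statistic."""
    a = np.mod(np.asarray(sample_a_deg, dtype=float), 360.0)
    b = np.mod(np.asarray(sample_b_deg, dtype=float), 360.0)
    n = len(a)
    obs = _watson_u2_stat(np.sort(a), np.sort(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _watson_u2_stat(np.sort(perm[:n]), np.sort(perm[n:])) >= obs:
            count += 1
    return (count + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# correlations and stability


def hd_curve_correlation(curve_a: DirectionalCurve,
                         curve_b: DirectionalCurve) -> float:
    """Pearson correlation of two directional curves over unmasked bins."""
    if curve_a.n_bins != curve_b.n_bins:
        raise ValueError("curves are on different bin grids")
    if (curve_a.masked_fraction > MAX_MASKED_FRACTION
            or curve_b.masked_fraction > MAX_MASKED_FRACTION):
        return np.nan
    m = np.isfinite(curve_a.rate_hz) & np.isfinite(curve_b.rate_hz)
    if m.sum() < 3:
        return np.nan
    a, b = curve_a.rate_hz[m], curve_b.rate_hz[m]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return pearsonr(a, b).statistic


def _field_curve(trajectory: Trajectory, cell: SpikeTrain,
                 fld: FiringField) -> DirectionalCurve:
    return classic_hd_curve(cell.spike_hd[fld.spike_indices],
                            trajectory.hd[fld.trajectory_sample_indices],
                            trajectory.frame_rate)


def field_correlation_analysis(session: Session, cell: SpikeTrain,
                               fields: list[FiringField],
                               min_spikes: int = 500) -> dict:
    """Between-field and within-field (half-session) curve correlations.

    Only fields with more than ``min_spikes`` spikes enter.  Between:
    classic-curve Pearson r for every unordered field pair.  Within: for
    each field, the r between its first-half and second-half classic
    curves.  Medians summarise the cell.
    """
    eligible = [f for f in fields if f.n_spikes > min_spikes]
    traj = session.trajectory
    curves = [_field_curve(traj, cell, f) for f in eligible]

    between = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            r = hd_curve_correlation(curves[i], curves[j])
            if np.isfinite(r):
                between.append(r)

    within = []
    half1, half2 = split_halves(Session(traj, [cell]))
    t_mid = half2.trajectory.time[0] if len(half2.trajectory) else np.inf
    for f in eligible:
        st = cell.spike_times[f.spike_indices]
        tt = traj.time[f.trajectory_sample_indices]
        c1 = classic_hd_curve(cell.spike_hd[f.spike_indices][st < t_mid],
                              traj.hd[f.trajectory_sample_indices][tt < t_mid],
                              traj.frame_rate)
        c2 = classic_hd_curve(cell.spike_hd[f.spike_indices][st >= t_mid],
                              traj.hd[f.trajectory_sample_indices][tt >= t_mid],
                              traj.frame_rate)
        r = hd_curve_correlation(c1, c2)
        if np.isfinite(r):
            within.append(r)

    return {
        "between_field_r": np.asarray(between),
        "within_field_r": np.asarray(within),
        "median_between": float(np.median(between)) if between else np.nan,
        "median_within": float(np.median(within)) if within else np.nan,
    }


def stability_percentile(observed_halves_r: float,
                         ensemble_a: ShuffleEnsemble,
                         ensemble_b: ShuffleEnsemble,
                         n_pairs: int | None = 100_000,
                         seed=0) -> float:
    """Percentile of the observed half-session r within the shuffle pairs.

    The null pairs every shuffle of the first half with every shuffle of
    the second (up to 1000 x 1000 correlations of distributive curves);
    ``n_pairs`` random pairs subsample this for tractability, and
    ``n_pairs=None`` computes the exhaustive product.
    """
    if not np.isfinite(observed_halves_r):
        raise ValueError("observed correlation is undefined")
    A, B = ensemble_a.curves, ensemble_b.curves
    m = np.isfinite(A).all(axis=0) & np.isfinite(B).all(axis=0)
    if m.sum() < 3:
        raise ValueError("too few jointly sampled direction bins")
    A = A[:, m]
    B = B[:, m]

    def standardise(X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan
        return (X - mu) / sd

    As, Bs = standardise(A), standardise(B)
    nA, nB = len(As), len(Bs)
    total = nA * nB
    if n_pairs is None or n_pairs >= total:
        rs = (As @ Bs.T / As.shape[1]).ravel()
    else:
        rng = np.random.default_rng(seed)
        flat = rng.integers(0, total, n_pairs)
        ia, ib = flat // nB, flat % nB
        rs = np.sum(As[ia] * Bs[ib], axis=1) / As.shape[1]
    rs = rs[np.isfinite(rs)]
    return float(percentileofscore(rs, observed_halves_r, kind="mean"))
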
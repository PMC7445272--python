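"""Conjunctive-cell input models of grid-cell directional modulation.

A downstream "pure grid" cell is modelled as a point integrator receiving
synaptic input from a small population of conjunctive cells: grid cells
whose firing requires both proximity to a field centre (shared triangular
lattice, 50 cm spacing, 20 cm FWHM fields) and a preferred head direction
(141 deg FWHM tuning).  Conjunctive spiking is Bernoulli at 1 ms with

    p = 0.28 * G(x, y) * 0.12 * H(hd)

where G is the cell's spatial probability map (per-field peaks either
uniform, or scaled by independent uniform(0, 1) draws and renormalised to
a maximum of 1) and H its head-direction tuning curve with height 1.

In the spatially *uniform* model every field of an input cell has the
same peak rate, so the mixture of head-direction preferences seen by the
downstream cell is the same in every one of its fields.  In the
*non-uniform* model the per-field peaks differ independently between
inputs, so each downstream field receives its own weighting of the input
preferences - the mechanism proposed to generate local, field-specific
directional tuning.

The downstream neuron is a conductance-based leaky integrate-and-fire
point neuron standing in for a detailed compartmental model.  Random
synapse placement across a dendritic tree is summarised by a lognormal
efficacy jitter per synapse (nine synapses per input, ~20% CV each,
redrawn every trial); averaging over an input's nine synapses leaves a
small (~7% CV) per-input efficacy spread, preserving trial-to-trial
variability in input strength without imposing a session-wide
directional bias common to all of the output cell's fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session_io import Session, Trajectory, \
    attach_kinematics, interp_circular_deg

__all__ = [
    "ConjunctiveCellSpec",
    "SynapseParams",
    "IntegratorParams",
    "ModelConfig",
    "build_population",
    "firing_probability",
    "simulate_conjunctive_spikes",
    "conductance_trace",
    "integrate_surrogate",
    "upsample_trajectory",
    "run_trial",
    "run_experiment",
]

def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


GRID_SPACING_CM = 50.0
SPATIAL_FWHM_CM = 20.0
HD_FWHM_DEG = 141.0
P_SPACE_SCALE = 0.28
P_HD_SCALE = 0.12
MAP_RESOLUTION_CM = 1.0
#: shared spatial phase of the input lattice: places four essentially
#: complete fields inside a 1 m arena, the most a 50 cm lattice admits
DEFAULT_PHASE = (12.5, 12.5)
LOG4 = 4.0 * np.log(2.0)


@dataclass
class ConjunctiveCellSpec:
    """Generative parameters of one conjunctive input cell."""

    field_centres: np.ndarray      # (n_fields, 2) cm, shared lattice
    peak_scales: np.ndarray        # per-field scaling, max = 1
    hd_pref: float                 # preferred head direction, deg
    spatial_fwhm: float = SPATIAL_FWHM_CM
    hd_fwhm: float = HD_FWHM_DEG
    p_space_scale: float = P_SPACE_SCALE
    p_hd_scale: float = P_HD_SCALE
    arena_cm: float = 100.0
    norm: float = 1.0              # divisor making the spatial map peak 1

    def spatial_map(self, x, y) -> np.ndarray:
        """Spatial probability factor G(x, y), peak-normalised and <= 1."""
        x = np.asarray(x, dtype=float)[..., None]
        y = np.asarray(y, dtype=float)[..., None]
        d2 = (x - self.field_centres[:, 0]) ** 2 \
            + (y - self.field_centres[:, 1]) ** 2
        g = np.sum(self.peak_scales
                   * np.exp(-LOG4 * d2 / self.spatial_fwhm ** 2), axis=-1)
        return np.minimum(g / self.norm, 1.0)

    def hd_tuning(self, hd_deg) -> np.ndarray:
        """Head-direction factor H(hd): Gaussian bump of height 1."""
        d = np.mod(np.asarray(hd_deg, dtype=float) - self.hd_pref + 180.0,
                   360.0) - 180.0
        return np.exp(-LOG4 * (d / self.hd_fwhm) ** 2)


@dataclass
class SynapseParams:
    """Synapses: instantaneous rise, exponential decay, fixed conductance.

    ``g_max_ns`` is the low-regime maximal conductance of the surrogate
    point neuron, calibrated once so that the downstream cell's peak
    in-field rate (~20-30 Hz) and session spike yield match recorded
    grid cells and leave enough spikes per field for the 500-spike
    correlation gate.  An absolute conductance tuned for a full dendritic
    morphology does not transfer to a point neuron, so only the
    high/low regime ratio (:data:`HIGH_LOW_CONDUCTANCE_RATIO`) is carried
    over unchanged.
    """

    n_synapses_per_input: int = 9
    decay_tau_ms: float = 2.0
    g_max_ns: float = 3.9          # low-conductance regime (calibrated)
    reversal_mv: float = 0.0

    def __post_init__(self):
        if self.decay_tau_ms <= 0 or self.g_max_ns <= 0:
            raise ValueError("synaptic taus and conductances must be positive")


#: Ratio between the high- and low-conductance regimes (250 / 0.603).
HIGH_LOW_CONDUCTANCE_RATIO = 250.0 / 0.603


@dataclass
class IntegratorParams:
    """Conductance-based leaky integrate-and-fire surrogate neuron."""

    tau_m_ms: float = 10.0
    r_in_mohm: float = 50.0
    e_rest_mv: float = -70.0
    v_threshold_mv: float = -50.0
    v_reset_mv: float = -65.0
    refractory_ms: float = 2.0

    def __post_init__(self):
        if self.v_threshold_mv <= self.v_reset_mv:
            raise ValueError("threshold must exceed reset")
        if min(self.tau_m_ms, self.r_in_mohm, self.refractory_ms) <= 0:
            raise ValueError("time constants and resistance must be positive")


@dataclass
class ModelConfig:
    """One model configuration (uniformity x conductance regime)."""

    uniformity: str = "non_uniform"        # or "uniform"
    conductance_regime: str = "low"        # or "high"
    n_inputs: int = 5
    n_trials: int = 20
    seed: int = 0
    #: peak-rate multiplier applied to conjunctive firing probabilities in
    #: the high regime (the published probability scalars correspond to the
    #: low regime; the high regime roughly doubles conjunctive peak rates)
    high_rate_multiplier: float = 2.33
    #: per-synapse lognormal efficacy CV standing in for random dendritic
    #: placement; averaging over the 9 synapses of an input leaves a
    #: per-input efficacy CV of about jitter/3, small enough not to impose
    #: a shared directional tilt across the output cell's fields
    synapse_jitter_cv: float = 0.2
    synapse: SynapseParams = field(default_factory=SynapseParams)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)

    def __post_init__(self):
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.uniformity not in ("uniform", "non_uniform"):
            raise ValueError(f"unknown uniformity {self.uniformity!r}")
        if self.conductance_regime not in ("low", "high"):
            raise ValueError(f"unknown regime {self.conductance_regime!r}")

    @property
    def g_max_ns(self) -> float:
        g = self.synapse.g_max_ns
        return g if self.conductance_regime == "low" \
            else g * HIGH_LOW_CONDUCTANCE_RATIO

    @property
    def rate_multiplier(self) -> float:
        return 1.0 if self.conductance_regime == "low" \
            else self.high_rate_multiplier


def _lattice(arena_cm: float, phase=DEFAULT_PHASE) -> np.ndarray:
    from .synthetic import hex_lattice_centres
    return hex_lattice_centres(GRID_SPACING_CM, arena_cm, phase,
                               margin=GRID_SPACING_CM / 2.0)


def build_population(n_cells: int, uniformity: str = "non_uniform",
                     seed=0, arena_cm: float = 100.0,
                     phase=DEFAULT_PHASE) -> list[ConjunctiveCellSpec]:
    """Build a co-aligned conjunctive-cell population.

    All cells share one triangular lattice (same spatial phase); preferred
    head directions are evenly spaced on [0, 360).  Under the non-uniform
    rule each cell's per-field peaks are independent uniform(0, 1) draws;
    each cell's spatial map is then renormalised to a peak of 1 over the
    arena.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    centres = _lattice(arena_cm, phase)
    streams = _as_seedseq(seed).spawn(n_cells)
    cells = []
    for k in range(n_cells):
        rng = np.random.default_rng(streams[k])
        if uniformity == "uniform":
            scales = np.ones(len(centres))
        else:
            scales = rng.uniform(0.0, 1.0, len(centres))
        spec = ConjunctiveCellSpec(centres, scales,
                                   hd_pref=360.0 * k / n_cells,
                                   arena_cm=arena_cm)
        spec.norm = _map_peak(spec)
        cells.append(spec)
    return cells


def _map_peak(spec: ConjunctiveCellSpec) -> float:
    """Peak of the un-normalised spatial map on the 1 cm arena grid."""
    g = np.arange(0.0, spec.arena_cm + MAP_RESOLUTION_CM, MAP_RESOLUTION_CM)
    xx, yy = np.meshgrid(g, g)
    d2 = (xx[..., None] - spec.field_centres[:, 0]) ** 2 \
        + (yy[..., None] - spec.field_centres[:, 1]) ** 2
    total = np.sum(spec.peak_scales
                   * np.exp(-LOG4 * d2 / spec.spatial_fwhm ** 2), axis=-1)
    return float(total.max())


def firing_probability(spec: ConjunctiveCellSpec, x, y, hd,
                       rate_multiplier: float = 1.0) -> np.ndarray:
    """Per-millisecond firing probability of a conjunctive cell."""
    return (rate_multiplier * spec.p_space_scale * spec.spatial_map(x, y)
            * spec.p_hd_scale * spec.hd_tuning(hd))


def upsample_trajectory(trajectory: Trajectory, dt_ms: float = 1.0):
    """Interpolate a frame-rate trajectory onto the 1 ms spiking grid."""
    t0, t1 = trajectory.time[0], trajectory.time[-1]
    tq = np.arange(t0, t1, dt_ms / 1000.0)
    xq = np.interp(tq, trajectory.time, trajectory.x)
    yq = np.interp(tq, trajectory.time, trajectory.y)
    hq = interp_circular_deg(tq, trajectory.time, trajectory.hd)
    return tq, xq, yq, hq


def simulate_conjunctive_spikes(spec: ConjunctiveCellSpec,
                                trajectory: Trajectory, seed=0,
                                rate_multiplier: float = 1.0,
                                upsampled=None) -> np.ndarray:
    """Bernoulli spiking at 1 ms resolution along a trajectory.

    At each millisecond the cell fires if the firing probability exceeds
    a uniform(0, 1) draw.  Returns spike times in seconds; pass the
    precomputed ``upsample_trajectory`` output to avoid re-interpolating
    for each cell of a population.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    tq, xq, yq, hq = upsampled if upsampled is not None \
        else upsample_trajectory(trajectory)
    p = firing_probability(spec, xq, yq, hq, rate_multiplier)
    rng = np.random.default_rng(seed)
    return tq[rng.random(len(tq)) < p]


def conductance_trace(input_spike_trains: list[np.ndarray],
                      synapse: SynapseParams, t_grid: np.ndarray,
                      weights=None) -> np.ndarray:
    """Total synaptic conductance (nS) on the 1 ms clock.

    Each input spike adds ``n_synapses * g_max`` (times the input's
    efficacy weight) instantaneously; the conductance decays
    exponentially with the synaptic time constant.
    """
    dt_ms = (t_grid[1] - t_grid[0]) * 1000.0 if len(t_grid) > 1 else 1.0
    decay = np.exp(-dt_ms / synapse.decay_tau_ms)
    if weights is None:
        weights = np.ones(len(input_spike_trains))
    impulses = np.zeros(len(t_grid))
    t0 = t_grid[0]
    for train, w in zip(input_spike_trains, weights):
        if len(train) == 0:
            continue
        idx = np.clip(np.round((np.asarray(train) - t0)
                               / (dt_ms / 1000.0)).astype(int),
                      0, len(t_grid) - 1)
        amp = w * synapse.n_synapses_per_input * synapse.g_max_ns
        np.add.at(impulses, idx, amp)
    # exact per-step exponential decay: g[t] = g[t-1]*decay + impulse[t]
    from scipy.signal import lfilter
    return lfilter([1.0], [1.0, -decay], impulses)


def integrate_surrogate(g_trace: np.ndarray, t_grid: np.ndarray,
                        params: IntegratorParams | None = None,
                        e_syn_mv: float = 0.0) -> np.ndarray:
    """Conductance-based LIF integration of a synaptic conductance trace.

    The membrane obeys ``tau_m dV/dt = -(V - E_rest) - g R (V - E_syn)``
    and is advanced with the exact exponential update per 1 ms step
    (conductance held constant within a step); crossing threshold emits a
    spike, resets the voltage and imposes an absolute refractory period.
    Returns output spike times in seconds.
    """
    params = params or IntegratorParams()
    if not np.all(np.isfinite(g_trace)):
        raise ValueError("conductance trace contains non-finite values")
    dt_ms = (t_grid[1] - t_grid[0]) * 1000.0 if len(t_grid) > 1 else 1.0
    spikes_idx = _lif_kernel(
        np.asarray(g_trace, dtype=np.float64), dt_ms, params.tau_m_ms,
        params.r_in_mohm * 1e-3,  # MOhm * nS gives dimensionless g*R / 1e3
        params.e_rest_mv, e_syn_mv, params.v_threshold_mv,
        params.v_reset_mv, max(1, int(round(params.refractory_ms / dt_ms))))
    return t_grid[spikes_idx]


def _lif_core(g, dt_ms, tau_m, r_gscale, e_rest, e_syn, v_th, v_reset,
              ref_steps):
    n = g.shape[0]
    out = np.empty(n, dtype=np.int64)
    k = 0
    v = e_rest
    wait = 0
    for i in range(n):
        if wait > 0:
            wait -= 1
            continue
        gr = g[i] * r_gscale          # dimensionless conductance ratio
        tau_eff = tau_m / (1.0 + gr)
        v_inf = (e_rest + gr * e_syn) / (1.0 + gr)
        v = v_inf + (v - v_inf) * np.exp(-dt_ms / tau_eff)
        if v >= v_th:
            out[k] = i
            k += 1
            v = v_reset
            wait = ref_steps
    return out[:k]


try:  # numba compilation is a large speed-up but not a hard requirement
    from numba import njit
    _lif_kernel = njit(cache=True)(_lif_core)
except ImportError:  # pragma: no cover
    _lif_kernel = _lif_core


@dataclass
class TrialResult:
    """Output of one model trial: the simulated session and its inputs."""

    session: Session
    inputs: list[ConjunctiveCellSpec]
    input_spike_counts: np.ndarray
    weights: np.ndarray


def run_trial(config: ModelConfig, trajectory: Trajectory, trial_seed,
              upsampled=None) -> TrialResult:
    """Simulate one trial: rebuild inputs, spike them, integrate."""
    ss = _as_seedseq(trial_seed)
    s_pop, s_weights, *s_cells = ss.spawn(2 + config.n_inputs)
    population = build_population(
        config.n_inputs, config.uniformity,
        seed=s_pop, arena_cm=trajectory.arena_size)
    rng_w = np.random.default_rng(s_weights)
    cv = config.synapse_jitter_cv
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    n_syn = config.synapse.n_synapses_per_input
    per_synapse = rng_w.lognormal(-sigma * sigma / 2.0, sigma,
                                  (config.n_inputs, n_syn))
    weights = per_synapse.mean(axis=1)

    if upsampled is None:
        upsampled = upsample_trajectory(trajectory)
    t_grid = upsampled[0]
    trains = [simulate_conjunctive_spikes(
        spec, trajectory, seed=s, rate_multiplier=config.rate_multiplier,
        upsampled=upsampled) for spec, s in zip(population, s_cells)]
    synapse = replace(config.synapse, g_max_ns=config.g_max_ns)
    g = conductance_trace(trains, synapse, t_grid, weights)
    out_spikes = integrate_surrogate(g, t_grid, config.integrator,
                                     e_syn_mv=config.synapse.reversal_mv)
    cell = attach_kinematics(trajectory, "model_grid", out_spikes)
    return TrialResult(Session(trajectory, [cell]), population,
                       np.array([len(t) for t in trains]), weights)


def run_experiment(config: ModelConfig, trajectory: Trajectory,
                   n_shuffles: int = 0, min_spikes: int = 500,
                   progress=None) -> dict:
    """Run all trials of a model configuration and analyse the output.

    For each trial the input population is rebuilt (fresh per-field peaks
    under the non-uniform rule, fresh synaptic-efficacy weights), the
    downstream cell is simulated, its firing fields are detected, and the
    between-field / within-field head-direction correlation analysis is
    applied.  With ``n_shuffles > 0`` the per-field distributive shuffle
    test also runs, yielding significant-bin counts and the proportion of
    directional fields.
    """
    from .directional import distributive_curve, field_correlation_analysis, \
        hd_curve_correlation, classic_hd_curve, shuffle_spike_locations, \
        significant_bins
    from .fields import assign_events_to_field, detect_fields, eligible_cell
    from .session_io import split_halves
    from .tuning import compute_rate_map

    upsampled = upsample_trajectory(trajectory)
    root = _as_seedseq(config.seed)
    trial_seeds = root.spawn(config.n_trials)

    between, within, whole_cell_halves = [], [], []
    cell_mean_between = []
    sig_bins_per_field, directional_flags = [], []
    trials: list[TrialResult] = []
    for ti in range(config.n_trials):
        res = run_trial(config, trajectory, trial_seeds[ti],
                        upsampled=upsampled)
        trials.append(res)
        session = res.session
        cell = session.cells[0]
        if len(cell) < 10:
            continue
        rm = compute_rate_map(trajectory, cell)
        flds = [assign_events_to_field(trajectory, cell, f, rm)
                for f in detect_fields(rm)]
        if eligible_cell(flds):
            corr = field_correlation_analysis(session, cell, flds,
                                              min_spikes=min_spikes)
            between.extend(corr["between_field_r"])
            within.extend(corr["within_field_r"])
            if len(corr["between_field_r"]):
                cell_mean_between.append(
                    float(np.mean(corr["between_field_r"])))
        # whole-cell half-session classic-curve correlation
        h1, h2 = split_halves(session)
        if len(h1.cells[0]) and len(h2.cells[0]):
            c1 = classic_hd_curve(h1.cells[0].spike_hd, h1.trajectory.hd,
                                  trajectory.frame_rate)
            c2 = classic_hd_curve(h2.cells[0].spike_hd, h2.trajectory.hd,
                                  trajectory.frame_rate)
            r = hd_curve_correlation(c1, c2)
            if np.isfinite(r):
                whole_cell_halves.append(r)
        if n_shuffles > 0:
            shuffle_seeds = np.random.SeedSequence(
                (config.seed, 7, ti)).spawn(len(flds))
            for f, s in zip(flds, shuffle_seeds):
                if f.n_spikes < 30:
                    continue
                obs = distributive_curve(
                    cell.spike_hd[f.spike_indices],
                    trajectory.hd[f.trajectory_sample_indices],
                    trajectory.frame_rate)
                ens = shuffle_spike_locations(
                    rm, trajectory, f.n_spikes, n_shuffles, seed=s,
                    sample_indices=f.trajectory_sample_indices)
                sig = significant_bins(obs, ens)
                sig_bins_per_field.append(sig.n_significant)
                directional_flags.append(sig.directional)
        if progress is not None:
            progress(ti)

    def _med(v):
        return float(np.median(v)) if len(v) else np.nan

    return {
        "trials": trials,
        "between_field_r": np.asarray(between),
        "within_field_r": np.asarray(within),
        "cell_mean_between_r": np.asarray(cell_mean_between),
        "whole_cell_half_r": np.asarray(whole_cell_halves),
        # per-cell averages first, then the median across simulated cells
        "median_between": _med(cell_mean_between),
        "median_between_pooled": _med(between),
        "median_within": _med(within),
        "median_whole_cell_half": _med(whole_cell_halves),
        "sig_bins_per_field": np.asarray(sig_bins_per_field),
        "prop_directional": (float(np.mean(directional_flags))
                             if directional_flags else np.nan),
    }
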
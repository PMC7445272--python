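"""End-to-end orchestration: session -> scores -> fields -> directional stats.

Runs the complete analysis on a session (loaded from disk or synthesised)
and produces deterministic per-cell and per-field tables.  All randomness
derives from named substreams of one root seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import directional as ds
from . import fields as fd
from . import tuning as tm
from .session_io import Session, split_halves

log = logging.getLogger("gridhead")

__all__ = ["AnalysisConfig", "Report", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Thresholds and sizes of the full analysis; defaults are canonical."""

    grid_score_threshold: float = 0.4
    hd_score_threshold: float = 0.5
    speed_score_threshold: float = 0.1
    bh_alpha: float = 0.05
    directional_percentile: float = 97.5
    min_field_bins: int = 45
    field_grow_fraction: float = 0.35
    min_field_spikes: int = 500
    n_shuffles: int = 1000
    stability_n_pairs: int = 100_000
    seed: int = 0
    exclude_fields: dict = field(default_factory=dict)  # cell_id -> [ids]

    def validate(self):
        if self.n_shuffles < 1:
            raise ValueError("shuffles must be >= 1")
        if not 0 < self.bh_alpha < 1:
            raise ValueError("bh_alpha must be in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Report:
    """Canonical output tables plus run metadata."""

    cell_table: pd.DataFrame
    field_table: pd.DataFrame
    metadata: dict

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.cell_table.to_csv(out_dir / "cells.tsv", sep="\t", index=False,
                               float_format="%.6g")
        self.field_table.to_csv(out_dir / "fields.tsv", sep="\t",
                                index=False, float_format="%.6g")
        with open(out_dir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def _stage(name):
    t0 = time.perf_counter()
    log.info("stage %s started", name)
    return lambda: log.info("stage %s done in %.1f s", name,
                            time.perf_counter() - t0)


def run_analysis(session: Session,
                 config: AnalysisConfig | None = None) -> Report:
    """Run the full analysis on one session.

    Per cell: grid / hd / speed scores and label, whole-cell half-session
    stability.  Per detected field (cells with at least two fields):
    distributive shuffle test with the directionality verdict, Watson
    U^2 against the field's trajectory directions, and half-session
    correlations.  Deterministic for a given (session, config).
    """
    config = config or AnalysisConfig()
    config.validate()
    traj = session.trajectory
    cell_rows, field_rows = [], []

    for ci, cell in enumerate(session.cells):
        done = _stage(f"cell {cell.cell_id}")
        cell_ss = np.random.SeedSequence((config.seed, ci))
        rm = tm.compute_rate_map(traj, cell)
        try:
            g = tm.grid_score(tm.compute_autocorrelogram(rm))
        except ValueError:
            g = np.nan
        h = tm.hd_score(cell.spike_hd) if len(cell) else np.nan
        try:
            sp = tm.speed_score(traj, cell)
        except ValueError:
            sp = np.nan
        scores = tm.classify_cell(g, h, sp)

        # whole-cell half-session stability
        half_r = np.nan
        if len(cell) > 1:
            h1, h2 = split_halves(Session(traj, [cell]))
            if len(h1.cells[0]) and len(h2.cells[0]):
                c1 = ds.classic_hd_curve(h1.cells[0].spike_hd,
                                         h1.trajectory.hd, traj.frame_rate)
                c2 = ds.classic_hd_curve(h2.cells[0].spike_hd,
                                         h2.trajectory.hd, traj.frame_rate)
                half_r = ds.hd_curve_correlation(c1, c2)

        flds = [fd.assign_events_to_field(traj, cell, f, rm)
                for f in fd.detect_fields(rm)]
        excluded = set(config.exclude_fields.get(cell.cell_id, []))
        flds = [f for f in flds if f.field_id not in excluded]
        eligible = fd.eligible_cell(flds)

        wat = np.nan
        wat_band = ""
        if len(cell) > 1:
            wat, wat_band = ds.watson_u2(cell.spike_hd, traj.hd)

        cell_rows.append({
            "cell_id": cell.cell_id, "n_spikes": len(cell),
            "grid_score": g, "hd_score": h, "speed_score": sp,
            "label": scores.label, "n_fields": len(flds),
            "eligible": eligible, "watson_u2": wat,
            "watson_p_band": wat_band, "half_session_r": half_r,
        })

        if eligible:
            corr = ds.field_correlation_analysis(
                session, cell, flds, min_spikes=config.min_field_spikes)
            cell_rows[-1]["median_between_field_r"] = corr["median_between"]
            cell_rows[-1]["median_within_field_r"] = corr["median_within"]
            f_seeds = cell_ss.spawn(len(flds))
            for f, fs in zip(flds, f_seeds):
                field_rows.append(_analyse_field(
                    session, cell, f, rm, config, fs))
        done()

    cell_table = pd.DataFrame(cell_rows)
    field_table = pd.DataFrame(field_rows) if field_rows else pd.DataFrame(
        columns=["cell_id", "field_id", "n_spikes", "n_significant_bins",
                 "percentile", "directional", "watson_u2", "watson_p_band",
                 "half_session_r", "stability_percentile"])
    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "n_cells": len(session.cells),
            "arena_size": traj.arena_size,
            "duration_s": traj.duration}
    return Report(cell_table, field_table, meta)


def _analyse_field(session, cell, f, rm, config, seed_seq):
    traj = session.trajectory
    s_shuf, s_a, s_b, s_pairs = seed_seq.spawn(4)
    row = {"cell_id": cell.cell_id, "field_id": f.field_id,
           "n_spikes": f.n_spikes, "touches_border": f.touches_border,
           "n_bins": f.n_bins}
    spike_hd = cell.spike_hd[f.spike_indices]
    traj_hd = traj.hd[f.trajectory_sample_indices]
    if f.n_spikes < 2 or len(traj_hd) < 2:
        return row
    obs = ds.distributive_curve(spike_hd, traj_hd, traj.frame_rate)
    ens = ds.shuffle_spike_locations(
        rm, traj, f.n_spikes, config.n_shuffles, seed=s_shuf,
        sample_indices=f.trajectory_sample_indices)
    sig = ds.significant_bins(obs, ens)
    row.update(n_significant_bins=sig.n_significant,
               percentile=sig.percentile, directional=sig.directional)
    wat, band = ds.watson_u2(spike_hd, traj_hd)
    row.update(watson_u2=wat, watson_p_band=band)

    # half-session stability of the field's distributive plot
    t_mid = traj.time[0] + (traj.time[-1] - traj.time[0]) / 2.0
    st = cell.spike_times[f.spike_indices]
    tt = traj.time[f.trajectory_sample_indices]
    m1s, m2s = st < t_mid, st >= t_mid
    m1t, m2t = tt < t_mid, tt >= t_mid
    c1 = ds.classic_hd_curve(spike_hd[m1s], traj_hd[m1t], traj.frame_rate)
    c2 = ds.classic_hd_curve(spike_hd[m2s], traj_hd[m2t], traj.frame_rate)
    row["half_session_r"] = ds.hd_curve_correlation(c1, c2)
    d1 = ds.distributive_curve(spike_hd[m1s], traj_hd[m1t], traj.frame_rate)
    d2 = ds.distributive_curve(spike_hd[m2s], traj_hd[m2t], traj.frame_rate)
    obs_r = ds.hd_curve_correlation(d1, d2)
    if np.isfinite(obs_r) and m1s.sum() >= 2 and m2s.sum() >= 2 \
            and m1t.sum() and m2t.sum():
        idx = f.trajectory_sample_indices
        try:
            ens_a = ds.shuffle_spike_locations(
                rm, traj, int(m1s.sum()), config.n_shuffles, seed=s_a,
                sample_indices=idx[m1t])
            ens_b = ds.shuffle_spike_locations(
                rm, traj, int(m2s.sum()), config.n_shuffles, seed=s_b,
                sample_indices=idx[m2t])
            row["stability_percentile"] = ds.stability_percentile(
                obs_r, ens_a, ens_b, n_pairs=config.stability_n_pairs,
                seed=s_pairs)
        except ValueError:
            pass
    return row
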
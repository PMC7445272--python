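"""Segmentation of individual firing fields from a spatial rate map.

Fields are detected iteratively: the global peak of the rate map seeds a
field if it exceeds the mean plus standard deviation of the rest of the
map; the field then grows by recursively absorbing neighbouring bins
whose rate exceeds 35% of the field's peak.  A candidate is accepted if
it covers more than 45 bins but less than half the arena; accepted bins
are removed and the search repeats until no seed qualifies.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .session_io import SpikeTrain, Trajectory
from .tuning import RateMap

__all__ = [
    "FiringField",
    "detect_fields",
    "assign_events_to_field",
    "eligible_cell",
    "MIN_FIELD_BINS",
    "FIELD_GROW_FRACTION",
]

MIN_FIELD_BINS = 45          # accepted field must exceed this bin count
FIELD_GROW_FRACTION = 0.35   # neighbours join above this fraction of peak

# 8-connectivity neighbourhood offsets
_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FiringField:
    """One detected firing field of one cell."""

    field_id: int
    member_bins: np.ndarray       # (n, 2) array of (row, col)
    peak_bin: tuple[int, int]
    peak_rate: float
    touches_border: bool
    spike_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    trajectory_sample_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_bins(self) -> int:
        return len(self.member_bins)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_indices)

    def bin_mask(self, n_bins: int) -> np.ndarray:
        m = np.zeros((n_bins, n_bins), dtype=bool)
        m[self.member_bins[:, 0], self.member_bins[:, 1]] = True
        return m


def _grow_field(rate: np.ndarray, seed: tuple[int, int],
                available: np.ndarray) -> list[tuple[int, int]]:
    """Flood-grow a field from its seed bin.

    Adds 8-neighbours whose rate exceeds 35% of the field peak (the seed,
    which is the global maximum and so remains the field's peak),
    recursing through newly added bins.
    """
    n = rate.shape[0]
    threshold = FIELD_GROW_FRACTION * rate[seed]
    members = {seed}
    queue = deque([seed])
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n and 0 <= cc < n and (rr, cc) not in members \
                    and available[rr, cc] and rate[rr, cc] > threshold:
                members.add((rr, cc))
                queue.append((rr, cc))
    return sorted(members)


def detect_fields(rate_map: RateMap,
                  discard_remnants: bool = True) -> list[FiringField]:
    """Segment all firing fields of a rate map, in detection order.

    Bins already claimed by an accepted field (or consumed by a rejected
    candidate) are excluded both from subsequent growth and from the
    mean + SD seed criterion, which is evaluated over the remaining
    unmasked bins excluding the candidate peak itself.

    Because an accepted field's growth stops at 35% of its peak, the
    skirt of a strong field can later seed a spurious "field" of its own.
    Such remnants are always 8-adjacent to the field they were carved
    from, whereas genuine neighbouring grid fields are separated by
    low-rate valleys; with ``discard_remnants`` (default) any candidate
    touching a previously accepted field, an already rejected remnant,
    or an exactly-zero carved-out region is rejected as a false
    positive, automating the visual screening such fragments otherwise
    require.
    """
    rate = np.array(rate_map.rate_hz, dtype=float)
    valid = np.isfinite(rate)
    n = rate.shape[0]
    max_bins = (n * n) / 2.0
    available = valid.copy()
    # accepted fields plus remnant rejects; remnants of remnants cascade
    # outward shell by shell, so rejection must taint as acceptance does
    tainted = np.zeros_like(valid)
    fields: list[FiringField] = []
    work = np.where(valid, rate, -np.inf)

    while True:
        if not available.any():
            break
        masked = np.where(available, work, -np.inf)
        peak_flat = int(np.argmax(masked))
        seed = (peak_flat // n, peak_flat % n)
        peak_rate = rate[seed]
        if not np.isfinite(peak_rate):
            break
        rest = masked[available]
        rest = rest[rest > -np.inf]
        rest = np.delete(rest, np.argmax(rest))  # exclude the peak itself
        if len(rest) == 0 or peak_rate <= rest.mean() + rest.std():
            break
        members = _grow_field(rate, seed, available)
        arr = np.asarray(members, dtype=int)
        available[arr[:, 0], arr[:, 1]] = False
        # a candidate hugging an exactly-zero (carved-out) region is the
        # rim of a field already removed, e.g. when detection re-runs on
        # a map whose fields were zeroed
        if discard_remnants and _touches(arr, tainted | (valid & (rate == 0.0)), n):
            tainted[arr[:, 0], arr[:, 1]] = True
            continue
        if not (MIN_FIELD_BINS < len(members) < max_bins):
            continue
        tainted[arr[:, 0], arr[:, 1]] = True
        touches = bool(np.any((arr == 0) | (arr == n - 1)))
        fields.append(FiringField(len(fields), arr, seed,
                                  float(peak_rate), touches))
    return fields


def _touches(bins: np.ndarray, claimed: np.ndarray, n: int) -> bool:
    """True when any bin is 8-adjacent to (or inside) a claimed region."""
    if not claimed.any():
        return False
    grown = ndimage.binary_dilation(claimed,
                                    structure=np.ones((3, 3), dtype=bool))
    return bool(grown[bins[:, 0], bins[:, 1]].any())


def assign_events_to_field(trajectory: Trajectory, cell: SpikeTrain,
                           fld: FiringField,
                           rate_map: RateMap) -> FiringField:
    """Attach the spike and trajectory-sample indices falling in a field.

    A spike (or trajectory sample) belongs to the field when its binned
    position is one of the field's member bins.  Returns a copy of the
    field with ``spike_indices`` and ``trajectory_sample_indices`` set.
    """
    mask = fld.bin_mask(rate_map.n_bins)
    sr, sc = rate_map.bin_of(cell.spike_x, cell.spike_y)
    spike_idx = np.flatnonzero(mask[sr, sc]) if len(cell) else \
        np.empty(0, dtype=int)
    tr, tc = rate_map.bin_of(trajectory.x, trajectory.y)
    traj_idx = np.flatnonzero(mask[tr, tc])
    return FiringField(fld.field_id, fld.member_bins, fld.peak_bin,
                       fld.peak_rate, fld.touches_border,
                       spike_idx, traj_idx)


def eligible_cell(fields: list[FiringField]) -> bool:
    """A cell enters per-field analyses only with at least two fields."""
    return len(fields) >= 2
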
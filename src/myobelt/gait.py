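"""Gait-cycle segmentation from vertical ground reaction force.

Heel contact is the first frame where the vertical GRF rises above a 20 N
threshold.  A bare first-crossing rule is fragile against force-plate noise,
so the detector adds two guards, both configurable: the signal must have been
continuously below threshold for ``min_swing`` seconds before a crossing
counts (debounce against chatter on the rising edge), and detected contacts
closer than ``min_cycle`` seconds to the previous one are discarded (no human
stride is that short).

Cycles (heel contact to next heel contact of the same foot) are linearly
resampled onto a 0–100 % grid of 101 points — the biomechanics convention —
and summarised per grid point by the ensemble mean and sample standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .timeseries import TimeSeries

__all__ = [
    "GaitEvents",
    "GaitCycleSet",
    "detect_heel_contacts",
    "segment_cycles",
    "time_normalize",
    "ensemble_stats",
    "build_cycle_set",
]


@dataclass
class GaitEvents:
    """Heel-contact sample indices plus the threshold that produced them."""

    contact_indices: np.ndarray
    threshold_N: float
    rate: float = 1000.0

    def __post_init__(self):
        self.contact_indices = np.asarray(self.contact_indices, dtype=int)
        if self.threshold_N <= 0:
            raise ValidationError(f"threshold must be > 0 N, got {self.threshold_N}")
        if np.any(np.diff(self.contact_indices) <= 0):
            raise ValidationError("contact indices must be strictly increasing")

    def __len__(self) -> int:
        return self.contact_indices.size

    def times(self) -> np.ndarray:
        return self.contact_indices / self.rate


@dataclass
class GaitCycleSet:
    """Time-normalised cycles of one channel on a common percent grid."""

    grid_percent: np.ndarray           # (n_points,) 0..100
    cycles: np.ndarray                 # (n_cycles, n_points)
    mean: np.ndarray = field(default=None)  # per-point ensemble mean
    sd: np.ndarray = field(default=None)    # per-point sample SD (ddof=1)

    def __post_init__(self):
        self.grid_percent = np.asarray(self.grid_percent, dtype=float)
        self.cycles = np.atleast_2d(np.asarray(self.cycles, dtype=float))
        if self.grid_percent.size < 2:
            raise ValidationError("grid must have >= 2 points")
        if self.cycles.shape[1] != self.grid_percent.size:
            raise ValidationError("cycle length does not match grid")
        if self.mean is None or self.sd is None:
            stats = ensemble_stats(self.cycles)
            self.mean, self.sd = stats["mean"], stats["sd"]

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid_percent.size


def detect_heel_contacts(vgrf: TimeSeries, threshold_N: float = 20.0,
                         min_swing_s: float = 0.05,
                         min_cycle_s: float = 0.3) -> GaitEvents:
    """Rising-edge threshold crossings of the vertical GRF.

    A contact is a sample i with F[i] > threshold and F[i-1] <= threshold,
    preceded by at least ``min_swing_s`` continuously below threshold, and at
    least ``min_cycle_s`` after the previously accepted contact.  No
    crossings is an empty event list, not an error.
    """
    F = vgrf.values
    if F.size == 0:
        raise ValidationError("empty GRF series")
    n_swing = max(1, int(round(min_swing_s * vgrf.rate)))
    n_cycle = int(round(min_cycle_s * vgrf.rate))
    above = F > threshold_N
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    accepted: list[int] = []
    for i in rising:
        if i < n_swing or np.any(above[i - n_swing:i]):
            continue
        if accepted and i - accepted[-1] < n_cycle:
            continue
        accepted.append(int(i))
    return GaitEvents(np.array(accepted, dtype=int), threshold_N, rate=vgrf.rate)


def segment_cycles(series: TimeSeries, events: GaitEvents) -> list[np.ndarray]:
    """Split a channel into per-cycle segments [contact_k, contact_{k+1}).

    n contacts yield n−1 cycles; data before the first and after the last
    contact are discarded.
    """
    idx = events.contact_indices
    if idx.size < 2:
        raise ValidationError(f"need >= 2 heel contacts to segment, got {idx.size}")
    if idx[-1] > len(series):
        raise ValidationError("event index beyond end of series")
    return [series.values[idx[k]:idx[k + 1]] for k in range(idx.size - 1)]


def time_normalize(cycle: Sequence[float], n_points: int = 101) -> np.ndarray:
    """Linear interpolation of one cycle onto an n_points 0–100 % grid.

    Endpoints are preserved exactly.
    """
    c = np.asarray(cycle, dtype=float)
    if c.size < 2:
        raise ValidationError(f"cycle must have >= 2 samples, got {c.size}")
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    x_old = np.linspace(0.0, 1.0, c.size)
    x_new = np.linspace(0.0, 1.0, n_points)
    return np.interp(x_new, x_old, c)


def ensemble_stats(cycles: Sequence[Sequence[float]]) -> dict[str, np.ndarray]:
    """Per-grid-point mean and sample SD (ddof=1; SD=0 for a single cycle)."""
    M = np.atleast_2d(np.asarray(cycles, dtype=float))
    if M.size == 0:
        raise ValidationError("no cycles supplied")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(M.shape[1])
    return {"mean": mean, "sd": sd}


def build_cycle_set(series: TimeSeries, events: GaitEvents,
                    n_points: int = 101) -> GaitCycleSet:
    """Segment, time-normalise and summarise one channel in one step."""
    cycles = [time_normalize(c, n_points) for c in segment_cycles(series, events)]
    grid = np.linspace(0.0, 100.0, n_points)
    return GaitCycleSet(grid_percent=grid, cycles=np.vstack(cycles))
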
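"""Between-cycle stability statistics of circumference and muscle activity.

For each condition (walk/run × co-contraction/neutral/relaxation) three
numbers summarise a set of time-normalised gait cycles:

* **average amplitude** — the mean over cycles of the cycle-mean offset from
  a reference (the belt's natural length for circumference, zero for %MVC
  activity);
* **average deviation** — the mean over the percent grid of the across-cycle
  sample standard deviation;
* **coefficient of variation** — 100 · deviation / amplitude, the
  between-cycle variability relative to the signal it rides on.

The reference length is an explicit parameter, never hard-coded: what
"natural length" includes (elastic part only, or the whole belt) is a
measurement-setup choice.  For the five-muscle activity summary the averaged
CV is reported under both conventions — the ratio of the averaged deviation
to the averaged amplitude, and the mean of the per-muscle CVs — because the
two genuinely differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .gait import GaitCycleSet

__all__ = ["CycleStats", "circumference_cycle_stats", "activity_cycle_stats", "MUSCLES"]

#: Fixed muscle order used everywhere: vastus lateralis, rectus femoris,
#: vastus medialis, biceps femoris long head, biceps femoris short head.
MUSCLES = ("VL", "RF", "VM", "BFL", "BFS")


@dataclass
class CycleStats:
    """Amplitude / deviation / CV triple for one channel and condition.

    ``cv_percent`` is None (flagged undefined) when the amplitude is zero.
    ``range_units`` is the within-cycle peak-to-peak excursion of the
    ensemble-mean cycle — the natural reading of a signal's "amplitude in the
    cycle" when one means its swing rather than its offset.
    """

    average_amplitude: float
    average_deviation: float
    cv_percent: float | None
    range_units: float | None = None

    def as_dict(self) -> dict:
        return {
            "average_amplitude": self.average_amplitude,
            "average_deviation": self.average_deviation,
            "cv_percent": self.cv_percent,
            "range": self.range_units,
        }


def _stats(cycles: GaitCycleSet, reference: float) -> CycleStats:
    per_cycle_amp = (cycles.cycles - reference).mean(axis=1)
    amplitude = float(per_cycle_amp.mean())
    deviation = float(cycles.sd.mean())
    cv = 100.0 * deviation / amplitude if amplitude != 0.0 else None
    rng = float(cycles.mean.max() - cycles.mean.min())
    return CycleStats(amplitude, deviation, cv, rng)


def circumference_cycle_stats(cycles: GaitCycleSet, reference_length_mm: float) -> CycleStats:
    """Stats of the circumference channel relative to its natural length."""
    if not np.isfinite(reference_length_mm):
        raise ValidationError("reference length must be finite")
    return _stats(cycles, reference_length_mm)


def activity_cycle_stats(per_muscle_cycles: Mapping[str, GaitCycleSet]) -> dict:
    """Per-muscle and averaged stats of the five %MVC activity channels.

    Returns ``{"per_muscle": {name: CycleStats}, "averaged": {...}}`` where
    the averaged entry carries the mean amplitude, the mean deviation, and
    the CV under both conventions:

    * ``cv_percent_ratio_of_averages`` = 100 · mean(deviations) / mean(amplitudes)
    * ``cv_percent_mean_of_cvs``       = mean of the per-muscle CVs
    """
    missing = [m for m in MUSCLES if m not in per_muscle_cycles]
    if missing:
        raise ValidationError(f"missing muscle channel(s): {', '.join(missing)}")
    per_muscle = {m: _stats(per_muscle_cycles[m], 0.0) for m in MUSCLES}
    amps = np.array([per_muscle[m].average_amplitude for m in MUSCLES])
    devs = np.array([per_muscle[m].average_deviation for m in MUSCLES])
    mean_amp = float(amps.mean())
    mean_dev = float(devs.mean())
    cv_ratio = 100.0 * mean_dev / mean_amp if mean_amp != 0.0 else None
    per_cvs = [per_muscle[m].cv_percent for m in MUSCLES]
    cv_mean = float(np.mean(per_cvs)) if all(c is not None for c in per_cvs) else None
    return {
        "per_muscle": per_muscle,
        "averaged": {
            "average_amplitude": mean_amp,
            "average_deviation": mean_dev,
            "cv_percent_ratio_of_averages": cv_ratio,
            "cv_percent_mean_of_cvs": cv_mean,
        },
    }
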
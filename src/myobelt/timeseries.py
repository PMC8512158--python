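"""Uniformly sampled time series — the carrier of every signal in the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError


@dataclass
class TimeSeries:
    """A uniformly sampled channel.

    Parameters
    ----------
    values
        1-D samples. Stored as a float64 array.
    rate
        Sampling rate in Hz (> 0).
    start_time
        Time of the first sample in seconds.
    name
        Channel label, e.g. ``"emg_VL"`` or ``"capacitance"``.
    units
        Physical units of the samples, e.g. ``"nF"``, ``"V"``, ``"N"``, ``"mm"``.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError(f"{self.name or 'series'}: values must be a non-empty 1-D array")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValidationError(f"{self.name or 'series'}: rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.name or 'series'}: values contain non-finite samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (len(self) - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.rate

    def with_values(self, values: np.ndarray, *, name: str | None = None,
                    units: str | None = None) -> "TimeSeries":
        """Copy of this series carrying new samples (same rate and start time)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name,
                       units=self.units if units is None else units)
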
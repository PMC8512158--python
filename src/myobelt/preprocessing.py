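"""Signal conditioning: Butterworth filtering, EMG envelopes, MVC normalisation,
and conversion of the belt's capacitance trace to circumference and its rate.

The surface-EMG envelope chain is the classical one: 20 Hz second-order
zero-lag high-pass to strip motion artifact and electrode drift, full-wave
rectification, then a 10 Hz second-order low-pass to leave the slow amplitude
modulation that tracks muscle activation.  Envelopes are normalised by each
muscle's maximum voluntary contraction (MVC) so activity is a dimensionless
fraction comparable across muscles and sessions.

Zero-lag mode applies the designed filter forward then backward (scipy
``filtfilt`` with odd-reflection padding of 3×order samples), which squares
the magnitude response: a second-order low-pass passes −3 dB (gain 1/√2) at
its cutoff when causal, but gain 0.5 when zero-lag.  Low-passes whose phase
behaviour is unspecified default to the causal single pass, with a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .calibration import CalibrationCurve, capacitance_to_length
from .errors import ValidationError
from .timeseries import TimeSeries

__all__ = [
    "FilterSpec",
    "butterworth_filter",
    "full_wave_rectify",
    "emg_envelope",
    "compute_mvc",
    "normalize_mvc",
    "process_circumference",
]

#: Residual negative excursions of the final envelope low-pass smaller than
#: this fraction of the envelope peak are clipped to zero.
ENVELOPE_CLIP_EPS = 1e-12


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description.

    kind
        ``"lowpass"`` or ``"highpass"``.
    cutoff_hz
        −3 dB frequency of the single (causal) pass; must be below Nyquist.
    order
        Filter order of the designed prototype (default 2).
    zero_lag
        Apply forward-backward for zero phase shift (doubles the effective
        order of the magnitude response).
    """

    kind: str
    cutoff_hz: float
    order: int = 2
    zero_lag: bool = False

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if not (np.isfinite(self.cutoff_hz) and self.cutoff_hz > 0):
            raise ValidationError(f"cutoff must be positive, got {self.cutoff_hz}")
        if self.order < 1:
            raise ValidationError(f"order must be >= 1, got {self.order}")


def butterworth_filter(series: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Apply a Butterworth filter, causal or zero-lag, preserving length and rate."""
    nyq = series.rate / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValidationError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz at rate {series.rate} Hz"
        )
    if len(series) <= 3 * spec.order:
        raise ValidationError(
            f"series of {len(series)} samples too short for order-{spec.order} filtering"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz / nyq, btype=spec.kind)
    if spec.zero_lag:
        out = signal.filtfilt(b, a, series.values, padtype="odd", padlen=3 * spec.order)
    else:
        # seed the filter state with the first sample so a large DC offset
        # does not produce a startup transient
        zi = signal.lfilter_zi(b, a) * series.values[0]
        out, _ = signal.lfilter(b, a, series.values, zi=zi)
    return series.with_values(out)


def full_wave_rectify(series: TimeSeries) -> TimeSeries:
    """Element-wise absolute value."""
    return series.with_values(np.abs(series.values))


def emg_envelope(raw: TimeSeries, *, highpass_hz: float = 20.0, lowpass_hz: float = 10.0,
                 order: int = 2, zero_lag_lowpass: bool = False,
                 clip_negative: bool = True) -> TimeSeries:
    """Linear envelope of a raw EMG channel.

    Chain: zero-lag high-pass → full-wave rectification → low-pass (causal by
    default, ``zero_lag_lowpass=True`` for phase-aligned analysis).  Small
    negative undershoots of the final low-pass are clipped to zero.
    """
    hp = butterworth_filter(raw, FilterSpec("highpass", highpass_hz, order, zero_lag=True))
    rect = full_wave_rectify(hp)
    env = butterworth_filter(rect, FilterSpec("lowpass", lowpass_hz, order,
                                              zero_lag=zero_lag_lowpass))
    if clip_negative:
        env = env.with_values(np.maximum(env.values, 0.0))
    return env.with_values(env.values, name=raw.name, units=raw.units)


def compute_mvc(trials_by_muscle: Mapping[str, Sequence[TimeSeries]]) -> dict[str, float]:
    """Per-muscle MVC: the maximum envelope value across the supplied
    co-contraction trials (static standing and seated maximal efforts)."""
    if not trials_by_muscle:
        raise ValidationError("no muscles supplied")
    mvc: dict[str, float] = {}
    for muscle, trials in trials_by_muscle.items():
        trials = list(trials)
        if not trials:
            raise ValidationError(f"no trials supplied for muscle {muscle!r}")
        mvc[muscle] = float(max(np.max(t.values) for t in trials))
    return mvc


def normalize_mvc(envelope: TimeSeries, mvc: float) -> TimeSeries:
    """Envelope scaled to fractions of MVC; dynamic activity may exceed 1."""
    if not (np.isfinite(mvc) and mvc > 0):
        raise ValidationError(f"MVC must be positive, got {mvc}")
    return envelope.with_values(envelope.values / mvc, units="%MVC")


def process_circumference(capacitance: TimeSeries, curve: CalibrationCurve, *,
                          lowpass_hz: float = 10.0, order: int = 2,
                          zero_lag: bool = False,
                          apply_filter: bool = True) -> tuple[TimeSeries, TimeSeries]:
    """Capacitance trace → (circumference length mm, rate of change mm/s).

    Lengths come from the calibration transfer function, are low-pass
    filtered at 10 Hz (causal by default), and differentiated by central
    finite differences (one-sided at the ends).
    """
    lengths = capacitance_to_length(curve, capacitance.values)
    length_ts = capacitance.with_values(lengths, name="circumference", units="mm")
    if apply_filter:
        length_ts = butterworth_filter(length_ts, FilterSpec("lowpass", lowpass_hz, order,
                                                             zero_lag=zero_lag))
    vel = np.gradient(length_ts.values, length_ts.dt)
    velocity_ts = length_ts.with_values(vel, name="circumference_velocity", units="mm/s")
    return length_ts, velocity_ts
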
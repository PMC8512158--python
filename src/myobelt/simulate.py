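"""Seed-reproducible synthetic multimodal sessions with known ground truth.

No recordings ship with the study (single subject, data on request), so this
module generates complete sessions — five raw EMG channels, vertical GRF and
belt capacitance — whose ground truth (activations, circumference, heel
contacts, model coefficients) is known exactly.  The generator emulates the
study protocol:

* gait-locked activation patterns: per-muscle sums of Gaussian bumps on the
  cycle phase, with independent per-cycle, per-muscle amplitude jitter
  (humans do not repeat strides exactly);
* raw EMG as a band-limited (20–450 Hz) zero-mean Gaussian carrier amplitude-
  modulated by the activation — the standard surface-EMG surrogate;
* vertical GRF with a double-hump stance for walking (≈1.1× and 1.0× body
  weight), a single higher hump for running, and exactly zero in swing;
* circumference from the quadratic cross-modal model of the true
  activations, plus additive Gaussian noise and an optional passive-
  deformation dip (a swing-phase negative half-sine: the belt sees the
  muscle deform passively while the EMG stays silent);
* capacitance by inverting the calibration transfer function.

Conditions: ``walk``, ``run``, ``squat``, ``cocontraction_standing``,
``cocontraction_sitting`` and ``passive_flexion``; gait conditions take a
``gait_style`` of ``neutral``, ``cocontraction`` (tonic offset on all
muscles) or ``relaxation`` (swing-phase activity scaled down).

One global seed drives independent per-channel substreams, so adding or
dropping a channel never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .calibration import BELT_CURVE, CalibrationCurve, length_to_capacitance
from .crossmodal import CrossModalModel, predict
from .cycle_stats import MUSCLES
from .errors import ValidationError
from .gait import detect_heel_contacts
from .timeseries import TimeSeries

__all__ = [
    "GaussianBump",
    "SimulationConfig",
    "SessionTruth",
    "SessionData",
    "DEFAULT_TRUTH_MODEL",
    "simulate_activations",
    "simulate_emg",
    "simulate_grf",
    "simulate_circumference",
    "simulate_capacitance",
    "generate_session",
    "concat_sessions",
]

#: Ground-truth model used by default: quadriceps dominate the circumference
#: change, with mild saturation (negative quadratic terms) at high effort.
#: At full co-contraction (all A=1) the circumference rises 14 mm above the
#: 96.6 mm resting elastic length; at walking-level activity (~0.1–0.3 MVC)
#: the swing is a couple of millimetres, matching the belt's field behaviour.
DEFAULT_TRUTH_MODEL = CrossModalModel(
    w1=np.array([6.0, 4.0, 6.0, 3.0, 3.0]),
    w2=np.array([-2.0, -1.5, -2.0, -1.5, -1.0]),
    b=96.5562,
)


@dataclass(frozen=True)
class GaussianBump:
    """One activation burst: Gaussian on the cycle phase (percent units)."""

    center_pct: float
    width_pct: float
    peak: float

    def __post_init__(self):
        if self.width_pct <= 0:
            raise ValidationError(f"bump width must be > 0, got {self.width_pct}")
        if not 0.0 <= self.peak <= 1.2:
            raise ValidationError(f"bump peak must lie in [0, 1.2], got {self.peak}")


def _bumps(spec: Sequence[tuple]) -> tuple[GaussianBump, ...]:
    return tuple(GaussianBump(*t) for t in spec)


# Per-muscle activation templates; centers/widths in % of the cycle.  The
# five muscles get deliberately distinct phasing (loading-response quadriceps
# bursts at slightly staggered times, pre-contact and mid-swing hamstring
# bursts) — real muscles do not fire in lock-step, and the stagger is what
# makes the per-muscle coefficients identifiable from gait data.
_WALK_TEMPLATES = {
    "VL": _bumps([(4, 6, 0.30), (90, 5, 0.15)]),
    "RF": _bumps([(12, 8, 0.22), (85, 6, 0.12)]),
    "VM": _bumps([(7, 6, 0.28), (95, 5, 0.14)]),
    "BFL": _bumps([(93, 7, 0.25), (45, 8, 0.12)]),
    "BFS": _bumps([(99, 6, 0.20), (55, 9, 0.10)]),
}
_RUN_TEMPLATES = {
    "VL": _bumps([(3, 7, 0.65), (88, 6, 0.30)]),
    "RF": _bumps([(10, 8, 0.50), (84, 6, 0.25)]),
    "VM": _bumps([(6, 7, 0.60), (93, 6, 0.28)]),
    "BFL": _bumps([(92, 7, 0.55), (40, 9, 0.22)]),
    "BFS": _bumps([(98, 7, 0.45), (50, 9, 0.18)]),
}
_SQUAT_TEMPLATES = {
    "VL": _bumps([(50, 16, 0.70)]),
    "RF": _bumps([(47, 14, 0.60)]),
    "VM": _bumps([(53, 18, 0.68)]),
    "BFL": _bumps([(55, 16, 0.50)]),
    "BFS": _bumps([(48, 14, 0.45)]),
}
_MVC_TEMPLATES = {m: _bumps([(50, 14, 1.0)]) for m in MUSCLES}

#: Per-condition defaults: (cycle_duration s, templates, stance fraction,
#: GRF mode, default passive amplitude mm).
_CONDITIONS = {
    "walk": (1.1, _WALK_TEMPLATES, 0.62, "walk", 0.0),
    "run": (0.7, _RUN_TEMPLATES, 0.35, "run", 0.0),
    "squat": (3.0, _SQUAT_TEMPLATES, None, "constant", 0.0),
    "cocontraction_standing": (8.0, _MVC_TEMPLATES, None, "constant", 0.0),
    "cocontraction_sitting": (8.0, _MVC_TEMPLATES, None, "seated", 0.0),
    "passive_flexion": (2.0, {m: () for m in MUSCLES}, None, "seated", 2.0),
}

_GAIT_STYLES = ("neutral", "cocontraction", "relaxation")


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic session.

    Fields left at None fall back to the condition preset.  The same config
    and seed always yield a byte-identical session.
    """

    condition: str = "walk"
    gait_style: str = "neutral"
    rate: float = 1000.0
    n_cycles: int = 20
    cycle_duration_s: float | None = None
    activation_templates: Mapping[str, Sequence[GaussianBump]] | None = None
    truth_model: CrossModalModel = field(default_factory=lambda: replace(DEFAULT_TRUTH_MODEL))
    calibration: CalibrationCurve = field(default_factory=lambda: BELT_CURVE)
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    emg_gain_V: float = 1e-3
    circumference_noise_sd_mm: float = 1.8
    passive_amplitude_mm: float | None = None
    grf_body_weight_N: float = 650.0
    cycle_jitter: float = 0.30
    tone_sd_mvc: float = 0.10
    cocontraction_offset: float = 0.10
    relaxation_scale: float = 0.6
    contact_lead_s: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.condition not in _CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; choose from {sorted(_CONDITIONS)}")
        if self.gait_style not in _GAIT_STYLES:
            raise ValidationError(
                f"unknown gait_style {self.gait_style!r}; choose from {_GAIT_STYLES}")
        if self.rate <= 0 or self.n_cycles < 1:
            raise ValidationError("rate and n_cycles must be positive")
        if self.cycle_duration_s is not None and self.cycle_duration_s <= 0:
            raise ValidationError("cycle_duration_s must be positive")
        lo, hi = self.emg_band_hz
        if not (0 < lo < hi):
            raise ValidationError(f"invalid EMG band {self.emg_band_hz}")
        if hi >= self.rate / 2:
            raise ValidationError(
                f"EMG band upper edge {hi} Hz >= Nyquist {self.rate / 2} Hz")
        if self.grf_body_weight_N <= 0:
            raise ValidationError("grf_body_weight_N must be positive")
        if min(self.circumference_noise_sd_mm, self.cycle_jitter, self.tone_sd_mvc) < 0:
            raise ValidationError("noise parameters must be non-negative")
        sf = _CONDITIONS[self.condition][2]
        if sf is not None:
            lead = self.contact_lead_s / self.resolved_cycle_duration_s
            if not (0 < lead and lead + sf < 1):
                raise ValidationError(
                    f"contact lead {self.contact_lead_s}s plus stance does not fit in a "
                    f"{self.resolved_cycle_duration_s}s cycle")
        if self.activation_templates is not None:
            for m in MUSCLES:
                for bump in self.activation_templates.get(m, ()):
                    if not isinstance(bump, GaussianBump):
                        raise ValidationError("templates must contain GaussianBump entries")

    # resolved (preset-aware) values -------------------------------------
    @property
    def resolved_cycle_duration_s(self) -> float:
        return self.cycle_duration_s if self.cycle_duration_s is not None \
            else _CONDITIONS[self.condition][0]

    @property
    def resolved_templates(self) -> Mapping[str, Sequence[GaussianBump]]:
        return self.activation_templates if self.activation_templates is not None \
            else _CONDITIONS[self.condition][1]

    @property
    def stance_fraction(self) -> float | None:
        return _CONDITIONS[self.condition][2]

    @property
    def resolved_passive_amplitude_mm(self) -> float:
        return self.passive_amplitude_mm if self.passive_amplitude_mm is not None \
            else _CONDITIONS[self.condition][4]

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.resolved_cycle_duration_s * self.rate))

    @property
    def n_samples(self) -> int:
        return self.n_cycles * self.samples_per_cycle


@dataclass
class SessionTruth:
    """Generator ground truth aligned sample-wise with the channels."""

    activations: np.ndarray            # (5, T) true %MVC fractions
    circumference_mm: np.ndarray       # (T,)
    contact_indices: np.ndarray        # heel contacts (empty for static trials)
    model: CrossModalModel
    condition: str


@dataclass
class SessionData:
    """One synthetic (or loaded) session: raw channels plus optional truth."""

    capacitance: TimeSeries
    emg: dict[str, TimeSeries]
    vgrf: TimeSeries
    truth: SessionTruth | None = None

    def __post_init__(self):
        lengths = {len(self.capacitance), len(self.vgrf)} | {len(s) for s in self.emg.values()}
        rates = {self.capacitance.rate, self.vgrf.rate} | {s.rate for s in self.emg.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValidationError("all session channels must share length and rate")

    @property
    def rate(self) -> float:
        return self.capacitance.rate

    @property
    def n_samples(self) -> int:
        return len(self.capacitance)


def _phase(config: SimulationConfig) -> np.ndarray:
    """Cycle phase in [0, 1) for every sample, 0 = heel contact.

    Gait conditions place heel contact ``contact_lead_s`` after the start of
    each generated cycle so the first contact is a detectable rising edge
    (the detector needs a stretch of swing below threshold before it).
    """
    idx = np.arange(config.n_samples)
    raw = (idx % config.samples_per_cycle) / config.samples_per_cycle
    if config.stance_fraction is None:
        return raw
    lead = config.contact_lead_s / config.resolved_cycle_duration_s
    return (raw - lead) % 1.0


def _bump_profile(bumps: Sequence[GaussianBump], phase: np.ndarray) -> np.ndarray:
    """Sum of circular Gaussians on the phase (wrap-around aware)."""
    out = np.zeros_like(phase)
    for b in bumps:
        c, w = b.center_pct / 100.0, b.width_pct / 100.0
        d = phase - c
        d -= np.round(d)  # circular distance in cycles
        out += b.peak * np.exp(-0.5 * (d / w) ** 2)
    return out


def simulate_activations(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """True activations as a (5, T) array of %MVC fractions.

    Stride-to-stride variability has two independent components per muscle:
    each burst's amplitude is jittered per cycle (Gaussian, SD
    ``cycle_jitter``, independent across bursts, cycles and muscles), and a
    slow tonic fluctuation (low-passed white noise at ~1 Hz, SD
    ``tone_sd_mvc``) rides under everything — resting muscle tone is never
    perfectly constant.  The ``cocontraction`` gait style adds a tonic
    offset to every muscle and ``relaxation`` scales swing-phase activity by
    ``relaxation_scale``.  Values are clipped to [0, 1.2].
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    phase = _phase(config)
    cycle_idx = np.arange(config.n_samples) // config.samples_per_cycle
    templates = config.resolved_templates
    has_bumps = any(len(templates.get(m, ())) for m in MUSCLES)
    tone_b, tone_a = _signal.butter(2, min(1.0 / (config.rate / 2.0), 0.99))
    A = np.zeros((5, config.n_samples))
    for i, m in enumerate(MUSCLES):
        prof = np.zeros(config.n_samples)
        for bump in templates.get(m, ()):
            fac = 1.0 + config.cycle_jitter * rng.standard_normal(config.n_cycles)
            fac = np.clip(fac, 0.2, None)
            prof += _bump_profile([bump], phase) * fac[cycle_idx]
        if config.tone_sd_mvc > 0 and has_bumps:
            tone = _signal.filtfilt(tone_b, tone_a, rng.standard_normal(config.n_samples))
            sd = np.std(tone)
            if sd > 0:
                prof += config.tone_sd_mvc * tone / sd
        A[i] = prof
    sf = config.stance_fraction
    if sf is not None and config.gait_style == "relaxation":
        swing = phase >= sf
        A[:, swing] *= config.relaxation_scale
    if config.gait_style == "cocontraction" and has_bumps:
        A += config.cocontraction_offset
    return np.clip(A, 0.0, 1.2)


def simulate_emg(activation: TimeSeries, config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> TimeSeries:
    """Raw EMG: unit-RMS band-limited Gaussian carrier × activation × gain."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.emg_band_hz
    nyq = activation.rate / 2.0
    if hi >= nyq:
        raise ValidationError(f"EMG band upper edge {hi} Hz >= Nyquist {nyq} Hz")
    white = rng.standard_normal(len(activation))
    b, a = _signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass")
    carrier = _signal.filtfilt(b, a, white)
    rms = np.sqrt(np.mean(carrier ** 2))
    if rms > 0:
        carrier /= rms
    raw = carrier * activation.values * config.emg_gain_V
    return activation.with_values(raw, name=f"emg_{activation.name}", units="V")


def simulate_grf(config: SimulationConfig) -> TimeSeries:
    """Vertical GRF (N): gait stance humps over an exactly-zero swing, or a
    constant support force for static/squat trials."""
    mode = _CONDITIONS[config.condition][3]
    bw = config.grf_body_weight_N
    T = config.n_samples
    if mode == "constant":
        values = np.full(T, bw)
    elif mode == "seated":
        values = np.full(T, 0.1 * bw)
    else:
        phase = _phase(config)
        sf = config.stance_fraction
        stance_phase = np.where(phase < sf, phase / sf, np.nan)
        if mode == "walk":
            humps = [(0.25, 0.10, 1.1), (0.75, 0.10, 1.0)]
        else:  # run
            humps = [(0.5, 0.18, 2.4)]
        values = np.zeros(T)
        in_stance = phase < sf
        sp = stance_phase[in_stance]
        v = np.zeros_like(sp)
        for c, w, peak in humps:
            v += peak * bw * np.exp(-0.5 * ((sp - c) / w) ** 2)
        values[in_stance] = v
    return TimeSeries(values, rate=config.rate, name="vgrf", units="N")


def _passive_profile(config: SimulationConfig) -> np.ndarray:
    """Swing-phase (or, for static trials, whole-cycle) negative half-sine."""
    amp = config.resolved_passive_amplitude_mm
    if amp == 0.0:
        return np.zeros(config.n_samples)
    phase = _phase(config)
    sf = config.stance_fraction
    if sf is None:
        s = -np.sin(np.pi * phase)
    else:
        s = np.zeros(config.n_samples)
        swing = phase >= sf
        s[swing] = -np.sin(np.pi * (phase[swing] - sf) / (1.0 - sf))
    return amp * s


def simulate_circumference(activations: np.ndarray, config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """True circumference (mm): quadratic model of the activations plus the
    passive-deformation dip plus additive Gaussian noise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = predict(config.truth_model, np.asarray(activations).T)
    L = L + _passive_profile(config)
    if config.circumference_noise_sd_mm > 0:
        L = L + config.circumference_noise_sd_mm * rng.standard_normal(L.size)
    return L


def simulate_capacitance(circumference_mm: np.ndarray,
                         calibration: CalibrationCurve,
                         rate: float) -> TimeSeries:
    """Belt capacitance (nF) by inverting the calibration transfer function."""
    C = length_to_capacitance(calibration, np.asarray(circumference_mm, dtype=float))
    return TimeSeries(C, rate=rate, name="capacitance", units="nF")


def generate_session(config: SimulationConfig) -> SessionData:
    """Assemble a full synthetic session with ground truth.

    Independent substreams (spawned from the single seed) drive the
    activation jitter, each EMG carrier, and the circumference noise.
    """
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_act = np.random.default_rng(streams[0])
    rng_emg = [np.random.default_rng(s) for s in streams[1:6]]
    rng_circ = np.random.default_rng(streams[6])

    A = simulate_activations(config, rng_act)
    emg = {}
    for i, m in enumerate(MUSCLES):
        act_ts = TimeSeries(A[i], rate=config.rate, name=m, units="%MVC")
        emg[m] = simulate_emg(act_ts, config, rng_emg[i])
    vgrf = simulate_grf(config)
    L = simulate_circumference(A, config, rng_circ)
    cap = simulate_capacitance(L, config.calibration, config.rate)

    # ground-truth heel contacts: first sample above 20 N within each cycle
    # (gait conditions only — static support force is not a contact event)
    contacts = []
    if config.stance_fraction is not None:
        spc = config.samples_per_cycle
        for k in range(config.n_cycles):
            seg = vgrf.values[k * spc:(k + 1) * spc]
            above = np.flatnonzero(seg > 20.0)
            if above.size:
                contacts.append(k * spc + int(above[0]))
    truth = SessionTruth(activations=A, circumference_mm=L,
                         contact_indices=np.array(contacts, dtype=int),
                         model=config.truth_model, condition=config.condition)
    return SessionData(capacitance=cap, emg=emg, vgrf=vgrf, truth=truth)


def concat_sessions(*sessions: SessionData) -> SessionData:
    """Concatenate sessions recorded at the same rate (protocols that chain
    trials, e.g. maximal co-contractions followed by squats)."""
    if not sessions:
        raise ValidationError("no sessions to concatenate")
    rate = sessions[0].rate
    if any(s.rate != rate for s in sessions):
        raise ValidationError("sessions must share the sampling rate")
    cap = np.concatenate([s.capacitance.values for s in sessions])
    vgrf = np.concatenate([s.vgrf.values for s in sessions])
    emg = {m: TimeSeries(np.concatenate([s.emg[m].values for s in sessions]),
                         rate=rate, name=f"emg_{m}", units="V") for m in MUSCLES}
    truth = None
    if all(s.truth is not None for s in sessions):
        offs = np.cumsum([0] + [s.n_samples for s in sessions[:-1]])
        truth = SessionTruth(
            activations=np.concatenate([s.truth.activations for s in sessions], axis=1),
            circumference_mm=np.concatenate([s.truth.circumference_mm for s in sessions]),
            contact_indices=np.concatenate(
                [s.truth.contact_indices + o for s, o in zip(sessions, offs)]),
            model=sessions[0].truth.model,
            condition="+".join(s.truth.condition for s in sessions),
        )
    return SessionData(
        capacitance=TimeSeries(cap, rate=rate, name="capacitance", units="nF"),
        emg=emg,
        vgrf=TimeSeries(vgrf, rate=rate, name="vgrf", units="N"),
        truth=truth,
    )


def verify_contacts(session: SessionData) -> bool:
    """Detector consistency check: detected contacts equal truth ±1 sample."""
    if session.truth is None:
        raise ValidationError("session has no ground truth")
    det = detect_heel_contacts(session.vgrf).contact_indices
    tru = session.truth.contact_indices
    return det.size == tru.size and bool(np.all(np.abs(det - tru) <= 1))
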
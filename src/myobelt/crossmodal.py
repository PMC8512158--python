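"""The cross-modal circumference model and its agreement metrics.

The thigh's circumference is driven by the bulging of the muscles under the
belt, so it is modelled as a quadratic form of the five recorded activities
(fractions of MVC):

    L_hat(t) = sum_i [ w_i1 * A_i(t) + w_i2 * A_i(t)^2 ] + b ,   i = VL, RF, VM, BFL, BFS

Coefficients are the ordinary least-squares minimiser of
sum_t (L(t) − L_hat(t))^2 over the recording.  Agreement between measured
and estimated circumference is assessed by RMSE, the OLS regression line of
measured on estimated, and ICC(2,1) — the two-way random-effects,
absolute-agreement, single-measure intraclass correlation with the paired
frames as targets and (measured, estimated) as the two raters:

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),  k = 2

with mean squares from the targets × raters two-way ANOVA decomposition.
Evaluation pairs are decimated to 10 Hz by default (the envelope and
circumference carry no useful content above the 10 Hz low-pass anyway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .calibration import BELT_CURVE, CalibrationCurve
from .cycle_stats import MUSCLES
from .errors import ValidationError
from .preprocessing import compute_mvc, emg_envelope, normalize_mvc, process_circumference

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SessionData

__all__ = [
    "CrossModalModel",
    "FitResult",
    "EvaluationConfig",
    "build_design",
    "fit",
    "predict",
    "rmse",
    "regression_line",
    "icc_2_1",
    "evaluate_session",
]


@dataclass
class CrossModalModel:
    """Quadratic activity→circumference map with the fixed muscle ordering."""

    w1: np.ndarray              # (5,) mm per unit %MVC
    w2: np.ndarray              # (5,) mm per unit %MVC^2
    b: float                    # mm
    muscle_order: tuple = MUSCLES

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.shape != (5,) or self.w2.shape != (5,):
            raise ValidationError("w1 and w2 must each have exactly 5 coefficients")
        if not (np.all(np.isfinite(self.w1)) and np.all(np.isfinite(self.w2))
                and np.isfinite(self.b)):
            raise ValidationError("model coefficients must be finite")

    def coefficients(self) -> np.ndarray:
        """Flat parameter vector (w1[0..4], w2[0..4], b)."""
        return np.concatenate([self.w1, self.w2, [self.b]])

    def as_dict(self) -> dict:
        return {"muscles": list(self.muscle_order), "w1": self.w1.tolist(),
                "w2": self.w2.tolist(), "b": self.b}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CrossModalModel":
        return cls(np.asarray(d["w1"]), np.asarray(d["w2"]), float(d["b"]))


@dataclass
class FitResult:
    """Fitted model plus the agreement metrics of one session."""

    model: CrossModalModel
    rmse_mm: float
    icc21: float | None
    regression_slope: float
    regression_intercept_mm: float
    n_frames: int

    def as_dict(self) -> dict:
        return {"model": self.model.as_dict(), "rmse_mm": self.rmse_mm,
                "icc21": self.icc21, "regression_slope": self.regression_slope,
                "regression_intercept_mm": self.regression_intercept_mm,
                "n_frames": self.n_frames}


def _check_activities(activities) -> np.ndarray:
    A = np.asarray(activities, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    if A.ndim != 2 or A.shape[1] != 5:
        raise ValidationError(f"activities must be T x 5 (muscle order {MUSCLES}), "
                              f"got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValidationError("activities contain non-finite values")
    return A


def build_design(activities) -> np.ndarray:
    """T×11 design matrix with columns [A_1..A_5, A_1^2..A_5^2, 1]."""
    A = _check_activities(activities)
    return np.hstack([A, A ** 2, np.ones((A.shape[0], 1))])


def fit(activities, circumference_mm) -> CrossModalModel:
    """Least-squares coefficients of the quadratic model.

    Rank-deficient or under-determined designs (heavy co-contraction can make
    the activity channels collinear) get the minimum-norm solution and a
    warning rather than a failure.
    """
    A = _check_activities(activities)
    L = np.asarray(circumference_mm, dtype=float).ravel()
    if L.size != A.shape[0]:
        raise ValidationError(f"{A.shape[0]} activity frames vs {L.size} circumference frames")
    if not np.all(np.isfinite(L)):
        raise ValidationError("circumference contains non-finite values")
    X = build_design(A)
    if X.shape[0] < X.shape[1]:
        warnings.warn(f"only {X.shape[0]} frames for {X.shape[1]} parameters; "
                      "under-determined fit, returning the minimum-norm solution")
    theta, _, rank, _ = np.linalg.lstsq(X, L, rcond=None)
    if X.shape[0] >= X.shape[1] and rank < X.shape[1]:
        warnings.warn(f"design rank {rank} < {X.shape[1]} (collinear activities); "
                      "returning the minimum-norm solution")
    return CrossModalModel(w1=theta[:5], w2=theta[5:10], b=float(theta[10]))


def predict(model: CrossModalModel, activities) -> np.ndarray:
    """Per-frame model circumference L_hat in mm."""
    return build_design(activities) @ model.coefficients()


def rmse(measured_mm, estimated_mm) -> float:
    """Root-mean-square difference between two equal-length traces."""
    x = np.asarray(measured_mm, dtype=float).ravel()
    y = np.asarray(estimated_mm, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def regression_line(estimated_mm, measured_mm) -> dict[str, float]:
    """OLS of measured (y) on estimated (x): returns {"slope", "intercept"}."""
    x = np.asarray(estimated_mm, dtype=float).ravel()
    y = np.asarray(measured_mm, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValidationError("need >= 2 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("estimated values have zero variance; regression undefined")
    slope, intercept = np.polyfit(x, y, deg=1)
    return {"slope": float(slope), "intercept": float(intercept)}


def icc_2_1(x, y) -> float | None:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``x`` and ``y`` are the two raters' scores over n paired targets.  With
    the two-way ANOVA mean squares MSR (rows/targets), MSC (columns/raters)
    and MSE (residual):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),  k = 2.

    Returns None (undefined) when the data carry no variance at all.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 paired observations, got {n}")
    k = 2
    M = np.column_stack([x, y])
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_total = float(np.sum((M - grand) ** 2))
    if ss_total == 0.0:
        return None
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    return float((msr - mse) / denom)


@dataclass
class EvaluationConfig:
    """Settings for the end-to-end session evaluation.

    activity_source
        ``"emg"`` (envelope + MVC normalisation of the raw channels) or
        ``"truth"`` (a synthetic session's generator activations).
    circumference_source
        ``"capacitance"`` (calibration + 10 Hz low-pass of the belt channel)
        or ``"truth"``.
    mvc
        Per-muscle MVC values; None computes each muscle's envelope maximum
        over this session (valid when the session contains maximal efforts).
    eval_rate_hz
        Rate the paired traces are decimated to before ICC / regression /
        RMSE (10 Hz default); None evaluates at the native rate.
    """

    calibration: CalibrationCurve = field(default_factory=lambda: BELT_CURVE)
    activity_source: str = "emg"
    circumference_source: str = "capacitance"
    mvc: Mapping[str, float] | None = None
    eval_rate_hz: float | None = 10.0
    zero_lag_lowpass: bool = False

    def __post_init__(self):
        if self.activity_source not in ("emg", "truth"):
            raise ValidationError(f"unknown activity_source {self.activity_source!r}")
        if self.circumference_source not in ("capacitance", "truth"):
            raise ValidationError(
                f"unknown circumference_source {self.circumference_source!r}")


def session_activities(session: "SessionData", config: EvaluationConfig) -> np.ndarray:
    """T×5 %MVC activity matrix of a session under the configured source."""
    if config.activity_source == "truth":
        if session.truth is None or session.truth.activations is None:
            raise ValidationError("session carries no ground-truth activations")
        return np.asarray(session.truth.activations).T
    envs = {m: emg_envelope(session.emg[m], zero_lag_lowpass=config.zero_lag_lowpass)
            for m in MUSCLES}
    mvc = dict(config.mvc) if config.mvc is not None else compute_mvc(
        {m: [envs[m]] for m in MUSCLES})
    return np.column_stack([normalize_mvc(envs[m], mvc[m]).values for m in MUSCLES])


def session_circumference(session: "SessionData", config: EvaluationConfig) -> np.ndarray:
    """Circumference trace (mm) of a session under the configured source."""
    if config.circumference_source == "truth":
        if session.truth is None or session.truth.circumference_mm is None:
            raise ValidationError("session carries no ground-truth circumference")
        return np.asarray(session.truth.circumference_mm)
    length_ts, _ = process_circumference(session.capacitance, config.calibration,
                                         zero_lag=config.zero_lag_lowpass)
    return length_ts.values


def evaluate_session(session: "SessionData",
                     config: EvaluationConfig | None = None) -> FitResult:
    """Fit the quadratic model on a session and score the agreement.

    Processes the session into %MVC activities and circumference, fits at
    the native rate, predicts, then computes RMSE, the measured-on-estimated
    regression line and ICC(2,1) on pairs decimated to ``eval_rate_hz``.
    """
    config = config or EvaluationConfig()
    A = session_activities(session, config)
    L = session_circumference(session, config)
    if A.shape[0] != L.size:
        raise ValidationError("activity and circumference lengths differ")
    model = fit(A, L)
    L_hat = predict(model, A)
    if config.eval_rate_hz is not None:
        step = max(1, int(round(session.rate / config.eval_rate_hz)))
    else:
        step = 1
    Lm, Le = L[::step], L_hat[::step]
    reg = regression_line(Le, Lm)
    return FitResult(model=model, rmse_mm=rmse(Lm, Le), icc21=icc_2_1(Lm, Le),
                     regression_slope=reg["slope"],
                     regression_intercept_mm=reg["intercept"], n_frames=int(L.size))
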
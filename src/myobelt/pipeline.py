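"""End-to-end pipeline: preprocess → segment → cycle stats → cross-modal fit.

``run_pipeline`` chains every stage on one session and emits a JSON-ready
report.  Any stage failure is re-raised as :class:`PipelineStageError`
naming the stage, and every report embeds the resolved configuration so a
run can be reproduced from its output alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

from .calibration import BELT_CURVE, CalibrationCurve
from .crossmodal import (EvaluationConfig, evaluate_session, session_activities)
from .cycle_stats import MUSCLES, activity_cycle_stats, circumference_cycle_stats
from .errors import PipelineStageError, ValidationError
from .gait import build_cycle_set, detect_heel_contacts
from .preprocessing import process_circumference
from .simulate import SessionData
from .timeseries import TimeSeries

__all__ = ["PipelineConfig", "run_pipeline"]

SCHEMA_VERSION = 1
log = logging.getLogger("myobelt.pipeline")


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run."""

    calibration: CalibrationCurve = field(default_factory=lambda: BELT_CURVE)
    heel_threshold_N: float = 20.0
    min_swing_s: float = 0.05
    min_cycle_s: float = 0.3
    n_points: int = 101
    eval_rate_hz: float | None = 10.0
    reference_length_mm: float = 96.5562
    activity_source: str = "emg"
    circumference_source: str = "capacitance"
    zero_lag_lowpass: bool = False
    mvc: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.heel_threshold_N <= 0:
            raise ValidationError("heel threshold must be > 0 N")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["calibration"] = {"a2": self.calibration.a2, "a1": self.calibration.a1,
                            "a0": self.calibration.a0,
                            "c_lo": self.calibration.valid_range[0],
                            "c_hi": self.calibration.valid_range[1]}
        if self.mvc is not None:
            d["mvc"] = dict(self.mvc)
        return d

    def evaluation(self) -> EvaluationConfig:
        return EvaluationConfig(calibration=self.calibration,
                                activity_source=self.activity_source,
                                circumference_source=self.circumference_source,
                                mvc=self.mvc, eval_rate_hz=self.eval_rate_hz,
                                zero_lag_lowpass=self.zero_lag_lowpass)


def _stage(name: str):
    """Decorator-free stage wrapper: call fn, re-raise with stage context."""
    class _Ctx:
        def __init__(self, stage): self.stage = stage
        def __enter__(self): log.info("stage %s: start", self.stage); return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(self.stage, str(exc)) from exc
            log.info("stage %s: done", self.stage)
    return _Ctx(name)


def run_pipeline(session: SessionData, config: PipelineConfig | None = None) -> dict:
    """Run every stage on one session and return the JSON-ready report.

    Stages: circumference conversion, activity extraction, heel-contact
    detection, gait segmentation + ensemble statistics (when at least two
    contacts exist), cycle statistics, and the cross-modal fit/evaluation.
    """
    config = config or PipelineConfig()
    report: dict = {"schema_version": SCHEMA_VERSION, "config": config.as_dict()}

    eval_cfg = config.evaluation()
    with _stage("preprocess"):
        length_ts, _ = process_circumference(session.capacitance, config.calibration,
                                             zero_lag=config.zero_lag_lowpass)
        activities = session_activities(session, eval_cfg)  # T x 5 %MVC
        log.info("preprocess: %d frames at %g Hz", len(length_ts), session.rate)

    with _stage("segment"):
        events = detect_heel_contacts(session.vgrf, config.heel_threshold_N,
                                      config.min_swing_s, config.min_cycle_s)
        report["gait"] = {"n_contacts": len(events),
                          "contact_times_s": events.times().tolist()}
        log.info("segment: %d heel contacts (threshold %g N)", len(events),
                 config.heel_threshold_N)

    if len(events) >= 2:
        with _stage("stats"):
            circ_set = build_cycle_set(length_ts, events, config.n_points)
            circ_stats = circumference_cycle_stats(circ_set, config.reference_length_mm)
            act_sets = {}
            for i, m in enumerate(MUSCLES):
                ts = TimeSeries(activities[:, i], rate=session.rate, name=m, units="%MVC")
                act_sets[m] = build_cycle_set(ts, events, config.n_points)
            act_stats = activity_cycle_stats(act_sets)
            report["circumference_stats"] = circ_stats.as_dict()
            report["activity_stats"] = {
                "per_muscle": {m: s.as_dict() for m, s in act_stats["per_muscle"].items()},
                "averaged": act_stats["averaged"],
            }
    else:
        report["circumference_stats"] = None
        report["activity_stats"] = None
        log.info("stats: skipped (%d contacts, need >= 2)", len(events))

    with _stage("fit"):
        result = evaluate_session(session, eval_cfg)
        report["fit"] = result.as_dict()
        log.info("fit: RMSE %.4g mm, ICC(2,1) %s", result.rmse_mm,
                 "undefined" if result.icc21 is None else f"{result.icc21:.4f}")

    return report
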
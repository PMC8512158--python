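"""Session CSV and truth-sidecar I/O.

The on-disk session format is a plain CSV with a ``time_s`` column followed
by named channel columns with units encoded in the names::

    time_s, capacitance_nF, emg_VL_V, emg_RF_V, emg_VM_V, emg_BFL_V, emg_BFS_V, vgrf_N

Sampling must be uniform; the rate is inferred from the time column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .crossmodal import CrossModalModel
from .cycle_stats import MUSCLES
from .errors import ValidationError
from .simulate import SessionData, SessionTruth
from .timeseries import TimeSeries

__all__ = ["read_session_csv", "write_session_csv", "write_truth_json", "read_truth_json",
           "SESSION_COLUMNS"]

SESSION_COLUMNS = ["time_s", "capacitance_nF"] + [f"emg_{m}_V" for m in MUSCLES] + ["vgrf_N"]


def write_session_csv(session: SessionData, path) -> None:
    """Write all raw channels; ground truth goes in a separate JSON sidecar."""
    t = session.capacitance.times()
    data = {"time_s": t, "capacitance_nF": session.capacitance.values}
    for m in MUSCLES:
        data[f"emg_{m}_V"] = session.emg[m].values
    data["vgrf_N"] = session.vgrf.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_session_csv(path) -> SessionData:
    """Load a session CSV (channels only; no ground truth).

    Errors name missing required columns; a jittered time column (relative
    step deviation above 1e−6) is a non-uniform-sampling error.
    """
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    dt = steps.mean()
    if dt <= 0 or np.max(np.abs(steps - dt)) > 1e-6 * max(abs(dt), 1e-30):
        raise ValidationError(f"{path}: time column is not uniformly sampled")
    rate = 1.0 / dt
    start = float(t[0])

    def ts(col: str, name: str, units: str) -> TimeSeries:
        return TimeSeries(df[col].to_numpy(dtype=float), rate=rate,
                          start_time=start, name=name, units=units)

    return SessionData(
        capacitance=ts("capacitance_nF", "capacitance", "nF"),
        emg={m: ts(f"emg_{m}_V", f"emg_{m}", "V") for m in MUSCLES},
        vgrf=ts("vgrf_N", "vgrf", "N"),
        truth=None,
    )


def write_truth_json(truth: SessionTruth, path) -> None:
    """Sidecar with the generator's model, events and condition (not the full
    per-sample truth traces, which reproduce from the config and seed)."""
    Path(path).write_text(json.dumps({
        "condition": truth.condition,
        "model": truth.model.as_dict(),
        "contact_indices": truth.contact_indices.tolist(),
    }, indent=2) + "\n")


def read_truth_json(path) -> dict:
    d = json.loads(Path(path).read_text())
    d["model"] = CrossModalModel.from_dict(d["model"])
    d["contact_indices"] = np.asarray(d["contact_indices"], dtype=int)
    return d
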
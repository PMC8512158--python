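"""Quadratic capacitance-to-length calibration of the stretch-belt sensor.

The belt is a capacitive stretch sensor: a silicone dielectric between
flocked silver-fiber electrodes whose capacitance grows nonlinearly with the
elastic part's elongation.  A single bench sweep (stretch the sensor step by
step, read capacitance on an LCR meter) is summarised by a quadratic transfer
function

    L(C) = a2 * C**2 + a1 * C + a0

with L the elastic-part length in mm and C the capacitance in nF.  Only the
increasing branch of the parabola (above its vertex) is physical, so the
inverse used to synthesise or deconvolve capacitance always takes the larger
quadratic root.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateDesignError, ValidationError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "BELT_CURVE",
    "fit_calibration",
    "capacitance_to_length",
    "length_to_capacitance",
    "goodness_of_fit",
    "hysteresis_index",
    "sensor_characterization",
    "read_calibration_csv",
    "write_calibration_csv",
    "save_curve_json",
    "load_curve_json",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One bench measurement: capacitance (nF) at a held length (mm)."""

    capacitance_nF: float
    length_mm: float

    def __post_init__(self):
        if not (np.isfinite(self.capacitance_nF) and self.capacitance_nF > 0):
            raise ValidationError(f"capacitance must be finite and > 0, got {self.capacitance_nF}")
        if not (np.isfinite(self.length_mm) and self.length_mm > 0):
            raise ValidationError(f"length must be finite and > 0, got {self.length_mm}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic transfer function L = a2*C^2 + a1*C + a0.

    ``valid_range`` is the capacitance interval (nF) covered by the bench
    sweep; evaluation outside it warns (walking data may transiently exceed
    the sweep) but does not fail.  The curve must be strictly increasing on
    the valid range, i.e. the range must sit on the branch above the vertex.
    """

    a2: float  # mm / nF^2
    a1: float  # mm / nF
    a0: float  # mm
    valid_range: tuple[float, float] = (465.0, 606.0)

    def __post_init__(self):
        c_lo, c_hi = self.valid_range
        if not all(np.isfinite(v) for v in (self.a2, self.a1, self.a0, c_lo, c_hi)):
            raise ValidationError("calibration coefficients and range must be finite")
        if c_lo >= c_hi:
            raise ValidationError(f"invalid capacitance range [{c_lo}, {c_hi}]")
        # monotone increasing branch: derivative 2*a2*C + a1 > 0 on the range
        # (exactly 0 is tolerated at the lower edge — a fitted range may start
        # at the vertex itself)
        d_lo = 2.0 * self.a2 * c_lo + self.a1
        d_hi = 2.0 * self.a2 * c_hi + self.a1
        if d_hi <= 0 or d_lo < -1e-9 * max(1.0, abs(self.a1)):
            raise ValidationError(
                "curve is not strictly increasing over the valid range "
                f"(derivative spans [{min(d_lo, d_hi):.3g}, {max(d_lo, d_hi):.3g}])"
            )

    @property
    def vertex_capacitance(self) -> float:
        """Capacitance at the parabola's minimum (−a1 / 2·a2); −inf for a2 ≤ 0."""
        if self.a2 <= 0:
            return -np.inf
        return -self.a1 / (2.0 * self.a2)

    @property
    def minimum_length(self) -> float:
        """Length at the vertex — the smallest length the curve can produce."""
        if self.a2 <= 0:
            return -np.inf
        c = self.vertex_capacitance
        return self.a2 * c * c + self.a1 * c + self.a0


#: Transfer function of the prototype belt (bench sweep 465–606 nF, 95–200 mm).
BELT_CURVE = CalibrationCurve(a2=0.00223, a1=-1.72592, a0=416.9272, valid_range=(465.0, 606.0))


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationCurve:
    """Least-squares quadratic fit of length on capacitance.

    Requires at least three distinct capacitance abscissae.  The valid range
    is set to ``[max(vertex C, min observed C), max observed C]`` so the
    returned curve is monotone on its declared domain.
    """
    pts = list(points)
    C = np.array([p.capacitance_nF for p in pts], dtype=float)
    L = np.array([p.length_mm for p in pts], dtype=float)
    if np.unique(C).size < 3:
        raise DegenerateDesignError(
            f"need >= 3 distinct capacitances to fit a quadratic, got {np.unique(C).size}"
        )
    a2, a1, a0 = np.polyfit(C, L, deg=2)
    c_min, c_max = float(C.min()), float(C.max())
    if a2 > 0:
        c_lo = max(-a1 / (2.0 * a2), c_min)
    else:
        c_lo = c_min
    return CalibrationCurve(a2=float(a2), a1=float(a1), a0=float(a0),
                            valid_range=(float(c_lo), c_max))


def capacitance_to_length(curve: CalibrationCurve, capacitance_nF):
    """Evaluate the transfer function; scalar in → scalar out, array in → array out.

    Warns (once per call) when samples fall outside the curve's valid range.
    """
    C = np.asarray(capacitance_nF, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValidationError("capacitance contains non-finite values")
    c_lo, c_hi = curve.valid_range
    n_out = int(np.count_nonzero((C < c_lo) | (C > c_hi)))
    if n_out:
        warnings.warn(
            f"{n_out} capacitance sample(s) outside the calibration range "
            f"[{c_lo:g}, {c_hi:g}] nF; extrapolating",
            stacklevel=2,
        )
    L = curve.a2 * C * C + curve.a1 * C + curve.a0
    return float(L) if np.isscalar(capacitance_nF) else L


def length_to_capacitance(curve: CalibrationCurve, length_mm):
    """Invert the transfer function on the increasing branch (larger root).

    Raises when a length lies below the parabola's minimum (no real root).
    """
    L = np.asarray(length_mm, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValidationError("length contains non-finite values")
    if curve.a2 == 0:
        if curve.a1 <= 0:
            raise ValidationError("linear curve with non-positive slope is not invertible "
                                  "on an increasing branch")
        C = (L - curve.a0) / curve.a1
        return float(C) if np.isscalar(length_mm) else C
    disc = curve.a1 * curve.a1 - 4.0 * curve.a2 * (curve.a0 - L)
    bad = disc < 0
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValidationError(
            f"length {np.atleast_1d(L)[idx]:.6g} mm (sample {idx}) is below the curve minimum "
            f"{curve.minimum_length:.6g} mm; no real capacitance solves it"
        )
    C = (-curve.a1 + np.sqrt(disc)) / (2.0 * curve.a2)
    return float(C) if np.isscalar(length_mm) else C


def goodness_of_fit(points: Sequence[CalibrationPoint], curve: CalibrationCurve) -> float:
    """Agreement of the curve with bench points, as 100·R² (percent)."""
    pts = list(points)
    if len(pts) < 2:
        raise ValidationError("need >= 2 points to assess fit")
    C = np.array([p.capacitance_nF for p in pts], dtype=float)
    L = np.array([p.length_mm for p in pts], dtype=float)
    ss_tot = float(np.sum((L - L.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValidationError("length variance is zero; R^2 undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = capacitance_to_length(curve, C)
    ss_res = float(np.sum((L - pred) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def hysteresis_index(forward_sweep: Sequence[CalibrationPoint],
                     backward_sweep: Sequence[CalibrationPoint]) -> float:
    """Maximum |C_forward − C_backward| (nF) over the overlapping length range.

    Both sweeps are linearly interpolated, capacitance as a function of
    length, onto the union of their length abscissae restricted to the
    overlap.  A mechanically ideal sensor (the plots of the stretch and
    release sweeps coincide) scores 0.
    """
    fwd = sorted(forward_sweep, key=lambda p: p.length_mm)
    bwd = sorted(backward_sweep, key=lambda p: p.length_mm)
    if not fwd or not bwd:
        raise ValidationError("both sweeps must be non-empty")
    Lf = np.array([p.length_mm for p in fwd])
    Cf = np.array([p.capacitance_nF for p in fwd])
    Lb = np.array([p.length_mm for p in bwd])
    Cb = np.array([p.capacitance_nF for p in bwd])
    lo = max(Lf.min(), Lb.min())
    hi = min(Lf.max(), Lb.max())
    if lo > hi:
        raise ValidationError(
            f"sweeps do not overlap in length ({Lf.min():g}-{Lf.max():g} vs {Lb.min():g}-{Lb.max():g} mm)"
        )
    grid = np.union1d(Lf, Lb)
    grid = grid[(grid >= lo) & (grid <= hi)]
    cf = np.interp(grid, Lf, Cf)
    cb = np.interp(grid, Lb, Cb)
    return float(np.max(np.abs(cf - cb)))


def sensor_characterization(L0_mm: float, L1_mm: float, added_mass_mg: float,
                            flock_width_mm: float, flock_depth_mm: float) -> dict:
    """Bench characterization numbers: relative elongation and flocking density.

    Returns ``{"elongation_percent", "areal_density_mg_per_mm2"}`` where
    elongation = 100·(L1−L0)/L0 and the areal density is the flocked mass per
    electrode area.
    """
    if L0_mm <= 0:
        raise ValidationError(f"initial length must be > 0, got {L0_mm}")
    area = flock_width_mm * flock_depth_mm
    if area <= 0:
        raise ValidationError(f"flocking area must be > 0, got {area}")
    return {
        "elongation_percent": 100.0 * (L1_mm - L0_mm) / L0_mm,
        "areal_density_mg_per_mm2": added_mass_mg / area,
    }


# ---------------------------------------------------------------------------
# serialization

def write_calibration_csv(points: Iterable[CalibrationPoint], path) -> None:
    """Two-column CSV: capacitance_nF, length_mm."""
    lines = ["capacitance_nF,length_mm"]
    lines += [f"{p.capacitance_nF!r},{p.length_mm!r}" for p in points]
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration_csv(path) -> list[CalibrationPoint]:
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != "capacitance_nF,length_mm":
        raise ValidationError(f"{path}: expected header 'capacitance_nF,length_mm'")
    out = []
    for line in text[1:]:
        c, l = line.split(",")
        out.append(CalibrationPoint(float(c), float(l)))
    return out


def save_curve_json(curve: CalibrationCurve, path) -> None:
    Path(path).write_text(json.dumps({
        "a2": curve.a2, "a1": curve.a1, "a0": curve.a0,
        "c_lo": curve.valid_range[0], "c_hi": curve.valid_range[1],
    }, indent=2) + "\n")


def load_curve_json(path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(a2=d["a2"], a1=d["a1"], a0=d["a0"],
                            valid_range=(d["c_lo"], d["c_hi"]))
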
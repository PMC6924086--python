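"""Least-squares strain-gauge calibration: voltage (V) -> force (N).

The gauge response is modelled as the line y = a + b x and fitted by the
closed-form normal equations

    a = (Σx² Σy − Σx Σxy) / (n Σx² − (Σx)²)
    b = (n Σxy − Σx Σy) / (n Σx² − (Σx)²)

evaluated exactly as written.  A small audit utility reports the worst
relative force error of a fit against known truth, excluding forces near
zero where a relative error is not meaningful.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Union

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SingularDesignError

PointsLike = Union[pd.DataFrame, np.ndarray, "tuple", "list"]


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted voltage-to-force line with diagnostics.

    ``a`` is the intercept (N), ``b`` the slope (N/V), ``residual_sd`` the
    residual standard deviation (N, ddof = 2), ``r_squared`` the coefficient
    of determination.
    """

    a: float
    b: float
    n: int
    residual_sd: float
    r_squared: float

    def __post_init__(self):
        if self.n < 3:
            raise ParameterError("calibration needs at least 3 points")
        if self.residual_sd < 0:
            raise ParameterError("residual_sd must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationFit":
        return cls(**json.loads(text))


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        cols = {c.lower(): c for c in points.columns}
        xcol = cols.get("voltage") or cols.get("x")
        ycol = cols.get("force") or cols.get("y")
        if xcol is None or ycol is None:
            raise ParameterError("expected columns voltage/force (or x/y)")
        return points[xcol].to_numpy(float), points[ycol].to_numpy(float)
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) table of (voltage, force)")
    return arr[:, 0], arr[:, 1]


def fit_linear(points) -> CalibrationFit:
    """Fit force = a + b * voltage by the closed-form least-squares sums.

    Requires at least 3 points with non-constant voltage.
    """
    x, y = _as_xy(points)
    n = x.size
    if n < 3:
        raise DataError("need at least 3 calibration points")
    sx = float(np.sum(x))
    sy = float(np.sum(y))
    sxx = float(np.sum(x * x))
    sxy = float(np.sum(x * y))
    denom = n * sxx - sx * sx
    if denom <= 0 or not np.isfinite(denom) or denom < 1e-12 * max(n * sxx, 1.0):
        raise SingularDesignError("voltages are (numerically) all equal")
    a = (sxx * sy - sx * sxy) / denom
    b = (n * sxy - sx * sy) / denom
    resid = y - (a + b * x)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if tss == 0 else max(0.0, min(1.0, 1.0 - rss / tss))
    residual_sd = float(np.sqrt(rss / (n - 2))) if n > 2 else 0.0
    return CalibrationFit(a=a, b=b, n=int(n), residual_sd=residual_sd, r_squared=r_squared)


def apply_calibration(fit: CalibrationFit, voltage) -> np.ndarray | float:
    """Translate gauge voltage(s) to force in Newton: F = a + b * V."""
    v = np.asarray(voltage, dtype=float)
    out = fit.a + fit.b * v
    return float(out) if out.ndim == 0 else out


def calibration_error(fit: CalibrationFit, truth, floor_frac: float = 0.05) -> float:
    """Maximum relative force error (%) of a fit against known truth.

    ``truth`` is a table of (voltage, true force).  Points whose true force
    magnitude falls below ``floor_frac`` of the largest true force are
    excluded: a relative error diverges as the true force approaches zero.
    """
    v, f_true = _as_xy(truth)
    floor = floor_frac * float(np.max(np.abs(f_true)))
    keep = np.abs(f_true) >= max(floor, np.finfo(float).tiny)
    if not np.any(keep):
        raise DataError("all truth points fall below the relative-error force floor")
    pred = apply_calibration(fit, v[keep])
    rel = np.abs(pred - f_true[keep]) / np.abs(f_true[keep])
    return float(rel.max() * 100.0)
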
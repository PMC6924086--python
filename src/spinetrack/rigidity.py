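"""Instant rigidity of a spine specimen under six loading modes.

Instant rigidity is the ratio of the applied load to the resulting
deformation at a single load step:

* axial compression:  R_c = F / Δl                [N/mm]
* axial torsion:      R_t = F·r / φ  or  F·r / d  [Nm/rad] / [Nm/mm]
* flexion/extension/lateral bending:
                      R_f = F·l / α  or  F·l / d  [Nm/rad] / [Nm/mm]

where F is the gauge force (N), r and l the constant lever arms (m), φ/α
the rotation angle (rad) and d the camera-measured shift (mm) of the arm
end.  The angle forms and the shift forms are both provided; which one a
protocol uses is an explicit choice, and results carry their units so the
two are never mixed silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .calibration import CalibrationFit, apply_calibration
from .errors import DataError, ParameterError, UndefinedRigidityError

log = logging.getLogger(__name__)


class LoadingMode(str, Enum):
    FLEXION = "flexion"
    EXTENSION = "extension"
    LATERAL_LEFT = "lateral_left"
    LATERAL_RIGHT = "lateral_right"
    TORSION_LEFT = "torsion_left"
    TORSION_RIGHT = "torsion_right"
    COMPRESSION = "compression"


BENDING_MODES = {
    LoadingMode.FLEXION,
    LoadingMode.EXTENSION,
    LoadingMode.LATERAL_LEFT,
    LoadingMode.LATERAL_RIGHT,
}
TORSION_MODES = {LoadingMode.TORSION_LEFT, LoadingMode.TORSION_RIGHT}


@dataclass(frozen=True)
class LoadStep:
    """One loading increment: force plus the measured deformation.

    ``arm_m`` is the lever arm (r for torsion, l for bending) in metres and
    is required for every mode except compression.  ``displacement_mm`` is
    the linear shift d (or Δl for compression); ``angle_rad`` the rotation
    angle φ/α when an angle-based variant is used.
    """

    step_index: int
    force_N: float
    displacement_mm: Optional[float] = None
    angle_rad: Optional[float] = None
    arm_m: Optional[float] = None
    n_readings_averaged: int = 1

    def __post_init__(self):
        if self.displacement_mm is None and self.angle_rad is None:
            raise ParameterError("a load step needs a displacement or an angle")
        if self.arm_m is not None and self.arm_m <= 0:
            raise ParameterError("lever arm must be positive")
        if self.n_readings_averaged < 1:
            raise ParameterError("n_readings_averaged must be >= 1")


@dataclass(frozen=True)
class RigidityResult:
    """Instant-rigidity series for one loading mode with a repeat summary."""

    mode: LoadingMode
    values: tuple
    units: str  # "N/mm" | "Nm/rad" | "Nm/mm"
    mean: float
    sd: float
    n_repeats: int

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "units": self.units,
            "values": list(self.values),
            "mean": self.mean,
            "sd": self.sd,
            "n_repeats": self.n_repeats,
        }


def rigidity_compression(step: LoadStep) -> float:
    """R_c = F / Δl in N/mm."""
    if not step.displacement_mm:
        raise UndefinedRigidityError("compression rigidity needs a non-zero length change")
    return step.force_N / step.displacement_mm


def rigidity_torsion(step: LoadStep, variant: str = "shift") -> float:
    """R_t = F·r/φ (variant='angle', Nm/rad) or F·r/d (variant='shift', Nm/mm)."""
    if step.arm_m is None:
        raise ParameterError("torsion rigidity needs the lever arm r")
    moment = step.force_N * step.arm_m
    if variant == "angle":
        if not step.angle_rad:
            raise UndefinedRigidityError("angle variant needs a non-zero rotation angle")
        return moment / step.angle_rad
    if variant == "shift":
        if not step.displacement_mm:
            raise UndefinedRigidityError("shift variant needs a non-zero arm shift")
        return moment / step.displacement_mm
    raise ParameterError(f"unknown variant {variant!r}")


def rigidity_bending(step: LoadStep, variant: str = "shift") -> float:
    """R_f = F·l/α (variant='angle', Nm/rad) or F·l/d (variant='shift', Nm/mm)."""
    if step.arm_m is None:
        raise ParameterError("bending rigidity needs the lever arm l")
    moment = step.force_N * step.arm_m
    if variant == "angle":
        if not step.angle_rad:
            raise UndefinedRigidityError("angle variant needs a non-zero flexion angle")
        return moment / step.angle_rad
    if variant == "shift":
        if not step.displacement_mm:
            raise UndefinedRigidityError("shift variant needs a non-zero arm shift")
        return moment / step.displacement_mm
    raise ParameterError(f"unknown variant {variant!r}")


def rigidity_of(step: LoadStep, mode: LoadingMode, variant: str = "shift") -> float:
    """Dispatch to the right rigidity formula for a loading mode."""
    if mode == LoadingMode.COMPRESSION:
        return rigidity_compression(step)
    if mode in TORSION_MODES:
        return rigidity_torsion(step, variant)
    return rigidity_bending(step, variant)


def units_for(mode: LoadingMode, variant: str = "shift") -> str:
    if mode == LoadingMode.COMPRESSION:
        return "N/mm"
    return "Nm/rad" if variant == "angle" else "Nm/mm"


def aggregate_steps(
    readings_per_step: Sequence[Sequence[float]],
    displacements_mm: Optional[Sequence[Optional[float]]] = None,
    angles_rad: Optional[Sequence[Optional[float]]] = None,
    arm_m: Optional[float] = None,
    n_avg: int = 1,
    fit: Optional[CalibrationFit] = None,
) -> list[LoadStep]:
    """Average raw per-step gauge readings into LoadSteps.

    Each step's force is the arithmetic mean of its first ``n_avg`` readings
    (gauge voltages translated through ``fit`` when given, otherwise already
    in Newton).  Averaging several readings per step suppresses gauge noise
    by roughly 1/sqrt(n_avg).
    """
    if n_avg < 1:
        raise ParameterError("n_avg must be >= 1")
    n = len(readings_per_step)
    disp = list(displacements_mm) if displacements_mm is not None else [None] * n
    angs = list(angles_rad) if angles_rad is not None else [None] * n
    if len(disp) != n or len(angs) != n:
        raise DataError("displacement/angle lists must match the number of steps")
    steps = []
    for i, readings in enumerate(readings_per_step):
        readings = list(readings)
        if len(readings) < n_avg:
            raise DataError(f"step {i} has {len(readings)} readings, needs {n_avg}")
        vals = np.asarray(readings[:n_avg], dtype=float)
        if fit is not None:
            vals = np.asarray(apply_calibration(fit, vals), dtype=float)
        steps.append(
            LoadStep(
                step_index=i,
                force_N=float(vals.mean()),
                displacement_mm=disp[i],
                angle_rad=angs[i],
                arm_m=arm_m,
                n_readings_averaged=n_avg,
            )
        )
    return steps


@dataclass(frozen=True)
class ProtocolMeta:
    """Warm-up metadata recorded with a run (not computed on)."""

    warmup_hz: float = 0.1
    warmup_cycles: int = 0


def run_protocol(
    steps_by_mode: Mapping[LoadingMode, Sequence[Sequence[LoadStep]]],
    variant: str = "shift",
    meta: ProtocolMeta = ProtocolMeta(),
) -> list[RigidityResult]:
    """Per-mode instant-rigidity series with a mean +/- SD summary over repeats.

    ``steps_by_mode`` maps each mode to a list of repeats, each repeat being
    the ordered load steps of one measurement sweep.  The summary is the
    mean and sample SD of the per-repeat mean rigidity (SD 0 for a single
    repeat).  Modes absent from the input are absent from the output.
    """
    del meta  # recorded by the caller's report; the rigidity math never uses it
    results = []
    for mode in LoadingMode:
        if mode not in steps_by_mode:
            log.info("mode %s not measured; skipping", mode.value)
            continue
        repeats = steps_by_mode[mode]
        if len(repeats) < 1:
            raise DataError(f"mode {mode.value} has no repeats")
        all_vals: list[float] = []
        repeat_means = []
        for rep in repeats:
            vals = [rigidity_of(s, mode, variant) for s in rep]
            if not vals:
                raise DataError(f"empty repeat for mode {mode.value}")
            all_vals.extend(vals)
            repeat_means.append(float(np.mean(vals)))
        mean = float(np.mean(repeat_means))
        sd = float(np.std(repeat_means, ddof=1)) if len(repeat_means) > 1 else 0.0
        results.append(
            RigidityResult(
                mode=mode,
                values=tuple(all_vals),
                units=units_for(mode, variant),
                mean=mean,
                sd=sd,
                n_repeats=len(repeats),
            )
        )
    return results


def normalize_to_intact(intact: RigidityResult, treated: RigidityResult) -> float:
    """Treated-specimen rigidity as a percentage of the intact specimen (intact = 100%)."""
    if intact.mode != treated.mode:
        raise ParameterError(f"mode mismatch: {intact.mode.value} vs {treated.mode.value}")
    if intact.units != treated.units:
        raise ParameterError(f"unit mismatch: {intact.units} vs {treated.units}")
    if intact.mean == 0:
        raise ParameterError("intact mean rigidity is zero; normalization undefined")
    return 100.0 * treated.mean / intact.mean


def normalized_table(
    intact: Sequence[RigidityResult], treated: Sequence[RigidityResult]
) -> dict[str, float]:
    """Per-mode normalized percentages for the modes present in both runs."""
    by_mode_i = {r.mode: r for r in intact}
    by_mode_t = {r.mode: r for r in treated}
    out = {}
    for mode in LoadingMode:
        if mode in by_mode_i and mode in by_mode_t:
            out[mode.value] = normalize_to_intact(by_mode_i[mode], by_mode_t[mode])
    return out
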
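"""Run configuration and the end-to-end offline workflow.

A run is described by one JSON file (paths, pipeline parameters, specimen
geometry, protocol metadata, seed).  ``run_full`` executes every stage the
configuration provides inputs for — tracking, displacement, calibration,
rigidity, intact-vs-treated normalization — and writes a report directory
of CSV/JSON outputs, each stamped with the hash of the configuration that
produced it.  Stages are isolated: a failure is recorded and the remaining
stages still run; the first failure is re-raised at the end.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .calibration import CalibrationFit, fit_linear
from .errors import ConfigError, StageError
from .imaging import DetectConfig, assemble_tracks, detect_discs
from .io import dump_json, read_image, read_table, tracks_to_frame
from .rigidity import LoadingMode, LoadStep, normalized_table, run_protocol
from .speckle import SpeckleConfig, measure_displacement

log = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    frames_glob: Optional[str] = None
    before_image: Optional[str] = None
    after_image: Optional[str] = None
    calibration_csv: Optional[str] = None
    steps_intact_csv: Optional[str] = None
    steps_treated_csv: Optional[str] = None


class PipelineConfig(_Strict):
    t_min: Optional[float] = None
    t_max: Optional[float] = None
    auto_frac: float = Field(0.28, gt=0, lt=1)
    struct_radius: float = Field(1.0, ge=0, le=10)
    min_pixels: int = Field(20, ge=1)
    max_jump_px: float = Field(15.0, gt=0)
    fft_window: str = Field("hann", pattern="^(hann|none)$")
    mm_per_px: Optional[float] = Field(None, gt=0)


class GeometryConfig(_Strict):
    arm_flexion_m: Optional[float] = Field(None, gt=0)
    arm_torsion_m: Optional[float] = Field(None, gt=0)


class ProtocolConfig(_Strict):
    repeats: int = Field(10, ge=1)
    warmup_hz: float = Field(0.1, gt=0)
    n_avg: int = Field(1, ge=1)
    variant: str = Field("shift", pattern="^(shift|angle)$")


class RunConfig(_Strict):
    paths: PathsConfig = PathsConfig()
    pipeline: PipelineConfig = PipelineConfig()
    geometry: GeometryConfig = GeometryConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def detect_config(self) -> DetectConfig:
        return DetectConfig(
            t_min=self.pipeline.t_min,
            t_max=self.pipeline.t_max if self.pipeline.t_max is not None else math.inf,
            auto_frac=self.pipeline.auto_frac,
            struct_radius=self.pipeline.struct_radius,
            min_pixels=self.pipeline.min_pixels,
        )

    def speckle_config(self) -> SpeckleConfig:
        return SpeckleConfig(window=self.pipeline.fft_window, mm_per_px=self.pipeline.mm_per_px)


def load_config(path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Unknown keys are rejected with the offending field path; every path the
    configuration references must exist at load time.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}: invalid JSON ({e})") from e
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as e:
        locs = "; ".join(".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors())
        raise ConfigError(f"{path}: {locs}") from e
    base = path.parent
    for field_name, rel in cfg.paths.model_dump().items():
        if rel is None:
            continue
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        if field_name == "frames_glob":
            if not glob.glob(str(p)):
                raise ConfigError(f"paths.frames_glob matches no files: {rel}")
        elif not p.exists():
            raise ConfigError(f"paths.{field_name} does not exist: {rel}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2, sort_keys=True) + "\n")


def _resolve(base: Path, rel: Optional[str]) -> Optional[Path]:
    if rel is None:
        return None
    p = Path(rel)
    return p if p.is_absolute() else base / p


def load_steps_csv(path, geometry: GeometryConfig, fit: Optional[CalibrationFit] = None):
    """Read a step table (mode, step, repeat, force|voltage, displacement_mm[, angle_rad]).

    Voltages are translated through ``fit`` when no force column is present.
    Returns the {mode: [repeat -> [LoadStep, ...]]} mapping run_protocol expects.
    """
    df = read_table(path)
    cols = {c.lower(): c for c in df.columns}
    if "force" in cols:
        force = df[cols["force"]].astype(float)
    elif "voltage" in cols and fit is not None:
        force = fit.a + fit.b * df[cols["voltage"]].astype(float)
    else:
        raise StageError("rigidity", f"{path}: needs a force column (or voltage + calibration fit)")
    out: dict[LoadingMode, list[list[LoadStep]]] = {}
    for (mode_name, repeat), group in df.assign(_force=force).groupby(
        [df[cols["mode"]], df[cols["repeat"]]], sort=True
    ):
        mode = LoadingMode(str(mode_name))
        if mode == LoadingMode.COMPRESSION:
            arm = None
        elif mode in (LoadingMode.TORSION_LEFT, LoadingMode.TORSION_RIGHT):
            arm = geometry.arm_torsion_m
        else:
            arm = geometry.arm_flexion_m
        if mode != LoadingMode.COMPRESSION and arm is None:
            raise StageError("rigidity", f"mode {mode.value} needs a lever arm in geometry config")
        steps = []
        for _, row in group.sort_values(cols["step"]).iterrows():
            angle = float(row[cols["angle_rad"]]) if "angle_rad" in cols and pd.notna(row[cols["angle_rad"]]) else None
            disp = float(row[cols["displacement_mm"]]) if "displacement_mm" in cols and pd.notna(row[cols["displacement_mm"]]) else None
            steps.append(
                LoadStep(
                    step_index=int(row[cols["step"]]),
                    force_N=float(row["_force"]),
                    displacement_mm=disp,
                    angle_rad=angle,
                    arm_m=arm,
                )
            )
        out.setdefault(mode, []).append(steps)
    return out


def _write_csv_stamped(path: Path, df: pd.DataFrame, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_full(cfg: RunConfig, out_dir, base_dir: Optional[Path] = None) -> dict:
    """Execute every configured stage and write a report directory.

    Returns the report dictionary (also written to ``report.json``).  If any
    stage failed, the remaining stages still run, partial outputs are kept,
    and the first failure is re-raised as a stage-tagged error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path.cwd()
    h = cfg.config_hash()
    report: dict = {
        "config_hash": h,
        "seed": cfg.seed,
        "spinetrack_version": __version__,
        "warmup_hz": cfg.protocol.warmup_hz,
        "stages": {},
        "errors": [],
    }
    failures: list[StageError] = []

    def _fail(stage: str, exc: Exception) -> None:
        err = exc if isinstance(exc, StageError) else StageError(stage, str(exc))
        log.error("stage %s failed: %s", stage, exc)
        report["errors"].append({"stage": stage, "message": str(exc)})
        failures.append(err)

    # --- tracking -----------------------------------------------------
    if cfg.paths.frames_glob:
        try:
            pattern = _resolve(base, cfg.paths.frames_glob)
            files = sorted(glob.glob(str(pattern)))
            dets = [detect_discs(read_image(f), cfg.detect_config(), frame_id=i) for i, f in enumerate(files)]
            tracks = assemble_tracks(dets, max_jump_px=cfg.pipeline.max_jump_px)
            _write_csv_stamped(out / "tracks.csv", tracks_to_frame(tracks), h)
            report["stages"]["track"] = {"n_frames": len(files), "n_tracks": len(tracks)}
        except Exception as e:  # noqa: BLE001 - stage isolation is the contract
            _fail("track", e)

    # --- displacement -------------------------------------------------
    if cfg.paths.before_image and cfg.paths.after_image:
        try:
            f1 = read_image(_resolve(base, cfg.paths.before_image), mm_per_px=cfg.pipeline.mm_per_px)
            f2 = read_image(_resolve(base, cfg.paths.after_image), mm_per_px=cfg.pipeline.mm_per_px)
            d = measure_displacement(f1, f2, cfg.speckle_config())
            payload = {"config_hash": h, **d.to_dict()}
            dump_json(out / "displacement.json", payload)
            report["stages"]["displace"] = d.to_dict()
        except Exception as e:  # noqa: BLE001
            _fail("displace", e)

    # --- calibration --------------------------------------------------
    fit: Optional[CalibrationFit] = None
    if cfg.paths.calibration_csv:
        try:
            fit = fit_linear(read_table(_resolve(base, cfg.paths.calibration_csv)))
            payload = {"config_hash": h, "a": fit.a, "b": fit.b, "n": fit.n,
                       "r_squared": fit.r_squared, "residual_sd": fit.residual_sd}
            dump_json(out / "calibration.json", payload)
            report["stages"]["calibrate"] = {k: payload[k] for k in ("a", "b", "n", "r_squared", "residual_sd")}
        except Exception as e:  # noqa: BLE001
            _fail("calibrate", e)

    # --- rigidity + normalization ------------------------------------
    results = {}
    for label, path_attr in (("intact", "steps_intact_csv"), ("treated", "steps_treated_csv")):
        rel = getattr(cfg.paths, path_attr)
        if not rel:
            continue
        try:
            steps = load_steps_csv(_resolve(base, rel), cfg.geometry, fit=fit)
            res = run_protocol(steps, variant=cfg.protocol.variant)
            results[label] = res
            payload = {"config_hash": h, "results": [r.to_dict() for r in res]}
            dump_json(out / f"rigidity_{label}.json", payload)
            report["stages"][f"rigidity_{label}"] = {r.mode.value: r.mean for r in res}
        except Exception as e:  # noqa: BLE001
            _fail(f"rigidity_{label}", e)
    if "intact" in results and "treated" in results:
        try:
            table = normalized_table(results["intact"], results["treated"])
            df = pd.DataFrame({"mode": list(table), "percent_of_intact": list(table.values())})
            _write_csv_stamped(out / "normalized.csv", df, h)
            report["stages"]["normalize"] = table
        except Exception as e:  # noqa: BLE001
            _fail("normalize", e)

    dump_json(out / "report.json", report)
    if failures:
        raise failures[0]
    return report
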
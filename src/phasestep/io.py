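"""File formats and run configuration.

Stacks are exchanged as multi-page TIFF (or a directory of equally shaped
single-page TIFFs, ordered by filename), one page per phase step; 16-bit
unsigned and 32-bit float pixels are accepted and promoted to double.
Step vectors are two-column delimited text (index, position in µm).
Run configuration is YAML; two shipped presets mirror the two instrument
setups (Talbot-Lau and modulated-phase-grating).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .contrast import DEFAULT_VISIBILITY_FLOOR
from .correction import StageConfig
from .model import FringeStack, StepVector

__all__ = [
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "read_steps",
    "write_steps",
    "RunConfig",
    "SimulationConfig",
    "read_config",
    "preset_path",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_ALLOWED_DTYPES = ("uint8", "uint16", "float32", "float64")


def _load_page(path: Path) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise OSError(f"unreadable TIFF {path}: {exc}") from exc
    if str(arr.dtype) not in _ALLOWED_DTYPES:
        raise ValueError(f"{path}: unsupported pixel type {arr.dtype}")
    return np.asarray(arr, dtype=np.float64)


def read_stack(path: str | Path) -> FringeStack:
    """Read a phase-stepping stack from a multi-page TIFF or a TIFF directory.

    Frames are ordered by page index (multi-page file) or by sorted filename
    (directory); inconsistent frame shapes raise an error naming the file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no TIFF files in directory {path}")
        frames = []
        shape = None
        for f in files:
            frame = _load_page(f)
            if frame.ndim != 2:
                raise ValueError(f"{f}: expected a single 2-D page, got shape {frame.shape}")
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise ValueError(
                    f"{f}: frame shape {frame.shape} differs from first frame {shape}"
                )
            frames.append(frame)
        return FringeStack(np.stack(frames))
    arr = _load_page(path)
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a multi-page stack, got array of shape {arr.shape}"
        )
    return FringeStack(arr)


def write_stack(stack: FringeStack, path: str | Path) -> None:
    """Write a stack as a 32-bit float multi-page TIFF."""
    tifffile.imwrite(
        Path(path), stack.intensities.astype(np.float32), photometric="minisblack"
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a single 2-D image, promoted to double."""
    arr = _load_page(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def write_steps(steps: StepVector, path: str | Path) -> None:
    """Two-column delimited text: step index, position (µm)."""
    with open(path, "w") as fh:
        fh.write(f"# period_W_um={steps.period_W!r} nominal_step_um={steps.nominal_step!r}\n")
        for i, x in enumerate(steps.positions):
            fh.write(f"{i}\t{float(x)!r}\n")


def read_steps(path: str | Path, period_W: float | None = None) -> StepVector:
    """Read a step vector written by :func:`write_steps`.

    The period is taken from the file header unless overridden.
    """
    nominal = 0.0
    positions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, value = token.partition("=")
                    if key == "period_W_um" and period_W is None:
                        period_W = float(value)
                    elif key == "nominal_step_um":
                        nominal = float(value)
                continue
            _, pos = line.split()
            positions.append(float(pos))
    if period_W is None:
        raise ValueError(f"{path}: no period_W in header and none supplied")
    return StepVector(np.array(positions), period_W=period_W, nominal_step=nominal)


@dataclass(frozen=True)
class SimulationConfig:
    shape: tuple[int, int] = (128, 128)
    mean_counts: float = 1.0e4
    step_error: float = 0.0  # µm, half-width of the uniform error
    noise: str = "poisson"


@dataclass(frozen=True)
class RunConfig:
    """Validated full run configuration."""

    scene: str  # "tli" | "mpgi"
    period_W: float
    n_steps: int
    step_size: float
    stages: list[StageConfig]
    visibility_floor: float = DEFAULT_VISIBILITY_FLOOR
    simulate: SimulationConfig = field(default_factory=SimulationConfig)

    def nominal_steps(self) -> StepVector:
        return StepVector(
            self.step_size * np.arange(self.n_steps),
            period_W=self.period_W,
            nominal_step=self.step_size,
        )


_TOP_KEYS = {"scene", "period_W", "n_steps", "step_size", "stages",
             "visibility_floor", "optimizer", "simulate"}
_STAGE_KEYS = {"n_harmonics", "half_range", "delta"}
_OPT_KEYS = {"max_iterations", "function_tolerance", "step_tolerance"}
_SIM_KEYS = {"shape", "mean_counts", "step_error", "noise"}


def read_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = {"period_W", "n_steps", "step_size", "stages"} - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required keys {sorted(missing)}")

    opt = raw.get("optimizer", {}) or {}
    if set(opt) - _OPT_KEYS:
        raise ValueError(f"{path}: unknown optimizer keys {sorted(set(opt) - _OPT_KEYS)}")
    opt_kwargs = {
        "max_iterations": int(opt.get("max_iterations", 100)),
        "function_tolerance": float(opt.get("function_tolerance", 1e-9)),
        "step_tolerance": float(opt.get("step_tolerance", 1e-6)),
    }

    stages_raw = raw["stages"]
    if not isinstance(stages_raw, list) or not stages_raw:
        raise ValueError(f"{path}: 'stages' must be a non-empty list")
    stages = []
    for i, s in enumerate(stages_raw):
        if not isinstance(s, dict):
            raise ValueError(f"{path}: stage {i} must be a mapping")
        if set(s) - _STAGE_KEYS:
            raise ValueError(f"{path}: stage {i} unknown keys {sorted(set(s) - _STAGE_KEYS)}")
        if {"n_harmonics", "half_range"} - set(s):
            raise ValueError(f"{path}: stage {i} needs 'n_harmonics' and 'half_range'")
        stages.append(
            StageConfig(
                n_H=int(s["n_harmonics"]),
                half_range=float(s["half_range"]),
                delta=int(s.get("delta", 0)),
                **opt_kwargs,
            )
        )

    sim_raw = raw.get("simulate", {}) or {}
    if set(sim_raw) - _SIM_KEYS:
        raise ValueError(f"{path}: unknown simulate keys {sorted(set(sim_raw) - _SIM_KEYS)}")
    sim = SimulationConfig(
        shape=tuple(sim_raw.get("shape", (128, 128))),
        mean_counts=float(sim_raw.get("mean_counts", 1.0e4)),
        step_error=float(sim_raw.get("step_error", 0.0)),
        noise=str(sim_raw.get("noise", "poisson")),
    )

    return RunConfig(
        scene=str(raw.get("scene", "mpgi")),
        period_W=float(raw["period_W"]),
        n_steps=int(raw["n_steps"]),
        step_size=float(raw["step_size"]),
        stages=stages,
        visibility_floor=float(raw.get("visibility_floor", DEFAULT_VISIBILITY_FLOOR)),
        simulate=sim,
    )


def preset_path(name: str) -> Path:
    """Path of a shipped preset configuration ('tli' or 'mpgi')."""
    ref = resources.files("phasestep") / "presets" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return Path(p)
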
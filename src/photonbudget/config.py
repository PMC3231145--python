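"""System configuration files, validation, and curve export.

A system configuration is one YAML (or JSON) document describing an
:class:`~photonbudget.calibration.OpticalTrain` plus the concentration sweep
settings.  Units are fixed by the schema — cm, cm^2, nm, degrees, mol/L,
volts, A/W, V/A — and never inferred; unknown keys are rejected so silent
typos cannot change a photon budget.

Curve export is deterministic: fixed column order, floats at six significant
digits, and a header carrying the configuration hash and the tool version so
any table can be traced back to the exact system that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .calibration import CalibrationCurve, OpticalTrain
from .exceptions import ConfigurationError

__all__ = [
    "SweepSpec",
    "SystemConfig",
    "load_config",
    "save_config",
    "config_hash",
    "export_curve",
]


class SweepSpec(BaseModel):
    """Concentration grid for calibration sweeps (mol/L)."""

    model_config = ConfigDict(extra="forbid")

    c_min: float = Field(default=1e-12, gt=0.0)
    c_max: float = Field(default=1e-3, gt=0.0)
    #: Default grid: 1e-12 to 1e-3 mol/L at 10 points per decade.
    n_points: int = Field(default=91, ge=2)
    spacing: Literal["log", "linear"] = "log"

    @model_validator(mode="after")
    def _check_range(self) -> "SweepSpec":
        if self.c_min >= self.c_max:
            raise ValueError("c_min must be < c_max")
        return self


class SystemConfig(BaseModel):
    """A complete, validated system description: train plus sweep."""

    model_config = ConfigDict(extra="forbid")

    schema_version: Literal[1] = 1
    train: OpticalTrain
    sweep: SweepSpec = SweepSpec()


def _format_validation_error(err: ValidationError) -> list[str]:
    messages = []
    for issue in err.errors():
        loc = ".".join(str(p) for p in issue["loc"]) or "<root>"
        messages.append(f"{loc}: {issue['msg']}")
    return messages


def load_config(path: Union[str, Path]) -> SystemConfig:
    """Load and validate a YAML/JSON system configuration.

    All schema violations are aggregated into one
    :class:`ConfigurationError` so a broken file is reported completely in a
    single pass.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at the top level")
    try:
        return SystemConfig.model_validate(raw)
    except ValidationError as err:
        violations = _format_validation_error(err)
        raise ConfigurationError(
            f"{path}: {len(violations)} validation error(s):\n  "
            + "\n  ".join(violations),
            violations=violations,
        ) from err


def save_config(cfg: SystemConfig, path: Union[str, Path]) -> Path:
    """Write a configuration as YAML; round-trips through load_config."""
    path = Path(path)
    data = cfg.model_dump(mode="json", exclude_none=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


def config_hash(cfg: SystemConfig) -> str:
    """Stable SHA-256 hash of the canonical JSON form of a configuration."""
    canonical = json.dumps(
        cfg.model_dump(mode="json", exclude_none=True), sort_keys=True
    )
    return hashlib.sha256(canonical.encode()).hexdigest()


def export_curve(
    curve: CalibrationCurve,
    path: Union[str, Path],
    fmt: Literal["csv", "json"] = "csv",
    *,
    cfg_hash: str | None = None,
) -> Path:
    """Write a calibration curve table with a provenance header.

    CSV output has ``#``-prefixed header lines (tool version, train name,
    interrogated volume, optional config hash) followed by the table; floats
    are formatted at six significant digits so identical inputs produce
    identical bytes.
    """
    path = Path(path)
    frame = curve.to_frame()
    header = {
        "tool": f"photonbudget {__version__}",
        "train": curve.train_name,
        "interrogated_volume_L": f"{curve.interrogated_volume_L:.6g}",
    }
    if cfg_hash is not None:
        header["config_hash"] = cfg_hash
    if fmt == "csv":
        with open(path, "w") as fh:
            for key, value in header.items():
                fh.write(f"# {key}: {value}\n")
            frame.to_csv(fh, index=False, float_format="%.6g")
    elif fmt == "json":
        payload = {
            "metadata": header,
            "columns": list(frame.columns),
            "rows": [
                [float(f"{v:.6g}") for v in row]
                for row in frame.itertuples(index=False)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ConfigurationError(f"unknown export format {fmt!r}")
    return path
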
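"""Configuration loading, result writers and run manifests.

Numeric output is fixed at 10 significant digits so that reruns with an
identical configuration produce byte-identical result files, which keeps
regression diffs trivial.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .scenarios import scenario_from_dict

__all__ = ["ConfigError", "load_config", "write_results", "RunManifest",
           "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.10g"

# Physiological bounds enforced on sweep configs unless explicitly overridden.
_P_BOUNDS = (0.02, 0.15)
_N_BOUNDS = (10, 100)


class ConfigError(ValueError):
    """Configuration file violates the schema; message carries field paths."""


def _require_number(cfg: Mapping[str, Any], path: str, key: str,
                    lo: float | None = None, hi: float | None = None) -> float:
    if key not in cfg:
        raise ConfigError(f"{path}.{key}: missing required field")
    val = cfg[key]
    if not isinstance(val, (int, float)) or isinstance(val, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {val!r}")
    if lo is not None and val < lo:
        raise ConfigError(f"{path}.{key}: {val} below lower bound {lo}")
    if hi is not None and val > hi:
        raise ConfigError(f"{path}.{key}: {val} above upper bound {hi}")
    return float(val)


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    The file must contain a top-level ``kind`` of ``crosslink`` or ``ada``.
    Cross-linking configs accept either explicit grid levels (``sweep``
    block as in the packaged presets) or a scalar scenario (``scenario``
    block with ``ag_total_pM``, ``p``, ``n`` ...).  The aggregation
    fraction and valency are checked against the physiological windows
    (2--15%, 10--100) unless ``allow_out_of_range: true`` is set.
    Round-trips load -> dump -> load unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kind = data.get("kind")
    if kind not in ("crosslink", "ada"):
        raise ConfigError(f"kind: expected 'crosslink' or 'ada', got {kind!r}")
    allow = bool(data.get("allow_out_of_range", False))
    if kind == "crosslink" and "scenario" in data:
        scn = data["scenario"]
        _require_number(scn, "scenario", "ag_total_pM", lo=0.0)
        if allow:
            _require_number(scn, "scenario", "p", lo=0.0, hi=1.0)
            _require_number(scn, "scenario", "n", lo=1)
        else:
            _require_number(scn, "scenario", "p", *_P_BOUNDS)
            _require_number(scn, "scenario", "n", *_N_BOUNDS)
        _require_number(scn, "scenario", "Ka", lo=0.0)
    if kind == "ada":
        for i, scn in enumerate(data.get("scenarios", [])):
            try:
                scenario_from_dict(scn)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"scenarios[{i}]: {exc}") from exc
    return data


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run's outputs."""

    config_hash: str
    package_version: str = _pkg_version
    seed: int | None = None
    started_at: str = ""
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def for_config(cls, config: Mapping[str, Any] | str,
                   seed: int | None = None) -> "RunManifest":
        text = (config if isinstance(config, str)
                else json.dumps(config, sort_keys=True, default=str))
        digest = hashlib.sha256(text.encode()).hexdigest()
        return cls(config_hash=digest, seed=seed,
                   started_at=time.strftime("%Y-%m-%dT%H:%M:%S%z"))

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "manifest.json"
        payload = {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "seed": self.seed,
            "started_at": self.started_at,
            "outputs": sorted(self.outputs),
            "schema_version": 1,
        }
        out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return out


def write_results(
    obj: "pd.DataFrame | Mapping[str, Any]",
    path: str | Path,
    fmt: str | None = None,
    manifest: RunManifest | None = None,
) -> Path:
    """Write a result table (CSV) or summary mapping (JSON).

    CSV output has a fixed column order (the frame's own) and 10
    significant digits; JSON summaries are schema-versioned and
    key-sorted.  The written path is appended to ``manifest`` if given.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = fmt or ("csv" if isinstance(obj, pd.DataFrame) else "json")
    try:
        if fmt == "csv":
            if not isinstance(obj, pd.DataFrame):
                raise ConfigError("CSV output requires a DataFrame")
            obj.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        elif fmt == "json":
            payload = {"schema_version": 1, **dict(obj)}
            path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                       default=float) + "\n")
        else:
            raise ConfigError(f"unsupported output format '{fmt}'")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    if manifest is not None:
        manifest.outputs.append(str(path))
    return path
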
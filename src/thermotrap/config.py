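"""Run configuration and reproducible result writing.

Configurations are YAML/JSON documents validated strictly (unknown keys
are rejected, defaults are filled); results are written as plain CSV/JSON
with a manifest carrying content hashes and the resolved configuration, so
a run can be reproduced bit-identically from its own output directory.
All randomness in the package flows from a single integer seed expanded
via ``numpy.random.SeedSequence`` with per-subsystem constants — no global
random state is ever used.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config", "write_results"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    height_m: float = 0.05
    width_m: float = 0.06
    thickness_m: float = 1.7e-4
    n_fractions: int = 4
    bottom_probe_height_m: float = 1.5e-3


class ThermalConfig(_Strict):
    delta_T_K: float = 15.0
    T_mean_C: float = 32.5


class SolverConfig(_Strict):
    nx: int = 40
    ny: int = 200


class NetworkConfig(_Strict):
    n_rows: int = 20
    n_cols: int = 20
    Q_in_nl_s: float = 1.0
    n_systems: int = 30
    n_repeats: int = 3


class RunConfig(_Strict):
    """Validated configuration of one pipeline run."""

    stage: str
    inputs: dict[str, str] = Field(default_factory=dict)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    thermal: ThermalConfig = Field(default_factory=ThermalConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    seed: int = 0
    out_dir: str = "results"


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Raises a validation error naming any unknown or ill-typed key.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: dict,
    out_dir: str | Path,
    config: RunConfig | None = None,
    force: bool = False,
) -> dict:
    """Write result tables plus a manifest with content hashes.

    ``tables`` maps names to DataFrames (written as ``<name>.csv``) or
    JSON-serialisable objects (written as ``<name>.json``).  Existing
    files are only overwritten with ``force=True``.  The manifest (also
    written as ``manifest.json``) records each file's sha256 and, when
    given, the resolved configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            target = out / f"{name}.csv"
        else:
            target = out / f"{name}.json"
        if target.exists() and not force:
            raise FileExistsError(f"{target} exists (use force=True to overwrite)")
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(target, index=False)
        else:
            target.write_text(json.dumps(obj, indent=1, default=float))
        entries[target.name] = _sha256(target)
    manifest = {
        "files": entries,
        "resolved_config": None if config is None else config.model_dump(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
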
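"""Table I/O, run configuration, and reproducible pipeline execution.

All tables are plain CSV with header rows. Column names embed units
(``*_deg``, ``*_s``, ``*_nS``, ``*_hz``, ``*_um``) so files cannot silently
mix conventions. Every read validates against the dialect schema and the
target type's invariants, reporting the offending row and column.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DIALECTS",
    "RunConfig",
    "read_table",
    "write_table",
    "read_config",
    "spawn_seeds",
    "file_checksum",
    "write_manifest",
]

# dialect name -> (required columns, per-column validator)
DIALECTS: dict[str, dict] = {
    "tuning_curves": {
        "columns": ["cell_id", "cell_type", "contrast", "direction_deg",
                    "trial", "response"],
        "nonneg": ["response"],
    },
    "conductances": {
        "columns": ["time_s", "channel", "direction_deg", "conductance_nS"],
        "nonneg": ["conductance_nS"],
    },
    "rates": {
        "columns": ["time_s", "population", "rate_hz"],
        "nonneg": ["rate_hz"],
    },
    "eye_trace": {
        "columns": ["time_s", "theta_deg", "is_saccade"],
        "nonneg": [],
    },
    "positions": {
        "columns": ["cell_id", "mosaic_id", "x_um", "y_um"],
        "nonneg": [],
    },
}


class TableValidationError(ValueError):
    pass


def read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read and validate a CSV in one of the named dialects."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect}")
    spec = DIALECTS[dialect]
    df = pd.read_csv(path)
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing columns {missing} for dialect '{dialect}'")
    numeric = [c for c in spec["columns"]
               if c not in ("cell_type", "contrast", "channel", "population")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise TableValidationError(
                f"{path}: non-numeric value in column '{col}' at row "
                f"{int(bad[0])}")
        df[col] = coerced
    for col in spec["nonneg"]:
        bad = df.index[df[col] < 0]
        if len(bad):
            raise TableValidationError(
                f"{path}: negative value in column '{col}' at row "
                f"{int(bad[0])}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, dialect: str) -> Path:
    """Write a CSV after checking it conforms to the dialect."""
    path = Path(path)
    spec = DIALECTS[dialect]
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise TableValidationError(
            f"refusing to write {path}: missing columns {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """One reproducible pipeline invocation."""

    command: str
    seed: int = 0
    out_dir: str = "."
    params: dict = dc_field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {"command": self.command, "seed": self.seed,
                "out_dir": self.out_dir, "params": self.params,
                "log_level": self.log_level}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "command" not in d:
            raise ValueError("configuration missing required block 'command'")
        return cls(command=d["command"], seed=int(d.get("seed", 0)),
                   out_dir=d.get("out_dir", "."),
                   params=d.get("params", {}),
                   log_level=d.get("log_level", "INFO"))


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        return RunConfig.from_dict(yaml.safe_load(text))
    return RunConfig.from_dict(json.loads(text))


def spawn_seeds(run_seed: int, n: int) -> list[int]:
    """Derive per-stage seeds from the run seed (SeedSequence.spawn).

    Stage k of any command always receives the k-th derived seed, so two
    runs with the same run seed are bit-identical.
    """
    ss = np.random.SeedSequence(run_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31))
            for child in ss.spawn(n)]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig,
                   inputs: list | None = None,
                   outputs: list | None = None) -> Path:
    """Write a provenance manifest next to a command's outputs."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "inputs": {str(p): file_checksum(p) for p in (inputs or [])},
        "outputs": {str(p): file_checksum(p) for p in (outputs or [])},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
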
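"""File formats, run configuration and provenance.

The record exchange format is a plain CSV with header
``animal_id,breed,dim,milk_g,fat_pct,protein_pct`` (UTF-8, decimal
point).  Fit parameters travel as JSON; the run configuration is a flat
YAML file.  Every output table can be stamped with provenance columns
(config hash, totals mode, ICAR edge policy) so a report always says
which calculation conventions produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .protocols import HORIZON_DAYS
from .simulate import FAT_PCT_RANGE, PROTEIN_PCT_RANGE

__all__ = [
    "RunConfig",
    "TESTDAY_COLUMNS",
    "read_testday_csv",
    "write_testday_csv",
    "stamp_provenance",
    "write_run_log",
]

logger = logging.getLogger("woodlact")

TESTDAY_COLUMNS = ["animal_id", "breed", "dim", "milk_g", "fat_pct", "protein_pct"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    horizon_days: int = HORIZON_DAYS
    protocols: tuple = ("A", "B", "C")
    totals_mode: str = "integral"
    icar_edges: str = "include"
    fcm_fat_reference: float = 3.5
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if "A" not in self.protocols:
            raise ValueError("protocols must include the reference protocol A")
        if self.totals_mode not in ("integral", "daily_sum"):
            raise ValueError(f"unknown totals_mode {self.totals_mode!r}")
        if self.icar_edges not in ("include", "between_only"):
            raise ValueError(f"unknown icar_edges {self.icar_edges!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "protocols" in raw:
            raw["protocols"] = tuple(raw["protocols"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["protocols"] = list(d["protocols"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the scientific settings (the output path is excluded)."""
        d = asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_testday_csv(path) -> tuple[pd.DataFrame, list]:
    """Read and validate a test-day CSV.

    Returns (records, rejects).  Rows failing validation are dropped and
    listed as (1-based data row number, reason); a missing column is a
    schema error and raises.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "breed": str})
    missing = [c for c in TESTDAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = df[TESTDAY_COLUMNS]
    if df.empty:
        logger.warning("test-day file %s contains a header but no rows", path)
        return df, []

    rejects = []
    numeric = {}
    for col in ["dim", "milk_g", "fat_pct", "protein_pct"]:
        numeric[col] = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = pd.concat(numeric, axis=1).isna().any(axis=1)

    dim_ok = numeric["dim"] >= 1
    milk_ok = numeric["milk_g"] >= 0
    fat_ok = (numeric["fat_pct"] > FAT_PCT_RANGE[0]) & (
        numeric["fat_pct"] < FAT_PCT_RANGE[1]
    )
    prot_ok = (numeric["protein_pct"] > PROTEIN_PCT_RANGE[0]) & (
        numeric["protein_pct"] < PROTEIN_PCT_RANGE[1]
    )

    for i in df.index:
        if bad_numeric[i]:
            rejects.append((i + 1, "non-numeric value"))
        elif not dim_ok[i]:
            rejects.append((i + 1, "dim out of range"))
        elif not milk_ok[i]:
            rejects.append((i + 1, "negative milk yield"))
        elif not (fat_ok[i] and prot_ok[i]):
            rejects.append((i + 1, "composition out of range"))
    bad_rows = {r - 1 for r, _ in rejects}
    clean = df.drop(index=bad_rows).copy()
    for col, vals in numeric.items():
        clean[col] = vals.drop(index=bad_rows)
    clean["dim"] = clean["dim"].astype(int)
    for row, reason in rejects:
        logger.warning("rejected row %d: %s", row, reason)
    return clean.reset_index(drop=True), rejects


def write_testday_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=TESTDAY_COLUMNS, float_format="%.6f")


def stamp_provenance(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = config.config_hash()
    out["totals_mode"] = config.totals_mode
    out["icar_edges"] = config.icar_edges
    return out


def write_run_log(config: RunConfig, out_dir, extra: dict | None = None) -> Path:
    """Write the mandatory run log: config hash, seed, library versions."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "config": asdict(config) | {"protocols": list(config.protocols)},
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "woodlact": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        log.update(extra)
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return path
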
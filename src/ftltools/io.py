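"""Typed reading and writing of count tables, reports and run configs.

Count tables are TSVs with one row per biological replicate and a header
naming each fluorescence class; the reader validates the schema for the
requested modality and returns typed count objects.  Reports are written
as TSV (stable column order, full precision plus 2-dp display columns) or
JSON with a run manifest.  Marker and T-DNA coordinates are 1-based bp
throughout; BED-like track inputs are 0-based half-open and converted at
this boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import (CrossoverEstimate, SeedClassCounts, TetradCounts,
                         ThreeColourPollenCounts, TwoColourPollenCounts)


__all__ = [
    "MODALITY_COLUMNS",
    "RunConfig",
    "read_count_table",
    "write_report",
    "read_track",
    "load_config",
]

#: header schema per modality; three-colour columns use the gate labels.
MODALITY_COLUMNS = {
    "pollen2": ["R3", "R5", "red_alone", "none"],
    "seed": ["N_GR", "N_G", "N_R", "N_N"],
    "tetrad": ["PD", "NPD", "T"],
    "pollen3": ["N_BYR", "N_BY-", "N_B-R", "N_B--",
                "N_-YR", "N_-Y-", "N_--R", "N_---"],
}

_BUILDERS = {
    "pollen2": lambda v: TwoColourPollenCounts(*v),
    "seed": lambda v: SeedClassCounts(*v),
    "tetrad": lambda v: TetradCounts(*v),
    "pollen3": lambda v: ThreeColourPollenCounts(*v),
}


@dataclass
class RunConfig:
    """Validated CLI/run parameters; flags override file values."""

    seed: int = 0
    alpha: float = 0.05
    out_dir: str = "."
    verbosity: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; ``overrides`` (e.g. CLI flags) win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {k: raw.pop(k) for k in ("seed", "alpha", "out_dir", "verbosity")
             if k in raw}
    return RunConfig(params=raw, **known)


def read_count_table(path, modality: str) -> list:
    """Read a per-replicate count TSV into typed count objects.

    Validates the header against the modality schema (missing or extra
    columns are named) and that every count is a non-negative integer
    (errors cite the 1-based data row).
    """
    if modality not in MODALITY_COLUMNS:
        raise ValueError(f"unknown modality {modality!r}; "
                         f"have {sorted(MODALITY_COLUMNS)}")
    expected = MODALITY_COLUMNS[modality]
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)} "
                         f"for modality {modality!r}")
    extra = [c for c in df.columns if c not in expected and c != "id"]
    if extra:
        raise ValueError(f"{path}: unexpected column(s) {', '.join(extra)}")
    out = []
    for i, row in enumerate(df[expected].itertuples(index=False), start=1):
        values = []
        for col, v in zip(expected, row):
            fv = float(v)
            if not fv.is_integer() or fv < 0:
                raise ValueError(f"{path} row {i}: column {col} must be a "
                                 f"non-negative integer, got {v!r}")
            values.append(int(fv))
        out.append(_BUILDERS[modality](values))
    return out


def _estimates_frame(results) -> pd.DataFrame:
    rows = []
    for i, est in enumerate(results):
        if not isinstance(est, CrossoverEstimate):
            raise TypeError(f"expected CrossoverEstimate, got {type(est)}")
        cm2, se2 = est.rounded()
        rows.append({"id": i, "method": est.method, "cM": est.cm,
                     "se": est.se, "n": est.n, "cM_2dp": cm2, "se_2dp": se2})
    return pd.DataFrame(
        rows, columns=["id", "method", "cM", "se", "n", "cM_2dp", "se_2dp"])


def write_report(results, path, format: str = "tsv",
                 seed: int | None = None, config: dict | None = None) -> None:
    """Write estimates to TSV or JSON (with a run manifest).

    Output is byte-stable for identical input.  The JSON manifest records
    the package version, the seed and a hash of the configuration so runs
    can be traced.
    """
    frame = _estimates_frame(results)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        cfg = json.dumps(config or {}, sort_keys=True)
        manifest = {
            "version": __version__,
            "seed": seed,
            "config_hash": hashlib.sha256(cfg.encode()).hexdigest()[:16],
        }
        payload = {"manifest": manifest,
                   "estimates": frame.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_track(path) -> pd.DataFrame:
    """Read a BED-like per-window track (chrom, start, end, value).

    Input coordinates are 0-based half-open (the BED convention); the
    returned frame keeps them as-is plus a 1-based ``start_1`` column for
    consistency with marker coordinates.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted window(s)")
    df["start_1"] = df["start"] + 1
    return df
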
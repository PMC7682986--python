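"""Readers and writers for segment tables, images, ground truth and configs.

Units and conventions, enforced on read: coordinates in nm, angles in
degrees (psi wrapped to [-180, 180)), Euler convention ZYZ intrinsic with
psi first, image pixel indices 0-based with origin top-left.

Segment tables travel either as plain CSV or as a single-block
STAR-dialect text table (``data_segments`` / ``loop_`` with one ``_name
#i`` line per column) — the flat-table subset of the STAR format used for
particle metadata in sub-tomogram averaging.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from polarimap.angles import wrap_angle
from polarimap.errors import SchemaError

__all__ = [
    "SEGMENT_COLUMNS",
    "read_segments",
    "write_segments",
    "read_star",
    "write_star",
    "read_stack",
    "write_stack",
    "PipelineConfig",
    "load_config",
    "save_config",
]

SEGMENT_COLUMNS = ["tomogram_id", "filament_id", "segment_id",
                   "x_nm", "y_nm", "z_nm", "rot_deg", "tilt_deg", "psi_deg"]

_INT_COLUMNS = ["tomogram_id", "filament_id", "segment_id"]


# ---------------------------------------------------------------------------
# STAR-dialect tables


def write_star(df: pd.DataFrame, path, block: str = "segments") -> None:
    """Write a DataFrame as a one-block STAR loop table."""
    path = Path(path)
    lines = [f"data_{block}", "", "loop_"]
    lines += [f"_{c} #{i + 1}" for i, c in enumerate(df.columns)]
    for row in df.itertuples(index=False):
        lines.append(" ".join(_star_value(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _star_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".6f")
    return str(v)


def read_star(path) -> pd.DataFrame:
    """Read a one-block STAR loop table into a DataFrame."""
    names: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            continue
        if line.startswith("_"):
            if not in_loop:
                raise SchemaError(f"column definition outside loop_ in {path}")
            names.append(line.split()[0].lstrip("_"))
            continue
        if in_loop:
            rows.append(line.split())
    if not names:
        raise SchemaError(f"no loop_ column definitions found in {path}")
    df = pd.DataFrame(rows, columns=names)
    for c in df.columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            pass  # non-numeric column stays as strings
    return df


# ---------------------------------------------------------------------------
# segment tables


def _validate_segments(df: pd.DataFrame, source) -> pd.DataFrame:
    for col in SEGMENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"segment table {source} is missing column {col!r}")
    out = df.copy()
    for col in _INT_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in SEGMENT_COLUMNS[3:]:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad = [c for c in SEGMENT_COLUMNS if out[c].isna().any()]
    if bad:
        raise SchemaError(f"segment table {source} has non-numeric or missing "
                          f"values in columns {bad}")
    for col in _INT_COLUMNS:
        out[col] = out[col].astype(int)
    out["psi_deg"] = wrap_angle(out["psi_deg"].to_numpy())
    return out


def read_segments(path, dialect: str | None = None) -> pd.DataFrame:
    """Read and validate a segment pose table (CSV or STAR dialect).

    ``dialect`` is 'csv' or 'star'; inferred from the file extension when
    omitted. Angles are wrapped on read; a missing or malformed required
    column raises :class:`SchemaError` naming the column.
    """
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix.lower() == ".star" else "csv"
    if dialect == "star":
        df = read_star(path)
    elif dialect == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _validate_segments(df, path)


def write_segments(df: pd.DataFrame, path, dialect: str | None = None) -> None:
    """Write a segment pose table as CSV or STAR dialect (by extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "star" if path.suffix.lower() == ".star" else "csv"
    cols = SEGMENT_COLUMNS + [c for c in df.columns if c not in SEGMENT_COLUMNS]
    out = df[[c for c in cols if c in df.columns]]
    if dialect == "star":
        write_star(out, path)
    elif dialect == "csv":
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# images


def write_stack(image: np.ndarray, path) -> None:
    """Write a 2D image or (T, H, W) stack as (multi-page) TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(image))


def read_stack(path) -> np.ndarray:
    """Read a TIFF image/stack; pixel indices are 0-based, origin top-left."""
    import tifffile

    return tifffile.imread(Path(path))


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All stage parameters of the polarity pipeline, with the field defaults.

    Defaults follow the analysis parameters of the bundle study: 16.5 nm
    segment spacing, 40 nm neighborhood radius, up to 3 neighboring
    filaments, 2/3 confidence cutoff (inclusive), 2.76 nm helical rise and
    95% confidence intervals. Seeds are mandatory for stochastic stages.
    """

    input_segments: str | None = None
    output_dir: str = "polarimap_out"
    segment_spacing_nm: float = 16.5
    neighborhood_radius_nm: float = 40.0
    neighborhood_k: int = 3
    neighbor_mode: str = "per-filament"
    confidence_threshold: float = 2.0 / 3.0
    rise_per_subunit_nm: float = 2.76
    ci_level: float = 0.95
    kde_bandwidth_deg: float = 10.0
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys raise, defaults fill gaps."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_summary(summary: dict, path) -> None:
    """Write a pipeline summary as deterministic, human-readable JSON."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True,
                                     default=float) + "\n")
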
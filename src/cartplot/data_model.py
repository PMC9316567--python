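"""Domain types, per-cell table I/O, and run configuration.

The canonical in-memory container for per-cell measurements is a
:class:`pandas.DataFrame` with one row per cell and the fixed column set
:data:`CELL_COLUMNS`.  Every other module consumes and produces these
frames; the small value types that parameterize an analysis run
(:class:`BackgroundEstimate`, :class:`ControlBounds`, ...) are frozen
dataclasses.

Column schema
-------------
``cell_id``        opaque identifier (string)
``experiment_id``  opaque identifier (string); tables mixing experiments
                   are partitioned on this column before analysis
``role``           one of ``control_green``, ``control_red``, ``cocultured``
``green_raw``      integrated green-channel fluorescence over the cell mask
``red_raw``        integrated red-channel fluorescence
``area``           cell-profile area (px^2 or um^2, consistent per experiment)
``perimeter``      cell peripheral circumference (same length unit)
``f5mc``           optional integrated nuclear anti-5mc fluorescence
``fpi``            optional integrated nuclear propidium-iodide fluorescence
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("cartplot")

__all__ = [
    "Role",
    "Group",
    "EU_DOMAINS",
    "CELL_COLUMNS",
    "CLASSIFIED_COLUMNS",
    "BackgroundEstimate",
    "ControlBounds",
    "AnalysisConfig",
    "CellTableError",
    "ConfigError",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "load_config",
    "subsample",
    "round_half_up",
]


class Role(str, enum.Enum):
    """Culture role of a cell: isolated control of either label, or co-cultured."""

    CONTROL_GREEN = "control_green"
    CONTROL_RED = "control_red"
    COCULTURED = "cocultured"


class Group(str, enum.Enum):
    """The five Cartesian-plot populations plus an explicit unclassified bucket.

    ``INDIST_RED`` / ``INDIST_GREEN`` are cells whose fluorescence is
    indistinguishable from the red (fibroblast) or green (cancer) control
    population; ``RED_SOME_GREEN`` / ``GREEN_SOME_RED`` belong to one
    population but carry some opposite-channel label; ``UNCERTAIN`` overlaps
    both control ranges; ``UNCLASSIFIED`` falls below both lower bounds.
    """

    INDIST_RED = "indist_red"
    RED_SOME_GREEN = "red_some_green"
    UNCERTAIN = "uncertain"
    GREEN_SOME_RED = "green_some_red"
    INDIST_GREEN = "indist_green"
    UNCLASSIFIED = "unclassified"


#: The seven Exchange-Unit domains, in ascending order.  The outer two are
#: singletons occupied exactly by the indistinguishable groups.
EU_DOMAINS = (
    "EU=-50",
    "-50<EU<=-30",
    "-30<EU<=-10",
    "-10<EU<=10",
    "10<EU<=30",
    "30<EU<50",
    "EU=50",
)

CELL_COLUMNS = [
    "cell_id",
    "experiment_id",
    "role",
    "green_raw",
    "red_raw",
    "area",
    "perimeter",
    "f5mc",
    "fpi",
]

CLASSIFIED_COLUMNS = CELL_COLUMNS + [
    "green_norm",
    "red_norm",
    "circularity",
    "group",
    "eu",
    "eu_domain",
    "cnf",
    "cnf_norm",
]

_NUMERIC_COLUMNS = ["green_raw", "red_raw", "area", "perimeter", "f5mc", "fpi"]

#: Slack on the isoperimetric check ``perimeter**2 >= 4*pi*area`` to admit
#: digitized perimeters of small regions (circularity up to ~1.2).
CIRCULARITY_EPS = 0.2


class CellTableError(ValueError):
    """Raised when a per-cell table violates the schema or a row invariant."""


class ConfigError(ValueError):
    """Raised for malformed or invalid configuration files."""


@dataclass(frozen=True)
class BackgroundEstimate:
    """Per-channel background fluorescence per unit area.

    Derived from control cells: the red background rate comes from
    green-labelled controls (whose red signal is pure background plus
    bleed-through) and vice versa.
    """

    green_bg_rate: float
    red_bg_rate: float

    def __post_init__(self) -> None:
        if self.green_bg_rate < 0 or self.red_bg_rate < 0:
            raise ValueError("background rates must be non-negative")


@dataclass(frozen=True)
class ControlBounds:
    """Classification bounds derived from the normalized control populations.

    ``green_lo`` is the (trimmed) minimum green NFU among green controls;
    ``red_bleed_hi`` the (trimmed) maximum red NFU among green controls;
    ``red_lo`` / ``green_bleed_hi`` are the symmetric bounds from red
    controls.  Own-channel ranges are unbounded above: transfer only adds
    opposite-channel signal, so a cell brighter than any control in its own
    channel is still within its population.
    """

    green_lo: float
    red_bleed_hi: float
    red_lo: float
    green_bleed_hi: float
    trim: float = 0.0

    def __post_init__(self) -> None:
        if self.green_bleed_hi >= self.green_lo or self.red_bleed_hi >= self.red_lo:
            raise ValueError(
                "overlapping control populations: bleed-through bounds "
                f"(green<={self.green_bleed_hi:.4g}, red<={self.red_bleed_hi:.4g}) must lie "
                f"strictly below the own-channel lower bounds "
                f"(green>={self.green_lo:.4g}, red>={self.red_lo:.4g}); "
                "classification aborted"
            )


@dataclass
class AnalysisConfig:
    """Run configuration with the defaults used throughout.

    ``max_controls`` / ``max_cocultured`` are the sampling caps applied by
    seeded uniform subsampling when an input table is larger (100 control
    cells and up to 1000 co-cultured cells are analyzed by default).
    """

    flip_eu: bool = False          # mirror EU sign / groups (opposite label orientation)
    trim: float = 0.0              # fraction trimmed per tail when deriving bounds
    background_mode: str = "cross" # 'cross' (from opposite-label controls) or 'none'
    max_controls: int = 100
    max_cocultured: int = 1000
    seed: int = 0
    mad_k: float | None = None     # cnf outlier exclusion: None = off
    green_channel: int = 0         # TIFF channel indices for segmentation
    red_channel: int = 1
    pi_channel: int | None = None
    mc5_channel: int | None = None
    min_size: int = 50             # minimum segmented-object size in pixels
    split_touching: bool = False
    out_dir: str = "cartplot_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim < 0.5:
            raise ConfigError(f"trim must be in [0, 0.5), got {self.trim}")
        if self.background_mode not in ("cross", "none"):
            raise ConfigError(
                f"background_mode must be 'cross' or 'none', got {self.background_mode!r}"
            )
        if self.max_controls < 1 or self.max_cocultured < 1:
            raise ConfigError("sampling caps must be positive")
        if self.mad_k is not None and self.mad_k <= 0:
            raise ConfigError("mad_k must be positive when set")


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    Absent keys take their defaults; unknown keys emit a warning.  ``None``
    or a missing/empty file yields all defaults.
    """
    if path is None:
        return AnalysisConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return AnalysisConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    for key in sorted(unknown):
        log.warning("config: ignoring unknown key %r", key)
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return AnalysisConfig(**kwargs)
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc


def validate_cell_table(df: pd.DataFrame, *, source: str = "<table>") -> pd.DataFrame:
    """Validate a per-cell table against the schema and row invariants.

    Returns the frame with canonical column order and dtypes.  Any violation
    raises :class:`CellTableError` naming the offending rows (0-based data
    row indices).
    """
    missing = [c for c in CELL_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise CellTableError(f"{source}: missing required column(s) {missing}")
    df = df.copy()
    for col in ("f5mc", "fpi"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CELL_COLUMNS]
    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rows = list(df.index[bad][:5])
            raise CellTableError(f"{source}: non-numeric {col!r} in row(s) {rows}")
        df[col] = coerced.astype(float)

    problems: list[str] = []

    def _check(mask: pd.Series, msg: str) -> None:
        if mask.any():
            problems.append(f"{msg} in row(s) {list(df.index[mask][:5])}")

    _check(~(df["area"] > 0), "non-positive area")
    _check(~(df["perimeter"] > 0), "non-positive perimeter")
    _check(df["green_raw"] < 0, "negative green_raw")
    _check(df["red_raw"] < 0, "negative red_raw")
    _check(df["f5mc"].notna() & (df["fpi"].isna() | ~(df["fpi"] > 0)),
           "f5mc present without positive fpi")
    # isoperimetric sanity: circularity must not exceed 1 beyond digitization slack
    circ = 4.0 * math.pi * df["area"] / df["perimeter"] ** 2
    _check((df["area"] > 0) & (df["perimeter"] > 0) & (circ > 1.0 + CIRCULARITY_EPS),
           "perimeter too short for area (circularity > 1)")
    valid_roles = {r.value for r in Role}
    _check(~df["role"].isin(valid_roles), f"role not in {sorted(valid_roles)}")
    if problems:
        raise CellTableError(f"{source}: " + "; ".join(problems))
    df["cell_id"] = df["cell_id"].astype(str)
    df["experiment_id"] = df["experiment_id"].astype(str)
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell CSV table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.index = pd.RangeIndex(len(df))
    return validate_cell_table(df, source=str(path))


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell (or classified) table as CSV with the canonical columns."""
    cols = [c for c in CLASSIFIED_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def subsample(df: pd.DataFrame, cap: int, rng: np.random.Generator) -> pd.DataFrame:
    """Uniformly subsample a table down to ``cap`` rows (seeded); identity if smaller."""
    if len(df) <= cap:
        return df
    idx = rng.choice(len(df), size=cap, replace=False)
    return df.iloc[np.sort(idx)].reset_index(drop=True)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (88.46 -> 88.5), as in printed percentage tables."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def split_by_experiment(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a table by ``experiment_id`` (analysis never mixes experiments)."""
    return {str(k): g.reset_index(drop=True) for k, g in df.groupby("experiment_id", sort=True)}
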
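"""Readers and writers for the package's CSV dialects and config files.

Survival series CSV: columns ``time_min`` (numeric) and ``cfu``
(integer), one series per file.  The control population N0 comes either
from the t=0 row (consumed as N0 when no explicit value is given) or
from the config key ``n0``.

Contingency CSV: header row of column labels, first column row labels,
integer cells.

Treatment grid CSV (long format): columns ``treatment``, ``time_min``,
``replicate``, ``cfu``.

Config files are YAML key-value mappings with the keys
``wavelength_nm``, ``intensity_wm2``, ``bandwidth_nm``, ``od600`` or
``transmittance``, ``fit_mode``, ``n0``, ``seed``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .kinetics import IrradianceConfig, SurvivalSeries
from .stats import ContingencyTable, TreatmentGrid

__all__ = [
    "read_survival_csv",
    "write_survival_csv",
    "read_contingency_csv",
    "read_grid_csv",
    "read_config",
    "irradiance_from_config",
]


def read_survival_csv(
    path,
    n0: float | None = None,
    count_ceiling: float | None = None,
) -> SurvivalSeries:
    """Parse a survival series CSV into a validated :class:`SurvivalSeries`.

    When ``n0`` is None the file must contain a t=0 row, whose count is
    consumed as the control population (the returned series then starts
    at the first irradiated time point).  Errors name the offending
    1-based data row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV surface
        raise ParseError(f"{path}: cannot read CSV: {exc}") from exc
    missing = {"time_min", "cfu"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    times, counts = [], []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        t = getattr(row, "time_min")
        c = getattr(row, "cfu")
        try:
            t = float(t)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: row {idx}: non-numeric time_min {t!r}")
        try:
            cf = float(c)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: row {idx}: non-numeric cfu {c!r}")
        if not cf.is_integer():
            raise ParseError(f"{path}: row {idx}: cfu must be an integer, got {c!r}")
        if cf < 0:
            raise ParseError(f"{path}: row {idx}: negative cfu {c!r}")
        times.append(t)
        counts.append(int(cf))
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise ParseError(
                f"{path}: row {i + 1}: times must be strictly increasing"
            )
    if n0 is None:
        if not times or times[0] != 0:
            raise ParseError(
                f"{path}: no n0 configured and no t=0 row to take it from"
            )
        n0 = float(counts[0])
        times, counts = times[1:], counts[1:]
    try:
        return SurvivalSeries(times, counts, n0=n0, count_ceiling=count_ceiling)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_survival_csv(series: SurvivalSeries, path) -> None:
    """Write a series (with its n0 as the t=0 row when absent)."""
    times = list(series.times)
    counts = [int(round(c)) for c in series.counts]
    if not times or times[0] != 0:
        times = [0.0] + times
        counts = [int(round(series.n0))] + counts
    pd.DataFrame({"time_min": times, "cfu": counts}).to_csv(path, index=False)


def read_contingency_csv(path) -> ContingencyTable:
    """Parse a labelled contingency table CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}") from exc
    try:
        return ContingencyTable(
            df.to_numpy(), row_labels=df.index, col_labels=df.columns
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_contingency_csv(table: ContingencyTable, path) -> None:
    pd.DataFrame(
        table.counts, index=list(table.row_labels), columns=list(table.col_labels)
    ).to_csv(path)


def read_grid_csv(path) -> TreatmentGrid:
    """Parse a long-format treatment grid CSV into a balanced grid."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read CSV: {exc}") from exc
    try:
        return TreatmentGrid.from_long(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_grid_csv(grid: TreatmentGrid, path) -> None:
    grid.to_long().to_csv(path, index=False)


def read_config(path) -> dict:
    """Load a YAML key-value config file into a plain dict."""
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a key-value mapping")
    return cfg


def irradiance_from_config(cfg: dict) -> IrradianceConfig:
    """Build an :class:`IrradianceConfig` from config keys.

    Recognised keys: ``wavelength_nm``, ``intensity_wm2``,
    ``bandwidth_nm``, ``od600``, ``transmittance``.  Missing keys fall
    back to the dataclass defaults; inconsistent od600/transmittance
    pairs raise a validation error.
    """
    kwargs = {}
    if "wavelength_nm" in cfg:
        kwargs["wavelength_nm"] = float(cfg["wavelength_nm"])
    if "intensity_wm2" in cfg:
        kwargs["intensity_h0"] = float(cfg["intensity_wm2"])
    if "bandwidth_nm" in cfg:
        kwargs["bandwidth_b"] = float(cfg["bandwidth_nm"])
    if cfg.get("od600") is not None:
        kwargs["od600"] = float(cfg["od600"])
    if cfg.get("transmittance") is not None:
        kwargs["transmittance_t"] = float(cfg["transmittance"])
    return IrradianceConfig(**kwargs)
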
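"""Areal space-time panels: the (areas x periods) count/population/covariate
container, long-format CSV input, and result-table export.

The canonical input is long format — one row per (area, period) — with a
schema naming which columns hold the area id, the period, the event count,
the population at risk and each covariate.  Static covariates (a single
value per area, e.g. provider densities measured once) are broadcast over
all periods.  The study panels this models are complete, so a missing
(area, period) cell is a hard error, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ArealPanel", "PanelSchema", "read_panel", "write_summaries"]


@dataclass(frozen=True)
class PanelSchema:
    """Column-role mapping for a long-format panel CSV."""

    area: str = "area"
    period: str = "period"
    count: str = "count"
    population: str = "population"
    covariates: tuple = ()      # covariate column names
    units: Mapping = field(default_factory=dict)   # covariate -> unit string

    @classmethod
    def from_mapping(cls, m: Mapping) -> "PanelSchema":
        m = dict(m)
        covs = m.get("covariates", ())
        if isinstance(covs, Mapping):
            units = dict(covs)
            covs = tuple(covs)
        else:
            covs = tuple(covs)
            units = dict(m.get("units", {}))
        return cls(area=m.get("area", "area"), period=m.get("period", "period"),
                   count=m.get("count", "count"),
                   population=m.get("population", "population"),
                   covariates=covs, units=units)


@dataclass(frozen=True)
class ArealPanel:
    """A complete space-time panel of event counts over areas and periods.

    ``counts`` and ``population`` are (n_areas, n_periods) arrays; every
    covariate is stored at the same shape (static covariates repeat their
    per-area value across periods).  Periods are calendar integers,
    strictly increasing and contiguous.
    """

    area_ids: tuple
    periods: tuple
    counts: np.ndarray
    population: np.ndarray
    covariates: Mapping = field(default_factory=dict)
    units: Mapping = field(default_factory=dict)

    def __post_init__(self):
        n, T = len(self.area_ids), len(self.periods)
        counts = np.asarray(self.counts)
        pop = np.asarray(self.population, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "population", pop)
        if len(set(self.area_ids)) != n:
            raise ValueError("area ids must be unique")
        pds = list(self.periods)
        if pds != sorted(set(pds)) or (len(pds) > 1 and np.any(np.diff(pds) != 1)):
            raise ValueError("periods must be strictly increasing and contiguous")
        if counts.shape != (n, T) or pop.shape != (n, T):
            raise ValueError(f"counts/population must have shape ({n}, {T})")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if np.any(pop <= 0):
            raise ValueError("population must be strictly positive")
        covs = {}
        for name, x in dict(self.covariates).items():
            x = np.asarray(x, dtype=float)
            if x.ndim == 1:                      # static: broadcast over periods
                if x.shape != (n,):
                    raise ValueError(f"covariate {name!r} has length {x.shape}, expected {n}")
                x = np.repeat(x[:, None], T, axis=1)
            if x.shape != (n, T):
                raise ValueError(f"covariate {name!r} has shape {x.shape}, expected ({n}, {T})")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"covariate {name!r} contains non-finite values")
            covs[name] = x
        object.__setattr__(self, "covariates", covs)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def covariate_names(self) -> tuple:
        return tuple(self.covariates)

    def to_frame(self, schema: PanelSchema | None = None) -> pd.DataFrame:
        """Long-format DataFrame, one row per (area, period)."""
        schema = schema or PanelSchema(covariates=self.covariate_names())
        n, T = self.n_areas, self.n_periods
        data = {
            schema.area: np.repeat(self.area_ids, T),
            schema.period: np.tile(self.periods, n),
            schema.count: self.counts.ravel().astype(int),
            schema.population: self.population.ravel(),
        }
        for name in self.covariate_names():
            data[name] = self.covariates[name].ravel()
        return pd.DataFrame(data)


def read_panel(path, schema: PanelSchema | Mapping) -> ArealPanel:
    """Read and validate a long-format panel CSV.

    Static covariate columns may either repeat their value on every
    period row of an area or appear on a single row per area (blank
    elsewhere); both collapse to one value per area broadcast over time.

    Raises
    ------
    ValueError
        On a missing (area, period) cell, duplicated rows, negative
        counts, non-positive populations or non-contiguous periods.
    """
    if not isinstance(schema, PanelSchema):
        schema = PanelSchema.from_mapping(schema)
    df = pd.read_csv(path)
    required = [schema.area, schema.period, schema.count, schema.population, *schema.covariates]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"panel file lacks columns {missing_cols}")

    df = df.copy()
    area_ids = tuple(pd.unique(df[schema.area]))
    periods = tuple(int(p) for p in sorted(pd.unique(df[schema.period])))

    dup = df.duplicated(subset=[schema.area, schema.period])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate cell ({row[schema.area]},{int(row[schema.period])})")
    present = set(zip(df[schema.area], df[schema.period].astype(int)))
    for a in area_ids:
        for p in periods:
            if (a, p) not in present:
                raise ValueError(f"missing cell ({a},{p})")

    df = df.set_index([schema.area, schema.period]).sort_index()
    n, T = len(area_ids), len(periods)

    def grid(col: str) -> np.ndarray:
        out = np.empty((n, T))
        for i, a in enumerate(area_ids):
            out[i] = df.loc[a, col].reindex(periods).to_numpy()
        return out

    covariates = {}
    for name in schema.covariates:
        x = grid(name)
        if np.isnan(x).any():
            # single-row-per-area static column: exactly one value per area
            vals = np.empty(n)
            for i, a in enumerate(area_ids):
                nz = df.loc[a, name].dropna().unique()
                if len(nz) != 1:
                    raise ValueError(f"covariate {name!r} for area {a!r} has "
                                     f"{len(nz)} distinct non-missing values, expected 1")
                vals[i] = nz[0]
            x = vals        # 1-D, broadcast by ArealPanel
        covariates[name] = x

    return ArealPanel(area_ids=area_ids, periods=periods,
                      counts=grid(schema.count), population=grid(schema.population),
                      covariates=covariates, units=dict(schema.units))


def write_summaries(tables: Mapping[str, pd.DataFrame], path,
                    manifest: Mapping | None = None) -> list:
    """Write named result tables as CSV plus a JSON manifest.

    Floats are serialized at full precision, so a write/read round-trip
    preserves values to better than 1e-12 relative.  Returns the list of
    files written.  Table names must be unique case-insensitively (they
    become file names).
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    names = [str(k) for k in tables]
    if len({n.lower() for n in names}) != len(names):
        raise ValueError("duplicate table names")
    written = []
    for name, table in tables.items():
        fp = out / f"{name}.csv"
        table.to_csv(fp, index=False, float_format="%.17g")
        written.append(fp)
    mf = dict(manifest or {})
    mf["tables"] = sorted(names)
    fp = out / "manifest.json"
    with open(fp, "w", encoding="utf-8") as fh:
        json.dump(mf, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(fp)
    return written
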
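"""Readers and writers for the package's plain-text interchange formats.

Length-frequency data travels as CSV in two layouts:

* raw:       columns ``date`` (ISO-8601 or decimal year), ``length_mm``;
* pre-binned: first column ``bin_lower_mm``, one column per sample date
  (ISO-8601 or decimal-year header) holding counts.

Environmental grids travel as long-format CSV with columns
``lon, lat, year, month, depth_m, sst_c, sss, catch_t`` (winter catch on the
December row of its winter year) or as NetCDF through xarray's scipy
backend.  All writers round-trip losslessly at the documented precision.
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ValidationError
from .habitat import EnvironmentalGrid
from .lfq import LengthFrequencyData

__all__ = [
    "write_lengths_csv",
    "write_lfq_csv",
    "read_lfq_csv",
    "write_grid_csv",
    "write_grid_netcdf",
    "read_grid",
]


def _format_date(key) -> str:
    if isinstance(key, _dt.date):
        return key.isoformat()
    return repr(float(key))


def _parse_date(text: str):
    try:
        return _dt.date.fromisoformat(text)
    except ValueError:
        try:
            return float(text)
        except ValueError:
            raise ValidationError(f"unparseable date {text!r}") from None


def write_lengths_csv(samples, path) -> None:
    """Write raw per-date lengths (a mapping or a LengthSamples) as
    ``date,length_mm`` rows."""
    mapping = getattr(samples, "samples", samples)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "length_mm"])
        for key in mapping:
            for val in np.asarray(mapping[key], dtype=float):
                w.writerow([_format_date(key), repr(float(val))])


def write_lfq_csv(lfq: LengthFrequencyData, path) -> None:
    """Write pre-binned counts: ``bin_lower_mm`` plus one column per date
    (decimal-year header)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_lower_mm"] + [repr(float(d)) for d in lfq.sample_dates])
        for i, lo in enumerate(lfq.bin_lower_mm):
            w.writerow([repr(float(lo))] + [int(c) for c in lfq.counts[i]])


def read_lfq_csv(path):
    """Read either length-frequency CSV layout.

    Returns a dict of date -> length array for the raw layout, or a
    :class:`LengthFrequencyData` for the pre-binned layout.  Malformed rows
    are reported with their line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValidationError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if header[:2] == ["date", "length_mm"]:
        out: dict = {}
        for ln, row in enumerate(rows[1:], start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValidationError(f"{path}:{ln}: expected 2 columns, got {len(row)}")
            key = _parse_date(row[0].strip())
            try:
                val = float(row[1])
            except ValueError:
                raise ValidationError(f"{path}:{ln}: bad length {row[1]!r}") from None
            if val <= 0 or not np.isfinite(val):
                raise ValidationError(f"{path}:{ln}: non-positive length {val}")
            out.setdefault(key, []).append(val)
        if not out:
            raise ValidationError(f"{path}: no data rows")
        return {k: np.asarray(v, dtype=float) for k, v in out.items()}
    if header[0] == "bin_lower_mm":
        try:
            dates = [float(_to_decimal_year(_parse_date(h))) for h in header[1:]]
        except ValidationError:
            raise ValidationError(
                f"{path}: pre-binned header must be bin_lower_mm followed by dates"
            ) from None
        lowers, counts = [], []
        for ln, row in enumerate(rows[1:], start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValidationError(f"{path}:{ln}: expected {len(header)} columns")
            lowers.append(float(row[0]))
            try:
                counts.append([int(float(c)) for c in row[1:]])
            except ValueError:
                raise ValidationError(f"{path}:{ln}: non-numeric count") from None
        lowers = np.asarray(lowers)
        if lowers.size > 1:
            widths = np.diff(lowers)
            if not np.allclose(widths, widths[0]):
                raise ValidationError(f"{path}: non-uniform bins in pre-binned layout")
        return LengthFrequencyData(lowers, np.asarray(dates), np.asarray(counts))
    raise ValidationError(
        f"{path}: unknown schema; expected headers 'date,length_mm' or "
        f"'bin_lower_mm,<date>,...', got {header[:3]}"
    )


def _to_decimal_year(key):
    from .lfq import decimal_year

    return decimal_year(key) if isinstance(key, _dt.date) else float(key)


_GRID_COLUMNS = ["lon", "lat", "year", "month", "depth_m", "sst_c", "sss", "catch_t"]


def write_grid_csv(grid: EnvironmentalGrid, path) -> None:
    """Write the grid as long-format CSV (one row per cell-month)."""
    grid.to_dataframe().to_csv(path, index=False)


def write_grid_netcdf(grid: EnvironmentalGrid, path) -> None:
    """Write the grid as NetCDF3 via xarray's scipy backend."""
    grid.ds.to_netcdf(path, engine="scipy")


def read_grid(path) -> EnvironmentalGrid:
    """Read an environmental grid from long CSV or NetCDF.

    CSV input is validated: the documented columns must be present (an error
    names the first missing one) and (lon, lat, year, month) keys must be
    unique.
    """
    path = Path(path)
    if path.suffix in (".nc", ".cdf", ".netcdf"):
        ds = xr.open_dataset(path, engine="scipy").load()
        return EnvironmentalGrid(ds)
    df = pd.read_csv(path)
    for col in _GRID_COLUMNS[:-1]:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if "catch_t" not in df.columns:
        df["catch_t"] = np.nan
    dup = df.duplicated(subset=["lon", "lat", "year", "month"])
    if dup.any():
        i = int(df.index[dup][0]) + 2  # header + 1-based
        raise ValidationError(f"{path}:{i}: duplicate (lon, lat, year, month) row")
    lon = np.sort(df["lon"].unique())
    lat = np.sort(df["lat"].unique())
    years = np.sort(df["year"].unique().astype(int))
    months = np.array([12, 1, 2])
    df = df.set_index(["year", "month", "lat", "lon"]).sort_index()
    shape = (years.size, months.size, lat.size, lon.size)
    sst = np.full(shape, np.nan)
    sss = np.full(shape, np.nan)
    depth = np.full((lat.size, lon.size), np.nan)
    catch: dict[int, np.ndarray] = {}
    li = {v: i for i, v in enumerate(lat)}
    lo = {v: i for i, v in enumerate(lon)}
    yi = {v: i for i, v in enumerate(years)}
    mi = {v: i for i, v in enumerate(months)}
    for (y, m, la, ln_), row in df.iterrows():
        a, b, c, d = yi[int(y)], mi[int(m)], li[la], lo[ln_]
        sst[a, b, c, d] = row["sst_c"]
        sss[a, b, c, d] = row["sss"]
        depth[c, d] = row["depth_m"]
        if int(m) == 12 and np.isfinite(row["catch_t"]):
            catch.setdefault(int(y), np.full((lat.size, lon.size), np.nan))[c, d] = row["catch_t"]
    data = {
        "depth_m": (("lat", "lon"), depth),
        "sst_c": (("year", "month", "lat", "lon"), sst),
        "sss": (("year", "month", "lat", "lon"), sss),
    }
    coords = {"lat": lat, "lon": lon, "year": years, "month": months}
    if catch:
        wyears = np.array(sorted(catch))
        coords["wyear"] = wyears
        data["catch_t"] = (("wyear", "lat", "lon"), np.stack([catch[y] for y in wyears]))
    return EnvironmentalGrid(xr.Dataset(data, coords=coords))
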
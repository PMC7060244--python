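"""CSV readers/writers for series, metadata, labels, coefficients and grids.

Long-format CSV is the canonical interchange: one row per observation for
series, one row per lake for everything else.  Every writer's output is
readable by its paired reader with a lossless round-trip (within float
formatting precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .curves import SeasonalCurve, SmoothFit
from .synthetic import OBS_PER_YEAR, LakeMeta, LakeSeries

_FLOAT_FMT = "%.9g"


def write_series_csv(path, series: list[LakeSeries]) -> None:
    """Write long-format series CSV: lake_id, time_index, decimal_year, lswt_c, ice."""
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "lake_id": s.lake_id,
            "time_index": s.times,
            "decimal_year": s.decimal_years,
            "lswt_c": s.values,
            "ice": s.ice_flags.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def read_series_csv(path) -> list[LakeSeries]:
    """Read long-format series CSV, validating schema and uniqueness.

    Either ``time_index`` (fortnight index) or ``date`` (ISO date, mapped to
    the fortnight containing it) identifies the observation time.
    """
    df = pd.read_csv(path)
    if "lake_id" not in df.columns or "lswt_c" not in df.columns:
        raise ValueError(f"{path}: need columns lake_id, lswt_c")
    if "time_index" not in df.columns:
        if "date" not in df.columns:
            raise ValueError(f"{path}: need a time_index or date column")
        d = pd.to_datetime(df["date"])
        year = d.dt.year - d.dt.year.min()
        frac = (d.dt.dayofyear - 1) / 365.25
        df["time_index"] = year * OBS_PER_YEAR + np.minimum(
            (frac * OBS_PER_YEAR).astype(int), OBS_PER_YEAR - 1)
    bad = df["lswt_c"].isna() | ~np.isfinite(pd.to_numeric(df["lswt_c"], errors="coerce"))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 0-base
        raise ValueError(f"{path}: non-numeric temperature at line(s) {lines[:5]}")
    dup = df.duplicated(subset=["lake_id", "time_index"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (lake_id, time_index) at line(s) {lines[:5]}")
    if "ice" not in df.columns:
        df["ice"] = 0
    out = []
    for lake_id, g in df.groupby("lake_id", sort=True):
        g = g.sort_values("time_index")
        n = len(g)
        if n % OBS_PER_YEAR != 0:
            raise ValueError(
                f"{path}: lake {lake_id} has {n} observations, "
                f"not a multiple of {OBS_PER_YEAR}")
        expected = np.arange(n)
        if not np.array_equal(g["time_index"].to_numpy(), expected):
            raise ValueError(f"{path}: lake {lake_id} has gaps in time_index")
        out.append(LakeSeries(str(lake_id), g["lswt_c"].to_numpy(float),
                              g["ice"].to_numpy() != 0, n // OBS_PER_YEAR))
    return out


def write_meta_csv(path, metas: list[LakeMeta]) -> None:
    pd.DataFrame([{
        "lake_id": m.lake_id, "lat": m.latitude, "lon": m.longitude,
        "elev_m": m.elevation, "area_km2": m.area_km2, "depth_m": m.mean_depth_m,
    } for m in metas]).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_meta_csv(path) -> list[LakeMeta]:
    df = pd.read_csv(path)
    return [LakeMeta(str(r.lake_id), float(r.lat), float(r.lon),
                     float(r.elev_m), float(r.area_km2), float(r.depth_m))
            for r in df.itertuples()]


def write_labels_csv(path, labels: dict[str, str], extra: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame({"lake_id": list(labels), "region_code": list(labels.values())})
    if extra is not None:
        df = df.merge(extra, on="lake_id", how="left")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_labels_csv(path) -> dict[str, str]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    idcol = cols.get("lake_id") or cols.get("cell_id")
    if idcol is None or "region_code" not in cols:
        raise ValueError(f"{path}: need lake_id (or cell_id) and region_code columns")
    return dict(zip(df[idcol].astype(str), df[cols["region_code"]].astype(str)))


def write_coefficients_csv(path, lake_ids: list[str], matrix: np.ndarray) -> None:
    df = pd.DataFrame(matrix, columns=[f"c{j}" for j in range(matrix.shape[1])])
    df.insert(0, "lake_id", lake_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_coefficients_csv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    ids = df["lake_id"].astype(str).tolist()
    return ids, df.drop(columns=["lake_id"]).to_numpy(float)


def write_profiles_csv(path, lake_ids: list[str], profiles: list[SeasonalCurve]) -> None:
    grid = profiles[0].grid
    df = pd.DataFrame(np.vstack([p.values for p in profiles]),
                      columns=[f"{g:.6f}" for g in grid])
    df.insert(0, "lake_id", lake_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_profiles_csv(path) -> tuple[list[str], list[SeasonalCurve]]:
    df = pd.read_csv(path)
    ids = df["lake_id"].astype(str).tolist()
    grid = np.array([float(c) for c in df.columns[1:]])
    vals = df.drop(columns=["lake_id"]).to_numpy(float)
    return ids, [SeasonalCurve(grid, v) for v in vals]


def write_label_grid_csv(path, grid: pd.DataFrame) -> None:
    grid.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_label_grid_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("lat_center", "lon_center", "region_code"):
        if col not in df.columns:
            raise ValueError(f"{path}: label grid needs column {col}")
    return df


def write_label_grid_geojson(path, grid: pd.DataFrame) -> None:
    """GeoJSON FeatureCollection of 2-degree cells with region labels."""
    import json
    feats = []
    for r in grid.itertuples():
        lat, lon = float(r.lat_center), float(r.lon_center)
        poly = [[[lon - 1, lat - 1], [lon + 1, lat - 1], [lon + 1, lat + 1],
                 [lon - 1, lat + 1], [lon - 1, lat - 1]]]
        props = {"region_code": r.region_code}
        if hasattr(r, "posterior"):
            props["posterior"] = float(r.posterior)
        feats.append({"type": "Feature",
                      "geometry": {"type": "Polygon", "coordinates": poly},
                      "properties": props})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))
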
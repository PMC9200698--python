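"""Readers and writers: CSV time series and tables, ASCII-grid DEM, GeoJSON layers.

All CSVs use comma separators, "." decimals, UTF-8 and ISO-8601 timestamps
(UTC wall time), so outputs are byte-stable across locales.  The DEM is a
single-band Esri ASCII grid; vector layers (plots, roads, inlets, stream
cells) are GeoJSON in a planar metric CRS with coordinates in metres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape

from .geometry import Inlet, Plot, Road
from .substances import SubstanceProperties

__all__ = [
    "write_rainfall", "read_rainfall",
    "write_stages", "read_stages",
    "write_series", "read_series",
    "write_dem_ascii", "read_dem_ascii",
    "write_catchment", "read_catchment",
    "write_substances", "read_substances",
    "write_applications", "read_applications",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised with the full list of schema violations found in the inputs."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("input schema violations:\n- " + "\n- ".join(errors))


# ---------------------------------------------------------------- time series


def write_rainfall(rain: pd.Series, path) -> None:
    df = pd.DataFrame({"timestamp": rain.index.map(lambda t: t.isoformat()), "depth_mm": rain.values})
    df.to_csv(path, index=False)


def read_rainfall(path) -> pd.Series:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError([f"{path}: rainfall file is empty"])
    errors = [f"{path}: missing column {c}" for c in ("timestamp", "depth_mm") if c not in df.columns]
    if errors:
        raise SchemaError(errors)
    s = pd.Series(df["depth_mm"].to_numpy(float), index=pd.to_datetime(df["timestamp"]), name="depth_mm")
    return s


def write_stages(stages: dict[str, pd.Series], path) -> None:
    parts = []
    for site, s in stages.items():
        parts.append(
            pd.DataFrame(
                {"site": site, "timestamp": s.index.map(lambda t: t.isoformat()), "stage_cm": s.values}
            )
        )
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_stages(path) -> dict[str, pd.Series]:
    df = pd.read_csv(path)
    out = {}
    for site, g in df.groupby("site"):
        out[str(site)] = pd.Series(
            g["stage_cm"].to_numpy(float), index=pd.to_datetime(g["timestamp"]), name="stage_cm"
        )
    return out


def write_series(series: pd.Series, path, value_col: str) -> None:
    pd.DataFrame(
        {"timestamp": series.index.map(lambda t: t.isoformat()), value_col: series.values}
    ).to_csv(path, index=False)


def read_series(path, value_col: str) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df[value_col].to_numpy(float), index=pd.to_datetime(df["timestamp"]), name=value_col)


# --------------------------------------------------------------------- raster


def write_dem_ascii(dem: np.ndarray, cell_size: float, path, nodata: float = -9999.0) -> None:
    """Esri ASCII grid, row 0 = northernmost row, origin at (0, 0)."""
    nrows, ncols = dem.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in dem:
            fh.write(" ".join(format(v, ".6f") for v in row) + "\n")


def read_dem_ascii(path) -> tuple[np.ndarray, float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        dem = np.loadtxt(fh)
    dem = dem.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None and (dem == nodata).any():
        dem = np.where(dem == nodata, np.nan, dem)
    return dem, header["cellsize"]


# -------------------------------------------------------------------- vectors


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _write_geojson(features: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(_feature_collection(features), fh, indent=1)


def _read_geojson(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)["features"]


# ------------------------------------------------------------------ catchment


def write_catchment(catchment, out_dir) -> None:
    """Serialise a catchment: DEM (ASCII grid), GeoJSON layers, meta JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dem_ascii(catchment.dem, catchment.cell_size, out / "dem.asc")

    _write_geojson(
        [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {"plot_id": p.plot_id, "crop": p.crop},
            }
            for p in catchment.plots
        ],
        out / "plots.geojson",
    )
    _write_geojson(
        [
            {
                "type": "Feature",
                "geometry": mapping(r.line),
                "properties": {"road_id": r.road_id, "surface": r.surface},
            }
            for r in catchment.roads
        ],
        out / "roads.geojson",
    )
    _write_geojson(
        [
            {
                "type": "Feature",
                "geometry": mapping(i.point),
                "properties": {"inlet_id": i.inlet_id, "row": i.row, "col": i.col},
            }
            for i in catchment.inlets
        ],
        out / "inlets.geojson",
    )
    rr, cc = np.nonzero(catchment.stream_mask)
    _write_geojson(
        [
            {
                "type": "Feature",
                "geometry": mapping(Point(0, 0)),
                "properties": {"rows": rr.tolist(), "cols": cc.tolist()},
            }
        ],
        out / "stream_cells.geojson",
    )
    from dataclasses import asdict

    meta = {
        "config": asdict(catchment.config),
        "sampled_aliases": catchment.sampled_aliases,
        "cs_member_ids": catchment.cs_member_ids,
    }
    with open(out / "catchment.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_catchment(in_dir):
    """Rebuild a SyntheticCatchment from the serialised layers."""
    from .synthetic import CatchmentConfig, SyntheticCatchment

    src = Path(in_dir)
    dem, cell = read_dem_ascii(src / "dem.asc")
    with open(src / "catchment.json") as fh:
        meta = json.load(fh)
    config = CatchmentConfig(**meta["config"])
    nrows, ncols = dem.shape

    plots = [
        Plot(f["properties"]["plot_id"], shape(f["geometry"]), f["properties"]["crop"])
        for f in _read_geojson(src / "plots.geojson")
    ]
    roads = [
        Road(f["properties"]["road_id"], shape(f["geometry"]), f["properties"]["surface"])
        for f in _read_geojson(src / "roads.geojson")
    ]
    inlets = [
        Inlet(
            f["properties"]["inlet_id"],
            int(f["properties"]["row"]),
            int(f["properties"]["col"]),
            *shape(f["geometry"]).coords[0],
        )
        for f in _read_geojson(src / "inlets.geojson")
    ]
    sf = _read_geojson(src / "stream_cells.geojson")[0]["properties"]
    stream_mask = np.zeros((nrows, ncols), dtype=bool)
    stream_mask[np.asarray(sf["rows"], int), np.asarray(sf["cols"], int)] = True

    road_mask = np.zeros((nrows, ncols), dtype=bool)
    road_surface = np.zeros((nrows, ncols), dtype=np.int8)
    for r in roads:
        # roads run along cell-row centrelines; mark cells within half a cell
        for x, y in _densify(r.line, cell / 2.0):
            row = int(nrows - y / cell - 0.5 + 0.5)
            col = int(x / cell)
            if 0 <= row < nrows and 0 <= col < ncols:
                road_mask[row, col] = True
                road_surface[row, col] = 2 if r.surface == "concrete" else 1

    from .geometry import rasterize_polygon

    agri_mask = np.zeros((nrows, ncols), dtype=bool)
    for p in plots:
        agri_mask |= rasterize_polygon(p.polygon, nrows, ncols, cell)

    return SyntheticCatchment(
        config=config,
        dem=dem,
        roads=roads,
        road_mask=road_mask,
        road_surface=road_surface,
        plots=plots,
        agri_mask=agri_mask,
        inlets=inlets,
        stream_mask=stream_mask,
        sampled_aliases=meta["sampled_aliases"],
        cs_member_ids=meta["cs_member_ids"],
    )


def _densify(line: LineString, step: float):
    n = max(int(line.length / step) + 1, 2)
    for d in np.linspace(0, line.length, n):
        p = line.interpolate(d)
        yield p.x, p.y


# --------------------------------------------------------------------- tables


def write_substances(substances: list[SubstanceProperties], path) -> None:
    from .substances import substances_to_frame

    substances_to_frame(substances).to_csv(path, index=False)


def read_substances(path) -> list[SubstanceProperties]:
    df = pd.read_csv(path)
    return [
        SubstanceProperties(
            name=r["name"],
            loq_ng_l=float(r["loq_ng_l"]),
            k_foc=float(r["k_foc"]),
            log10_kow=float(r["log10_kow"]),
            dt50_soil_d=float(r["dt50_soil_d"]),
            dt50_water_d=float(r["dt50_water_d"]),
            is_transformation_product=bool(r["is_transformation_product"]),
        )
        for _, r in df.iterrows()
    ]


def write_applications(applications, path) -> None:
    pd.DataFrame(
        {
            "application_id": [a.application_id for a in applications],
            "substance": [a.substance for a in applications],
            "date": [pd.Timestamp(a.date).date().isoformat() for a in applications],
            "plot_id": [a.plot_id for a in applications],
            "mass_g": [a.mass_g for a in applications],
            "area_m2": [a.area_m2 for a in applications],
        }
    ).to_csv(path, index=False)


def read_applications(path):
    from .synthetic import ApplicationRecord

    df = pd.read_csv(path)
    return [
        ApplicationRecord(
            int(r["application_id"]),
            r["substance"],
            pd.Timestamp(r["date"]),
            r["plot_id"],
            float(r["mass_g"]),
            float(r["area_m2"]),
        )
        for _, r in df.iterrows()
    ]


def validate_samples(samples: pd.DataFrame, substances: list[SubstanceProperties]) -> list[str]:
    """Cross-validate a concentration table against the substance table.

    Returns the exhaustive list of schema violations (empty when valid).
    """
    errors = []
    required = ["site", "event_id", "substance", "value_ng_l", "loq_ng_l", "censored"]
    for c in required:
        if c not in samples.columns:
            errors.append(f"samples: missing column {c}")
    if "substance" in samples.columns:
        known = {s.name for s in substances}
        unknown = sorted(set(samples["substance"]) - known)
        for u in unknown:
            errors.append(f"samples: unknown substance '{u}' in column 'substance'")
    return errors
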
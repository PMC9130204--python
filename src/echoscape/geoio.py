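"""File interchange: GeoJSON geometries, netCDF echograms, CSV tables.

All geometries live in a local projected plane (metres); geographic
lat/long only ever appears at I/O time, supplied by the caller.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .echo import Echogram


def write_geojson(geometries: dict, path) -> None:
    """Write named shapely geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name, **(props or {})}, "geometry": mapping(geom)}
        for name, (geom, props) in (
            (k, v if isinstance(v, tuple) else (v, None)) for k, v in geometries.items()
        )
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_geojson(path) -> dict:
    """Read a FeatureCollection back into {name or label: shapely geometry}."""
    data = json.loads(Path(path).read_text())
    out = {}
    for i, feat in enumerate(data["features"]):
        props = feat.get("properties") or {}
        name = props.get("name") or props.get("label") or f"feature_{i}"
        out[name] = shape(feat["geometry"])
    return out


def read_label_polygons(path) -> list:
    """Label polygons for echo partitioning: list of (label, polygon)."""
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        label = (feat.get("properties") or {}).get("label", "unlabelled")
        out.append((label, shape(feat["geometry"])))
    return out


def echogram_to_dataset(e: Echogram) -> xr.Dataset:
    return xr.Dataset(
        {
            "sv": (("ping", "depth"), e.sv),
            "x": ("ping", e.ping_x),
            "y": ("ping", e.ping_y),
            "time_s": ("ping", e.ping_times),
            "bottom_depth": ("ping", e.bottom_depth),
        },
        coords={"depth": e.depth_centers},
        attrs={"depth_bin_m": e.depth_bin_m, "frequency_khz": e.frequency_khz},
    )


def write_echogram(e: Echogram, path) -> None:
    """Write an echogram as netCDF (classic format, scipy backend)."""
    echogram_to_dataset(e).to_netcdf(path, engine="scipy")


def read_echogram(path) -> Echogram:
    with xr.open_dataset(path, engine="scipy") as ds:
        return Echogram(
            sv=ds["sv"].values,
            depth_bin_m=float(ds.attrs["depth_bin_m"]),
            ping_x=ds["x"].values,
            ping_y=ds["y"].values,
            ping_times=ds["time_s"].values,
            bottom_depth=ds["bottom_depth"].values,
            frequency_khz=float(ds.attrs["frequency_khz"]),
        )


def write_esdu(esdu: pd.DataFrame, path) -> None:
    esdu.to_csv(path, index=False)


def read_esdu(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map(dataset: xr.Dataset, path) -> None:
    """Kriged map to netCDF; sidecar CSV when the suffix is .csv."""
    path = Path(path)
    if path.suffix == ".csv":
        df = dataset.to_dataframe().reset_index()
        df.to_csv(path, index=False)
    else:
        dataset.to_netcdf(path, engine="scipy")


def write_json(obj: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
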
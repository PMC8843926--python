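"""Readers/writers and run configuration.

CSV tables are comma-separated UTF-8 with a header; dates are normalized to
ISO-8601 on read.  Rasters travel as NetCDF (via xarray); nodata is NaN
in-file and in-memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .raster import LakeRasterStack

log = logging.getLogger("mergedchl")

#: Default column map: WQP-style header -> normalized name.  Already
#: normalized headers pass through untouched.
WQP_COLUMN_MAP = {
    "MonitoringLocationIdentifier": "site_id",
    "ActivityLocation/LatitudeMeasure": "latitude",
    "ActivityLocation/LongitudeMeasure": "longitude",
    "LatitudeMeasure": "latitude",
    "LongitudeMeasure": "longitude",
    "ActivityStartDate": "sample_date",
    "ActivityStartTime/Time": "sample_time",
    "ActivityDepthHeightMeasure/MeasureValue": "depth_m",
    "CharacteristicName": "characteristic",
    "ResultMeasureValue": "value",
    "ResultAnalyticalMethod/MethodIdentifier": "method_id",
}

REQUIRED_RECORD_COLUMNS = ("site_id", "latitude", "longitude", "sample_date",
                           "depth_m", "characteristic", "value")


def read_insitu_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an in situ record table, renaming WQP-style columns.

    ``column_map`` (source name -> normalized name) overrides/extends the
    WQP defaults.  Missing required columns are a hard error; rows whose
    coordinates fail to parse are logged and dropped.
    """
    cmap = dict(WQP_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype={"sample_time": str})
    df = df.rename(columns={c: cmap[c] for c in df.columns if c in cmap})
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table {path} is missing required columns {missing}")
    for coord in ("latitude", "longitude"):
        df[coord] = pd.to_numeric(df[coord], errors="coerce")
    bad = df["latitude"].isna() | df["longitude"].isna() | \
        ~df["latitude"].between(-90, 90) | ~df["longitude"].between(-180, 180)
    if bad.any():
        log.warning("dropping %d rows with unparseable/out-of-range coordinates",
                    int(bad.sum()))
        df = df[~bad]
    df["sample_date"] = pd.to_datetime(df["sample_date"], errors="coerce"
                                       ).dt.strftime("%Y-%m-%d")
    return df.reset_index(drop=True)


def stack_to_dataset(stack: LakeRasterStack) -> xr.Dataset:
    """Encode a LakeRasterStack as an xarray Dataset (NaN nodata)."""
    coords = {"date": pd.DatetimeIndex(stack.dates),
              "y": np.arange(stack.shape[0]), "x": np.arange(stack.shape[1])}
    data = {
        "water_mask": (("y", "x"), stack.water_mask.astype(np.int8)),
        "lake_id": (("y", "x"), stack.lake_id.astype(np.int32)),
    }
    for alg, arr in stack.chla.items():
        data[f"chla_{alg}"] = (("date", "y", "x"), np.asarray(arr, dtype=float))
    for name, flag in stack.flags.items():
        flag = np.asarray(flag)
        dims = ("date", "y", "x") if flag.ndim == 3 else ("y", "x")
        data[f"flag_{name}"] = (dims, flag.astype(np.int8))
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["pixel_size"] = stack.pixel_size
    return ds


def dataset_to_stack(ds: xr.Dataset) -> LakeRasterStack:
    """Inverse of :func:`stack_to_dataset`."""
    chla = {name[len("chla_"):]: ds[name].values
            for name in ds.data_vars if name.startswith("chla_")}
    flags = {name[len("flag_"):]: ds[name].values.astype(bool)
             for name in ds.data_vars if name.startswith("flag_")}
    return LakeRasterStack(
        water_mask=ds["water_mask"].values.astype(bool),
        lake_id=ds["lake_id"].values.astype(int),
        dates=[pd.Timestamp(d) for d in pd.DatetimeIndex(ds["date"].values)],
        chla=chla, flags=flags,
        pixel_size=float(ds.attrs.get("pixel_size", 300.0)))


def write_stack(stack: LakeRasterStack, path) -> None:
    """Write a stack to NetCDF (classic format; NaN marks nodata)."""
    ds = stack_to_dataset(stack)
    enc = {v: {"dtype": "float64"} for v in ds.data_vars
           if str(v).startswith("chla_")}
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_stack(path) -> LakeRasterStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_stack(ds.load())


@dataclass
class RunConfig:
    """Resolved run parameters; validated on load, echoed next to outputs."""

    sensor: str = "MERIS"
    merge_preset: str = "C15-M10"
    mph_min: float | None = None
    c2rcc_max: float | None = None
    window_hours: float = 6.0
    max_depth_m: float = 2.0
    erosion_pixels: int = 2
    min_resolvable_pixels: int = 3
    min_survivors: int = 10
    buffer_radius_m: float = 300.0
    composite_min_n: int = 1
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_hours <= 0:
            raise ValueError("window_hours must be positive")
        if self.erosion_pixels < 0:
            raise ValueError("erosion_pixels must be >= 0")
        if self.max_depth_m <= 0:
            raise ValueError("max_depth_m must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extras=extras)

    def resolved_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def write_resolved(self, out_path) -> Path:
        """Write the fully resolved config next to an output file."""
        target = Path(out_path).with_suffix(".config.yaml")
        target.write_text(yaml.safe_dump(self.resolved_dict(), sort_keys=True))
        return target
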
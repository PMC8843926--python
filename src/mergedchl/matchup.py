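"""Quality-assured satellite / in situ match-up construction.

In situ records in a Water Quality Portal (WQP)-like layout are filtered to
surface chlorophyll-a measurements, assigned a UTC sampling instant (missing
clock times are imputed as 12:00 local), paired to the nearest satellite
overpass within a temporal window (±6 h by default), and matched to the
single pixel containing the sample position — provided that pixel and all 8
neighbors are pure water (not land, not mixed-flagged, not cloud/snow-ice
flagged).  Every stage reports a rejection tally so that the record budget
is fully audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import erode_shoreline

#: Meters per degree of latitude (spherical approximation).
M_PER_DEG = 111_320.0

#: Accepted chlorophyll-a pigment names after normalization (lower case,
#: hyphens/underscores → spaces).  Editable default covering common WQP
#: CharacteristicName variants; chlorophyll-b/-c and phaeophytin are rejected.
CHLA_SYNONYMS = frozenset({
    "chlorophyll a",
    "chlorophyll a, corrected for pheophytin",
    "chlorophyll a, uncorrected for pheophytin",
    "chlorophyll a (probe relative fluorescence)",
    "chlorophyll a (probe)",
    "chlorophyll a, free of pheophytin",
    "chla",
    "chl a",
})

#: In situ values above this ceiling (µg L⁻¹) are physically suspect
#: (wind-concentrated surface scum at most); they are flagged, never dropped.
IMPLAUSIBLE_CEILING = 50_000.0


@dataclass(frozen=True)
class SceneGrid:
    """North-up 300-m grid anchored at a geographic origin.

    Columns increase eastward from ``origin_lon``, rows increase southward
    from ``origin_lat``; a local equirectangular projection converts degrees
    to meters.  Pixel (r, c) covers the half-open square
    [c·s, (c+1)·s) × [r·s, (r+1)·s) in projected meters, so containment at
    pixel boundaries is deterministic.
    """

    shape: tuple[int, int]
    origin_lon: float = -90.0
    origin_lat: float = 45.0
    pixel_size: float = 300.0

    def lonlat_to_xy(self, lon, lat):
        x = (np.asarray(lon, float) - self.origin_lon) * M_PER_DEG * \
            math.cos(math.radians(self.origin_lat))
        y = (self.origin_lat - np.asarray(lat, float)) * M_PER_DEG
        return x, y

    def xy_to_lonlat(self, x, y):
        lon = self.origin_lon + np.asarray(x, float) / (
            M_PER_DEG * math.cos(math.radians(self.origin_lat)))
        lat = self.origin_lat - np.asarray(y, float) / M_PER_DEG
        return lon, lat

    def xy_to_rowcol(self, x, y):
        """Containing pixel for projected coordinates (half-open intervals)."""
        return (np.floor(np.asarray(y, float) / self.pixel_size).astype(int),
                np.floor(np.asarray(x, float) / self.pixel_size).astype(int))

    def lonlat_to_rowcol(self, lon, lat):
        """Containing pixel indices (row, col); may fall outside the grid."""
        return self.xy_to_rowcol(*self.lonlat_to_xy(lon, lat))

    def rowcol_to_lonlat(self, row, col):
        """Geographic coordinates of pixel centers."""
        x = (np.asarray(col, float) + 0.5) * self.pixel_size
        y = (np.asarray(row, float) + 0.5) * self.pixel_size
        return self.xy_to_lonlat(x, y)

    def contains(self, row, col) -> bool:
        h, w = self.shape
        return 0 <= row < h and 0 <= col < w


@dataclass
class SatelliteScene:
    """One overpass: per-algorithm chl-a grids plus masks and flags.

    ``chla`` maps algorithm name → (H, W) array; ``flags`` maps flag name
    (``cloud``, ``snow_ice``) → boolean (H, W) arrays.  The mixed-pixel flag
    is derived from the water mask by shoreline erosion unless supplied.
    """

    scene_id: str
    overpass_utc: pd.Timestamp
    grid: SceneGrid
    water_mask: np.ndarray
    chla: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    mixed: np.ndarray | None = None
    erode_pixels: int = 2

    def __post_init__(self) -> None:
        self.overpass_utc = pd.Timestamp(self.overpass_utc)
        if self.overpass_utc.tzinfo is None:
            self.overpass_utc = self.overpass_utc.tz_localize("UTC")
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        if self.mixed is None:
            self.mixed, _ = erode_shoreline(self.water_mask, self.erode_pixels)

    def pure_water(self) -> np.ndarray:
        """Water pixels clear of land adjacency and of every quality flag."""
        pure = self.water_mask & ~self.mixed
        for flag in self.flags.values():
            pure &= ~np.asarray(flag, dtype=bool)
        return pure


def _normalize_pigment(name: str) -> str:
    return str(name).strip().lower().replace("-", " ").replace("_", " ")


def _is_surface(depth) -> bool:
    return isinstance(depth, str) and depth.strip().lower() == "surface"


def filter_records(records: pd.DataFrame, max_depth_m: float = 2.0,
                   synonyms: frozenset = CHLA_SYNONYMS,
                   ceiling: float = IMPLAUSIBLE_CEILING):
    """Retain surface chlorophyll-a records; tally rejections per rule.

    Rules, in application order (conjunctive, so order only affects the
    tally attribution, not the retained set):

    1. ``pigment`` — characteristic must be a chlorophyll-a synonym.
    2. ``nonpositive_value`` — value must be finite and > 0.
    3. ``depth`` — depth ≤ ``max_depth_m`` or the literal label "surface"
       (the label wins when both are present).

    Values above ``ceiling`` are marked in a boolean ``implausible`` column
    but retained.  Returns (retained, tally) where tally includes the input
    and retained counts.
    """
    df = records.copy()
    tally: dict[str, int] = {"input": len(df)}

    pig_ok = df["characteristic"].map(
        lambda c: _normalize_pigment(c) in synonyms)
    tally["rejected_pigment"] = int((~pig_ok).sum())
    df = df[pig_ok]

    val = pd.to_numeric(df["value"], errors="coerce")
    val_ok = np.isfinite(val) & (val > 0)
    tally["rejected_nonpositive_value"] = int((~val_ok).sum())
    df = df[val_ok].copy()
    df["value"] = pd.to_numeric(df["value"])

    def depth_ok(d) -> bool:
        if _is_surface(d):
            return True
        try:
            dv = float(d)
        except (TypeError, ValueError):
            return False  # unparseable depth and no surface label
        if math.isnan(dv):
            return False  # no depth measure and no surface label
        return dv <= max_depth_m

    d_ok = df["depth_m"].map(depth_ok)
    tally["rejected_depth"] = int((~d_ok).sum())
    df = df[d_ok].copy()

    df["implausible"] = df["value"] > ceiling
    tally["retained"] = len(df)
    return df, tally


def assign_time(records: pd.DataFrame, imputed_local_time: str = "12:00"):
    """Attach a UTC sampling instant to each record.

    Records with a clock time use it; records without one are imputed at
    ``imputed_local_time`` local.  Local-to-UTC conversion uses the
    ``timezone_offset_h`` column when present, else an offset derived from
    longitude (round(lon / 15)).  Records without a date are rejected.

    Returns (records with ``sample_utc`` and ``time_imputed`` columns, tally).
    """
    df = records.copy()
    tally = {"input": len(df)}

    dates = pd.to_datetime(df["sample_date"], errors="coerce")
    ok = dates.notna()
    tally["rejected_missing_date"] = int((~ok).sum())
    df = df[ok].copy()
    dates = dates[ok]

    if "timezone_offset_h" in df.columns:
        offsets = pd.to_numeric(df["timezone_offset_h"], errors="coerce")
    else:
        offsets = pd.Series(np.nan, index=df.index)
    lon_offsets = np.round(pd.to_numeric(df["longitude"], errors="coerce") / 15.0)
    offsets = offsets.fillna(lon_offsets)

    times = df["sample_time"] if "sample_time" in df.columns else pd.Series(
        None, index=df.index, dtype=object)
    imputed = times.isna() | (times.astype(str).str.strip() == "")
    time_str = times.where(~imputed, imputed_local_time).astype(str)

    local = pd.to_datetime(dates.dt.strftime("%Y-%m-%d") + " " + time_str,
                           errors="coerce")
    bad_time = local.isna()
    tally["rejected_unparseable_time"] = int(bad_time.sum())
    df = df[~bad_time].copy()

    utc = local[~bad_time] - pd.to_timedelta(offsets[~bad_time], unit="h")
    df["sample_utc"] = utc.dt.tz_localize("UTC")
    df["time_imputed"] = imputed[~bad_time].to_numpy()
    df["timezone_offset_h"] = offsets[~bad_time].to_numpy()
    tally["retained"] = len(df)
    return df, tally


def temporal_pair(sample_utc: pd.Timestamp, scenes, window_hours: float = 6.0):
    """Nearest-in-time scene within ±``window_hours``, or None.

    Ties on |Δt| are broken toward the earlier overpass.
    """
    sample_utc = pd.Timestamp(sample_utc)
    if sample_utc.tzinfo is None:
        sample_utc = sample_utc.tz_localize("UTC")
    best = None
    best_key = None
    for scene in scenes:
        dt_h = (scene.overpass_utc - sample_utc).total_seconds() / 3600.0
        if abs(dt_h) <= window_hours:
            key = (abs(dt_h), scene.overpass_utc)
            if best_key is None or key < best_key:
                best, best_key = scene, key
    return best


def extract_pixel(lon: float, lat: float, scene: SatelliteScene):
    """Locate the containing pixel and check the purity neighborhood.

    The sample must fall on the grid, and the containing pixel plus all 8
    neighbors must be pure water (pixels on the grid border fail: their
    neighborhood is incomplete).  Returns (result dict, rejection-reason);
    exactly one of the two is None.
    """
    row, col = scene.grid.lonlat_to_rowcol(lon, lat)
    row, col = int(row), int(col)
    if not scene.grid.contains(row, col):
        return None, "off_grid"
    h, w = scene.grid.shape
    if not (0 < row < h - 1 and 0 < col < w - 1):
        return None, "incomplete_neighborhood"
    pure = scene.pure_water()
    if not pure[row - 1:row + 2, col - 1:col + 2].all():
        return None, "impure_neighborhood"
    values = {f"chla_{alg}": float(np.asarray(grid)[row, col])
              for alg, grid in scene.chla.items()}
    return {"row": row, "col": col, **values}, None


def build_matchups(records: pd.DataFrame, scenes, window_hours: float = 6.0,
                   max_depth_m: float = 2.0, dedupe: bool = True,
                   average_per_pixel: bool = False):
    """Full QA pipeline: filter → time → temporal pair → pixel extraction.

    One match-up per in situ record at most, paired to the nearest-in-time
    scene within the window.  Exact duplicate rows are dropped first (switch
    off with ``dedupe``); ``average_per_pixel`` optionally collapses multiple
    records falling in the same pixel of the same scene to their mean.

    Returns (matchup table, audit dict of per-stage tallies).
    """
    audit: dict[str, dict] = {}
    df = records.copy()
    if dedupe:
        before = len(df)
        df = df.drop_duplicates().reset_index(drop=True)
        audit["dedupe"] = {"input": before, "dropped_duplicates": before - len(df),
                           "retained": len(df)}

    df, tally = filter_records(df, max_depth_m=max_depth_m)
    audit["filter"] = tally
    df, tally = assign_time(df)
    audit["time"] = tally

    rows = []
    pair_tally = {"input": len(df), "rejected_no_scene_in_window": 0,
                  "rejected_off_grid": 0, "rejected_incomplete_neighborhood": 0,
                  "rejected_impure_neighborhood": 0, "retained": 0}
    for _, rec in df.iterrows():
        scene = temporal_pair(rec["sample_utc"], scenes, window_hours)
        if scene is None:
            pair_tally["rejected_no_scene_in_window"] += 1
            continue
        hit, reason = extract_pixel(float(rec["longitude"]), float(rec["latitude"]),
                                    scene)
        if hit is None:
            pair_tally[f"rejected_{reason}"] += 1
            continue
        dt_h = (scene.overpass_utc - rec["sample_utc"]).total_seconds() / 3600.0
        rows.append({**rec.to_dict(), **hit, "scene_id": scene.scene_id,
                     "overpass_utc": scene.overpass_utc, "time_diff_h": dt_h})
        pair_tally["retained"] += 1
    audit["pairing"] = pair_tally

    matchups = pd.DataFrame(rows)
    if average_per_pixel and len(matchups):
        keys = ["scene_id", "row", "col"]
        agg = {c: ("mean" if pd.api.types.is_numeric_dtype(matchups[c]) else "first")
               for c in matchups.columns if c not in keys}
        before = len(matchups)
        matchups = matchups.groupby(keys, as_index=False).agg(agg)
        audit["pixel_average"] = {"input": before, "retained": len(matchups)}
    return matchups, audit
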
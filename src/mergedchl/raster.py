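"""Gridded lake operations: shoreline masking, resolvable lakes, composites,
buffer extraction, trophic classification and lake summaries.

The grids are 300-m resolution by default, matching the full-resolution pixel
size of the MERIS and OLCI sensors at nadir.  Land-adjacent water pixels are
contaminated by adjacency effects (stray light from bright land), so the two
water pixels nearest land are flagged as mixed, leaving a 600-m in-lake
buffer of pure water; a lake is resolvable when at least three pure pixels
remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

#: NLA trophic-state classes with inclusive upper chl-a bounds (µg L⁻¹).
TROPHIC_CLASSES = (
    ("oligotrophic", 2.0),
    ("mesotrophic", 7.0),
    ("eutrophic", 30.0),
    ("hypereutrophic", float("inf")),
)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connected (Chebyshev) neighborhood


@dataclass
class LakeRasterStack:
    """Co-registered grids for one scene stack.

    ``chla`` maps an algorithm name to a (n_dates, H, W) array; ``flags``
    maps a flag name (``cloud``, ``mixed``, ``snow_ice``) to boolean arrays of
    the same shape (``mixed`` may be a single (H, W) grid).  ``lake_id`` is 0
    outside lakes.
    """

    water_mask: np.ndarray
    lake_id: np.ndarray
    dates: list = field(default_factory=list)
    chla: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    pixel_size: float = 300.0

    def __post_init__(self) -> None:
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        self.lake_id = np.asarray(self.lake_id)
        if self.water_mask.shape != self.lake_id.shape:
            raise ValueError("water_mask and lake_id must have the same shape")
        if np.any((self.lake_id > 0) & ~self.water_mask):
            raise ValueError("lake_id is nonzero on non-water pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.water_mask.shape


def erode_shoreline(water_mask: np.ndarray, n_pixels: int = 2):
    """Flag the ``n_pixels`` water pixels nearest land as mixed.

    Land is dilated ``n_pixels`` times with an 8-connected structuring
    element; water under the dilation is mixed, the rest is pure.  Pixels
    beyond the grid edge are treated as land.

    Returns
    -------
    (mixed, pure) : tuple of boolean grids
    """
    water = np.asarray(water_mask, dtype=bool)
    if water.size == 0:
        return water.copy(), water.copy()
    if n_pixels < 0:
        raise ValueError("n_pixels must be >= 0")
    if n_pixels == 0:
        return np.zeros_like(water), water.copy()
    land = ~water
    near_land = ndimage.binary_dilation(land, structure=_STRUCT8,
                                        iterations=n_pixels, border_value=1)
    mixed = water & near_land
    return mixed, water & ~mixed


def resolvable_lakes(water_mask: np.ndarray, lake_id: np.ndarray,
                     n_erode: int = 2, min_pure: int = 3):
    """Identify lakes retaining at least ``min_pure`` pure pixels after
    shoreline erosion.

    Returns
    -------
    (ids, counts) : (sorted list of lake ids, Series of pure-pixel counts
    per lake id for all lakes present)
    """
    lake_id = np.asarray(lake_id)
    _, pure = erode_shoreline(water_mask, n_erode)
    all_ids = np.unique(lake_id[lake_id > 0])
    kept = lake_id[pure & (lake_id > 0)]
    counts = pd.Series(0, index=pd.Index(all_ids, name="lake_id"), dtype=int)
    if kept.size:
        vc = pd.Series(kept).value_counts()
        counts.loc[vc.index] = vc.values
    ids = sorted(int(i) for i in counts.index[counts >= min_pure])
    return ids, counts


def _valid_obs(stack: LakeRasterStack, algorithm: str) -> np.ndarray:
    """(n_dates, H, W) mask of unflagged, finite observations."""
    chla = np.asarray(stack.chla[algorithm], dtype=float)
    valid = np.isfinite(chla)
    for name, flag in stack.flags.items():
        flag = np.asarray(flag, dtype=bool)
        if flag.ndim == 2:
            flag = np.broadcast_to(flag, chla.shape)
        valid &= ~flag
    valid &= np.broadcast_to(stack.water_mask, chla.shape)
    return valid


def composite(stack: LakeRasterStack, algorithm: str, date_index=None,
              min_n: int = 1, sample_sd: bool = False):
    """Per-pixel mean, SD and valid-observation count over selected dates.

    Flagged (cloud/mixed/snow-ice), non-finite and non-water observations are
    excluded.  Pixels with fewer than ``min_n`` valid observations are NaN.
    SD is the population SD by default (``sample_sd`` switches to n−1).
    """
    chla = np.asarray(stack.chla[algorithm], dtype=float)
    valid = _valid_obs(stack, algorithm)
    if date_index is not None:
        sel = np.zeros(chla.shape[0], dtype=bool)
        sel[np.asarray(date_index)] = True
        valid = valid & sel[:, None, None]
    vals = np.where(valid, chla, np.nan)
    count = valid.sum(axis=0)
    ddof = 1 if sample_sd else 0
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=ddof)
    mean = np.where(count >= max(min_n, 1), mean, np.nan)
    sd = np.where(count >= max(min_n, ddof + 1), sd, np.nan)
    return {"mean": mean, "sd": sd, "count": count}


def monthly_composite(stack: LakeRasterStack, year: int, month: int,
                      algorithm: str, min_n: int = 1, sample_sd: bool = False):
    """Composite restricted to scenes in a calendar month (civil dates)."""
    dates = pd.DatetimeIndex(pd.to_datetime(stack.dates))
    idx = np.flatnonzero((dates.year == year) & (dates.month == month))
    if idx.size == 0:
        raise ValueError(f"no scene dates in {year}-{month:02d}")
    return composite(stack, algorithm, date_index=idx,
                     min_n=min_n, sample_sd=sample_sd)


def buffer_average(field2d: np.ndarray, point_xy_m: tuple[float, float],
                   pixel_size: float = 300.0, radius_m: float = 300.0,
                   valid_mask: np.ndarray | None = None):
    """Mean (± SD, n) over valid pixels whose centers lie within ``radius_m``
    of a point given in grid coordinates (meters; x right, y down, origin at
    the top-left grid corner).  Pixel centers sit at ((col+0.5), (row+0.5))
    times the pixel size.  Returns (nan, nan, 0) when no valid pixel falls in
    the buffer."""
    f = np.asarray(field2d, dtype=float)
    h, w = f.shape
    x, y = point_xy_m
    cols = (np.arange(w) + 0.5) * pixel_size
    rows = (np.arange(h) + 0.5) * pixel_size
    dist2 = (rows[:, None] - y) ** 2 + (cols[None, :] - x) ** 2
    inside = dist2 <= radius_m ** 2
    ok = inside & np.isfinite(f)
    if valid_mask is not None:
        ok &= np.asarray(valid_mask, dtype=bool)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), float("nan"), 0
    vals = f[ok]
    return float(vals.mean()), float(vals.std()), n


def classify_trophic(chla):
    """NLA trophic class for chl-a value(s): oligotrophic ≤ 2, mesotrophic
    (2, 7], eutrophic (7, 30], hypereutrophic > 30 µg L⁻¹ (upper bounds
    inclusive).  Non-positive or non-finite input classifies as ``"invalid"``.
    """
    x = np.asarray(chla, dtype=float)
    out = np.full(x.shape, "invalid", dtype=object)
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(x) & (x > 0)
        lower = 0.0
        for label, upper in TROPHIC_CLASSES:
            out[ok & (x > lower) & (x <= upper)] = label
            lower = upper
    if np.ndim(chla) == 0:
        return str(out[()])
    return out


def lake_summary(composite_mean: np.ndarray, lake_id: np.ndarray,
                 pure_mask: np.ndarray | None = None, min_valid: int = 1,
                 ascending: bool = False):
    """Per-lake mean chl-a, trophic class and rank.

    Means are taken over valid (finite) pixels of each lake, restricted to
    ``pure_mask`` when given (shoreline-eroded pixels only).  Lakes with
    fewer than ``min_valid`` valid pixels are excluded and listed in the
    second return value.  Ranking is by mean chl-a (descending by default),
    ties broken by lake id.
    """
    mean = np.asarray(composite_mean, dtype=float)
    lake_id = np.asarray(lake_id)
    sel = (lake_id > 0) & np.isfinite(mean)
    if pure_mask is not None:
        sel &= np.asarray(pure_mask, dtype=bool)
    df = pd.DataFrame({"lake_id": lake_id[sel], "chla": mean[sel]})
    grouped = df.groupby("lake_id")["chla"].agg(["mean", "count"])
    excluded = sorted(int(i) for i in
                      set(np.unique(lake_id[lake_id > 0])) - set(grouped.index)) + \
        sorted(int(i) for i in grouped.index[grouped["count"] < min_valid])
    grouped = grouped[grouped["count"] >= min_valid]
    out = grouped.reset_index().rename(columns={"mean": "mean_chla", "count": "n_valid"})
    out["trophic"] = classify_trophic(out["mean_chla"].to_numpy())
    out = out.sort_values(["mean_chla", "lake_id"],
                          ascending=[ascending, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True), excluded


def trophic_fraction_summary(labels_by_period: dict) -> pd.DataFrame:
    """Fraction of lakes in each trophic class per period.

    ``labels_by_period`` maps a period key (e.g. month name) to an iterable
    of class labels.  Returns a DataFrame indexed by period with one column
    per class; empty periods are omitted.
    """
    classes = [c for c, _ in TROPHIC_CLASSES]
    rows = {}
    for period, labels in labels_by_period.items():
        labels = list(labels)
        if not labels:
            continue
        counts = pd.Series(labels).value_counts()
        rows[period] = [counts.get(c, 0) / len(labels) for c in classes]
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes)
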
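"""Synthetic scenes, spectra, pseudo-algorithm outputs and in situ tables.

Everything the retrieval, merging and validation machinery consumes can be
generated here deterministically from a seed: lake shapes on a land grid,
true chl-a fields, BRR spectra constructed so the MPH pipeline inverts them
exactly, pseudo C2RCC / MPH(P) outputs with regime-dependent multiplicative
log-normal error, and WQP-style record tables with controlled fractions of
QA-rule violations so survivor counts are known by construction.

All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .matchup import SceneGrid, SatelliteScene
from .mph import CHLA_POLY, NOMINAL_BANDS
from .raster import LakeRasterStack, erode_shoreline


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LakeSpec:
    """An elliptical lake: center (row, col), semi-axes in pixels, id > 0."""

    center: tuple[float, float]
    semiaxes: tuple[float, float]
    lake_id: int

    def __post_init__(self) -> None:
        a, b = self.semiaxes
        if a <= 0 or b <= 0:
            raise ValueError(f"degenerate lake geometry: semiaxes {self.semiaxes}")
        if self.lake_id <= 0:
            raise ValueError("lake_id must be positive")


@dataclass(frozen=True)
class SceneRecipe:
    """Deterministic description of a synthetic scene stack.

    ``chla_field`` is one of ``("constant", value)``,
    ``("gradient", low, high, axis)`` (axis 0 = north→south) or
    ``("lognormal", median, sigma_log10)`` (spatially smoothed log-normal
    patchiness).  ``cloud_fraction`` / ``ice_fraction`` give the per-date
    flagged-area fractions.  Identical recipe + seed ⇒ identical outputs.
    """

    shape: tuple[int, int] = (40, 40)
    lakes: tuple[LakeSpec, ...] = ()
    chla_field: tuple = ("constant", 20.0)
    dates: tuple[str, ...] = ("2011-07-01",)
    cloud_fraction: float = 0.0
    ice_fraction: float = 0.0
    origin_lon: float = -90.0
    origin_lat: float = 45.0
    pixel_size: float = 300.0

    def grid(self) -> SceneGrid:
        return SceneGrid(shape=self.shape, origin_lon=self.origin_lon,
                         origin_lat=self.origin_lat, pixel_size=self.pixel_size)


def _lake_masks(recipe: SceneRecipe):
    h, w = recipe.shape
    rows, cols = np.mgrid[0:h, 0:w]
    lake_id = np.zeros((h, w), dtype=int)
    for lake in recipe.lakes:
        r0, c0 = lake.center
        a, b = lake.semiaxes
        inside = ((rows - r0) / a) ** 2 + ((cols - c0) / b) ** 2 <= 1.0
        lake_id[inside] = lake.lake_id
    return lake_id > 0, lake_id


def _truth_field(recipe: SceneRecipe, rng: np.random.Generator) -> np.ndarray:
    h, w = recipe.shape
    kind = recipe.chla_field[0]
    if kind == "constant":
        return np.full((h, w), float(recipe.chla_field[1]))
    if kind == "gradient":
        _, lo, hi, axis = recipe.chla_field
        ramp = np.linspace(float(lo), float(hi), h if axis == 0 else w)
        return np.broadcast_to(ramp[:, None] if axis == 0 else ramp[None, :],
                               (h, w)).copy()
    if kind == "lognormal":
        _, median, sigma = recipe.chla_field
        noise = rng.standard_normal((h, w))
        smooth = ndimage.gaussian_filter(noise, sigma=2.0)
        smooth *= 1.0 / max(smooth.std(), 1e-12)
        return float(median) * 10.0 ** (float(sigma) * smooth)
    raise ValueError(f"unknown chla_field kind {kind!r}")


def _flag_mask(shape, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially coherent random flag mask covering ~``fraction`` of pixels."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    return noise >= np.quantile(noise, 1.0 - fraction)


def generate_scene_stack(recipe: SceneRecipe, rng: np.random.Generator
                         ) -> LakeRasterStack:
    """Build a LakeRasterStack with a ``truth`` chl-a layer per date."""
    water, lake_id = _lake_masks(recipe)
    truth = _truth_field(recipe, rng)
    n_dates = len(recipe.dates)
    chla = np.broadcast_to(truth, (n_dates,) + recipe.shape).copy()
    chla[:, ~water] = np.nan
    mixed, _ = erode_shoreline(water, 2)
    flags = {
        "cloud": np.stack([_flag_mask(recipe.shape, recipe.cloud_fraction, rng)
                           for _ in range(n_dates)]),
        "snow_ice": np.stack([_flag_mask(recipe.shape, recipe.ice_fraction, rng)
                              for _ in range(n_dates)]),
        "mixed": mixed,
    }
    return LakeRasterStack(water_mask=water, lake_id=lake_id,
                           dates=[pd.Timestamp(d) for d in recipe.dates],
                           chla={"truth": chla}, flags=flags,
                           pixel_size=recipe.pixel_size)


# ---------------------------------------------------------------------------
# Forward BRR model (inverse of the chl-a recalibration cubic)
# ---------------------------------------------------------------------------

def _invert_chla_cubic(chla) -> np.ndarray:
    """MPH index whose cubic recalibration equals ``chla`` (chla ≥ 0).

    The cubic is strictly increasing with derivative ≥ 3475.8, so the root
    is unique and bracketed by [0, chla/3475.8]; 80 bisection steps give far
    better than 1e-12 relative accuracy.
    """
    c = np.asarray(chla, dtype=float)
    if np.any(c < 0):
        raise ValueError("chla must be non-negative")
    a3, a2, a1 = CHLA_POLY[:3]
    deriv_min = a1 - a2 ** 2 / (3 * a3)  # positive: cubic strictly increasing
    lo = np.zeros_like(c)
    hi = c / deriv_min + 1e-12
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = np.polyval(CHLA_POLY, mid)
        too_low = val < c
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def chla_to_brr(chla, baseline: float = 0.02, sensor: str = "MERIS"):
    """Construct a BRR spectrum whose MPH retrieval returns ``chla``.

    A flat baseline at all five bands plus a 709-nm peak of height MPH*,
    the unique root of the recalibration cubic.  With a flat baseline the
    MPH baseline term vanishes and the index equals the peak height exactly.
    Scalar input returns a :class:`~mergedchl.mph.BRRSpectrum`; array input
    returns a dict band → array.
    """
    from .mph import BRRSpectrum

    mph_star = _invert_chla_cubic(chla)
    scalar = np.ndim(chla) == 0
    bands = {b: np.broadcast_to(np.asarray(baseline, float),
                                np.shape(mph_star)).copy()
             for b in NOMINAL_BANDS}
    bands[709] = bands[709] + mph_star
    if scalar:
        return BRRSpectrum({b: float(v) for b, v in bands.items()}, sensor=sensor)
    return bands


# ---------------------------------------------------------------------------
# Pseudo-algorithm error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Regime-dependent multiplicative error for the two pseudo-retrievals.

    MPH(P): unbiased above the crossover ``mph_crossover`` (τ_M); below it a
    graded underestimation ``(truth/τ_M)**mph_under_exponent`` times an
    optional constant ``mph_under_factor``.  C2RCC: a low/mid-range
    overestimation factor below ``c2rcc_crossover`` (τ_C); above it an
    optional degradation (``c2rcc_high_factor`` with extra log-noise
    ``c2rcc_sigma_high``), and a hard saturation ceiling.  All noise is
    log-normal in log10 space.  ``*_invalid_p`` are per-record probabilities
    of the retrieval being flagged invalid.
    """

    mph_sigma_log10: float = 0.10
    mph_crossover: float = 10.0
    mph_under_exponent: float = 1.5
    mph_under_factor: float = 1.0
    mph_invalid_p: float = 0.0
    c2rcc_sigma_log10: float = 0.10
    c2rcc_crossover: float = 15.0
    c2rcc_over_factor: float = 1.16
    c2rcc_high_factor: float = 1.0
    c2rcc_sigma_high: float | None = None
    c2rcc_ceiling: float = 100.0
    c2rcc_invalid_p: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mph_under_factor", "c2rcc_over_factor",
                     "c2rcc_high_factor", "c2rcc_ceiling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mph_sigma_log10", "c2rcc_sigma_log10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def recovery_matchups(n: int, rng: np.random.Generator,
                      mph_crossover: float = 10.0,
                      c2rcc_crossover: float = 15.0):
    """Strong-contrast dual-algorithm match-ups with known regime crossovers.

    Construction designed so the survivor-set MAE_mult surface of the
    threshold grid search has its minimum at (``c2rcc_crossover``,
    ``mph_crossover``).  A survivor-only error statistic rewards discarding
    any above-average-noise subpopulation, so identifiability requires four
    ingredients working together:

    * MPH underestimation below its crossover is *graded*,
      ``(truth/τ_M)**4``, keeping MPH outputs continuous through τ_M: every
      lowering of the MPH-minimum threshold admits records with a strictly
      positive bias, penalizing thresholds below τ_M.
    * In situ observations of high-biomass water carry large sampling error
      (patchy surface blooms make point samples unrepresentative), while the
      satellite MPH retrieval there is precise.  This error attaches to the
      *record*, not to a branch, so no threshold choice can shed it — it
      keeps the baseline MAE above the low/mid-range C2RCC error and makes
      every exclusion of accurate low/mid C2RCC records costly.
    * C2RCC *saturates to a low background* (τ_C/3) above its crossover
      (out-of-scope inversions return low values): any configuration that
      routes high-biomass records into the C2RCC branch admits them as
      strongly erroneous survivors, so "use C2RCC everywhere" cells lose.
    * MPH is invalid for 15 % of low/mid-biomass records (low-signal index
      values clamp to invalid), which populates the C2RCC branch with
      accurate mid-range values right up to τ_C: C2RCC-maximum thresholds
      below τ_C cut them and are penalized.
    * C2RCC degrades slightly approaching its crossover (a 0.95 bias between
      the crossovers): routing records of the both-good overlap band into the
      C2RCC branch is strictly penalized, pinning the MPH minimum at τ_M, and
      good C2RCC outputs stay below τ_C so the windows just above τ_C are
      empty and the deterministic tie-break settles at the crossover.

    Noise levels (log10 SD): MPH 0.01; C2RCC 0.015 below τ_C; saturation
    background 0.3; observations 0.02 below τ_C, 0.25 above.  True chl-a is
    log-normal (median 12 µg L⁻¹, log10 SD 0.5, clipped to 0.5–500).
    """
    from .threshold_search import DualAlgorithmMatchups

    t = np.clip(12.0 * 10 ** (0.5 * rng.standard_normal(n)), 0.5, 500.0)
    high = t >= c2rcc_crossover
    obs = t * 10 ** (np.where(high, 0.25, 0.02) * rng.standard_normal(n))
    mph = t * np.where(t < mph_crossover, (t / mph_crossover) ** 4, 1.0) \
        * 10 ** (0.01 * rng.standard_normal(n))
    mph_ok = high | (rng.random(n) >= 0.15)
    bias_c = np.where(t < mph_crossover, 1.0, 0.95)
    c2 = np.where(~high,
                  t * bias_c * 10 ** (0.015 * rng.standard_normal(n)),
                  (c2rcc_crossover / 3.0) * 10 ** (0.3 * rng.standard_normal(n)))
    return DualAlgorithmMatchups(observed=obs, chla_c2rcc=c2, chla_mph=mph,
                                 mph_valid=mph_ok)


def apply_error_model(truth, model: ErrorModel, rng: np.random.Generator):
    """Pseudo C2RCC and MPH(P) outputs for true chl-a values.

    Returns (chla_c2rcc, chla_mph, c2rcc_valid, mph_valid); invalid entries
    are NaN with a false flag.
    """
    t = np.atleast_1d(np.asarray(truth, dtype=float))
    if np.any(t <= 0):
        raise ValueError("true chl-a must be strictly positive")

    low_m = t < model.mph_crossover
    bias_m = np.where(
        low_m,
        model.mph_under_factor * (t / model.mph_crossover) ** model.mph_under_exponent,
        1.0)
    mph = t * bias_m * 10.0 ** (model.mph_sigma_log10 * rng.standard_normal(t.shape))

    low_c = t < model.c2rcc_crossover
    bias_c = np.where(low_c, model.c2rcc_over_factor, model.c2rcc_high_factor)
    sigma_high = (model.c2rcc_sigma_high if model.c2rcc_sigma_high is not None
                  else model.c2rcc_sigma_log10)
    sigma_c = np.where(low_c, model.c2rcc_sigma_log10, sigma_high)
    c2rcc = t * bias_c * 10.0 ** (sigma_c * rng.standard_normal(t.shape))
    c2rcc = np.minimum(c2rcc, model.c2rcc_ceiling)

    mph_valid = rng.random(t.shape) >= model.mph_invalid_p
    c2rcc_valid = rng.random(t.shape) >= model.c2rcc_invalid_p
    mph = np.where(mph_valid, mph, np.nan)
    c2rcc = np.where(c2rcc_valid, c2rcc, np.nan)
    if np.ndim(truth) == 0:
        return float(c2rcc[0]), float(mph[0]), bool(c2rcc_valid[0]), bool(mph_valid[0])
    return c2rcc, mph, c2rcc_valid, mph_valid


def sample_truth(n: int, rng: np.random.Generator, median: float = 10.0,
                 sigma_log10: float = 0.55, lo: float = 0.1,
                 hi: float = 872.0) -> np.ndarray:
    """Log-normal true chl-a values clipped to a plausible in situ range."""
    t = median * 10.0 ** (sigma_log10 * rng.standard_normal(n))
    return np.clip(t, lo, hi)


def dual_matchups(n: int, model: ErrorModel, rng: np.random.Generator,
                  truth: np.ndarray | None = None, median: float = 10.0,
                  sigma_log10: float = 0.55):
    """Synthetic dual-algorithm match-up table (observed + both retrievals)."""
    from .threshold_search import DualAlgorithmMatchups

    if truth is None:
        truth = sample_truth(n, rng, median=median, sigma_log10=sigma_log10)
    c2rcc, mph, c_ok, m_ok = apply_error_model(truth, model, rng)
    return DualAlgorithmMatchups(observed=truth, chla_c2rcc=c2rcc, chla_mph=mph,
                                 c2rcc_valid=c_ok, mph_valid=m_ok)


# ---------------------------------------------------------------------------
# In situ record tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordSpec:
    """Controlled violation mix for a synthetic in situ table.

    Each fraction assigns a disjoint subset of records exactly one QA
    violation, so the number of compliant survivors is
    ``n − round(n·f_pigment) − round(n·f_deep) − round(n·f_offwindow)
    − round(n·f_shore)`` (missing-time records stay compliant: they are
    imputed at local noon, which the scene overpass is arranged to satisfy).
    """

    frac_wrong_pigment: float = 0.0
    frac_deep: float = 0.0
    frac_missing_time: float = 0.0
    frac_offwindow: float = 0.0
    frac_shore: float = 0.0
    depth_m: float = 0.5
    timezone_offset_h: float = -6.0

    def violation_counts(self, n: int) -> dict[str, int]:
        counts = {
            "wrong_pigment": round(n * self.frac_wrong_pigment),
            "deep": round(n * self.frac_deep),
            "offwindow": round(n * self.frac_offwindow),
            "shore": round(n * self.frac_shore),
            "missing_time": round(n * self.frac_missing_time),
        }
        fatal = sum(v for k, v in counts.items() if k != "missing_time")
        if fatal + counts["missing_time"] > n:
            raise ValueError("violation fractions exceed the record count")
        return counts

    def expected_survivors(self, n: int) -> int:
        c = self.violation_counts(n)
        return n - c["wrong_pigment"] - c["deep"] - c["offwindow"] - c["shore"]


def sample_insitu_records(scene: SatelliteScene, truth: np.ndarray, n: int,
                          spec: RecordSpec, rng: np.random.Generator,
                          value_noise_sigma_log10: float = 0.0) -> pd.DataFrame:
    """WQP-style record table sampled at known pixels of one scene.

    Compliant records sit at pure-water pixels with interior (non-border)
    3×3 pure neighborhoods, timestamps inside the ±6 h window and depth ≤
    2 m; violation subsets defined by ``spec`` each break exactly one rule.
    ``truth`` is the (H, W) true chl-a field; observed values are the pixel
    truth times optional log-normal noise.
    """
    if n == 0:
        return pd.DataFrame(columns=[
            "site_id", "latitude", "longitude", "sample_date", "sample_time",
            "timezone_offset_h", "depth_m", "characteristic", "value",
            "method_id"])
    pure = scene.pure_water()
    inner = np.zeros_like(pure)
    inner[1:-1, 1:-1] = True
    good3x3 = ndimage.minimum_filter(pure.astype(np.uint8), size=3,
                                     mode="constant", cval=0).astype(bool)
    candidates = np.argwhere(good3x3 & inner)
    if candidates.size == 0:
        raise ValueError("scene has no interior pure 3x3 neighborhood")
    picks = candidates[rng.integers(0, len(candidates), size=n)]

    mixed_pixels = np.argwhere(scene.mixed)
    counts = spec.violation_counts(n)
    labels = np.array(["ok"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for kind in ("wrong_pigment", "deep", "offwindow", "shore", "missing_time"):
        k = counts[kind]
        labels[order[pos:pos + k]] = kind
        pos += k

    overpass = scene.overpass_utc
    offset = spec.timezone_offset_h
    rows = []
    for i in range(n):
        r, c = picks[i]
        kind = labels[i]
        if kind == "shore":
            if len(mixed_pixels) == 0:
                raise ValueError("scene has no mixed shoreline pixels to violate")
            r, c = mixed_pixels[rng.integers(0, len(mixed_pixels))]
        lon, lat = scene.grid.rowcol_to_lonlat(int(r), int(c))
        value = float(truth[int(r), int(c)])
        if value_noise_sigma_log10 > 0:
            value *= 10.0 ** (value_noise_sigma_log10 * rng.standard_normal())
        # local sampling instant within ±2 h of overpass (well inside ±6 h)
        local = overpass.tz_convert(None) + pd.Timedelta(hours=offset) + \
            pd.Timedelta(hours=float(rng.uniform(-2, 2)))
        sample_time = local.strftime("%H:%M")
        sample_date = local.strftime("%Y-%m-%d")
        if kind == "offwindow":
            local_bad = overpass.tz_convert(None) + pd.Timedelta(hours=offset) - \
                pd.Timedelta(hours=8.0 + float(rng.uniform(0, 3)))
            sample_time = local_bad.strftime("%H:%M")
            sample_date = local_bad.strftime("%Y-%m-%d")
        elif kind == "missing_time":
            sample_time = ""
            noon_local = pd.Timestamp(f"{sample_date} 12:00")
            noon_utc = noon_local - pd.Timedelta(hours=offset)
            if abs((noon_utc.tz_localize("UTC") - overpass).total_seconds()) > 6 * 3600:
                raise ValueError(
                    "overpass too far from local noon for missing-time records "
                    "to stay compliant; adjust the overpass time")
        rows.append({
            "site_id": f"SITE-{i:04d}",
            "latitude": float(lat),
            "longitude": float(lon),
            "sample_date": sample_date,
            "sample_time": sample_time,
            "timezone_offset_h": offset,
            "depth_m": spec.depth_m if kind != "deep" else 5.0,
            "characteristic": ("Chlorophyll b" if kind == "wrong_pigment"
                               else "Chlorophyll a"),
            "value": value,
            "method_id": "EPA 445.0",
            "violation": kind,
        })
    return pd.DataFrame(rows)


def scene_from_stack(stack: LakeRasterStack, date_index: int,
                     grid: SceneGrid, overpass_utc, scene_id: str = "scene-0",
                     algorithms: dict | None = None) -> SatelliteScene:
    """Wrap one date of a stack as a SatelliteScene.

    ``algorithms`` maps algorithm name → (H, W) chl-a grid; defaults to the
    stack's layers at ``date_index``.
    """
    if algorithms is None:
        algorithms = {alg: np.asarray(arr)[date_index]
                      for alg, arr in stack.chla.items()}
    flags = {}
    for name, flag in stack.flags.items():
        flag = np.asarray(flag)
        if name == "mixed":
            continue
        flags[name] = flag[date_index] if flag.ndim == 3 else flag
    mixed = stack.flags.get("mixed")
    return SatelliteScene(scene_id=scene_id, overpass_utc=overpass_utc,
                          grid=grid, water_mask=stack.water_mask,
                          chla=algorithms, flags=flags,
                          mixed=None if mixed is None else np.asarray(mixed))
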
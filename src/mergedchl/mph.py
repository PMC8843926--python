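"""Maximum Peak Height (MPH) spectral index and its chlorophyll-a recalibration.

The MPH index measures the height of the largest red/NIR reflectance peak
(681, 709, or 753 nm) above a linear baseline drawn between 664 and 885 nm in
bottom-of-Rayleigh reflectance (BRR).  A single cubic polynomial, calibrated
across eukaryote- and cyanobacteria-dominated waters, converts the index to a
chlorophyll-a concentration in µg L⁻¹.

All functions treat NaN as the invalid-value marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Nominal band-center labels (nm) required on every spectrum.
NOMINAL_BANDS = (664, 681, 709, 753, 885)

#: Candidate peak bands searched for the maximum BRR.
PEAK_BANDS = (681, 709, 753)

#: Nominal label -> actual band-center wavelength (nm) per sensor.  MERIS
#: band centers coincide with the nominal labels; the OLCI defaults are the
#: Sentinel-3 OLCI band centers conventionally substituted for them (Oa08,
#: Oa10, Oa11, Oa12, Oa18).  Both tables are plain data and may be overridden
#: per spectrum or per call.
SENSOR_BAND_CENTERS: dict[str, dict[int, float]] = {
    "MERIS": {664: 664.0, 681: 681.0, 709: 709.0, 753: 753.0, 885: 885.0},
    "OLCI": {664: 665.0, 681: 681.25, 709: 708.75, 753: 753.75, 885: 885.0},
}

#: Coefficients of the chl-a recalibration cubic (highest degree first;
#: zero intercept).
CHLA_POLY = (848468.0, -72058.0, 5515.7, 0.0)


class MissingBandError(KeyError):
    """A required nominal band is absent from a spectrum."""


@dataclass(frozen=True)
class BRRSpectrum:
    """Bottom-of-Rayleigh reflectance at the five MPH bands for one pixel.

    Parameters
    ----------
    values
        Mapping from nominal band label (nm, one of ``NOMINAL_BANDS``) to the
        dimensionless BRR value.  Slightly negative values are permitted: BRR
        is a corrected quantity and can undershoot zero.
    sensor
        ``"MERIS"`` or ``"OLCI"``; selects the actual band-center wavelengths
        used in the baseline term.
    band_centers
        Optional explicit nominal -> actual wavelength override.
    """

    values: Mapping[int, float]
    sensor: str = "MERIS"
    band_centers: Mapping[int, float] | None = field(default=None)

    def __post_init__(self) -> None:
        for band in NOMINAL_BANDS:
            if band not in self.values:
                raise MissingBandError(f"spectrum is missing required band {band} nm")
        if self.band_centers is None and self.sensor not in SENSOR_BAND_CENTERS:
            raise ValueError(
                f"unknown sensor {self.sensor!r}; expected one of "
                f"{sorted(SENSOR_BAND_CENTERS)} or explicit band_centers"
            )

    @property
    def centers(self) -> Mapping[int, float]:
        if self.band_centers is not None:
            return self.band_centers
        return SENSOR_BAND_CENTERS[self.sensor]


@dataclass(frozen=True)
class MPHResult:
    """Outcome of the MPH computation for one pixel.

    ``mph`` is the dimensionless index, ``lambda_max`` the nominal label of
    the winning peak band, ``brr_max`` the BRR at that band and ``chla`` the
    recalibrated chlorophyll-a (NaN until conversion, or when invalid).
    """

    mph: float
    lambda_max: int
    brr_max: float
    chla: float = float("nan")


def compute_mph(spectrum: BRRSpectrum) -> MPHResult:
    """Compute the MPH index for one spectrum.

    The peak band is the argmax of BRR over 681/709/753 nm (ties broken
    toward the shorter wavelength); the index is the peak height above the
    664–885 nm baseline evaluated at the sensor's actual band centers.
    A non-finite band value yields an all-NaN result rather than an error.
    """
    vals = {b: float(spectrum.values[b]) for b in NOMINAL_BANDS}
    if not all(np.isfinite(v) for v in vals.values()):
        return MPHResult(float("nan"), PEAK_BANDS[0], float("nan"))

    lambda_max = max(PEAK_BANDS, key=lambda b: (vals[b], -b))
    brr_max = vals[lambda_max]
    centers = spectrum.centers
    slope = (centers[lambda_max] - centers[664]) / (centers[885] - centers[664])
    mph = brr_max - vals[664] - (vals[885] - vals[664]) * slope
    return MPHResult(mph, lambda_max, brr_max)


def mph_to_chla(mph: float | np.ndarray, clamp_negative: bool = True):
    """Convert MPH index values to chlorophyll-a (µg L⁻¹) via the cubic
    ``848468·x³ − 72058·x² + 5515.7·x``.

    The cubic is strictly increasing over the reals, so negative indices map
    to negative concentrations; with ``clamp_negative`` (default) those are
    replaced by NaN, the invalid marker.  Non-finite input propagates as NaN.
    """
    x = np.asarray(mph, dtype=float)
    with np.errstate(invalid="ignore", over="ignore"):
        chla = np.polyval(CHLA_POLY, np.where(np.isfinite(x), x, 0.0))
    chla = np.where(np.isfinite(x), chla, np.nan)
    if clamp_negative:
        with np.errstate(invalid="ignore"):
            chla = np.where(chla < 0.0, np.nan, chla)
    if np.isscalar(mph) or np.ndim(mph) == 0:
        return float(chla)
    return chla


def mph_chla_pixel(spectrum: BRRSpectrum, clamp_negative: bool = True) -> MPHResult:
    """Compute the MPH index and its chl-a conversion for one spectrum."""
    res = compute_mph(spectrum)
    return MPHResult(res.mph, res.lambda_max, res.brr_max,
                     mph_to_chla(res.mph, clamp_negative=clamp_negative))


def compute_mph_arrays(brr: Mapping[int, np.ndarray], sensor: str = "MERIS",
                       band_centers: Mapping[int, float] | None = None):
    """Vectorized MPH over co-registered band arrays.

    Parameters
    ----------
    brr
        Mapping nominal band -> array of BRR values (broadcastable shapes).

    Returns
    -------
    (mph, lambda_max) : tuple of arrays
        Index values (NaN where any band is non-finite) and the nominal
        wavelength of the winning peak band.
    """
    for band in NOMINAL_BANDS:
        if band not in brr:
            raise MissingBandError(f"band stack is missing required band {band} nm")
    centers = band_centers or SENSOR_BAND_CENTERS[sensor]
    arrays = {b: np.asarray(brr[b], dtype=float) for b in NOMINAL_BANDS}
    arrays = dict(zip(NOMINAL_BANDS, np.broadcast_arrays(*arrays.values())))

    peaks = np.stack([arrays[b] for b in PEAK_BANDS])  # argmax -> first max: shortest λ
    with np.errstate(invalid="ignore"):
        idx = np.nanargmax(np.where(np.isnan(peaks), -np.inf, peaks), axis=0)
    lambda_max = np.asarray(PEAK_BANDS)[idx]
    brr_max = np.take_along_axis(peaks, idx[None, ...], axis=0)[0]

    lam = np.vectorize(centers.__getitem__, otypes=[float])(lambda_max)
    slope = (lam - centers[664]) / (centers[885] - centers[664])
    mph = brr_max - arrays[664] - (arrays[885] - arrays[664]) * slope

    finite = np.ones_like(mph, dtype=bool)
    for b in NOMINAL_BANDS:
        finite &= np.isfinite(arrays[b])
    mph = np.where(finite, mph, np.nan)
    return mph, lambda_max


def mph_table(df, sensor: str = "MERIS", prefix: str = "brr_",
              clamp_negative: bool = True,
              band_centers: Mapping[int, float] | None = None):
    """Append ``mph``, ``lambda_max`` and ``chla_mph`` columns to a table of
    per-row BRR values in columns ``{prefix}664 … {prefix}885``."""
    brr = {}
    for band in NOMINAL_BANDS:
        col = f"{prefix}{band}"
        if col not in df.columns:
            raise MissingBandError(f"input table is missing column {col!r}")
        brr[band] = df[col].to_numpy(dtype=float)
    mph, lambda_max = compute_mph_arrays(brr, sensor=sensor, band_centers=band_centers)
    out = df.copy()
    out["mph"] = mph
    out["lambda_max"] = lambda_max
    out["chla_mph"] = mph_to_chla(mph, clamp_negative=clamp_negative)
    return out
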
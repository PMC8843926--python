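"""Pixel-wise merging of C2RCC and MPH(P) chlorophyll-a.

The merge leverages each retrieval where it performs best: the MPH(P) value
is retained where it exceeds a minimum threshold (high-biomass regime); below
that, the C2RCC value is used provided it is valid and under a maximum
threshold (low-biomass regime); otherwise the pixel is reported invalid.
A variant is named ``C_x-M_y`` after its C2RCC maximum x and MPH(P) minimum y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class MergeSource(IntEnum):
    """Which algorithm supplied the merged value (NONE = discarded)."""

    NONE = 0
    MPH = 1
    C2RCC = 2


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class MergeConfig:
    """Threshold pair defining one merged-algorithm variant.

    ``mph_min`` — MPH(P) chl-a above which the MPH value is retained (µg L⁻¹).
    ``c2rcc_max`` — C2RCC chl-a below which the C2RCC value is accepted (µg L⁻¹).
    """

    mph_min: float
    c2rcc_max: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.mph_min > 0 and self.c2rcc_max > 0):
            raise ValueError("merge thresholds must be positive")
        if not self.name:
            object.__setattr__(
                self, "name", f"C_{_fmt(self.c2rcc_max)}-M_{_fmt(self.mph_min)}"
            )


#: Published variants: the error-optimal pair and two based on natural breaks
#: in the in situ distribution.
PRESETS: dict[str, MergeConfig] = {
    "C15-M10": MergeConfig(mph_min=10.0, c2rcc_max=15.0, name="C_15-M_10"),
    "C50-M10": MergeConfig(mph_min=10.0, c2rcc_max=50.0, name="C_50-M_10"),
    "C50-M15": MergeConfig(mph_min=15.0, c2rcc_max=50.0, name="C_50-M_15"),
}


@dataclass(frozen=True)
class AlgorithmPixel:
    """Paired algorithm outputs for one pixel, each with a validity flag.

    NaN and a false flag are the same invalidity; the constructor normalizes
    so that ``chla_* is NaN ⟺ *_valid is False``.
    """

    chla_c2rcc: float
    chla_mph: float
    c2rcc_valid: bool = True
    mph_valid: bool = True

    def __post_init__(self) -> None:
        c_ok = self.c2rcc_valid and math.isfinite(self.chla_c2rcc)
        m_ok = self.mph_valid and math.isfinite(self.chla_mph)
        object.__setattr__(self, "c2rcc_valid", c_ok)
        object.__setattr__(self, "mph_valid", m_ok)
        if not c_ok:
            object.__setattr__(self, "chla_c2rcc", float("nan"))
        if not m_ok:
            object.__setattr__(self, "chla_mph", float("nan"))


def merge_pixel(pixel: AlgorithmPixel, config: MergeConfig) -> tuple[float, MergeSource]:
    """Merge one pixel.

    Decision rule: the MPH(P) chl-a is retained if valid and strictly above
    ``mph_min``; otherwise the C2RCC chl-a is selected if valid and strictly
    below ``c2rcc_max``; otherwise the result is NaN.  Values exactly at a
    threshold fall through to the next branch.
    """
    if pixel.mph_valid and pixel.chla_mph > config.mph_min:
        return pixel.chla_mph, MergeSource.MPH
    if pixel.c2rcc_valid and pixel.chla_c2rcc < config.c2rcc_max:
        return pixel.chla_c2rcc, MergeSource.C2RCC
    return float("nan"), MergeSource.NONE


def merge_arrays(chla_mph, chla_c2rcc, config: MergeConfig,
                 mph_valid=None, c2rcc_valid=None):
    """Vectorized merge of co-registered grids (or 1-D record arrays).

    Validity masks default to finiteness of the corresponding values.

    Returns
    -------
    (merged, source) : tuple of arrays
        Merged chl-a with NaN invalid-markers, and ``MergeSource`` codes.
    """
    m = np.asarray(chla_mph, dtype=float)
    c = np.asarray(chla_c2rcc, dtype=float)
    if m.shape != c.shape:
        raise ValueError(f"shape mismatch: mph {m.shape} vs c2rcc {c.shape}")
    m_ok = np.isfinite(m) if mph_valid is None else (np.asarray(mph_valid, bool) & np.isfinite(m))
    c_ok = np.isfinite(c) if c2rcc_valid is None else (np.asarray(c2rcc_valid, bool) & np.isfinite(c))

    with np.errstate(invalid="ignore"):
        use_mph = m_ok & (m > config.mph_min)
        use_c2rcc = ~use_mph & c_ok & (c < config.c2rcc_max)

    merged = np.full(m.shape, np.nan)
    merged[use_mph] = m[use_mph]
    merged[use_c2rcc] = c[use_c2rcc]
    source = np.full(m.shape, int(MergeSource.NONE), dtype=np.int8)
    source[use_mph] = int(MergeSource.MPH)
    source[use_c2rcc] = int(MergeSource.C2RCC)
    return merged, source


def merge_raster(mph_raster, c2rcc_raster, config: MergeConfig,
                 mph_valid=None, c2rcc_valid=None):
    """Alias of :func:`merge_arrays` for 2-D co-registered rasters."""
    return merge_arrays(mph_raster, c2rcc_raster, config,
                        mph_valid=mph_valid, c2rcc_valid=c2rcc_valid)
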
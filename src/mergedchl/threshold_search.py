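"""Exhaustive search for the error-optimal merge threshold pair.

Every combination of MPH(P)-minimum and C2RCC-maximum candidates is applied
to a dual-algorithm match-up table; each candidate pair is scored by MAE_mult
over the records its merge retains, and the pair with the lowest MAE_mult is
selected.  Survivorship is recomputed per cell — a record discarded as
invalid under one threshold pair may be retained under another — and the
per-cell match-up count is reported so sparsely populated cells can be
excluded from the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .merge import MergeConfig, merge_arrays
from .metrics import MatchupSet, bias_mult, mae_mult


@dataclass(frozen=True)
class DualAlgorithmMatchups:
    """Match-up records carrying both algorithm outputs plus the observation.

    ``observed`` must be strictly positive; algorithm values may be NaN or
    carry explicit validity flags (non-positive outputs are treated as
    invalid — a negative retrieval is an invalidity, not a measurement).
    """

    observed: np.ndarray
    chla_c2rcc: np.ndarray
    chla_mph: np.ndarray
    c2rcc_valid: np.ndarray | None = None
    mph_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        o = np.atleast_1d(np.asarray(self.observed, dtype=float))
        c = np.atleast_1d(np.asarray(self.chla_c2rcc, dtype=float))
        m = np.atleast_1d(np.asarray(self.chla_mph, dtype=float))
        if not (o.shape == c.shape == m.shape) or o.ndim != 1:
            raise ValueError("observed/c2rcc/mph must be 1-D arrays of equal length")
        if o.size == 0:
            raise ValueError("at least one match-up record is required")
        if not np.all(o > 0):
            raise ValueError("observed chl-a must be strictly positive")
        with np.errstate(invalid="ignore"):
            c_ok = np.isfinite(c) & (c > 0)
            m_ok = np.isfinite(m) & (m > 0)
        if self.c2rcc_valid is not None:
            c_ok &= np.asarray(self.c2rcc_valid, dtype=bool)
        if self.mph_valid is not None:
            m_ok &= np.asarray(self.mph_valid, dtype=bool)
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "chla_c2rcc", np.where(c_ok, c, np.nan))
        object.__setattr__(self, "chla_mph", np.where(m_ok, m, np.nan))
        object.__setattr__(self, "c2rcc_valid", c_ok)
        object.__setattr__(self, "mph_valid", m_ok)

    @property
    def n(self) -> int:
        return int(self.observed.size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, obs_col: str = "observed",
                   c2rcc_col: str = "chla_c2rcc", mph_col: str = "chla_mph"
                   ) -> "DualAlgorithmMatchups":
        return cls(df[obs_col].to_numpy(float),
                   df[c2rcc_col].to_numpy(float),
                   df[mph_col].to_numpy(float))


@dataclass(frozen=True)
class ConfigScore:
    """Scores for one threshold pair; MAE/bias are NaN when nothing survives."""

    config: MergeConfig
    mae_mult: float
    bias_mult: float
    n_retained: int


def evaluate_config(data: DualAlgorithmMatchups, config: MergeConfig) -> ConfigScore:
    """Apply the merge rule per record, drop discarded records, and score
    the survivors with MAE_mult and bias_mult."""
    merged, _ = merge_arrays(data.chla_mph, data.chla_c2rcc, config,
                             mph_valid=data.mph_valid, c2rcc_valid=data.c2rcc_valid)
    keep = np.isfinite(merged)
    n = int(keep.sum())
    if n == 0:
        return ConfigScore(config, float("nan"), float("nan"), 0)
    ms = MatchupSet(merged[keep], data.observed[keep])
    return ConfigScore(config, mae_mult(ms), bias_mult(ms), n)


@dataclass(frozen=True)
class ThresholdSurface:
    """MAE_mult over the (MPH-min × C2RCC-max) candidate grid.

    ``mae[i, j]`` scores ``MergeConfig(mph_grid[i], c2rcc_grid[j])``;
    ``reliable`` marks cells retaining at least ``min_n`` match-ups, the only
    cells eligible for the optimum.
    """

    mph_grid: np.ndarray
    c2rcc_grid: np.ndarray
    mae: np.ndarray
    bias: np.ndarray
    n_retained: np.ndarray
    min_n: int
    optimum: MergeConfig
    reliable: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Long-format surface: one row per (mph_min, c2rcc_max) cell."""
        mm, cc = np.meshgrid(self.mph_grid, self.c2rcc_grid, indexing="ij")
        return pd.DataFrame({
            "mph_min": mm.ravel(),
            "c2rcc_max": cc.ravel(),
            "mae_mult": self.mae.ravel(),
            "bias_mult": self.bias.ravel(),
            "n": self.n_retained.ravel(),
            "reliable": self.reliable.ravel(),
        })


def grid_search(data: DualAlgorithmMatchups,
                mph_grid=None, c2rcc_grid=None, min_n: int = 10) -> ThresholdSurface:
    """Exhaustively score every threshold pair and select the optimum.

    The default grid is 1–50 µg L⁻¹ in 1 µg L⁻¹ steps on both axes.  Cells
    retaining fewer than ``min_n`` records are marked unreliable and excluded
    from the argmin (tiny survivor sets make MAE_mult incomparable).  Ties on
    MAE_mult are broken toward larger n, then smaller mph_min, then smaller
    c2rcc_max.
    """
    mph_grid = np.arange(1.0, 51.0) if mph_grid is None else np.asarray(mph_grid, float)
    c2rcc_grid = np.arange(1.0, 51.0) if c2rcc_grid is None else np.asarray(c2rcc_grid, float)
    if mph_grid.size == 0 or c2rcc_grid.size == 0:
        raise ValueError("threshold grids must be nonempty")
    if np.any(np.diff(mph_grid) <= 0) or np.any(np.diff(c2rcc_grid) <= 0):
        raise ValueError("threshold grids must be strictly increasing")

    shape = (mph_grid.size, c2rcc_grid.size)
    mae = np.full(shape, np.nan)
    bias = np.full(shape, np.nan)
    n_ret = np.zeros(shape, dtype=int)

    # Precompute per-record log residuals for each algorithm; per cell the
    # merge only decides which residual (or neither) each record contributes.
    obs_log = np.log10(data.observed)
    with np.errstate(invalid="ignore"):
        res_m = np.log10(data.chla_mph) - obs_log
        res_c = np.log10(data.chla_c2rcc) - obs_log

    for i, m_min in enumerate(mph_grid):
        with np.errstate(invalid="ignore"):
            use_mph = data.mph_valid & (data.chla_mph > m_min)
        for j, c_max in enumerate(c2rcc_grid):
            with np.errstate(invalid="ignore"):
                use_c = ~use_mph & data.c2rcc_valid & (data.chla_c2rcc < c_max)
            res = np.where(use_mph, res_m, np.where(use_c, res_c, np.nan))
            keep = np.isfinite(res)
            n = int(keep.sum())
            n_ret[i, j] = n
            if n:
                kept = res[keep]
                mae[i, j] = 10.0 ** np.abs(kept).mean()
                bias[i, j] = 10.0 ** kept.mean()

    reliable = np.isfinite(mae) & (n_ret >= min_n)
    if not reliable.any():
        raise ValueError("no threshold configuration retains any reliable match-up set")

    ii, jj = np.nonzero(reliable)
    order = sorted(
        zip(ii, jj),
        key=lambda ij: (mae[ij], -n_ret[ij], mph_grid[ij[0]], c2rcc_grid[ij[1]]),
    )
    bi, bj = order[0]
    optimum = MergeConfig(mph_min=float(mph_grid[bi]), c2rcc_max=float(c2rcc_grid[bj]))
    return ThresholdSurface(mph_grid, c2rcc_grid, mae, bias, n_ret, min_n,
                            optimum, reliable)
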
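"""Multiplicative (log-space) error metrics for satellite vs in situ chl-a.

Chl-a spans orders of magnitude and its retrieval error is roughly
proportional to concentration, so performance is scored on log10 residuals:

    MAE_mult  = 10^(mean |log10 M − log10 O|)   — geometric-mean absolute error
    bias_mult = 10^(mean (log10 M − log10 O))   — geometric-mean bias

MAE_mult = 1.5 means modeled values differ from observations by a factor of
1.5 on average, in either direction; bias_mult < 1 indicates systematic
underestimation and > 1 overestimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MatchupSet:
    """Paired modeled/observed chl-a values (µg L⁻¹), both strictly positive."""

    modeled: np.ndarray
    observed: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.modeled, dtype=float))
        o = np.atleast_1d(np.asarray(self.observed, dtype=float))
        object.__setattr__(self, "modeled", m)
        object.__setattr__(self, "observed", o)
        if m.shape != o.shape or m.ndim != 1:
            raise ValueError("modeled and observed must be 1-D arrays of equal length")
        if m.size == 0:
            raise ValueError("a match-up set needs at least one record")
        for name, arr in (("modeled", m), ("observed", o)):
            with np.errstate(invalid="ignore"):
                bad = ~(arr > 0.0) | ~np.isfinite(arr)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                ident = self.ids[i] if self.ids is not None else i
                raise ValueError(
                    f"non-positive or non-finite {name} value {arr[i]!r} "
                    f"at record {ident!r}; log metrics require positive values"
                )

    @property
    def n(self) -> int:
        return int(self.modeled.size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, model_col: str, obs_col: str,
                   id_col: str | None = None) -> "MatchupSet":
        ids = df[id_col].to_numpy() if id_col else df.index.to_numpy()
        return cls(df[model_col].to_numpy(float), df[obs_col].to_numpy(float), ids)


def log_residuals(matchups: MatchupSet) -> np.ndarray:
    """Per-record residuals log10(M) − log10(O)."""
    return np.log10(matchups.modeled) - np.log10(matchups.observed)


def mae_mult(matchups: MatchupSet) -> float:
    """Geometric-mean absolute multiplicative error (≥ 1; 1 = perfect)."""
    return float(10.0 ** np.mean(np.abs(log_residuals(matchups))))


def bias_mult(matchups: MatchupSet) -> float:
    """Geometric-mean multiplicative bias (< 1 under-, > 1 overestimation)."""
    return float(10.0 ** np.mean(log_residuals(matchups)))


def residual_summary(matchups: MatchupSet, bin_width: float = 0.25,
                     bin_range: tuple[float, float] | None = None) -> dict:
    """Summary of log10 residuals: mean, median, and fixed-width histogram.

    ``bin_range`` defaults to the residual range padded to whole bins around
    zero, so the histogram is reproducible for a given bin width.
    """
    res = log_residuals(matchups)
    if bin_range is None:
        lo = np.floor(res.min() / bin_width) * bin_width
        hi = np.ceil(res.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = bin_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(res, bins=edges)
    return {
        "n": matchups.n,
        "residuals": res,
        "mean": float(res.mean()),
        "median": float(np.median(res)),
        "hist_counts": counts,
        "hist_edges": edges,
    }


def score(matchups: MatchupSet) -> dict:
    """Convenience bundle: n, MAE_mult, bias_mult and residual summary."""
    summ = residual_summary(matchups)
    return {
        "n": matchups.n,
        "mae_mult": mae_mult(matchups),
        "bias_mult": bias_mult(matchups),
        "residual_mean": summ["mean"],
        "residual_median": summ["median"],
    }


def star_plot_bias(b: float | Sequence[float]):
    """Presentation transform |1 − bias_mult| used for star plots (0 = best)."""
    return np.abs(1.0 - np.asarray(b, dtype=float))
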
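"""Pixel-wise monotonic trend detection on annual stacks.

Implements the rank-based Mann-Kendall test with tie-corrected variance
and continuity-corrected normal deviate, and the Theil-Sen slope
(median of all pairwise slopes).  Significance is two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import Grid

__all__ = ["TrendResult", "mk_test", "sen_slope", "trend_raster"]

#: pixels with fewer than this fraction of years present get nodata
MIN_VALID_FRACTION = 0.7

TREND_NODATA = float(np.nan)


@dataclass(frozen=True)
class TrendResult:
    s: int
    var_s: float
    z: float
    p: float
    slope: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0,1]")
        if self.s != 0 and self.slope != 0 and np.sign(self.slope) != np.sign(self.s):
            # pairwise-median slope and S always agree in sign
            raise ValueError("slope sign inconsistent with S")


def _tie_term(x: np.ndarray) -> float:
    """Sum over tie groups of t(t-1)(2t+5)."""
    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t * (t - 1) * (2 * t + 5)))


def mk_test(series) -> TrendResult:
    """Mann-Kendall test (with Sen slope) on an annual series.

    Missing values (NaN) are dropped; the surviving observations keep
    their original year indices so gaps widen pairwise distances.
    Requires at least 3 valid observations.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    idx = np.flatnonzero(~np.isnan(x))
    if idx.size < 3:
        raise ValueError("need at least 3 valid observations")
    x = x[idx]
    t = idx.astype(float)
    n = x.size

    i, j = np.triu_indices(n, k=1)
    diff = x[j] - x[i]
    s = int(np.sum(np.sign(diff)))
    slopes = diff / (t[j] - t[i])
    slope = float(np.median(slopes))

    var_s = (n * (n - 1) * (2 * n + 5) - _tie_term(x)) / 18.0
    if var_s <= 0 or s == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var_s)
    else:
        z = (s + 1) / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TrendResult(s=s, var_s=var_s, z=z, p=min(p, 1.0), slope=slope)


def sen_slope(series) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(j - i), i < j."""
    x = np.asarray(series, dtype=float)
    idx = np.flatnonzero(~np.isnan(x))
    if idx.size < 2:
        raise ValueError("need at least 2 valid observations")
    x = x[idx]
    t = idx.astype(float)
    i, j = np.triu_indices(x.size, k=1)
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def mk_exact_p(series) -> float:
    """Exact two-sided p-value by enumerating all orderings (oracle; n <= 8)."""
    from itertools import permutations

    x = np.asarray(series, dtype=float)
    n = x.size
    if n > 8:
        raise ValueError("exact permutation p-value limited to n <= 8")
    i, j = np.triu_indices(n, k=1)

    def stat(v):
        return abs(int(np.sum(np.sign(v[j] - v[i]))))

    observed = stat(x)
    hits = total = 0
    for perm in permutations(range(n)):
        total += 1
        if stat(x[list(perm)]) >= observed:
            hits += 1
    return hits / total


def trend_raster(stack, min_valid_fraction: float = MIN_VALID_FRACTION):
    """Per-pixel MK test + Sen slope over an annual multi-band stack.

    Parameters
    ----------
    stack : list of Grid
        Bands ordered by year, sharing geometry and nodata.
    min_valid_fraction : float
        Pixels with a smaller share of valid years get nodata (NaN).

    Returns
    -------
    (slope Grid, p Grid) with NaN nodata.
    """
    if len(stack) < 3:
        raise ValueError("need at least 3 bands")
    first = stack[0]
    for g in stack[1:]:
        if not g.same_geometry(first):
            raise ValueError("stack bands must share geometry")
    n = len(stack)
    data = np.stack(
        [np.where(g.valid(), g.values.astype(float), np.nan) for g in stack]
    )
    flat = data.reshape(n, -1)
    n_valid = np.sum(~np.isnan(flat), axis=0)
    ok = n_valid >= max(3, math.ceil(min_valid_fraction * n))

    i, j = np.triu_indices(n, k=1)
    diff = flat[j, :] - flat[i, :]  # (n_pairs, n_pix); NaN where either endpoint missing
    with np.errstate(invalid="ignore"):
        s = np.nansum(np.sign(diff), axis=0)
        pair_slopes = diff / (j - i)[:, None]
        slope = np.nanmedian(pair_slopes, axis=0)

    # tie-corrected variance; per-pixel n and tie structure
    var_s = n_valid * (n_valid - 1) * (2 * n_valid + 5) / 18.0
    # correct pixels that actually contain ties (rare for continuous data)
    sorted_flat = np.sort(flat, axis=0)  # NaNs sort to the end
    has_tie = np.any(np.diff(sorted_flat, axis=0) == 0, axis=0)
    for pix in np.flatnonzero(has_tie & ok):
        col = flat[:, pix]
        var_s[pix] -= _tie_term(col[~np.isnan(col)]) / 18.0

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(
            s > 0, (s - 1) / np.sqrt(var_s), np.where(s < 0, (s + 1) / np.sqrt(var_s), 0.0)
        )
    z = np.where(var_s <= 0, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))

    slope = np.where(ok, slope, np.nan).reshape(first.shape)
    p = np.where(ok, p, np.nan).reshape(first.shape)
    slope_grid = Grid(slope, first.transform, first.crs_id, nodata=TREND_NODATA)
    p_grid = Grid(p, first.transform, first.crs_id, nodata=TREND_NODATA)
    return slope_grid, p_grid
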
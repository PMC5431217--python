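"""Observed temporal beta diversity.

Bray-Curtis dissimilarity on log(x+1)-transformed abundances over
consecutive-year pairs, summarised per site, plus a lag profile used as a
temporal-autocorrelation diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

from .community_io import CommunityMatrix, ValidationError

_LOG_BASE = {"e": np.e, "10": 10.0, "2": 2.0}


@dataclass
class DissimilaritySeries:
    """Consecutive-year dissimilarities for one site.

    ``mean`` is the site's observed temporal beta diversity (beta_obs); the
    standard deviation is over the pair values (n-1 denominator).  With a
    single pair the SD is reported as 0 and ``sd_degenerate`` is set, keeping
    downstream tables rectangular.
    """

    site_id: str
    pairs: list[tuple[int, int]]
    values: np.ndarray
    sd_degenerate: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))


@dataclass
class LagProfile:
    """Mean dissimilarity by year separation (lag) for one site."""

    site_id: str
    lags: np.ndarray
    mean_dissimilarity: np.ndarray
    smoothed: np.ndarray
    lag1_effect: float


def log_transform(counts: np.ndarray, base: str | float = "e") -> np.ndarray:
    """log(x + 1) transform; zeros map to zero, shape preserved."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValidationError("counts must be non-negative")
    out = np.log1p(x)
    b = _LOG_BASE.get(str(base), None)
    if b is None:
        b = float(base)
    if b != np.e:
        out = out / np.log(b)
    return out


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), in [0, 1].

    Both vectors all-zero is undefined and raises (it signals an empty
    sample year upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bray_curtis needs two equal-length vectors")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("bray_curtis entries must be non-negative")
    if not (x.any() or y.any()):
        raise ValidationError("bray_curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def consecutive_dissimilarities(
    matrix: CommunityMatrix, log_base: str | float = "e"
) -> DissimilaritySeries:
    """Bray-Curtis over each adjacent year pair of a log-transformed matrix."""
    totals = matrix.counts.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        raise ValidationError(
            f"site {matrix.site_id!r}: zero total abundance in year(s) "
            f"{matrix.years[empty].tolist()}"
        )
    z = log_transform(matrix.counts, base=log_base)
    values = np.array(
        [bray_curtis(z[i], z[i + 1]) for i in range(matrix.n_years - 1)]
    )
    pairs = [
        (int(matrix.years[i]), int(matrix.years[i + 1]))
        for i in range(matrix.n_years - 1)
    ]
    return DissimilaritySeries(
        site_id=matrix.site_id,
        pairs=pairs,
        values=values,
        sd_degenerate=len(values) < 2,
    )


def _running_mean(y: np.ndarray, span: float) -> np.ndarray:
    """Centred running mean over a fraction ``span`` of the points."""
    n = len(y)
    half = max(int(round(span * n / 2)), 1)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.nanmean(y[lo:hi])
    return out


def lag_profile(
    matrix: CommunityMatrix,
    smoother_span: float = 0.5,
    log_base: str | float = "e",
) -> LagProfile:
    """Dissimilarity as a function of year separation.

    All C(n_years, 2) pairs are computed, grouped by lag and smoothed with a
    running mean.  ``lag1_effect`` estimates how much lower the one-year-step
    dissimilarity is than the long-lag plateau (clamped at 0): the size of
    the short-range temporal autocorrelation.
    """
    if matrix.n_years < 3:
        raise ValidationError("lag_profile needs at least 3 years")
    z = log_transform(matrix.counts, base=log_base)
    n = matrix.n_years
    max_lag = n - 1
    sums = np.zeros(max_lag)
    cnts = np.zeros(max_lag, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            lag = j - i
            sums[lag - 1] += bray_curtis(z[i], z[j])
            cnts[lag - 1] += 1
    means = sums / cnts
    smoothed = _running_mean(means, smoother_span)
    # plateau = mean of the smoothed upper half of the lag range
    plateau = float(np.mean(smoothed[max_lag // 2:]))
    effect = max(plateau - float(smoothed[0]), 0.0)
    return LagProfile(
        site_id=matrix.site_id,
        lags=np.arange(1, max_lag + 1),
        mean_dissimilarity=means,
        smoothed=smoothed,
        lag1_effect=effect,
    )
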
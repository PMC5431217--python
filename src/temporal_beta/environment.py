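"""Environmental covariates from raw field-style records.

Bed disturbance from marked-stone surveys, substrate heterogeneity from
Wentworth-class quadrats, bryophyte cover, water temperature from logger
series, and connectivity as riffle area within a 500-m buffer, plus a
Spearman rank-consistency diagnostic for repeatedly measured covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .community_io import ValidationError

logger = logging.getLogger(__name__)

N_WENTWORTH_CLASSES = 10  # silt (0) .. large boulder / bedrock (9)


class Season(str, Enum):
    SPRING = "spring"
    SUMMER = "summer"


class SizeClass(str, Enum):
    P50 = "p50"
    P75 = "p75"
    P90 = "p90"


class Direction(str, Enum):
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"


@dataclass
class StoneMovementRecord:
    site_id: str
    period_id: str
    season: Season
    size_class: SizeClass
    n_stones: int
    n_moved: int

    def __post_init__(self) -> None:
        if self.n_stones <= 0:
            raise ValidationError(f"{self.site_id}/{self.period_id}: n_stones must be > 0")
        if not 0 <= self.n_moved <= self.n_stones:
            raise ValidationError(
                f"{self.site_id}/{self.period_id}: n_moved outside [0, n_stones]"
            )


@dataclass
class SubstrateQuadrat:
    site_id: str
    class_counts: np.ndarray  # counts over Wentworth classes 0..9

    def __post_init__(self) -> None:
        self.class_counts = np.asarray(self.class_counts, dtype=int)
        if self.class_counts.shape != (N_WENTWORTH_CLASSES,):
            raise ValidationError(
                f"{self.site_id}: quadrat needs {N_WENTWORTH_CLASSES} class counts"
            )
        if np.any(self.class_counts < 0) or self.class_counts.sum() == 0:
            raise ValidationError(f"{self.site_id}: quadrat counts invalid")


@dataclass
class RiffleSegment:
    site_id: str
    direction: Direction
    length: float  # m
    width: float  # m

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValidationError(f"{self.site_id}: riffle dimensions must be > 0")


# ---------------------------------------------------------------------------
# bed disturbance


def _period_percents(
    records: Sequence[StoneMovementRecord], site: str
) -> pd.Series:
    recs = [r for r in records if r.site_id == site]
    if not recs:
        raise ValidationError(f"no stone-movement records for site {site!r}")
    df = pd.DataFrame(
        {
            "period": [r.period_id for r in recs],
            "n_stones": [r.n_stones for r in recs],
            "n_moved": [r.n_moved for r in recs],
        }
    )
    # stones pooled over the three size classes within a monitoring period
    g = df.groupby("period", sort=True).sum(numeric_only=True)
    return 100.0 * g["n_moved"] / g["n_stones"]


def bed_movement_intensity(
    records: Sequence[StoneMovementRecord], site: str
) -> float:
    """BMI: mean percentage of stones moved per monitoring period."""
    return float(_period_percents(records, site).mean())


def bed_movement_frequency(
    records: Sequence[StoneMovementRecord], site: str, threshold: float = 20.0
) -> float:
    """Fraction of periods with strictly more than ``threshold`` % moved."""
    p = _period_percents(records, site)
    return float((p > threshold).mean())


def bed_movement_maximum(records: Sequence[StoneMovementRecord], site: str) -> float:
    return float(_period_percents(records, site).max())


# ---------------------------------------------------------------------------
# habitat structure


def simpson_substrate_diversity(
    quadrats: Sequence[SubstrateQuadrat], site: str, pooled: bool = True
) -> float:
    """Substrate Simpson diversity 1/D = 1 / sum(p_c^2).

    Quadrats are pooled by default before computing proportions; with
    ``pooled=False`` the per-quadrat indices are averaged instead.
    """
    qs = [q for q in quadrats if q.site_id == site]
    if not qs:
        raise ValidationError(f"no substrate quadrats for site {site!r}")

    def inv_d(counts: np.ndarray) -> float:
        p = counts / counts.sum()
        return float(1.0 / np.sum(p**2))

    if pooled:
        total = np.sum([q.class_counts for q in qs], axis=0)
        return inv_d(total)
    return float(np.mean([inv_d(q.class_counts) for q in qs]))


def mean_cover(values: Iterable[float]) -> float:
    """Mean of replicate percent-cover estimates (each in [0, 100])."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("mean_cover needs at least one value")
    if np.any((v < 0) | (v > 100)):
        raise ValidationError("cover values must lie in [0, 100]")
    return float(v.mean())


def mean_temperature(daily_means_by_year: Mapping[int, Sequence[float]]) -> float:
    """Mean water temperature: per-year mean of daily means, then mean of years."""
    if not daily_means_by_year:
        raise ValidationError("no temperature years supplied")
    yearly = []
    for year, days in daily_means_by_year.items():
        d = np.asarray(list(days), dtype=float)
        if d.size == 0:
            raise ValidationError(f"year {year}: no daily means")
        yearly.append(d.mean())
    return float(np.mean(yearly))


def connectivity_riffle_area(
    segments: Sequence[RiffleSegment], site: str
) -> float:
    """Riffle area (m^2) within the 500-m buffer, both directions summed."""
    segs = [s for s in segments if s.site_id == site]
    return float(sum(s.length * s.width for s in segs))


# ---------------------------------------------------------------------------
# diagnostics


def rank_consistency(values: np.ndarray | pd.DataFrame) -> float:
    """Mean pairwise Spearman correlation of site rankings across time points.

    ``values`` is a sites x time matrix of one covariate.  Average ranks are
    used for ties; a time point where all sites tie is skipped with a
    warning.  The statistic is invariant to monotone transforms of the
    covariate.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 2:
        raise ValidationError("rank_consistency needs >= 3 sites and >= 2 time points")
    rs = []
    for a in range(v.shape[1]):
        for b in range(a + 1, v.shape[1]):
            if np.ptp(v[:, a]) == 0 or np.ptp(v[:, b]) == 0:
                warnings.warn(
                    f"time-point pair ({a}, {b}) skipped: constant ranking",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            rs.append(spearmanr(v[:, a], v[:, b]).statistic)
    if not rs:
        raise ValidationError("all time-point pairs were constant")
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# tabular front-end


def environment_from_tables(
    stones: pd.DataFrame,
    quadrats: pd.DataFrame,
    bryophytes: pd.DataFrame,
    temperature: pd.DataFrame,
    riffles: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the six-predictor table (without gamma) from raw tables.

    Expected columns: stones(site, period, season, size_class, n_stones,
    n_moved); quadrats(site, class_0..class_9); bryophytes(site, quadrat,
    cover); temperature(site, year, daily_mean) or (site, date, daily_mean);
    riffles(site, direction, length_m, width_m).
    """
    stone_recs = [
        StoneMovementRecord(
            site_id=str(r.site),
            period_id=str(r.period),
            season=Season(str(r.season)),
            size_class=SizeClass(str(r.size_class)),
            n_stones=int(r.n_stones),
            n_moved=int(r.n_moved),
        )
        for r in stones.itertuples()
    ]
    class_cols = [f"class_{c}" for c in range(N_WENTWORTH_CLASSES)]
    quad_recs = [
        SubstrateQuadrat(str(r["site"]), r[class_cols].to_numpy())
        for _, r in quadrats.iterrows()
    ]
    riffle_recs = [
        RiffleSegment(str(r.site), Direction(str(r.direction)),
                      float(r.length_m), float(r.width_m))
        for r in riffles.itertuples()
    ]
    temp = temperature.copy()
    if "year" not in temp.columns:
        temp["year"] = pd.to_datetime(temp["date"]).dt.year
    sites = sorted(
        set(stones["site"].astype(str))
        | set(quadrats["site"].astype(str))
        | set(bryophytes["site"].astype(str))
    )
    rows = []
    for s in sites:
        t = temp[temp["site"].astype(str) == s]
        by_year = {int(y): g["daily_mean"].tolist() for y, g in t.groupby("year")}
        rows.append(
            {
                "site": s,
                "bmi": bed_movement_intensity(stone_recs, s),
                "bryophytes": mean_cover(
                    bryophytes.loc[bryophytes["site"].astype(str) == s, "cover"]
                ),
                "simpson": simpson_substrate_diversity(quad_recs, s),
                "temperature": mean_temperature(by_year),
                "connectivity": connectivity_riffle_area(riffle_recs, s),
            }
        )
    return pd.DataFrame(rows)
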
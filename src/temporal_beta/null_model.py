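"""Marginal-preserving null model for temporal beta diversity.

For one site the observed years x taxa matrix is randomized in two stages:

1. *Binary stage* — the presence/absence structure is shuffled by the
   curveball trade algorithm, which repeatedly swaps random subsets of the
   non-shared presences of two random rows.  Row sums (per-year richness,
   alpha), column sums (taxon frequencies), total fill and the set of
   occupied columns (site gamma) are all conserved, and at stationarity the
   chain samples uniformly from the fixed-marginals ensemble.
2. *Quantitative stage* — each row's observed total abundance is
   redistributed over that row's (randomized) presences: every present taxon
   receives one individual and the surplus is allocated multinomially with
   equal cell probabilities, so row totals are exact and every presence has
   count >= 1.

Each iteration yields the mean consecutive-year Bray-Curtis dissimilarity of
the log(x+1)-transformed null matrix.  The mean and SD of these per-iteration
means give the chance expectation (beta_exp, SD beta_exp), and the departure

    beta_dep = (beta_obs - beta_exp) / SD beta_exp

is a standardized effect size: beta_dep < -2 reads as "more stable (less
dissimilar among consecutive years) than expected by chance".
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .community_io import CommunityMatrix, ValidationError
from .diversity import consecutive_dissimilarities, log_transform

ALLOCATION_SCHEMES = ("multinomial_min1", "shuffle_nonzero")


class Stability(str, Enum):
    MORE_STABLE_THAN_CHANCE = "more_stable_than_chance"
    INDISTINGUISHABLE = "indistinguishable"


@dataclass
class NullConfig:
    """Configuration of the null engine.

    ``burn_in_trades``/``thin_trades`` default (when None) to
    ceil(10 * n_rows * ln(n_rows + 1)) and 2 * n_rows trades respectively;
    both are recorded in the run manifest.
    """

    n_iter: int = 1000
    burn_in_trades: Optional[int] = None
    thin_trades: Optional[int] = None
    seed: Optional[int] = None
    allocation_scheme: str = "multinomial_min1"
    log_base: str | float = "e"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        if self.burn_in_trades is not None and self.burn_in_trades < 0:
            raise ValidationError("burn_in_trades must be >= 0")
        if self.allocation_scheme not in ALLOCATION_SCHEMES:
            raise ValidationError(
                f"unknown allocation scheme {self.allocation_scheme!r}"
            )


@dataclass
class NullDistribution:
    """Null expectation and departure statistic for one site."""

    site_id: str
    beta_obs: float
    beta_exp_mean: float
    beta_exp_sd: float
    beta_dep: float
    n_iter: int
    degenerate: bool = False
    per_iteration_means: Optional[np.ndarray] = None


def default_burn_in(n_rows: int) -> int:
    return int(math.ceil(10.0 * n_rows * math.log(n_rows + 1.0)))


def default_thinning(n_rows: int) -> int:
    return 2 * n_rows


def site_rng(master_seed: int, site_id: str) -> np.random.Generator:
    """Independent, order-invariant random stream for one site.

    Derived from (master seed, CRC32 of the site id) so per-site results do
    not depend on how many or in what order other sites are processed.
    """
    h = zlib.crc32(str(site_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), h]))


# ---------------------------------------------------------------------------
# binary stage


def _curveball_inplace(P: np.ndarray, trades: int, rng: np.random.Generator) -> None:
    """Run ``trades`` curveball trades on boolean matrix ``P`` in place."""
    n_rows = P.shape[0]
    if n_rows < 2:
        return
    rows_i = rng.integers(0, n_rows, size=trades)
    rows_j = rng.integers(0, n_rows - 1, size=trades)
    rows_j = np.where(rows_j >= rows_i, rows_j + 1, rows_j)  # j != i
    for t in range(trades):
        i = rows_i[t]
        j = rows_j[t]
        ri = P[i]
        rj = P[j]
        diff = np.flatnonzero(ri != rj)
        if diff.size < 2:
            continue
        k = int(ri[diff].sum())  # presences exclusive to row i
        if k == 0 or k == diff.size:
            continue
        pick = rng.permutation(diff.size)[:k]
        ri[diff] = False
        rj[diff] = True
        sel = diff[pick]
        ri[sel] = True
        rj[sel] = False


def binary_randomize(
    presence: np.ndarray, trades: int, rng: np.random.Generator
) -> np.ndarray:
    """Curveball-randomize a binary matrix, preserving row and column sums.

    Returns a new matrix; the input is not modified.
    """
    if trades < 0:
        raise ValidationError("trades must be >= 0")
    P = np.asarray(presence).astype(bool)
    if P.ndim != 2:
        raise ValidationError("presence must be a 2-D binary matrix")
    if P.shape[0] and not P.any(axis=1).all():
        raise ValidationError("presence matrix has an all-zero row")
    P = P.copy()
    _curveball_inplace(P, trades, rng)
    return P


# ---------------------------------------------------------------------------
# quantitative stage


def allocate_abundances(
    row_totals: np.ndarray,
    presence: np.ndarray,
    scheme: str = "multinomial_min1",
    rng: Optional[np.random.Generator] = None,
    observed_values: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Distribute each row's total abundance over its presence cells.

    ``multinomial_min1`` (default): each presence cell receives 1 individual
    and the surplus ``N_i - k_i`` is allocated multinomially with equal cell
    probabilities, so row sums are preserved exactly.

    ``shuffle_nonzero``: permute ``observed_values`` (the matrix's observed
    non-zero abundances) over the presence cells of the whole matrix.  Row
    sums are then generally NOT preserved; a warning is issued.
    """
    rng = np.random.default_rng() if rng is None else rng
    P = np.asarray(presence).astype(bool)
    totals = np.asarray(row_totals, dtype=int)
    if totals.shape != (P.shape[0],):
        raise ValidationError("row_totals length must equal number of rows")
    k = P.sum(axis=1)
    out = np.zeros(P.shape, dtype=int)
    if scheme == "multinomial_min1":
        short = np.flatnonzero(totals < k)
        if short.size:
            raise ValidationError(
                f"rows {short.tolist()}: total abundance smaller than number of "
                "presences; cannot give every present taxon >= 1 individual"
            )
        for i in range(P.shape[0]):
            cells = np.flatnonzero(P[i])
            ki = cells.size
            if ki == 0:
                continue
            alloc = np.ones(ki, dtype=int)
            surplus = int(totals[i]) - ki
            if surplus > 0:
                alloc += rng.multinomial(surplus, np.full(ki, 1.0 / ki))
            out[i, cells] = alloc
        return out
    if scheme == "shuffle_nonzero":
        if observed_values is None:
            raise ValidationError("shuffle_nonzero needs the observed non-zero values")
        values = np.asarray(observed_values, dtype=int)
        n_cells = int(P.sum())
        if values.size != n_cells:
            raise ValidationError(
                f"shuffle_nonzero: {values.size} observed values for {n_cells} "
                "presence cells"
            )
        warnings.warn(
            "shuffle_nonzero does not preserve per-year abundance totals",
            UserWarning,
            stacklevel=2,
        )
        out[P] = rng.permutation(values)
        return out
    raise ValidationError(f"unknown allocation scheme {scheme!r}")


# ---------------------------------------------------------------------------
# departure statistic


def beta_departure(beta_obs: float, beta_exp_mean: float, beta_exp_sd: float) -> float:
    """Standardized effect size (beta_obs - beta_exp) / SD beta_exp.

    A zero SD (degenerate null ensemble) yields 0 by convention; callers flag
    that case explicitly.
    """
    if beta_exp_sd < 0:
        raise ValidationError("beta_exp_sd must be >= 0")
    if beta_exp_sd == 0:
        return 0.0
    return (beta_obs - beta_exp_mean) / beta_exp_sd


def classify_stability(beta_dep: float, threshold: float = -2.0) -> Stability:
    """Strict threshold: beta_dep < threshold means more stable than chance."""
    if not np.isfinite(beta_dep):
        raise ValidationError("beta_dep must be finite")
    if beta_dep < threshold:
        return Stability.MORE_STABLE_THAN_CHANCE
    return Stability.INDISTINGUISHABLE


# ---------------------------------------------------------------------------
# estimator


class TemporalBetaNull(BaseEstimator):
    """Null-model departure of temporal beta diversity for one site.

    A fit/attributes-style estimator over a single years x taxa count matrix.

    Parameters
    ----------
    n_iter : int, default 1000
        Number of null iterations.
    burn_in, thinning : int or None
        Curveball trades before the first iteration and between subsequent
        iterations (a thinned chain).  None selects the size-based defaults.
    allocation : {"multinomial_min1", "shuffle_nonzero"}
        Quantitative reallocation scheme.
    log_base : {"e", "10", "2"} or float
        Base of the log(x+1) transform applied after randomization.
    random_state : int, Generator or None
        Seed or generator for the trade and allocation stream.
    check_conservation : bool
        Assert marginal conservation on every iteration (test mode).

    Attributes
    ----------
    beta_obs_, beta_exp_mean_, beta_exp_sd_, beta_dep_ : float
    degenerate_ : bool
        True when the null SD was zero and beta_dep_ was set to 0.
    per_iteration_means_ : ndarray of shape (n_iter,)
    stability_ : Stability
    """

    def __init__(
        self,
        n_iter: int = 1000,
        burn_in: Optional[int] = None,
        thinning: Optional[int] = None,
        allocation: str = "multinomial_min1",
        log_base: str | float = "e",
        random_state=None,
        keep_iterations: bool = True,
        check_conservation: bool = False,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thinning = thinning
        self.allocation = allocation
        self.log_base = log_base
        self.random_state = random_state
        self.keep_iterations = keep_iterations
        self.check_conservation = check_conservation

    def _mean_consecutive_bc(self, z: np.ndarray) -> float:
        d = np.abs(np.diff(z, axis=0)).sum(axis=1)
        s = (z[1:] + z[:-1]).sum(axis=1)
        return float(np.mean(d / s))

    def fit(self, X, y=None):
        """Fit on a counts matrix (years x taxa) or a CommunityMatrix."""
        if isinstance(X, CommunityMatrix):
            counts = X.counts
            self.site_id_ = X.site_id
        else:
            counts = np.asarray(X, dtype=int)
            self.site_id_ = getattr(self, "site_id_", "")
            if counts.ndim != 2 or counts.shape[0] < 2:
                raise ValidationError("need a 2-D counts matrix with >= 2 rows")
            if np.any(counts < 0):
                raise ValidationError("counts must be non-negative")
        if np.any(counts.sum(axis=1) == 0):
            raise ValidationError("a year with zero total abundance is invalid")
        cfg = NullConfig(
            n_iter=self.n_iter,
            burn_in_trades=self.burn_in,
            thin_trades=self.thinning,
            allocation_scheme=self.allocation,
            log_base=self.log_base,
        )
        if isinstance(self.random_state, np.random.Generator):
            rng = self.random_state
        else:
            rng = np.random.default_rng(self.random_state)

        n_rows = counts.shape[0]
        burn = default_burn_in(n_rows) if cfg.burn_in_trades is None else cfg.burn_in_trades
        thin = default_thinning(n_rows) if cfg.thin_trades is None else cfg.thin_trades
        self.burn_in_ = burn
        self.thinning_ = thin

        z_obs = log_transform(counts, base=self.log_base)
        self.beta_obs_ = self._mean_consecutive_bc(z_obs)

        P = counts > 0
        row_totals = counts.sum(axis=1)
        obs_values = counts[P] if self.allocation == "shuffle_nonzero" else None
        row_sums0 = P.sum(axis=1)
        col_sums0 = P.sum(axis=0)

        Pn = P.copy()
        means = np.empty(cfg.n_iter)
        for it in range(cfg.n_iter):
            _curveball_inplace(Pn, burn if it == 0 else thin, rng)
            null_counts = allocate_abundances(
                row_totals, Pn, scheme=self.allocation, rng=rng,
                observed_values=obs_values,
            )
            if self.check_conservation:
                assert np.array_equal(Pn.sum(axis=1), row_sums0)
                assert np.array_equal(Pn.sum(axis=0), col_sums0)
                assert int(Pn.sum()) == int(P.sum())
                if self.allocation == "multinomial_min1":
                    assert np.array_equal(null_counts.sum(axis=1), row_totals)
            zn = log_transform(null_counts, base=self.log_base)
            means[it] = self._mean_consecutive_bc(zn)

        self.n_iter_ = cfg.n_iter
        self.beta_exp_mean_ = float(means.mean())
        self.beta_exp_sd_ = float(means.std(ddof=1)) if cfg.n_iter > 1 else 0.0
        self.degenerate_ = self.beta_exp_sd_ == 0.0
        self.beta_dep_ = beta_departure(
            self.beta_obs_, self.beta_exp_mean_, self.beta_exp_sd_
        )
        self.stability_ = classify_stability(self.beta_dep_)
        self.per_iteration_means_ = means if self.keep_iterations else None
        return self


def null_distribution(matrix: CommunityMatrix, cfg: NullConfig) -> NullDistribution:
    """Run the null engine on one site under a NullConfig (thin wrapper)."""
    est = TemporalBetaNull(
        n_iter=cfg.n_iter,
        burn_in=cfg.burn_in_trades,
        thinning=cfg.thin_trades,
        allocation=cfg.allocation_scheme,
        log_base=cfg.log_base,
        random_state=cfg.seed,
    ).fit(matrix)
    # cross-check the vectorized observed beta against the reference path
    assert math.isclose(
        est.beta_obs_,
        consecutive_dissimilarities(matrix, log_base=cfg.log_base).mean,
        rel_tol=1e-12,
    )
    return NullDistribution(
        site_id=matrix.site_id,
        beta_obs=est.beta_obs_,
        beta_exp_mean=est.beta_exp_mean_,
        beta_exp_sd=est.beta_exp_sd_,
        beta_dep=est.beta_dep_,
        n_iter=est.n_iter_,
        degenerate=est.degenerate_,
        per_iteration_means=est.per_iteration_means_,
    )
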
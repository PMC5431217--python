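"""Exhaustive-subset OLS with AICc multimodel inference.

Every subset of the candidate predictors (2^p models including the
intercept-only model; 64 for the six study predictors) is fit by ordinary
least squares on z-scored response and predictors.  Models are ranked by
AICc; Akaike weights give each model's relative support, and a predictor's
importance is the summed weight of all models containing it.  Running the
same selection twice — once with the observed beta diversity and once with
the null departure as response — contrasts drivers acting through
stochastic channels (importance collapses under the second response) with
deterministic ones (importance persists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .community_io import ValidationError


@dataclass
class CandidateModel:
    """One fitted predictor subset."""

    variables: tuple[str, ...]
    coefficients: dict[str, float]
    rss: float
    k_params: int  # slopes + intercept + residual variance
    aicc: float
    adj_r2: float
    delta: float = math.nan
    weight: float = math.nan


@dataclass
class ModelSelectionResult:
    """All candidate models plus derived importance values."""

    models: list[CandidateModel]
    importance: pd.Series
    response_label: str = ""
    importance_threshold: float = 0.80
    delta_threshold: float = 2.0

    @property
    def best_set(self) -> list[CandidateModel]:
        return best_models(self, self.delta_threshold)

    @property
    def important(self) -> pd.Series:
        return self.importance >= self.importance_threshold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.models, key=lambda m: m.delta):
            row = {"variables": "+".join(m.variables) or "(intercept)"}
            row.update({v: m.coefficients.get(v, math.nan) for v in self.importance.index})
            row.update(
                {"adj_r2": m.adj_r2, "aicc": m.aicc, "delta": m.delta, "weight": m.weight}
            )
            rows.append(row)
        return pd.DataFrame(rows)


def standardize(y: np.ndarray, X: pd.DataFrame | np.ndarray):
    """Center to mean 0 and scale to SD 1 (n-1 denominator), column-wise."""
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    if len(y) < 3:
        raise ValidationError("need at least 3 observations")
    sds = Xv.std(axis=0, ddof=1)
    zero = [names[j] for j in np.flatnonzero(sds == 0)]
    if zero:
        raise ValidationError(f"zero-variance predictors: {zero}")
    if y.std(ddof=1) == 0:
        raise ValidationError("zero-variance response")
    Xz = (Xv - Xv.mean(axis=0)) / sds
    yz = (y - y.mean()) / y.std(ddof=1)
    return yz, pd.DataFrame(Xz, columns=names)


def _gaussian_aicc(rss: float, n: int, k: int) -> float:
    """AICc from the profile Gaussian log-likelihood; k counts the intercept
    and the residual variance in addition to the slopes."""
    llf = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


class AICcAllSubsets(BaseEstimator):
    """All-subsets OLS with AICc ranking, Akaike weights and importance.

    Parameters
    ----------
    delta_threshold : float, default 2.0
        Delta-AICc bound for the "equal support" best-model set.
    importance_threshold : float, default 0.80
        Summed-weight bound above which a predictor is called important.
    standardize : bool, default True
        Z-score the response and predictors before fitting, so slopes are
        standardized regression coefficients.

    Attributes
    ----------
    models_ : list of CandidateModel (2^p entries)
    importance_ : pd.Series indexed by predictor
    weights_ : ndarray of Akaike weights (sum to 1)
    best_models_ : models with delta < delta_threshold, sorted by delta
    feature_names_in_ : list of predictor names
    """

    def __init__(
        self,
        delta_threshold: float = 2.0,
        importance_threshold: float = 0.80,
        standardize: bool = True,
    ):
        self.delta_threshold = delta_threshold
        self.importance_threshold = importance_threshold
        self.standardize = standardize

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y, dtype=float)
        n, p = Xv.shape
        if len(y) != n:
            raise ValidationError("X and y lengths differ")
        k_max = p + 2
        if n <= k_max + 1:
            raise ValidationError(
                f"n = {n} too small for the largest model (needs n > {k_max + 1})"
            )
        if self.standardize:
            y, Xdf = standardize(y, pd.DataFrame(Xv, columns=names))
            Xv = Xdf.to_numpy()
        full = np.column_stack([np.ones(n), Xv])
        if np.linalg.matrix_rank(full) < p + 1:
            corr = np.corrcoef(Xv, rowvar=False)
            pairs = [
                (names[a], names[b])
                for a in range(p)
                for b in range(a + 1, p)
                if abs(corr[a, b]) > 1 - 1e-10
            ]
            raise ValidationError(f"singular design; collinear predictors: {pairs}")

        models: list[CandidateModel] = []
        for size in range(p + 1):
            for subset in combinations(range(p), size):
                cols = np.column_stack([np.ones(n)] + [Xv[:, j] for j in subset])
                beta, _, _, _ = np.linalg.lstsq(cols, y, rcond=None)
                resid = y - cols @ beta
                rss = float(resid @ resid)
                tss = float(((y - y.mean()) ** 2).sum())
                k = len(subset) + 2
                n_slopes = len(subset)
                adj_r2 = 1.0 - (rss / (n - n_slopes - 1)) / (tss / (n - 1))
                models.append(
                    CandidateModel(
                        variables=tuple(names[j] for j in subset),
                        coefficients={
                            names[j]: float(beta[i + 1]) for i, j in enumerate(subset)
                        },
                        rss=rss,
                        k_params=k,
                        aicc=_gaussian_aicc(rss, n, k),
                        adj_r2=adj_r2,
                    )
                )
        aiccs = np.array([m.aicc for m in models])
        deltas = aiccs - aiccs.min()
        w = np.exp(-deltas / 2.0)
        w /= w.sum()
        for m, d, wi in zip(models, deltas, w):
            m.delta = float(d)
            m.weight = float(wi)
        self.models_ = models
        self.weights_ = w
        self.feature_names_in_ = names
        imp = {
            v: float(sum(m.weight for m in models if v in m.variables)) for v in names
        }
        self.importance_ = pd.Series(imp, name="importance")
        self.best_models_ = sorted(
            (m for m in models if m.delta < self.delta_threshold),
            key=lambda m: m.delta,
        )
        return self

    def result(self, response_label: str = "") -> ModelSelectionResult:
        return ModelSelectionResult(
            models=self.models_,
            importance=self.importance_,
            response_label=response_label,
            importance_threshold=self.importance_threshold,
            delta_threshold=self.delta_threshold,
        )


def fit_all_subsets(
    y: Sequence[float] | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    response_label: str = "",
    delta_threshold: float = 2.0,
    importance_threshold: float = 0.80,
) -> ModelSelectionResult:
    """Fit every predictor subset and return the ranked result table."""
    est = AICcAllSubsets(
        delta_threshold=delta_threshold,
        importance_threshold=importance_threshold,
    ).fit(X, y)
    return est.result(response_label)


def variable_importance(result: ModelSelectionResult) -> pd.DataFrame:
    """Per-variable summed Akaike weight with the importance flag."""
    return pd.DataFrame(
        {
            "variable": result.importance.index,
            "importance": result.importance.to_numpy(),
            "important": (result.importance >= result.importance_threshold).to_numpy(),
        }
    )


def best_models(
    result: ModelSelectionResult, delta_threshold: float = 2.0
) -> list[CandidateModel]:
    """Models with delta AICc strictly below the threshold, sorted by delta."""
    if delta_threshold <= 0:
        raise ValidationError("delta_threshold must be > 0")
    return sorted(
        (m for m in result.models if m.delta < delta_threshold),
        key=lambda m: m.delta,
    )
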
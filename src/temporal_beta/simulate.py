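"""Synthetic multi-year stream-community datasets with known structure.

The generator emulates the shape of a boreal-stream macroinvertebrate
monitoring series — a ~129-taxon regional pool, per-site totals of 50-81
taxa across years, per-year richness around 25-40, strongly skewed
abundances and year-to-year persistence — while wiring two covariates to
community variability through two deliberately different channels:

* a *stabilizer* covariate (bryophyte-like, V1) acts deterministically, i.e.
  in a species-identity-dependent way: it raises the occupancy persistence
  of individual taxa in proportion to a fixed per-taxon trait, and it
  strengthens the year-to-year memory of resident populations' abundances
  (the AR(1) coefficient of log abundance).  Both create temporal structure
  beyond what the marginal totals imply, so the channel moves the null
  departure beta_dep as well as the observed dissimilarity.
* an *immigration/recruitment* covariate (connectivity-like, V2) acts
  stochastically, i.e. identity-free: it controls how unstable the annual
  recruitment lottery is.  Each year a random, identity-free fraction of
  that year's community fails to recruit (is thinned), and the amplitude of
  that fraction shrinks with connectivity — well-connected sites receive a
  steady propagule supply, weakly connected sites have boom-and-bust years.
  Thinning changes per-year richness and totals, which the null model
  conditions on, so observed and expected dissimilarity rise together and
  beta_dep is left largely untouched.

The expected analysis outcome on default settings is therefore the headline
contrast: the connectivity-like covariate matters for observed beta
diversity (weakly connected sites more variable), and the bryophyte-like
covariate dominates once the null departure is the response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .community_io import (
    CommunityMatrix,
    EnvironmentTable,
    StudyDataset,
    ValidationError,
)

# observed-covariate scales: latent ~ N(0,1) mapped onto field-realistic units
_COVARIATE_MAPS = {
    "bmi": (12.0, 7.0, 0.0, 100.0),  # loc, scale, lo, hi
    "bryophytes": (35.0, 18.0, 0.0, 100.0),
    "simpson": (4.0, 1.2, 1.0, np.inf),
    "temperature": (9.0, 1.5, -np.inf, np.inf),
    "connectivity": (900.0, 350.0, 50.0, np.inf),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study generator.

    Defaults reproduce the study conditions: 23 sites, 14 consecutive
    years, a 129-taxon regional pool, site taxon totals of 50-81 and
    per-year richness in the 25-40 band.
    """

    n_sites: int = 23
    n_years: int = 14
    pool_size: int = 129
    site_gamma_range: tuple[int, int] = (50, 81)
    target_alpha: tuple[int, int] = (25, 40)
    first_year: int = 2000

    # occupancy dynamics of the persistent core
    persistence_base: float = 0.72
    recolonization_base: float = 0.22
    stabilizer_effect: float = 0.5

    # identity-free channels
    immigration_base: float = 6.0  # expected single-year transient colonists/yr
    recruitment_variability: float = 0.25  # max annual thinning fraction at V2 = 0
    connectivity_effect: float = 0.75  # how strongly V2 damps the thinning

    # abundances (log scale)
    abundance_mu: float = 1.6
    abundance_sigma: float = 1.0
    ar1_rho: float = 0.5
    ar1_rho_slope: float = 0.35  # stabilizer effect on abundance memory

    stabilizer_covariate: str = "bryophytes"
    immigration_covariate: str = "connectivity"
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.persistence_base, self.recolonization_base,
                  self.recruitment_variability):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities/fractions must lie in [0, 1]")
        lo, hi = self.site_gamma_range
        if lo > hi or self.pool_size < hi:
            raise ValidationError("pool_size must cover the gamma range")
        if self.target_alpha[0] > self.target_alpha[1]:
            raise ValidationError("target_alpha range must be ordered")
        if self.n_years < 2 or self.n_sites < 1:
            raise ValidationError("need n_years >= 2 and n_sites >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("site_gamma_range", "target_alpha"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_swapped_channels(self) -> "SyntheticConfig":
        """Exchange the stabilizer and immigration covariates (symmetry
        check: the expected importance pattern swaps with them)."""
        return replace(
            self,
            stabilizer_covariate=self.immigration_covariate,
            immigration_covariate=self.stabilizer_covariate,
        )


def _pool_traits(cfg: SyntheticConfig) -> np.ndarray:
    """Fixed per-taxon stabilizer responsiveness for the regional pool.

    Half-normal, so a site-level stabilizer value shifts mean persistence
    monotonically (required for linear recovery of the channel).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7A17]))
    return np.abs(rng.normal(size=cfg.pool_size))


def _observed_covariate(name: str, latent: float, noise: float) -> float:
    loc, scale, lo, hi = _COVARIATE_MAPS[name]
    return float(np.clip(loc + scale * (latent + noise), lo, hi))


def generate_site(
    cfg: SyntheticConfig,
    site_index: int,
    rng: np.random.Generator,
    traits: Optional[np.ndarray] = None,
) -> tuple[CommunityMatrix, dict[str, float]]:
    """Generate one site's community matrix and its covariate row.

    Returns the matrix (taxa observed at least once at the site) and a dict
    with the five observed covariates plus the latent channel values.
    """
    if traits is None:
        traits = _pool_traits(cfg)
    latents = {name: float(rng.normal()) for name in _COVARIATE_MAPS}
    z_stab = latents[cfg.stabilizer_covariate]
    z_imm = latents[cfg.immigration_covariate]

    gamma_target = int(
        rng.integers(cfg.site_gamma_range[0], cfg.site_gamma_range[1] + 1)
    )
    pool_idx = rng.choice(cfg.pool_size, size=gamma_target, replace=False)
    t = traits[pool_idx]

    # identity-dependent persistence and abundance memory (stabilizer channel)
    p = expit(logit(cfg.persistence_base) + cfg.stabilizer_effect * z_stab * t)
    r = cfg.recolonization_base
    rho = float(np.clip(cfg.ar1_rho + cfg.ar1_rho_slope * z_stab, 0.0, 1.0))

    # identity-free channels (immigration/recruitment)
    lam = cfg.immigration_base
    drop_amp = float(
        np.clip(
            cfg.recruitment_variability * np.exp(-cfg.connectivity_effect * z_imm),
            0.0,
            0.5,
        )
    )

    n_years, g = cfg.n_years, gamma_target
    occ = np.zeros((n_years, g), dtype=bool)  # persistent-core occupancy
    pi0 = r / (r + 1.0 - p) if r > 0 else np.full(g, cfg.persistence_base)
    occ[0] = rng.random(g) < pi0
    for y in range(1, n_years):
        stay = occ[y - 1] & (rng.random(g) < p)
        arrive = ~occ[y - 1] & (rng.random(g) < r)
        occ[y] = stay | arrive

    counts = np.zeros((n_years, g), dtype=int)
    log_ab = np.full(g, np.nan)
    mu, sig = cfg.abundance_mu, cfg.abundance_sigma
    for y in range(n_years):
        row = occ[y]
        fresh = row & (np.isnan(log_ab) | (~occ[y - 1] if y else True))
        persist = row & ~fresh
        log_ab[fresh] = rng.normal(mu, sig, size=int(fresh.sum()))
        if persist.any():
            innov = rng.normal(size=int(persist.sum()))
            log_ab[persist] = (
                mu * (1 - rho)
                + rho * log_ab[persist]
                + sig * np.sqrt(1 - rho**2) * innov
            )
        counts[y, row] = np.maximum(1, np.round(np.exp(log_ab[row])).astype(int))

        # identity-free transient colonists, present this year only
        available = np.flatnonzero(~row)
        m = min(int(rng.poisson(lam)), available.size)
        if m > 0:
            chosen = rng.choice(available, size=m, replace=False)
            trans = np.exp(rng.normal(mu, sig, size=m))
            counts[y, chosen] = np.maximum(1, np.round(trans).astype(int))

        # identity-free recruitment lottery: a random fraction of this
        # year's community fails to appear
        d_t = rng.uniform(0.0, drop_amp)
        present = np.flatnonzero(counts[y] > 0)
        k = int(round(d_t * present.size))
        if k and present.size - k >= 3:
            counts[y, rng.choice(present, size=k, replace=False)] = 0
        if counts[y].sum() == 0:  # pathological configs only
            counts[y, int(rng.integers(g))] = 1

    taxa = [f"t{int(i):03d}" for i in pool_idx]
    order = np.argsort(taxa)
    matrix = CommunityMatrix(
        site_id=f"S{site_index + 1:02d}",
        years=np.arange(cfg.first_year, cfg.first_year + n_years),
        taxa=[taxa[j] for j in order],
        counts=counts[:, order],
    )
    cov = {
        name: _observed_covariate(name, z, float(rng.normal(0.0, cfg.noise_sd)))
        for name, z in latents.items()
    }
    cov.update({f"latent_{k}": v for k, v in latents.items()})
    return matrix, cov


def generate_dataset(cfg: SyntheticConfig) -> StudyDataset:
    """Generate a full study dataset; bit-identical for a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xDA7A]))
    traits = _pool_traits(cfg)
    matrices = []
    rows = []
    for i in range(cfg.n_sites):
        m, cov = generate_site(cfg, i, rng, traits=traits)
        matrices.append(m)
        rows.append(
            {
                "site": m.site_id,
                **{k: v for k, v in cov.items() if not k.startswith("latent_")},
                "gamma": m.gamma,
            }
        )
    env = EnvironmentTable(pd.DataFrame(rows))
    pool = sorted({t for m in matrices for t in m.taxa})
    return StudyDataset(matrices=matrices, environment=env, regional_pool=pool)
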
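"""Reading, validating and writing community matrices and environment tables.

The unit of every downstream computation is a single site's years x taxa
count matrix (one pooled sample per site-year).  Long "tidy" files with
columns ``site, year, taxon, count`` are the canonical interchange format;
a wide per-site years x taxa table is accepted as a secondary reader.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENV_PREDICTORS = [
    "bmi",
    "bryophytes",
    "simpson",
    "temperature",
    "connectivity",
    "gamma",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class CommunityMatrix:
    """One site's years x taxa abundance matrix.

    Parameters
    ----------
    site_id
        Site identifier.
    years
        Strictly increasing, consecutive calendar years (one row each).
    taxa
        Taxon identifiers (one column each), unique, lexicographically
        ordered on construction via :meth:`from_records`.
    counts
        Non-negative integer abundances, shape ``(len(years), len(taxa))``.
    """

    site_id: str
    years: np.ndarray
    taxa: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts)
        if self.years.ndim != 1 or len(self.years) < 2:
            raise ValidationError(
                f"site {self.site_id!r}: need at least 2 years, got {len(self.years)}"
            )
        if len(set(self.years.tolist())) != len(self.years) or np.any(
            np.diff(self.years) <= 0
        ):
            raise ValidationError(
                f"site {self.site_id!r}: years must be strictly increasing without duplicates"
            )
        if np.any(np.diff(self.years) != 1):
            missing = [
                y
                for y in range(int(self.years[0]), int(self.years[-1]) + 1)
                if y not in set(self.years.tolist())
            ]
            raise ValidationError(
                f"site {self.site_id!r}: years must be consecutive; missing {missing}"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"site {self.site_id!r}: duplicate taxon identifiers")
        if self.counts.shape != (len(self.years), len(self.taxa)):
            raise ValidationError(
                f"site {self.site_id!r}: counts shape {self.counts.shape} does not "
                f"match {len(self.years)} years x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.round(self.counts).astype(int)
            if not np.allclose(self.counts, as_int):
                raise ValidationError(
                    f"site {self.site_id!r}: counts must be integers"
                )
            self.counts = as_int
        if np.any(self.counts < 0):
            raise ValidationError(f"site {self.site_id!r}: negative counts")
        # All-zero taxon columns carry no information for this site.
        occupied = self.counts.sum(axis=0) > 0
        if not occupied.all():
            dropped = [t for t, keep in zip(self.taxa, occupied) if not keep]
            logger.warning(
                "site %r: dropping %d all-zero taxon columns: %s",
                self.site_id,
                len(dropped),
                dropped,
            )
            self.taxa = [t for t, keep in zip(self.taxa, occupied) if keep]
            self.counts = self.counts[:, occupied]
        if len(self.taxa) == 0:
            raise ValidationError(f"site {self.site_id!r}: no non-zero taxa")

    # -- diversity summaries -------------------------------------------------

    @property
    def n_years(self) -> int:
        return len(self.years)

    def alpha(self) -> np.ndarray:
        """Per-year taxon richness (number of non-zero cells per row)."""
        return (self.counts > 0).sum(axis=1)

    @property
    def gamma(self) -> int:
        """Total number of taxa recorded at this site across all years."""
        return int((self.counts.sum(axis=0) > 0).sum())

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_records(
        cls, site_id: str, records: Iterable[tuple[int, str, int]]
    ) -> "CommunityMatrix":
        """Build a matrix from ``(year, taxon, count)`` records.

        Absent (year, taxon) combinations are zero; taxa are ordered
        lexicographically so the result is independent of record order.
        """
        recs = list(records)
        years = sorted({int(y) for y, _, _ in recs})
        taxa = sorted({t for _, t, _ in recs})
        yi = {y: i for i, y in enumerate(years)}
        ti = {t: j for j, t in enumerate(taxa)}
        counts = np.zeros((len(years), len(taxa)), dtype=int)
        for y, t, c in recs:
            counts[yi[int(y)], ti[t]] = c
        return cls(site_id=site_id, years=np.array(years), taxa=taxa, counts=counts)

    def to_long(self) -> pd.DataFrame:
        """Long-format frame of the non-zero cells (``site,year,taxon,count``)."""
        rows = []
        for i, y in enumerate(self.years):
            for j, t in enumerate(self.taxa):
                c = int(self.counts[i, j])
                if c > 0:
                    rows.append((self.site_id, int(y), t, c))
        return pd.DataFrame(rows, columns=["site", "year", "taxon", "count"])


@dataclass
class EnvironmentTable:
    """Per-site covariate table with one row per site.

    Columns: bed-movement intensity (``bmi``, percent), ``bryophytes``
    (percent cover), ``simpson`` (substrate Simpson 1/D, >= 1),
    ``temperature`` (deg C), ``connectivity`` (m^2 riffle area within a
    500-m buffer), and ``gamma`` (site total taxon richness).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "site" in df.columns:
            df = df.set_index("site")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicated site rows: {dups}")
        missing_cols = [c for c in ENV_PREDICTORS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"environment table missing columns: {missing_cols}")
        df = df[ENV_PREDICTORS].astype(float)
        bad = df.isna()
        if bad.to_numpy().any():
            cells = [
                f"({site}, {col})"
                for site in df.index
                for col in df.columns
                if bad.loc[site, col]
            ]
            raise ValidationError(f"missing environment values at cells: {cells}")
        if len(df) == 0:
            raise ValidationError("environment table is empty")
        self.data = df

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    def predictors(self) -> pd.DataFrame:
        return self.data[ENV_PREDICTORS]


@dataclass
class StudyDataset:
    """Community matrices plus their matching environment table."""

    matrices: list[CommunityMatrix]
    environment: EnvironmentTable
    regional_pool: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        mat_sites = {m.site_id for m in self.matrices}
        env_sites = set(self.environment.sites)
        if mat_sites != env_sites:
            raise ValidationError(
                f"site mismatch between matrices and environment: "
                f"only-matrices={sorted(mat_sites - env_sites)}, "
                f"only-environment={sorted(env_sites - mat_sites)}"
            )
        for m in self.matrices:
            env_gamma = self.environment.data.loc[m.site_id, "gamma"]
            if int(round(env_gamma)) != m.gamma:
                raise ValidationError(
                    f"site {m.site_id!r}: environment gamma {env_gamma} != "
                    f"matrix gamma {m.gamma}"
                )
        if not self.regional_pool:
            pool: set[str] = set()
            for m in self.matrices:
                pool.update(m.taxa)
            self.regional_pool = sorted(pool)

    @property
    def sites(self) -> list[str]:
        return [m.site_id for m in self.matrices]


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"empty file: {path}")
    sep = delimiter if delimiter is not None else None
    # sep=None triggers python-engine sniffing across comma/tab/semicolon
    return pd.read_csv(path, sep=sep, engine="python")


def read_community_long(
    path: str | Path,
    delimiter: str | None = None,
    exclude_taxa: Sequence[str] = (),
) -> list[CommunityMatrix]:
    """Read a long-format community file into one matrix per site.

    The file must have columns ``site, year, taxon, count``.  Duplicate
    (site, year, taxon) rows, negative or non-integer counts, and gaps in a
    site's year sequence are all hard errors.  ``exclude_taxa`` drops the
    named taxa before pivoting (e.g. groups not counted in every year).
    """
    df = _read_table(path, delimiter)
    required = ["site", "year", "taxon", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"community file missing columns: {missing}")
    df = df[required].copy()
    if exclude_taxa:
        df = df[~df["taxon"].astype(str).isin(set(exclude_taxa))]
    dup = df.duplicated(subset=["site", "year", "taxon"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise ValidationError(f"duplicate (site, year, taxon) rows at lines {rows}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        rows = (df.index[bad] + 2).tolist()
        raise ValidationError(
            f"counts must be non-negative integers; offending lines {rows}"
        )
    df["count"] = counts.astype(int)
    matrices = []
    for site, grp in df.groupby("site", sort=True):
        matrices.append(
            CommunityMatrix.from_records(
                str(site),
                grp[["year", "taxon", "count"]].itertuples(index=False, name=None),
            )
        )
    return matrices


def read_community_wide(
    path: str | Path, site_id: str, delimiter: str | None = None
) -> CommunityMatrix:
    """Read one site's wide years x taxa table (first column = year)."""
    df = _read_table(path, delimiter)
    year_col = df.columns[0]
    years = df[year_col].astype(int).to_numpy()
    taxa = [str(c) for c in df.columns[1:]]
    counts = df[df.columns[1:]].to_numpy()
    order = np.argsort(taxa)
    return CommunityMatrix(
        site_id=site_id,
        years=years,
        taxa=[taxa[j] for j in order],
        counts=counts[:, order],
    )


def read_environment(path: str | Path, delimiter: str | None = None) -> EnvironmentTable:
    """Read and validate the per-site environment table.

    Expects columns ``site, bmi, bryophytes, simpson, temperature,
    connectivity, gamma``; ``gamma`` may instead be attached later from the
    community matrices via :func:`attach_gamma`.
    """
    df = _read_table(path, delimiter)
    if "site" not in df.columns:
        raise ValidationError("environment file must have a 'site' column")
    if "gamma" not in df.columns:
        df = df.assign(gamma=np.nan)
    logger.info(
        "environment units: bmi %%, bryophytes %%, simpson 1/D, temperature degC, "
        "connectivity m^2, gamma taxa"
    )
    return EnvironmentTable(df)


def attach_gamma(
    env: pd.DataFrame, matrices: Sequence[CommunityMatrix]
) -> EnvironmentTable:
    """Fill the ``gamma`` column from community matrices and validate."""
    df = env.copy()
    if "site" in df.columns:
        df = df.set_index("site")
    gammas = {m.site_id: m.gamma for m in matrices}
    df["gamma"] = [gammas.get(str(s), np.nan) for s in df.index]
    df.index.name = "site"
    return EnvironmentTable(df.reset_index())


# ---------------------------------------------------------------------------
# writers


def write_community_long(matrices: Sequence[CommunityMatrix], path: str | Path) -> None:
    frames = [m.to_long() for m in matrices]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_environment(env: EnvironmentTable, path: str | Path) -> None:
    env.data.reset_index().rename(columns={"index": "site"}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  manifest: dict | None = None) -> list[Path]:
    """Write result tables as TSV plus an optional JSON run manifest.

    ``tables`` maps a basename (without extension) to a frame; an empty
    mapping or an empty frame is an error so a truncated run cannot silently
    produce an empty results directory.
    """
    if not tables:
        raise ValidationError("no result tables to write")
    for name, df in tables.items():
        if len(df) == 0:
            raise ValidationError(f"result table {name!r} is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        written.append(p)
    if manifest is not None:
        p = out / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(p)
    return written
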
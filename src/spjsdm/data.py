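"""Community data container and CSV ingestion.

A community data set couples four site/species-aligned tables:

* ``Y`` — the site x species response matrix (presence-absence 0/1 or a
  continuous measurement),
* ``X`` — the site x covariate design matrix (first column constant 1),
* ``S`` — site coordinates in 2-D Euclidean units,
* ``T`` — an optional species x trait design matrix (first column 1).

All spatial computations in this package treat coordinates as planar
Euclidean; no CRS or great-circle handling is performed.  Project
geographic coordinates before loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CommunityData", "read_community", "write_community"]


class DataValidationError(ValueError):
    """Raised when input tables violate the model's data contract."""


@dataclass
class CommunityData:
    """Aligned response, covariate, coordinate and trait tables.

    Parameters
    ----------
    Y : (n_sites, n_species) ndarray
        Responses; 0/1 for probit species, real-valued for Gaussian species.
    X : (n_sites, n_covariates) ndarray
        Covariate design matrix; column 0 is the intercept (all ones).
    S : (n_sites, 2) ndarray
        Site coordinates (Euclidean).
    T : (n_species, n_traits) ndarray, optional
        Trait design matrix; column 0 is the intercept.  When omitted it
        defaults to a single intercept column, in which case the trait
        regression reduces to a shared prior mean for the rows of beta.
    species_names, site_ids : list of str
        Identifier lists; defaulted to ``sp<j>`` / ``site<i>`` if omitted.
    """

    Y: np.ndarray
    X: np.ndarray
    S: np.ndarray
    T: np.ndarray | None = None
    species_names: list[str] = field(default_factory=list)
    site_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.Y.ndim != 2:
            raise DataValidationError("Y must be a 2-D site x species matrix")
        n_y, n_s = self.Y.shape
        if self.X.ndim != 2 or self.X.shape[0] != n_y:
            raise DataValidationError(
                f"X has {self.X.shape[0]} rows but Y has {n_y} sites"
            )
        if self.S.shape != (n_y, 2):
            raise DataValidationError(
                f"S must be (n_sites, 2); got {self.S.shape} with n_sites={n_y}"
            )
        if self.T is None:
            self.T = np.ones((n_s, 1))
        else:
            self.T = np.asarray(self.T, dtype=float)
            if self.T.ndim != 2 or self.T.shape[0] != n_s:
                raise DataValidationError(
                    f"T has {self.T.shape[0]} rows but Y has {n_s} species"
                )
        if np.isnan(self.Y).any():
            raise DataValidationError(
                "Y contains missing values; the sampler requires complete "
                "responses (imputation would change the likelihood)"
            )
        for name, M in (("X", self.X), ("S", self.S), ("T", self.T)):
            if not np.isfinite(M).all():
                raise DataValidationError(f"{name} contains non-finite values")
        if not self.species_names:
            self.species_names = [f"sp{j}" for j in range(n_s)]
        if not self.site_ids:
            self.site_ids = [f"site{i}" for i in range(n_y)]
        if len(self.species_names) != n_s:
            raise DataValidationError("species_names length mismatch")
        if len(self.site_ids) != n_y:
            raise DataValidationError("site_ids length mismatch")

    @property
    def n_sites(self) -> int:
        return self.Y.shape[0]

    @property
    def n_species(self) -> int:
        return self.Y.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_traits(self) -> int:
        return self.T.shape[1]

    def validate_bernoulli(self, species: np.ndarray | None = None) -> None:
        """Check that the given species columns (default: all) are 0/1."""
        cols = np.arange(self.n_species) if species is None else np.asarray(species)
        sub = self.Y[:, cols]
        if not np.isin(sub, (0.0, 1.0)).all():
            bad = np.unique(sub[~np.isin(sub, (0.0, 1.0))])[:5]
            raise DataValidationError(
                f"Bernoulli responses must be 0/1; found values {bad.tolist()}"
            )


def _read_indexed_csv(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataValidationError(f"duplicate {what} ids in {path}: {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric cells in {path}: {exc}") from exc
    if df.isna().any().any():
        raise DataValidationError(f"missing values in {path}")
    return df


def _align(df: pd.DataFrame, ids, what: str, path) -> pd.DataFrame:
    missing = [i for i in ids if i not in df.index]
    if missing:
        raise DataValidationError(
            f"{what} ids missing from {path}: {missing[:5]}"
            + (" ..." if len(missing) > 5 else "")
        )
    return df.loc[list(ids)]


def read_community(y_path, x_path, s_path, t_path=None) -> CommunityData:
    """Load aligned community tables from CSV files.

    Every file carries a header row; the first column holds site ids
    (``Y``, ``X``, ``S``) or species ids (``T``).  The coordinate table
    must provide columns named ``x`` and ``y``.  Site and species order
    is taken from ``Y``; the other tables are reindexed to match, and
    unmatched ids raise a descriptive error.
    """
    ydf = pd.read_csv(y_path, index_col=0)
    ydf.index = ydf.index.astype(str)
    if ydf.index.duplicated().any():
        raise DataValidationError(f"duplicate site ids in {y_path}")
    try:
        ydf = ydf.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric cells in {y_path}: {exc}") from exc
    if ydf.isna().any().any():
        raise DataValidationError(f"missing responses in {y_path}")
    site_ids = list(ydf.index)
    species = [str(c) for c in ydf.columns]

    xdf = _align(_read_indexed_csv(x_path, "site"), site_ids, "site", x_path)
    sdf = _align(_read_indexed_csv(s_path, "site"), site_ids, "site", s_path)
    for col in ("x", "y"):
        if col not in sdf.columns:
            raise DataValidationError(
                f"coordinate table {s_path} must have columns 'x' and 'y'"
            )
    S = sdf[["x", "y"]].to_numpy()

    T = None
    if t_path is not None:
        tdf = _align(_read_indexed_csv(t_path, "species"), species, "species", t_path)
        T = tdf.to_numpy()

    return CommunityData(
        Y=ydf.to_numpy(),
        X=xdf.to_numpy(),
        S=S,
        T=T,
        species_names=species,
        site_ids=site_ids,
    )


def write_community(data: CommunityData, outdir, prefix: str = "") -> dict:
    """Write a community to ``<outdir>/<prefix>{Y,X,S,T}.csv``; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    ydf = pd.DataFrame(data.Y, index=data.site_ids, columns=data.species_names)
    xdf = pd.DataFrame(
        data.X, index=data.site_ids,
        columns=[f"x{k}" for k in range(data.n_covariates)],
    )
    sdf = pd.DataFrame(data.S, index=data.site_ids, columns=["x", "y"])
    for name, df in (("Y", ydf), ("X", xdf), ("S", sdf)):
        p = os.path.join(outdir, f"{prefix}{name}.csv")
        df.to_csv(p, index_label="id")
        paths[name] = p
    tdf = pd.DataFrame(
        data.T, index=data.species_names,
        columns=[f"t{k}" for k in range(data.n_traits)],
    )
    p = os.path.join(outdir, f"{prefix}T.csv")
    tdf.to_csv(p, index_label="id")
    paths["T"] = p
    return paths
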
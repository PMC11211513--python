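"""Core data containers for genotype/phenotype data.

Rows are samples, columns are SNP markers everywhere in this package;
marker dosages are counts of the ALT allele (0, 1 or 2) unless a caller
supplies continuous imputed dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"genotype matrix must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class GenotypeMatrix:
    """An n x m matrix of allele dosages with sample and marker labels.

    Parameters
    ----------
    values : (n, m) array of float
        Allele dosages; must be finite (impute or reject missing data at
        the I/O layer before constructing).
    sample_ids : sequence of n str, optional
        Defaults to ``S0..S{n-1}``.
    marker_ids : sequence of m str, optional
        Defaults to ``M0..M{m-1}``.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)
    marker_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = _as_2d_float(self.values)
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise ValueError("need at least 1 marker")
        if not np.isfinite(self.values).all():
            raise ValueError("genotype matrix contains non-finite entries")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if self.marker_ids is None:
            self.marker_ids = [f"M{j}" for j in range(m)]
        else:
            self.marker_ids = [str(s) for s in self.marker_ids]
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.marker_ids) != m:
            raise ValueError(
                f"{len(self.marker_ids)} marker ids for {m} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.marker_ids),
        )


@dataclass
class PhenotypeVector:
    """A length-n trait vector with sample labels, aligned to a GenotypeMatrix."""

    values: np.ndarray
    sample_ids: list[str] = field(default=None)
    trait: str = "trait"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype vector contains non-finite entries")
        n = self.values.size
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} values")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def take(self, idx) -> "PhenotypeVector":
        idx = np.asarray(idx)
        return PhenotypeVector(
            self.values[idx], [self.sample_ids[i] for i in idx], self.trait
        )


def as_genotype_matrix(X) -> GenotypeMatrix:
    """Coerce an array or GenotypeMatrix to GenotypeMatrix."""
    if isinstance(X, GenotypeMatrix):
        return X
    return GenotypeMatrix(np.asarray(X, dtype=float))


def as_phenotype_vector(Y) -> PhenotypeVector:
    if isinstance(Y, PhenotypeVector):
        return Y
    return PhenotypeVector(np.asarray(Y, dtype=float))
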
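"""Labeled symmetric distance matrices shared by every pipeline stage.

Genetic distances, spectral (Euclidean) distances and metabolite-profile
distances all travel through :class:`DistanceMatrix`, so label alignment
between genotype and phenotype happens in exactly one place
(:meth:`DistanceMatrix.reorder`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = ["DistanceMatrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances with unique labels.

    Parameters
    ----------
    labels
        Item names, one per row/column, unique, order-significant.
    values
        ``(n, n)`` array; finite, symmetric, zero diagonal, non-negative.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if values.shape != (n, n):
            raise ValueError(f"values shape {values.shape} does not match {n} labels")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(values < -1e-12):
            raise ValueError("distance matrix has negative entries")
        # canonicalize: exact symmetry and zero diagonal
        sym = (values + values.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        object.__setattr__(self, "values", sym)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_condensed(cls, labels, condensed) -> "DistanceMatrix":
        """Build from a scipy-style condensed (upper-triangle) vector."""
        return cls(tuple(labels), squareform(np.asarray(condensed, dtype=float)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(tuple(map(str, df.index)), df.to_numpy(dtype=float))

    @classmethod
    def read_csv(cls, path) -> "DistanceMatrix":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    # -- accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy ``squareform`` order."""
        return squareform(self.values, checks=False)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels) -> "DistanceMatrix":
        """Return the same distances with rows/columns in ``labels`` order.

        Raises ``ValueError`` listing the mismatch when label sets differ.
        """
        labels = tuple(str(x) for x in labels)
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) - set(self.labels))
            extra = sorted(set(self.labels) - set(labels))
            raise ValueError(
                f"label set mismatch: missing={missing} extra={extra}"
            )
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)
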
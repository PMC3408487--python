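"""Labelled trait (co)variance matrices.

A :class:`CovMatrix` is the exchange currency of the package: the same
container holds broad-sense genetic (G) matrices, residual matrices,
phenotypic covariance matrices and group sample covariances.  Estimates
returned by unconstrained-structure REML are *not* required to be positive
semi-definite -- boundary solutions with zero variances next to nonzero
covariances are legitimate output of that estimator -- so PSD status is
recorded rather than enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CovMatrix"]

_SYM_TOL = 1e-8


@dataclass
class CovMatrix:
    """A symmetric labelled covariance matrix with an effective sample size.

    Parameters
    ----------
    labels : list of str
        Trait names, one per row/column.
    values : (k, k) ndarray
        Symmetric matrix.  Symmetrised on construction; asymmetry beyond
        ``1e-8`` (relative to the largest entry) is an error.
    n_effective : int
        Number of independent units (families, individuals, populations)
        behind the estimate.
    """

    labels: list[str]
    values: np.ndarray
    n_effective: int = 0
    psd: bool = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"covariance matrix must be square, got {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        scale = max(1.0, float(np.abs(v).max()))
        if np.abs(v - v.T).max() > _SYM_TOL * scale:
            raise ValueError("matrix is not symmetric")
        self.values = 0.5 * (v + v.T)
        self.psd = bool(np.linalg.eigvalsh(self.values).min() >= -_SYM_TOL * scale)

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def require_compatible(self, other: "CovMatrix") -> None:
        if self.labels != other.labels:
            raise ValueError(
                f"trait labels differ: {self.labels} vs {other.labels}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        """Write as labelled CSV (trait names as header row and column)."""
        self.to_dataframe().to_csv(path, index_label="trait")

    @classmethod
    def from_csv(cls, path, n_effective: int = 0) -> "CovMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), n_effective)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_effective: int = 0) -> "CovMatrix":
        return cls(list(df.columns), df.to_numpy(dtype=float), n_effective)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CovMatrix(labels={self.labels}, n_effective={self.n_effective}, "
            f"psd={self.psd})\n{self.to_dataframe().round(4)}"
        )
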
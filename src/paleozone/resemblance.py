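"""Pairwise resemblance among samples: Bray-Curtis, Euclidean, conversions.

Bray-Curtis dissimilarity between samples j and k is
``sum |x_jt - x_kt| / sum (x_jt + x_kt)`` over taxa t — bounded in [0, 1]
and insensitive to shared absences.  Euclidean distance serves the
(univariate or multivariate) environmental profiles.  Similarity and
dissimilarity interconvert as ``s = 1 - d`` for bounded coefficients only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import AssemblageCounts

__all__ = ["ResemblanceMatrix", "bray_curtis", "euclidean_matrix", "convert"]

KIND_SIMILARITY = "similarity"
KIND_DISSIMILARITY = "dissimilarity"

#: Coefficients bounded in [0, 1] (eligible for similarity conversion).
_BOUNDED = {"bray-curtis"}


@dataclass
class ResemblanceMatrix:
    """Symmetric sample x sample resemblance with declared kind."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = KIND_DISSIMILARITY
    coefficient: str = "bray-curtis"
    transform: str = "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("resemblance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("resemblance matrix must be symmetric")
        expected_diag = 1.0 if self.kind == KIND_SIMILARITY else 0.0
        if not np.allclose(np.diag(v), expected_diag, atol=1e-12):
            raise ValueError(f"diagonal must equal {expected_diag} for kind {self.kind!r}")
        if self.kind not in (KIND_SIMILARITY, KIND_DISSIMILARITY):
            raise ValueError(f"unknown kind {self.kind!r}")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def is_bounded(self) -> bool:
        return self.coefficient in _BOUNDED

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(
    counts: AssemblageCounts, expect_transformed: bool = True
) -> ResemblanceMatrix:
    """Bray-Curtis dissimilarity matrix of an assemblage table.

    The conventional pipeline square-root transforms abundances first; to
    guard against silently skipping that step this function refuses
    non-``transformed`` input unless ``expect_transformed=False`` is passed
    explicitly.
    """
    if expect_transformed and counts.mode != "transformed":
        raise ValueError(
            "input is not marked 'transformed'; apply sqrt_transform first or "
            "pass expect_transformed=False to use raw abundances deliberately"
        )
    if np.any(counts.values < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    row_sums = counts.values.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("all-zero sample: Bray-Curtis undefined for a zero/zero pair")
    d = pdist(counts.values, metric="braycurtis")
    return ResemblanceMatrix(
        sample_ids=list(counts.sample_ids),
        values=squareform(d),
        kind=KIND_DISSIMILARITY,
        coefficient="bray-curtis",
        transform="sqrt" if counts.mode == "transformed" else counts.mode,
    )


def euclidean_matrix(values, sample_ids: list[str] | None = None, name: str = "euclidean") -> ResemblanceMatrix:
    """Euclidean distance matrix of a profile (1-D series or n x p matrix)."""
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if np.any(~np.isfinite(v)):
        raise ValueError("profile contains undefined entries")
    ids = sample_ids if sample_ids is not None else [str(i + 1) for i in range(len(v))]
    d = squareform(pdist(v, metric="euclidean"))
    return ResemblanceMatrix(ids, d, KIND_DISSIMILARITY, coefficient=name)


def convert(matrix: ResemblanceMatrix, to_kind: str) -> ResemblanceMatrix:
    """Convert similarity <-> dissimilarity via ``s = 1 - d``.

    Unbounded coefficients (Euclidean) refuse conversion to similarity.
    """
    if to_kind not in (KIND_SIMILARITY, KIND_DISSIMILARITY):
        raise ValueError(f"unknown kind {to_kind!r}")
    if to_kind == matrix.kind:
        return matrix
    if to_kind == KIND_SIMILARITY and not matrix.is_bounded:
        raise ValueError(
            f"cannot convert unbounded coefficient {matrix.coefficient!r} to similarity"
        )
    return ResemblanceMatrix(
        sample_ids=list(matrix.sample_ids),
        values=1.0 - matrix.values,
        kind=to_kind,
        coefficient=matrix.coefficient,
        transform=matrix.transform,
        meta=dict(matrix.meta),
    )
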
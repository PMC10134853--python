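"""Alpha diversity, Bray-Curtis dissimilarity, and principal-coordinate analysis.

Alpha indices follow the common ecology defaults: richness is the count of
observed taxa, Chao1 the bias-corrected estimator
``S_obs + F1(F1-1)/(2(F2+1))`` with singleton/doubleton counts F1/F2, and
Simpson the Gini-Simpson form ``1 - sum(p_i^2)`` (the inverse form ``1/sum``
is available behind a flag). PCoA is classical metric scaling: the squared
distance matrix is double-centred, eigendecomposed, and axes with positive
eigenvalues are kept; negative eigenvalues are reported in the result rather
than silently dropped, and no Cailliez/Lingoes correction is applied unless
requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .io import CountTable, RelAbundanceTable, ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (condensed) vector in scipy's pdist order."""
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def select(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(tuple(sample_ids), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class Ordination:
    """PCoA result: sample coordinates plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame      # samples x retained axes
    eigenvalues: np.ndarray        # full spectrum, non-increasing
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    return arr


def richness(counts) -> int:
    """Number of taxa with count > 0."""
    return int((_as_counts(counts) > 0).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton and doubleton counts."""
    arr = _as_counts(counts)
    s_obs = float((arr > 0).sum())
    f1 = float((arr == 1).sum())
    f2 = float((arr == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    if f1 == 0:
        return s_obs
    if f2 == 0:  # classic estimator undefined at F2=0; fall back to corrected
        return s_obs + f1 * (f1 - 1.0) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def simpson(counts, inverse: bool = False) -> float:
    """Gini-Simpson diversity ``1 - sum(p^2)`` (or inverse Simpson ``1/sum(p^2)``)."""
    arr = _as_counts(counts).astype(float)
    total = arr.sum()
    if total <= 0:
        raise ValidationError("Simpson index requires a positive total count")
    p = arr / total
    d = float(np.sum(p * p))
    return 1.0 / d if inverse else 1.0 - d


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Richness, Chao1, and Simpson for every sample of a count table."""
    rows = {
        s: {
            "richness": richness(table.data[s]),
            "chao1": chao1(table.data[s]),
            "simpson": simpson(table.data[s]),
        }
        for s in table.sample_ids
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: CountTable | RelAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min) / sum(x + y)`` between samples."""
    mat = table.data.to_numpy(dtype=float).T  # samples x taxa
    if mat.shape[0] < 2:
        raise ValidationError("Bray-Curtis requires at least two samples")
    zero = mat.sum(axis=1) == 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValidationError(f"Bray-Curtis undefined for all-zero samples: {bad}")
    values = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(tuple(table.sample_ids), values)


def pcoa(d: DistanceMatrix, n_axes: int | None = None,
         correction: str | None = None) -> Ordination:
    """Classical metric scaling of a distance matrix.

    ``correction`` may be ``"lingoes"`` to add the smallest constant to the
    squared distances that makes the Gower matrix positive semidefinite; by
    default no correction is applied and negative eigenvalues are reported.
    """
    n = d.n
    if n_axes is not None and n_axes > n - 1:
        raise ValidationError(f"n_axes={n_axes} exceeds samples-1={n - 1}")
    dist = d.values
    gower = _gower_center(dist)
    eigvals, eigvecs = eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if correction == "lingoes" and eigvals[-1] < -1e-12:
        c = -eigvals[-1]
        sq = dist**2 + 2.0 * c * (1.0 - np.eye(n))
        gower = _gower_center(np.sqrt(sq))
        eigvals, eigvecs = eigh(gower)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    elif correction is not None and correction != "lingoes":
        raise ValueError(f"unknown correction {correction!r}")

    pos = eigvals > max(1e-12 * abs(eigvals[0]), 1e-12) if eigvals[0] > 0 else eigvals > 0
    total_pos = eigvals[pos].sum()
    keep = np.flatnonzero(pos)
    if n_axes is not None:
        keep = keep[:n_axes]
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    props = eigvals[keep] / total_pos if total_pos > 0 else np.zeros(len(keep))
    frame = pd.DataFrame(
        coords,
        index=list(d.sample_ids),
        columns=[f"PCo{i + 1}" for i in range(len(keep))],
    )
    return Ordination(frame, eigvals, props)


def _gower_center(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    a = -0.5 * dist**2
    centering = np.eye(n) - np.ones((n, n)) / n
    return centering @ a @ centering
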
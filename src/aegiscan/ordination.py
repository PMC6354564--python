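"""Identity-by-state distances and principal coordinates analysis.

The between-accession distance is 1 − IBS over jointly called loci, with
allele-sharing score 1 for identical calls, 0.5 for heterozygote versus
homozygote, and 0 for opposite homozygotes.  Missing data are handled
pairwise: each sample pair is compared only at loci called in both.

PCoA is classical metric multidimensional scaling: double-center −½D²,
eigendecompose, scale eigenvectors by the square root of their (positive)
eigenvalues.  Variance proportions are reported over positive eigenvalues
only, so they sum to 100% across all retained axes.  Axis signs are
arbitrary; only the recovered geometry is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .genotype_io import CallMatrix, NOCALL

__all__ = ["DistanceMatrix", "OrdinationResult", "ibs_distance", "pcoa",
           "genotype_pca"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance grid shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


@dataclass
class OrdinationResult:
    """Principal coordinates with per-axis variance proportions (%)."""

    labels: list[str]
    coordinates: np.ndarray  # samples × k
    eigenvalues: np.ndarray  # length k, non-increasing, positive
    variance_proportions: np.ndarray  # %, over positive eigenvalues

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def ibs_distance(matrix: CallMatrix) -> DistanceMatrix:
    """1 − identity-by-state between every sample pair.

    Raises if some pair shares no jointly called locus (naming the pair).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    calls = matrix.calls.astype(float)
    called = matrix.calls != NOCALL
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {matrix.sample_ids[i]!r} and "
                    f"{matrix.sample_ids[j]!r} share no jointly called loci")
            # dosage difference 0/1/2 -> sharing 1/0.5/0
            diff = np.abs(calls[both, i] - calls[both, j])
            d[i, j] = d[j, i] = 1.0 - float(np.mean(1.0 - diff / 2.0))
    return DistanceMatrix(labels=matrix.sample_ids, values=d)


def pcoa(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical PCoA of a distance matrix, keeping up to ``k`` axes.

    Negative eigenvalues (non-Euclidean distances) are dropped from both the
    axes and the variance denominator.  Requesting more axes than there are
    positive eigenvalues truncates with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10 * abs(vals[0]), 1e-12) if vals.size else vals > 0
    vals_pos, vecs_pos = vals[pos], vecs[:, pos]
    if k > vals_pos.size:
        warnings.warn(
            f"requested {k} axes but only {vals_pos.size} positive "
            "eigenvalues; truncating", stacklevel=2)
        k = vals_pos.size
    coords = vecs_pos[:, :k] * np.sqrt(vals_pos[:k])
    var = 100 * vals_pos / vals_pos.sum()
    return OrdinationResult(labels=list(dist.labels), coordinates=coords,
                            eigenvalues=vals_pos[:k],
                            variance_proportions=var)


def genotype_pca(matrix: CallMatrix, k: int = 2) -> OrdinationResult:
    """PCA on centered genotype dosages (missing set to the marker mean).

    Offered as the covariance-based alternative to distance-based PCoA.
    """
    calls = matrix.calls.astype(float)
    calls[matrix.calls == NOCALL] = np.nan
    col_ok = ~np.all(np.isnan(calls), axis=1)
    calls = calls[col_ok]
    mean = np.nanmean(calls, axis=1, keepdims=True)
    x = np.where(np.isnan(calls), mean, calls) - mean
    # samples are observations: eigendecompose the samples × samples Gram
    g = x.T @ x / x.shape[0]
    vals, vecs = linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    vals_pos, vecs_pos = vals[pos], vecs[:, pos]
    k = min(k, vals_pos.size)
    coords = vecs_pos[:, :k] * np.sqrt(vals_pos[:k] * x.shape[0])
    var = 100 * vals_pos / vals_pos.sum()
    return OrdinationResult(labels=matrix.sample_ids, coordinates=coords,
                            eigenvalues=vals_pos[:k],
                            variance_proportions=var)
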
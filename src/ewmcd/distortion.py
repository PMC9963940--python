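"""Cluster-distortion primitives: centroid, SSE, MSE, and the acceptance test.

The oversampling window is steered by the distortion of a *virtual
cluster* — the set of current-chunk positive points.  Distortion is the
K-means-style sum of squared Euclidean distances (SSE) from the points
to their centroid; MSE is SSE divided by the point count.  A candidate
point from the previous window is accepted when including it does not
raise the cluster's MSE, with the centroid held fixed at its value
before the candidate is considered.

Holding the centroid fixed gives a closed form: including candidate
``x`` changes the mean squared distance from ``SSE/n`` to
``(SSE + d(x, c)^2) / (n + 1)``, which is ``<= SSE/n`` exactly when
``d(x, c)^2 <= MSE``.  The acceptance test below uses that shortcut;
the definitional recomputation is kept in the test suite as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VirtualCluster", "compute_centroid", "sse", "mse", "accepts"]


def compute_centroid(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise arithmetic mean of a non-empty (n, d) point set."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    return points.mean(axis=0)


def sse(points: np.ndarray, centroid: np.ndarray) -> float:
    """Sum of squared Euclidean distances from each point to the centroid."""
    points = np.asarray(points, dtype=float)
    centroid = np.asarray(centroid, dtype=float)
    if points.ndim != 2 or points.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if centroid.shape != (points.shape[1],):
        raise ValueError(
            f"centroid dimension {centroid.shape} does not match "
            f"points dimension {points.shape[1]}"
        )
    diffs = points - centroid
    return float(np.einsum("ij,ij->", diffs, diffs))


def mse(points: np.ndarray, centroid: np.ndarray) -> float:
    """Mean squared distance: ``sse(points, centroid) / len(points)``."""
    points = np.asarray(points, dtype=float)
    return sse(points, centroid) / points.shape[0]


@dataclass(frozen=True)
class VirtualCluster:
    """The positive-point reference cluster VC(T) with its distortion.

    Attributes
    ----------
    points : numpy.ndarray
        (n, d) array of positive feature vectors.
    centroid : numpy.ndarray
        Coordinate-wise mean of ``points`` (symbol CW(T)).
    sse, mse : float
        Sum / mean of squared Euclidean distances to the centroid.
    n : int
        Number of points.
    """

    points: np.ndarray
    centroid: np.ndarray
    sse: float
    mse: float
    n: int

    @classmethod
    def from_points(cls, points: np.ndarray) -> "VirtualCluster":
        points = np.asarray(points, dtype=float)
        centroid = compute_centroid(points)
        total = sse(points, centroid)
        return cls(
            points=points,
            centroid=centroid,
            sse=total,
            mse=total / points.shape[0],
            n=points.shape[0],
        )


def accepts(candidate: np.ndarray, cluster: VirtualCluster) -> bool:
    """Distortion test: does ``candidate`` keep the cluster coherent?

    True iff the cluster's mean squared distance, recomputed with the
    candidate included but the centroid unchanged, does not exceed the
    current MSE — equivalently, iff the candidate's squared Euclidean
    distance to the centroid is ``<= cluster.mse``.  The boundary case
    (distance exactly ``sqrt(MSE)``) is accepted.

    Candidates are always judged against the cluster's baseline MSE,
    never cumulatively as earlier acceptances accrue.  A degenerate
    cluster with zero distortion (all points identical) accepts only
    candidates exactly at the centroid.
    """
    candidate = np.asarray(candidate, dtype=float)
    if candidate.shape != cluster.centroid.shape:
        raise ValueError(
            f"candidate dimension {candidate.shape} does not match "
            f"cluster dimension {cluster.centroid.shape}"
        )
    diff = candidate - cluster.centroid
    return float(diff @ diff) <= cluster.mse
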
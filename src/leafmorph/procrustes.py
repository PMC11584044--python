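"""Pairwise and generalized Procrustes superimposition.

Full Procrustes is used throughout: every configuration is translated to a
zero centroid and scaled to unit centroid size, so the superimposition
removes position, size, and orientation and the residual distance reflects
shape alone.  Size information is carried separately by the traditional
shape descriptors.

The generalized scheme follows the classical iteration: start from an
arbitrary reference (the first configuration), superimpose every leaf onto
the current mean, average, renormalize, and repeat until the mean stops
moving.  Reflection is disallowed by default — a mirrored leaf is a
different leaf — but can be enabled, in which case the better of the raw
and reflected alignments is used.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, GeometryError
from .landmarking import LandmarkConfiguration

logger = logging.getLogger(__name__)

__all__ = ["AlignedSet", "superimpose_pair", "gpa", "distance_matrix"]


def _normalize(points: np.ndarray, label: str = "") -> np.ndarray:
    """Center to zero centroid and scale to unit centroid size."""
    centered = points - points.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size < 1e-12:
        raise GeometryError(f"configuration {label!r}: zero centroid size")
    return centered / size


def _optimal_rotation(A: np.ndarray, B: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Orthogonal matrix R minimizing ||A @ R - B||_F for normalized A, B."""
    M = A.T @ B
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U = U.copy()
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def _superimpose(A: np.ndarray, B: np.ndarray, allow_reflection: bool = False) -> tuple[np.ndarray, float]:
    """Superimpose normalized copies of A onto B; return (A_aligned, distance)."""
    An = _normalize(A)
    Bn = _normalize(B)
    R = _optimal_rotation(An, Bn, allow_reflection)
    aligned = An @ R
    return aligned, float(np.linalg.norm(aligned - Bn))


def superimpose_pair(
    A: LandmarkConfiguration,
    B: LandmarkConfiguration,
    allow_reflection: bool = False,
) -> tuple[LandmarkConfiguration, float]:
    """Superimpose configuration A onto B, returning (A_aligned, distance).

    Both configurations are centered and scaled to unit centroid size; A is
    then rotated by the orthogonal matrix (from the SVD of the
    cross-covariance, determinant forced +1 unless ``allow_reflection``)
    minimizing the summed squared distance to B.  The distance is the root
    sum of squared point-wise residuals after superimposition.
    """
    if A.n_points != B.n_points:
        raise CorrespondenceError(
            f"point counts differ: {A.id!r} has {A.n_points}, {B.id!r} has {B.n_points}"
        )
    aligned, dist = _superimpose(A.points, B.points, allow_reflection)
    return LandmarkConfiguration(id=A.id, points=aligned, S=A.S), dist


@dataclass
class AlignedSet:
    """Output of generalized Procrustes analysis.

    ``mean_shape`` has zero centroid and unit centroid size; ``distances``
    are per-leaf Procrustes distances to the mean after the final
    superimposition.
    """

    configurations: list[LandmarkConfiguration]
    mean_shape: LandmarkConfiguration
    distances: np.ndarray
    iterations: int
    converged: bool
    tolerance: float
    objective_history: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": [c.id for c in self.configurations], "procrustes_distance": self.distances}
        )

    def save(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "mean_shape": self.mean_shape.points.tolist(),
            "S": self.mean_shape.S,
            "iterations": self.iterations,
            "converged": self.converged,
            "tolerance": self.tolerance,
        }
        Path(json_path).write_text(json.dumps(meta))


def gpa(
    configs: list[LandmarkConfiguration],
    tolerance: float = 1e-6,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> AlignedSet:
    """Generalized Procrustes analysis of a set of configurations.

    The mean is initialized as the (normalized) first configuration; each
    iteration superimposes every configuration onto the mean, replaces the
    mean with the coordinate-wise average renormalized to unit centroid
    size, and stops when the Procrustes distance between successive means
    drops below ``tolerance``.  If ``max_iter`` is reached first, results
    are still returned with ``converged=False`` and a warning.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    counts = {c.n_points for c in configs}
    if len(counts) != 1:
        raise CorrespondenceError(f"mixed point counts in GPA input: {sorted(counts)}")
    S = configs[0].S
    mean = _normalize(configs[0].points, configs[0].id)
    aligned = [c.points for c in configs]
    distances = np.zeros(len(configs))
    objective_history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i, c in enumerate(configs):
            aligned[i], distances[i] = _superimpose(c.points, mean, allow_reflection)
        objective_history.append(float(np.sum(distances**2)))
        new_mean = _normalize(np.mean(aligned, axis=0))
        _, mean_change = _superimpose(new_mean, mean, allow_reflection)
        mean = new_mean
        if mean_change < tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last mean change above tolerance {tolerance:g})",
            stacklevel=2,
        )
    # Final superimposition onto the settled mean.
    for i, c in enumerate(configs):
        aligned[i], distances[i] = _superimpose(c.points, mean, allow_reflection)
    out_configs = [
        LandmarkConfiguration(id=c.id, points=a, S=S) for c, a in zip(configs, aligned)
    ]
    mean_config = LandmarkConfiguration(id="mean", points=mean, S=S)
    return AlignedSet(
        configurations=out_configs,
        mean_shape=mean_config,
        distances=distances.copy(),
        iterations=iterations,
        converged=converged,
        tolerance=tolerance,
        objective_history=objective_history,
    )


def distance_matrix(aligned: AlignedSet, allow_reflection: bool = False) -> pd.DataFrame:
    """Symmetric matrix of pairwise Procrustes distances between all leaves.

    Each entry is an independent pairwise superimposition (not a distance in
    the common GPA frame), so the matrix is exactly symmetric with a zero
    diagonal.
    """
    configs = aligned.configurations
    n = len(configs)
    ids = [c.id for c in configs]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, d = _superimpose(configs[i].points, configs[j].points, allow_reflection)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=ids, columns=ids)
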
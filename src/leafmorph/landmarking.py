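"""Tip/base detection, orientation, and pseudo-landmark resampling.

Leaves with inconsistent lobing carry only two reliable homologous
landmarks: the tip and the base.  Every other point is a pseudo-landmark
placed at a fixed arc-length position along the outline, so that point ``k``
on one leaf corresponds to point ``k`` on every other leaf along the
proximal-distal axis.

The convention used throughout: a configuration has ``2*S`` points, index 0
is the base, indices ``0..S-1`` run up one side of the leaf from base
(inclusive) to tip (exclusive), index ``S`` is the tip, and ``S..2S-1`` run
back down the other side toward the base (exclusive).  Tip and base each
appear exactly once, so no landmark is double-weighted in superimposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError
from .outline_io import LeafOutline

__all__ = [
    "LandmarkConfiguration",
    "find_tip_base",
    "reindex_and_orient",
    "resample_equidistant",
    "landmark_outline",
    "OrientedOutline",
]

DEFAULT_LANDMARKS_PER_SIDE = 100


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Fixed-length pseudo-landmark representation of one leaf.

    ``points`` has exactly ``2*S`` rows; the base is row 0 and the tip row
    ``S`` by construction.
    """

    id: str
    points: np.ndarray  # (2S, 2)
    S: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (2 * self.S, 2):
            raise GeometryError(
                f"configuration {self.id!r}: expected {2 * self.S} points, got {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def tip_index(self) -> int:
        return self.S

    @property
    def n_points(self) -> int:
        return 2 * self.S

    def to_frame(self) -> pd.DataFrame:
        n = self.n_points
        return pd.DataFrame(
            {
                "id": [self.id] * n,
                "index": np.arange(n),
                "x": self.points[:, 0],
                "y": self.points[:, 1],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {"id": self.id, "S": self.S, "points": self.points.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "LandmarkConfiguration":
        d = json.loads(text)
        return cls(id=d["id"], points=np.asarray(d["points"]), S=d["S"])


@dataclass(frozen=True)
class OrientedOutline(LeafOutline):
    """An outline re-indexed to start at the base and rotated upright.

    The base sits at the origin, the base->tip vector points along +y, and
    the winding is counter-clockwise.  ``tip_index`` locates the tip in the
    re-indexed vertex list.
    """

    tip_index: int = 0


def _closed_points(points: np.ndarray) -> np.ndarray:
    return np.vstack([points, points[:1]])


def _cumulative_arclength(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Cumulative arc length; includes the closing edge when ``closed``."""
    pts = _closed_points(points) if closed else points
    seg = np.hypot(*(np.diff(pts, axis=0).T))
    return np.concatenate([[0.0], np.cumsum(seg)])


def find_tip_base(outline: LeafOutline, tip_rule: str = "arc") -> tuple[int, int]:
    """Locate the tip and base vertices of a traced leaf.

    The trace starts and ends at the two corners of the cut petiole end, so
    the base is the vertex nearest the midpoint of the first and last trace
    points.  The tip is the vertex farthest from the base — along the closed
    contour by arc length (``tip_rule="arc"``, robust to recurved lobes) or
    by straight-line distance (``tip_rule="euclidean"``).  Ties break to the
    lowest index.

    Returns ``(tip_index, base_index)``.
    """
    pts = outline.points
    if len(pts) < 4:
        raise GeometryError(f"outline {outline.id!r}: too short to locate tip and base")
    petiole_mid = (pts[0] + pts[-1]) / 2.0
    base = int(np.argmin(np.hypot(*(pts - petiole_mid).T)))
    if tip_rule == "euclidean":
        tip = int(np.argmax(np.hypot(*(pts - pts[base]).T)))
    elif tip_rule == "arc":
        cum = _cumulative_arclength(pts, closed=True)
        total = cum[-1]
        forward = np.abs(cum[:-1] - cum[base])
        arc_dist = np.minimum(forward, total - forward)
        tip = int(np.argmax(arc_dist))
    else:
        raise ValueError(f"unknown tip_rule {tip_rule!r}")
    return tip, base


def reindex_and_orient(
    outline: LeafOutline, tip_index: int, base_index: int
) -> OrientedOutline:
    """Re-index the vertex list to start at the base and rotate upright.

    Idempotent: orienting an already-oriented outline (with its own
    ``tip_index`` and base 0) returns the same vertices.
    """
    pts = outline.points
    n = len(pts)
    if np.allclose(pts[tip_index], pts[base_index]):
        raise GeometryError(f"outline {outline.id!r}: tip and base coincide")
    rolled = np.roll(pts, -base_index, axis=0)
    tip = (tip_index - base_index) % n
    # Normalize winding to counter-clockwise (positive signed area),
    # keeping the base at index 0.
    x, y = rolled[:, 0], rolled[:, 1]
    signed2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if signed2 < 0:
        rolled = rolled[np.r_[0, np.arange(n - 1, 0, -1)]]
        tip = (n - tip) % n
    base_pt = rolled[0].copy()
    shifted = rolled - base_pt
    axis = shifted[tip]
    norm = float(np.hypot(*axis))
    if norm < 1e-12:
        raise GeometryError(f"outline {outline.id!r}: zero-length base->tip axis")
    c, s = axis[1] / norm, axis[0] / norm  # rotate so axis -> +y
    rot = np.array([[c, -s], [s, c]])
    oriented = shifted @ rot.T
    return OrientedOutline(id=outline.id, points=oriented, tip_index=tip)


def resample_equidistant(
    outline: OrientedOutline, S: int = DEFAULT_LANDMARKS_PER_SIDE
) -> LandmarkConfiguration:
    """Resample an oriented outline to ``2*S`` equidistant pseudo-landmarks.

    The tip splits the closed contour into two sides; each side is resampled
    by arc-length linear interpolation to ``S`` points.  Side 1 spans base
    (inclusive) to tip (exclusive); side 2 spans tip (inclusive) back toward
    the base (exclusive), giving exactly ``2*S`` points with the base at
    index 0 and the tip at index ``S``.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    pts = outline.points
    tip = outline.tip_index
    if tip <= 0 or tip >= len(pts):
        raise GeometryError(f"outline {outline.id!r}: tip index {tip} does not split the contour")
    side1 = pts[: tip + 1]
    side2 = np.vstack([pts[tip:], pts[:1]])
    out = np.empty((2 * S, 2), dtype=float)
    for k, side in enumerate((side1, side2)):
        cum = _cumulative_arclength(side, closed=False)
        total = cum[-1]
        if total <= 0:
            raise GeometryError(f"outline {outline.id!r}: side {k + 1} has zero arc length")
        targets = np.arange(S) * (total / S)  # endpoint of each side excluded
        out[k * S : (k + 1) * S, 0] = np.interp(targets, cum, side[:, 0])
        out[k * S : (k + 1) * S, 1] = np.interp(targets, cum, side[:, 1])
    return LandmarkConfiguration(id=outline.id, points=out, S=S)


def landmark_outline(
    outline: LeafOutline,
    S: int = DEFAULT_LANDMARKS_PER_SIDE,
    tip_rule: str = "arc",
) -> LandmarkConfiguration:
    """Full landmarking of one raw outline: detect, orient, resample."""
    tip, base = find_tip_base(outline, tip_rule=tip_rule)
    oriented = reindex_and_orient(outline, tip, base)
    return resample_equidistant(oriented, S=S)


def configurations_to_csv(configs: list[LandmarkConfiguration], path: str | Path) -> None:
    pd.concat([c.to_frame() for c in configs], ignore_index=True).to_csv(path, index=False)
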
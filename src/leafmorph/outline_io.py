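"""Reading, writing, and measuring raw leaf outlines.

An outline is an ordered closed polygon traced around a leaf, from one end
of the petiole, around the blade, and back to the other end of the petiole.
The on-disk format is the two-column XY coordinate text file produced by
ImageJ's segmented-line export: one vertex per line, tab-separated, no
header.  The reader also tolerates a single header line and comma or
whitespace delimiters.

Traditional shape descriptors (area, perimeter, length, width, circularity,
aspect ratio) are computed directly on the raw traced polygon, petiole
included.  Length and width are measured as extents of the vertex
projections onto the base-to-tip axis and its perpendicular, which makes
every descriptor invariant to how the specimen happened to be oriented.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, GeometryError

logger = logging.getLogger(__name__)

__all__ = [
    "LeafOutline",
    "ShapeDescriptors",
    "read_outline",
    "write_outline",
    "measure_descriptors",
    "polygon_area",
    "polygon_perimeter",
]

_NUMBER_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


@dataclass(frozen=True)
class LeafOutline:
    """An ordered closed polygon in pixel units.

    The last vertex is implicitly connected back to the first; the closing
    vertex is *not* stored.  Consecutive duplicate vertices are collapsed on
    construction via :func:`read_outline`.
    """

    id: str
    points: np.ndarray  # (n, 2) float array

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError(f"outline {self.id!r}: points must be (n, 2)")
        if pts.shape[0] < 3:
            raise GeometryError(f"outline {self.id!r}: needs >= 3 vertices, got {pts.shape[0]}")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def is_simple(self) -> bool:
        """Check the polygon for self-intersection (advisory, not fatal)."""
        from shapely.geometry import Polygon

        return Polygon(self.points).is_simple


@dataclass(frozen=True)
class ShapeDescriptors:
    """Traditional morphometric descriptors of one leaf outline.

    ``circularity`` is 4*pi*Area/Perimeter**2: 1 for a perfect circle,
    decreasing toward 0 with boundary complexity (lobing).  ``aspect_ratio``
    is the tip-to-base extent over the perpendicular extent: larger values
    mean a longer, narrower leaf.
    """

    id: str
    area: float
    perimeter: float
    length: float
    width: float
    circularity: float
    aspect_ratio: float


def _dedupe_consecutive(points: np.ndarray) -> np.ndarray:
    if len(points) < 2:
        return points
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(points[1:] != points[:-1], axis=1)
    return points[keep]


def read_outline(path: str | Path, id: str | None = None) -> LeafOutline:
    """Read an XY coordinate text file into a :class:`LeafOutline`.

    Accepts tab, comma, or whitespace delimited pairs; a single non-numeric
    header line is skipped.  Consecutive duplicate vertices are collapsed.

    Raises
    ------
    FormatError
        If a data line is not a numeric pair, or fewer than three valid
        vertices remain.
    """
    path = Path(path)
    leaf_id = id if id is not None else path.stem
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = [t for t in re.split(r"[,\t\s]+", line) if t]
            if len(tokens) < 2:
                raise FormatError(f"{path}:{lineno}: expected an XY pair, got {line!r}")
            try:
                x, y = float(tokens[0]), float(tokens[1])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # tolerated header line, e.g. "X\tY"
                raise FormatError(
                    f"{path}:{lineno}: non-numeric token in {line!r}"
                ) from None
            rows.append((x, y))
    if len(rows) < 3:
        raise FormatError(f"{path}: fewer than 3 valid vertices ({len(rows)})")
    raw = np.array(rows, dtype=float)
    pts = _dedupe_consecutive(raw)
    if len(pts) != len(raw):
        logger.info("%s: collapsed %d duplicate consecutive vertices", path, len(raw) - len(pts))
    if len(pts) < 3:
        raise FormatError(f"{path}: fewer than 3 distinct vertices after deduplication")
    outline = LeafOutline(id=leaf_id, points=pts)
    logger.info("read %s: %d vertices", path, outline.n_points)
    if not outline.is_simple():
        logger.warning("outline %s is self-intersecting", leaf_id)
    return outline


def write_outline(outline: LeafOutline, path: str | Path) -> None:
    """Write an outline as a tab-separated XY text file (no header)."""
    np.savetxt(path, outline.points, fmt="%.10g", delimiter="\t")


def polygon_area(points: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula."""
    x, y = points[:, 0], points[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def polygon_perimeter(points: np.ndarray) -> float:
    """Length of the closed polygonal boundary."""
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def measure_descriptors(outline: LeafOutline, tip: int, base: int) -> ShapeDescriptors:
    """Compute traditional shape descriptors from a raw outline.

    Parameters
    ----------
    outline
        The raw traced polygon (petiole included).
    tip, base
        Vertex indices of the leaf tip and leaf base.  Length is the extent
        of all vertices projected onto the unit base->tip axis; width the
        extent onto its perpendicular.

    Raises
    ------
    GeometryError
        If tip and base coincide in space (zero-length axis).
    """
    pts = outline.points
    n = len(pts)
    if not (0 <= tip < n and 0 <= base < n) or tip == base:
        raise GeometryError(f"outline {outline.id!r}: invalid tip/base indices {tip}, {base}")
    axis = pts[tip] - pts[base]
    norm = float(np.hypot(*axis))
    if norm < 1e-12:
        raise GeometryError(f"outline {outline.id!r}: tip and base coincide")
    u = axis / norm
    v = np.array([-u[1], u[0]])
    proj_l = pts @ u
    proj_w = pts @ v
    length = float(proj_l.max() - proj_l.min())
    width = float(proj_w.max() - proj_w.min())
    if width < 1e-12:
        raise GeometryError(f"outline {outline.id!r}: degenerate (zero width)")
    area = polygon_area(pts)
    perimeter = polygon_perimeter(pts)
    circ = 4.0 * np.pi * area / perimeter**2
    return ShapeDescriptors(
        id=outline.id,
        area=area,
        perimeter=perimeter,
        length=length,
        width=width,
        circularity=float(circ),
        aspect_ratio=length / width,
    )
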
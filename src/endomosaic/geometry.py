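"""Planar cell-mosaic geometry.

A field of endothelium is modelled as a rectangle tiled by the Voronoi
cells of the pointed cell centers.  This module builds the tessellation,
derives neighbor relations from shared Voronoi edges, computes per-cell
morphometry (area variability and hexagonality), and extracts contiguous
groups of cells — the geometric substrate for grading and counting.

Coordinates are real-valued with the origin at the field's top-left
corner, x rightward and y downward (image convention).  Units are
micrometres unless a caller tags otherwise.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon

__all__ = [
    "FieldRect",
    "Mosaic",
    "MorphometrySummary",
    "tessellate",
    "morphometry",
    "contiguous_groups",
]

#: Two centers closer than this (µm) are considered duplicates.
DUPLICATE_TOL = 1e-9

#: A shared Voronoi edge shorter than this (µm) does not create adjacency;
#: degenerate corner contacts are not neighbors.
MIN_EDGE_LEN = 1e-9


@dataclass(frozen=True)
class FieldRect:
    """Axis-aligned rectangular field of view, in µm."""

    width: float = 935.0
    height: float = 748.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.width) and np.isfinite(self.height)):
            raise ValueError("field dimensions must be finite")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6


@dataclass
class MorphometrySummary:
    """Per-field cell morphometry.

    ``cv_area`` (sd/mean of cell areas) quantifies polymegethism;
    ``hexagonality`` (fraction of interior cells with exactly six
    neighbors) quantifies pleomorphism.
    """

    n_cells: int
    mean_area: float
    cv_area: float
    hexagonality: float

    def __post_init__(self) -> None:
        if self.cv_area < 0:
            raise ValueError("cv_area must be non-negative")
        if np.isfinite(self.hexagonality) and not (0.0 <= self.hexagonality <= 1.0):
            raise ValueError("hexagonality must lie in [0, 1]")


@dataclass
class Mosaic:
    """A tessellated field: centers, clipped Voronoi polygons, adjacency."""

    field: FieldRect
    centers: np.ndarray  # (n, 2) float
    polygons: list[np.ndarray]  # per cell, (k, 2) vertex loops, CCW
    adjacency: list[set[int]]  # symmetric, irreflexive
    true_ecd: float | None = None  # cells/mm², set by generators

    _shapely_cache: list[Polygon] | None = dc_field(
        default=None, repr=False, compare=False
    )

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def polygon_areas(self) -> np.ndarray:
        return np.array([_shoelace_area(p) for p in self.polygons])

    def shapely_polygons(self) -> list[Polygon]:
        if self._shapely_cache is None:
            self._shapely_cache = [Polygon(p) for p in self.polygons]
        return self._shapely_cache

    def interior_mask(self, tol: float | None = None) -> np.ndarray:
        """Cells whose polygon does not touch the field boundary."""
        if tol is None:
            tol = 1e-9 * max(self.field.width, self.field.height)
        mask = np.empty(self.n_cells, dtype=bool)
        w, h = self.field.width, self.field.height
        for i, poly in enumerate(self.polygons):
            x, y = poly[:, 0], poly[:, 1]
            mask[i] = (
                (x > tol).all()
                and (x < w - tol).all()
                and (y > tol).all()
                and (y < h - tol).all()
            )
        return mask

    def adjacency_mapping(self) -> dict[int, set[int]]:
        return {i: set(nbrs) for i, nbrs in enumerate(self.adjacency)}


def _shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _as_points(centers: Sequence | np.ndarray) -> np.ndarray:
    pts = np.asarray(centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centers must be an (n, 2) array of points")
    if not np.isfinite(pts).all():
        raise ValueError("centers must be finite")
    return pts


def tessellate(centers: Sequence | np.ndarray, field: FieldRect) -> Mosaic:
    """Voronoi tessellation of ``centers`` clipped to ``field``.

    Every unbounded Voronoi region is closed by clipping to the field
    rectangle, so the polygons tile the field exactly.  Adjacency holds
    between two cells iff they share a Voronoi edge longer than
    :data:`MIN_EDGE_LEN`.

    Raises
    ------
    ValueError
        If a center lies on/outside the field or two centers coincide
        within :data:`DUPLICATE_TOL`; the message names offending indices.
    """
    pts = _as_points(centers)
    n = len(pts)
    if n < 1:
        raise ValueError("need at least one center")

    w, h = field.width, field.height
    outside = np.nonzero(
        (pts[:, 0] <= 0) | (pts[:, 0] >= w) | (pts[:, 1] <= 0) | (pts[:, 1] >= h)
    )[0]
    if outside.size:
        raise ValueError(
            f"centers not strictly inside field at indices {outside.tolist()}"
        )

    if n > 1:
        tree = cKDTree(pts)
        dup_pairs = sorted(tuple(sorted(p)) for p in tree.query_pairs(DUPLICATE_TOL))
        if dup_pairs:
            raise ValueError(f"duplicate centers at index pairs {dup_pairs}")

    # Reflect the points across all four field edges; the Voronoi cell of
    # each original point in the augmented diagram is then exactly its
    # field-clipped cell (the edge bisector with each mirror image is the
    # field edge itself), which makes the tiling exact by construction.
    mirrored = np.vstack(
        [
            pts,
            np.column_stack([-pts[:, 0], pts[:, 1]]),
            np.column_stack([2 * w - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], -pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * h - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)

    polygons: list[np.ndarray] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - mirrors close all
            raise RuntimeError("unbounded region survived mirroring")
        verts = vor.vertices[region]
        # Voronoi cells are convex: an angular sort around the centroid
        # yields a valid CCW vertex loop regardless of qhull ordering.
        centroid = verts.mean(axis=0)
        order = np.argsort(
            np.arctan2(verts[:, 1] - centroid[1], verts[:, 0] - centroid[0])
        )
        polygons.append(verts[order])

    adjacency: list[set[int]] = [set() for _ in range(n)]
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n or q >= n:
            continue  # ridge against a mirror image: a field-edge border
        if -1 in rv:  # pragma: no cover
            continue
        v = vor.vertices[rv]
        if np.hypot(*(v[0] - v[1])) > MIN_EDGE_LEN:
            adjacency[p].add(int(q))
            adjacency[q].add(int(p))

    return Mosaic(field=field, centers=pts, polygons=polygons, adjacency=adjacency)


def morphometry(mosaic: Mosaic, interior_only: bool = True) -> MorphometrySummary:
    """Area statistics and hexagonality of a mosaic.

    ``cv_area`` is computed over interior cells when ``interior_only``
    (boundary-clipped cells have truncated areas), otherwise over all
    cells.  Hexagonality is always over interior cells, since boundary
    cells have clipped neighborhoods.
    """
    interior = mosaic.interior_mask()
    n_interior = int(interior.sum())
    if interior_only and n_interior == 0:
        raise ValueError("no interior cells; cannot compute interior-only morphometry")

    areas = mosaic.polygon_areas()
    sel = areas[interior] if interior_only else areas
    mean_area = float(sel.mean())
    cv_area = float(sel.std(ddof=0) / mean_area) if len(sel) > 1 else 0.0

    if n_interior:
        six = sum(
            1 for i in np.nonzero(interior)[0] if len(mosaic.adjacency[i]) == 6
        )
        hexagonality = six / n_interior
    else:
        hexagonality = float("nan")

    return MorphometrySummary(
        n_cells=len(sel),
        mean_area=mean_area,
        cv_area=cv_area,
        hexagonality=hexagonality,
    )


def contiguous_groups(
    member_ids: Iterable[int],
    adjacency: Mapping[int, Iterable[int]] | Sequence[Iterable[int]],
) -> list[set[int]]:
    """Connected components of the adjacency graph restricted to ``member_ids``.

    Returned largest-first; ties broken by smallest member id.  Ids absent
    from ``adjacency`` raise ``ValueError``.
    """
    members = set(int(i) for i in member_ids)
    if isinstance(adjacency, Mapping):
        known = set(adjacency.keys())
        neighbors = lambda i: adjacency[i]  # noqa: E731
    else:
        known = set(range(len(adjacency)))
        neighbors = lambda i: adjacency[i]  # noqa: E731
    unknown = members - known
    if unknown:
        raise ValueError(f"unknown cell ids {sorted(unknown)}")

    groups: list[set[int]] = []
    seen: set[int] = set()
    for start in sorted(members):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        seen.add(start)
        while queue:
            cur = queue.popleft()
            for nbr in neighbors(cur):
                nbr = int(nbr)
                if nbr in members and nbr not in seen:
                    seen.add(nbr)
                    comp.add(nbr)
                    queue.append(nbr)
        groups.append(comp)
    groups.sort(key=lambda g: (-len(g), min(g)))
    return groups
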
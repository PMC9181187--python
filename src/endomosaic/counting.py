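"""Variable-frame center-method cell density.

The center method points every cell center inside a hand-drawn frame and
reports density as count over frame area.  A cell counts iff its pointed
center is strictly inside the frame polygon (the standard bias-canceling
edge rule).  Frames pool by summed count over summed area — not by
averaging per-frame ratios — and five per-field estimates summarize to a
per-cornea mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "DEFAULT_UM_PER_PX",
    "Calibration",
    "FrameAnnotation",
    "ECDEstimate",
    "CorneaECD",
    "calibrate",
    "count_frame",
    "pool_frames",
    "field_ecd",
    "cornea_ecd",
]

#: 935 µm over 1280 px == 748 µm over 1024 px: the default isotropic pitch.
DEFAULT_UM_PER_PX = 935.0 / 1280.0

#: Fields are expected to capture at least this many cells.
DEFAULT_MIN_CELLS = 200


def calibrate(n_px: int, extent_um: float) -> float:
    """µm per pixel from a known physical extent imaged over ``n_px`` pixels."""
    if n_px <= 0 or extent_um <= 0:
        raise ValueError("pixel count and extent must be positive")
    return extent_um / n_px


@dataclass(frozen=True)
class Calibration:
    um_per_px_x: float = DEFAULT_UM_PER_PX
    um_per_px_y: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        if self.um_per_px_x <= 0 or self.um_per_px_y <= 0:
            raise ValueError("calibration factors must be positive")

    @classmethod
    def identity(cls) -> "Calibration":
        """For annotations already expressed in µm."""
        return cls(1.0, 1.0)

    def px_area_to_mm2(self, area_px2: float) -> float:
        return area_px2 * self.um_per_px_x * self.um_per_px_y / 1e6


@dataclass
class FrameAnnotation:
    """Pointed centers plus a drawn boundary polygon (same pixel units)."""

    pointed_centers: np.ndarray  # (n, 2)
    boundary: np.ndarray  # (k, 2) simple polygon vertex loop

    def __post_init__(self) -> None:
        self.pointed_centers = np.asarray(self.pointed_centers, dtype=float).reshape(
            -1, 2
        )
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2 or len(self.boundary) < 3:
            raise ValueError("boundary must be a (k>=3, 2) vertex loop")

    def polygon(self) -> Polygon:
        return Polygon(self.boundary)


@dataclass(frozen=True)
class ECDEstimate:
    """A cell count over an area; density is count/area by construction."""

    n_cells: int
    area_mm2: float
    ecd: float
    method: str  # "specular_center_method" | "hoechst"

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area must be positive")

    @classmethod
    def from_count(cls, n_cells: int, area_mm2: float, method: str) -> "ECDEstimate":
        if area_mm2 <= 0:
            raise ValueError("area must be positive")
        return cls(
            n_cells=int(n_cells),
            area_mm2=float(area_mm2),
            ecd=n_cells / area_mm2,
            method=method,
        )


@dataclass
class CorneaECD:
    """Mean ± sample SD of the densities of exactly five fields."""

    field_estimates: list[ECDEstimate]
    mean: float
    sd: float


def count_frame(frame: FrameAnnotation, cal: Calibration) -> ECDEstimate:
    """Center-method density of one annotated frame.

    Every pointed center must lie strictly inside the boundary; offenders
    are reported by index.  The frame area is the polygon's own area.
    """
    poly = frame.polygon()
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("boundary polygon must be simple (non-self-intersecting)")
    if poly.area <= 0:
        raise ValueError("degenerate boundary polygon (area <= 0)")
    if len(frame.pointed_centers) < 1:
        raise ValueError("at least one pointed center required")

    inside = shapely.contains_xy(
        poly, frame.pointed_centers[:, 0], frame.pointed_centers[:, 1]
    )
    if not inside.all():
        bad = np.nonzero(~inside)[0].tolist()
        raise ValueError(f"pointed centers outside boundary at indices {bad}")

    area_mm2 = cal.px_area_to_mm2(poly.area)
    return ECDEstimate.from_count(
        len(frame.pointed_centers), area_mm2, "specular_center_method"
    )


def pool_frames(frames: Sequence[ECDEstimate]) -> ECDEstimate:
    """Area-weighted pooling: total count over total area (never a mean of
    per-frame ratios).  Frames must share a method tag and be disjoint
    (caller-asserted)."""
    if not frames:
        raise ValueError("cannot pool an empty list of frames")
    methods = {f.method for f in frames}
    if len(methods) > 1:
        raise ValueError(f"cannot pool mixed methods {sorted(methods)}")
    n = sum(f.n_cells for f in frames)
    area = sum(f.area_mm2 for f in frames)
    return ECDEstimate.from_count(n, area, methods.pop())


def field_ecd(
    frames: Sequence[ECDEstimate], min_cells: int = DEFAULT_MIN_CELLS
) -> tuple[ECDEstimate, bool]:
    """Pooled per-field estimate plus a low-count warning flag.

    The flag is set when fewer than ``min_cells`` cells were captured in
    total (inclusive threshold: exactly ``min_cells`` is acceptable)."""
    pooled = pool_frames(frames)
    return pooled, pooled.n_cells < min_cells


def cornea_ecd(five_fields: Sequence[ECDEstimate]) -> CorneaECD:
    """Unweighted mean and sample (n-1) SD of exactly five field densities."""
    if len(five_fields) != 5:
        raise ValueError(f"exactly 5 field estimates required, got {len(five_fields)}")
    ecds = np.array([f.ecd for f in five_fields], dtype=float)
    return CorneaECD(
        field_estimates=list(five_fields),
        mean=float(ecds.mean()),
        sd=float(ecds.std(ddof=1)),
    )
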
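"""Plain-text serialization: CSV tables, JSON records, image writers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .counting import ECDEstimate, FrameAnnotation
from .grading import CellFlags
from .synthesis import GroundTruth

__all__ = [
    "centers_to_csv",
    "centers_from_csv",
    "polygons_to_csv",
    "ground_truth_to_csv",
    "ground_truth_from_csv",
    "flags_to_csv",
    "flags_from_csv",
    "boundary_to_csv",
    "boundary_from_csv",
    "estimate_to_json",
    "write_image",
    "write_manifest",
    "to_jsonable",
]


def centers_to_csv(centers: np.ndarray, path: str | Path, unit: str = "um") -> None:
    df = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            f"x_{unit}": centers[:, 0],
            f"y_{unit}": centers[:, 1],
        }
    )
    df.to_csv(path, index=False)


def centers_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    xcol = next(c for c in df.columns if c.startswith("x_"))
    ycol = next(c for c in df.columns if c.startswith("y_"))
    return df[[xcol, ycol]].to_numpy(dtype=float)


def polygons_to_csv(polygons: Sequence[np.ndarray], path: str | Path) -> None:
    rows = []
    for cid, poly in enumerate(polygons):
        for vi, (x, y) in enumerate(poly):
            rows.append((cid, vi, x, y))
    pd.DataFrame(rows, columns=["cell_id", "vertex_index", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def ground_truth_to_csv(gt: GroundTruth, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(gt.n_cells),
            "x_px": gt.centers_px[:, 0],
            "y_px": gt.centers_px[:, 1],
            "visible": gt.visible.astype(int),
            "border_distinct": gt.border_distinct.astype(int),
            "nucleus_x_px": gt.nuclei_px[:, 0],
            "nucleus_y_px": gt.nuclei_px[:, 1],
        }
    ).to_csv(path, index=False)


def ground_truth_from_csv(path: str | Path, um_per_px: float) -> GroundTruth:
    df = pd.read_csv(path)
    return GroundTruth(
        centers_px=df[["x_px", "y_px"]].to_numpy(dtype=float),
        nuclei_px=df[["nucleus_x_px", "nucleus_y_px"]].to_numpy(dtype=float),
        visible=df["visible"].to_numpy(dtype=bool),
        border_distinct=df["border_distinct"].to_numpy(dtype=bool),
        um_per_px=um_per_px,
    )


def flags_to_csv(flags: Sequence[CellFlags], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [f.cell_id for f in flags],
            "countable": [int(f.countable) for f in flags],
            "border_distinct": [int(f.border_distinct) for f in flags],
        }
    ).to_csv(path, index=False)


def flags_from_csv(path: str | Path) -> list[CellFlags]:
    df = pd.read_csv(path)
    return [
        CellFlags(int(r.cell_id), bool(r.countable), bool(r.border_distinct))
        for r in df.itertuples()
    ]


def boundary_to_csv(frame: FrameAnnotation, path: str | Path, frame_id: int = 0) -> None:
    pd.DataFrame(
        {
            "frame_id": frame_id,
            "vertex_index": np.arange(len(frame.boundary)),
            "x_px": frame.boundary[:, 0],
            "y_px": frame.boundary[:, 1],
        }
    ).to_csv(path, index=False)


def boundary_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("vertex_index")
    return df[["x_px", "y_px"]].to_numpy(dtype=float)


def to_jsonable(obj):
    """Recursively convert dataclasses/numpy containers to JSON-safe types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return to_jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def estimate_to_json(estimate: ECDEstimate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_jsonable(estimate), indent=2))


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def write_manifest(path: str | Path, seed: int, config_obj, extra: dict | None = None) -> None:
    payload = to_jsonable(config_obj)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = {"seed": seed, "config": payload, "config_sha256": digest}
    if extra:
        manifest.update(to_jsonable(extra))
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
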
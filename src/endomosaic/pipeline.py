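"""End-to-end study pipeline.

For each simulated cornea and storage session: generate/evolve a mosaic
per field, derive ground-truth visibility, grade the field, count the
specular arm with a fold-avoiding variable frame, count the nuclear-
stain arm over a large frame at the final session, then aggregate
grades, densities, and the paired statistics.  Fully reproducible from
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np

from .counting import (
    Calibration,
    DEFAULT_MIN_CELLS,
    ECDEstimate,
    FrameAnnotation,
    cornea_ecd,
    count_frame,
    field_ecd,
)
from .geometry import FieldRect, Mosaic
from .grading import CellFlags, grade_image, tabulate_grades
from .io import to_jsonable, write_image
from .nuclei import NucleusDetection, detect_nuclei, hoechst_ecd
from .stats import paired_compare, repeated_compare_days
from .synthesis import (
    FoldSpec,
    GeneratorConfig,
    GroundTruth,
    SessionSeries,
    generate_mosaic,
    ground_truth_flags,
    plan_fields,
    render_hoechst,
    render_specular,
    simulate_series,
)

__all__ = [
    "ArmPreset",
    "PipelineConfig",
    "ARM_PRESETS",
    "expected_record_count",
    "run_pipeline",
]

N_FIELDS = 5
ECD_TRUNCATION = (1000.0, 4000.0)


@dataclass(frozen=True)
class ArmPreset:
    name: str
    n_corneas: int
    session_days: tuple[int, ...]
    ecd_mean: float
    ecd_sd: float


ARM_PRESETS = {
    "one_month": ArmPreset("one_month", 50, (2, 26, 28), 2299.0, 332.0),
    "three_month": ArmPreset("three_month", 12, (2, 23, 44, 65, 86, 88), 1831.0, 213.0),
}


@dataclass(frozen=True)
class PipelineConfig:
    arm: str = "one_month"
    n_corneas: int | None = None  # None -> preset value
    session_days: tuple[int, ...] | None = None
    generator: GeneratorConfig = dc_field(default_factory=GeneratorConfig)
    min_cells: int = DEFAULT_MIN_CELLS
    seed: int = 0
    out_dir: str | None = None
    render_images: bool = False
    # per-session behavior (first session is the baseline acquisition)
    session_loss: float = 0.02
    fold_coverage_start: float = 0.18
    fold_coverage_end: float = 0.02
    indistinct_fraction: float = 0.04

    def __post_init__(self) -> None:
        if self.arm not in ARM_PRESETS:
            raise ValueError(f"unknown arm {self.arm!r}")

    @property
    def preset(self) -> ArmPreset:
        return ARM_PRESETS[self.arm]

    @property
    def corneas(self) -> int:
        return self.n_corneas if self.n_corneas is not None else self.preset.n_corneas

    @property
    def days(self) -> tuple[int, ...]:
        return (
            tuple(self.session_days)
            if self.session_days is not None
            else self.preset.session_days
        )


def expected_record_count(config: PipelineConfig) -> int:
    """corneas x sessions x five fields — one grading record per image."""
    return config.corneas * len(config.days) * N_FIELDS


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def _draw_target_ecd(rng: np.random.Generator, mean: float, sd: float) -> float:
    lo, hi = ECD_TRUNCATION
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def _merge_intervals(bands: np.ndarray) -> list[tuple[float, float]]:
    if len(bands) == 0:
        return []
    ordered = bands[np.argsort(bands[:, 0])]
    merged = [tuple(ordered[0])]
    for lo, hi in ordered[1:]:
        plo, phi = merged[-1]
        if lo <= phi:
            merged[-1] = (plo, max(phi, hi))
        else:
            merged.append((lo, hi))
    return merged


def _fold_avoiding_frame(
    field: FieldRect, bands: np.ndarray
) -> np.ndarray:
    """Largest horizontal strip of the field clear of (horizontal) fold
    bands, as a rectangle vertex loop in µm.  Full field when no bands."""
    gaps = []
    cursor = 0.0
    for lo, hi in _merge_intervals(bands):
        lo, hi = max(lo, 0.0), min(hi, field.height)
        if lo > cursor:
            gaps.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < field.height:
        gaps.append((cursor, field.height))
    if not gaps:
        y0, y1 = 0.0, field.height
    else:
        y0, y1 = max(gaps, key=lambda g: g[1] - g[0])
    return np.array(
        [(0.0, y0), (field.width, y0), (field.width, y1), (0.0, y1)]
    )


def _count_specular_field(
    mosaic: Mosaic,
    visible: np.ndarray,
    bands: np.ndarray,
    min_cells: int,
) -> tuple[ECDEstimate, bool, int]:
    """Auto-annotate one field: point every visible cell whose center is
    strictly inside the largest fold-free frame and apply the center
    method.  Falls back to the full field if the frame captures nothing."""
    frame_poly = _fold_avoiding_frame(mosaic.field, bands)
    y0, y1 = frame_poly[0, 1], frame_poly[2, 1]
    sel = (
        visible
        & (mosaic.centers[:, 1] > y0)
        & (mosaic.centers[:, 1] < y1)
        & (mosaic.centers[:, 0] > 0.0)
        & (mosaic.centers[:, 0] < mosaic.field.width)
    )
    if not sel.any():
        frame_poly = _fold_avoiding_frame(mosaic.field, np.empty((0, 2)))
        sel = visible if visible.any() else np.ones(mosaic.n_cells, dtype=bool)
    frame = FrameAnnotation(pointed_centers=mosaic.centers[sel], boundary=frame_poly)
    est = count_frame(frame, Calibration.identity())
    pooled, warn = field_ecd([est], min_cells=min_cells)
    return pooled, warn, int(sel.sum())


def _hoechst_field_estimate(
    mosaic: Mosaic,
    gt: GroundTruth,
    gen_cfg: GeneratorConfig,
    render_images: bool,
) -> ECDEstimate:
    margin_um = 10 * gt.um_per_px
    boundary = np.array(
        [
            (margin_um, margin_um),
            (mosaic.field.width - margin_um, margin_um),
            (mosaic.field.width - margin_um, mosaic.field.height - margin_um),
            (margin_um, mosaic.field.height - margin_um),
        ]
    )
    frame = FrameAnnotation(pointed_centers=np.empty((0, 2)), boundary=boundary)
    if render_images:
        image, nuclei_px = render_hoechst(mosaic, gen_cfg, nuclei_um=gt.nuclei_um())
        detection = detect_nuclei(image)
        px_frame = FrameAnnotation(
            pointed_centers=np.empty((0, 2)), boundary=boundary / gt.um_per_px
        )
        return hoechst_ecd(
            detection, px_frame, Calibration(gt.um_per_px, gt.um_per_px)
        )
    detection = NucleusDetection(
        centers=gt.nuclei_um(), threshold_used=float("nan"), min_blob_px=0
    )
    return hoechst_ecd(detection, frame, Calibration.identity())


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full simulated study for one arm; returns the report dict."""
    preset = config.preset
    days = config.days
    n_sessions = len(days)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    layout = plan_fields(field=config.generator.field)
    coverages = np.linspace(
        config.fold_coverage_start, config.fold_coverage_end, n_sessions
    )
    band_width = config.generator.folds.band_width
    fold_specs = [
        FoldSpec(
            n_bands=max(0, int(round(c * config.generator.field.height / band_width))),
            band_width=band_width,
            orientation_deg=0.0,
        )
        for c in coverages
    ]
    loss = tuple(
        0.0 if k == 0 else config.session_loss for k in range(n_sessions)
    )
    series = SessionSeries(days=tuple(days), loss_fractions=loss)

    grade_records: list[dict] = []
    grade_categories: list[str] = []
    sm_by_day: dict[int, list[list[float]]] = {d: [] for d in days}
    cells_by_day: dict[int, list[list[int]]] = {d: [] for d in days}
    cornea_rows: list[dict] = []
    sm_final: list[float] = []
    hoechst_final: list[float] = []

    for c in range(config.corneas):
        rng_c = np.random.default_rng([config.seed, 7, c])
        target = _draw_target_ecd(rng_c, preset.ecd_mean, preset.ecd_sd)
        per_day_sm: dict[int, list[ECDEstimate]] = {d: [] for d in days}
        per_day_cells: dict[int, list[int]] = {d: [] for d in days}
        final_sm_fields: list[ECDEstimate] = []
        final_h_fields: list[ECDEstimate] = []

        for f in range(N_FIELDS):
            base_seed = _derive_seed(config.seed, c, f)
            gen_cfg = replace(
                config.generator,
                target_ecd=target,
                seed=base_seed,
                indistinct_fraction=config.indistinct_fraction,
            )
            mosaic0, gt0 = generate_mosaic(gen_cfg)
            sessions = simulate_series(
                mosaic0, series, seed=_derive_seed(base_seed, 1), ground_truth0=gt0
            )

            for k, (mosaic, gt) in enumerate(sessions):
                sess_cfg = replace(
                    gen_cfg, seed=_derive_seed(base_seed, 2, k), folds=fold_specs[k]
                )
                visible, distinct, bands = ground_truth_flags(mosaic, sess_cfg)
                gt.visible = visible
                gt.border_distinct = distinct

                if config.render_images and out_dir:
                    image, gt_r = render_specular(mosaic, gt, sess_cfg)
                    write_image(
                        image, out_dir / f"c{c:03d}_d{days[k]:03d}_f{f}.png"
                    )

                flags = [
                    CellFlags(i, bool(visible[i]), bool(visible[i] and distinct[i]))
                    for i in range(mosaic.n_cells)
                ]
                grade = grade_image(flags, mosaic.adjacency)
                grade_categories.append(grade.category)

                est, warn, n_pointed = _count_specular_field(
                    mosaic, visible, bands, config.min_cells
                )
                per_day_sm[days[k]].append(est)
                per_day_cells[days[k]].append(est.n_cells)
                grade_records.append(
                    {
                        "cornea": c,
                        "day": days[k],
                        "field": layout[f].label,
                        "category": grade.category,
                        "largest_group": grade.largest_group,
                        "n_cells_counted": est.n_cells,
                        "ecd": est.ecd,
                        "low_count_warning": warn,
                        "true_ecd": mosaic.true_ecd,
                    }
                )
                if k == n_sessions - 1:
                    final_sm_fields.append(est)
                    final_h_fields.append(
                        _hoechst_field_estimate(
                            mosaic, gt, sess_cfg, config.render_images
                        )
                    )

        for d in days:
            sm_by_day[d].append([e.ecd for e in per_day_sm[d]])
            cells_by_day[d].append(per_day_cells[d])
            cr = cornea_ecd(per_day_sm[d])
            cornea_rows.append(
                {"cornea": c, "day": d, "sm_mean": cr.mean, "sm_sd": cr.sd}
            )

        sm_cornea = cornea_ecd(final_sm_fields)
        h_cornea = cornea_ecd(final_h_fields)
        sm_final.append(sm_cornea.mean)
        hoechst_final.append(h_cornea.mean)

    table = tabulate_grades(grade_categories)

    comparison = None
    if len(sm_final) >= 3:
        comparison = paired_compare(sm_final, hoechst_final)

    cells_over_time = None
    if n_sessions >= 2 and config.corneas >= 3:  # pairwise tests need n >= 3
        per_day_means = {
            d: [float(np.mean(v)) for v in cells_by_day[d]] for d in days
        }
        rc = repeated_compare_days(per_day_means)
        cells_over_time = {
            "omnibus_f": rc.omnibus_f,
            "omnibus_p": rc.omnibus_p,
            "pairs": [list(p) for p in rc.pair_labels],
            "raw_p": rc.pairwise.raw.tolist(),
            "adjusted_p": rc.pairwise.adjusted.tolist(),
        }

    all_cells = [r["n_cells_counted"] for r in grade_records]
    report = {
        "arm": config.arm,
        "seed": config.seed,
        "n_corneas": config.corneas,
        "session_days": list(days),
        "field_layout": [
            {"label": p.label, "cx_um": p.cx, "cy_um": p.cy} for p in layout
        ],
        "n_grading_records": len(grade_records),
        "expected_grading_records": expected_record_count(config),
        "grade_table": {
            "index": list(table.index),
            "columns": {col: table[col].tolist() for col in table.columns},
        },
        "grading_records": grade_records,
        "cornea_ecd": cornea_rows,
        "cells_per_image": {
            "mean": float(np.mean(all_cells)),
            "sd": float(np.std(all_cells, ddof=1)) if len(all_cells) > 1 else 0.0,
            "min": int(np.min(all_cells)),
            "max": int(np.max(all_cells)),
        },
        "sm_vs_hoechst": to_jsonable(comparison) if comparison else None,
        "sm_final_mean": float(np.mean(sm_final)),
        "sm_final_sd": float(np.std(sm_final, ddof=1)) if len(sm_final) > 1 else 0.0,
        "hoechst_final_mean": float(np.mean(hoechst_final)),
        "hoechst_final_sd": (
            float(np.std(hoechst_final, ddof=1)) if len(hoechst_final) > 1 else 0.0
        ),
        "cells_over_time": cells_over_time,
    }

    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(to_jsonable(report), indent=2)
        )
    return report
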
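"""End-to-end plate analysis: frames in, growth summaries out.

Stages: segment the first frame for seed pixels -> split into grid-labelled
instances -> segment every frame for root pixels and expand each instance's
bounding box -> measure per-seed root length by skeletonization (seed body
masked out) -> estimate germination from the radicle-emergence area signal
-> fit a line to length vs time from germination to the first neighbor
overlap (or series end) whose slope is the growth rate -> emit the
five-number summaries, dashboard and datasheets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from . import io as rio
from .measurement import (
    GrowthSummary,
    LengthSeries,
    estimate_germination_from_area,
    fit_growth_rate,
    germination_index,
    skeleton_length,
)
from .plate import PlateTimeSeries
from .segmentation import SegmentationModel, segment
from .tracking import SeedInstance, detect_seed_instances, update_tracks

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineParams:
    """Tunable knobs of the end-to-end analysis.

    ``margin_mm`` is the box-claiming margin expressed physically
    (~0.09 mm, i.e. 5 px at 58.4 px/mm) and converted to pixels with the
    plate's calibration.  ``min_excess_px`` / ``germ_persist`` parameterize
    the radicle-emergence detector; ``seed_dilate_px`` is how far the
    frame-0 seed body is dilated before being masked out of root length
    measurements.
    """

    rows: int = 8
    cols: int = 8
    margin_mm: float = 0.09
    min_excess_px: int = 3
    germ_persist: int = 2
    seed_dilate_px: int = 2
    root_width_px: float = 3.0  # approximate root caliber, for the tip cap
    # the fit starts at the first frame whose length exceeds this, skipping
    # the partially-hidden emergence transient behind the seed body
    min_fit_length_mm: float = 0.2


@dataclass
class PipelineResult:
    instances: list[SeedInstance]
    length_series: list[LengthSeries]
    summaries: list[GrowthSummary]
    germination_index: float | None
    empty_plate: bool = False
    outputs: dict = field(default_factory=dict)


def run_pipeline(
    series: PlateTimeSeries,
    seed_model: SegmentationModel | None = None,
    root_model: SegmentationModel | None = None,
    params: PipelineParams | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Analyze one plate time-lapse.

    Models default to the classical backend.  With ``out_dir`` set, the
    dashboard figure, the per-seed summary CSV and the full length-series
    CSV are written there.
    """
    p = params or PipelineParams()
    seed_model = seed_model or SegmentationModel(target="seed", backend="classical")
    root_model = root_model or SegmentationModel(target="root", backend="classical")
    scale = series.scale_px_per_mm
    margin_px = max(1, int(round(p.margin_mm * scale)))
    plate = series.plate_id

    logger.info("plate %s: %d frames %s", plate, series.n_frames, series.frame_shape)
    seed_mask = segment(series.frames[0], seed_model)
    instances = detect_seed_instances(seed_mask, (p.rows, p.cols))
    logger.info("plate %s: %d seed instances", plate, len(instances))
    if not instances:
        logger.warning("plate %s: empty first frame, empty-plate report", plate)
        return PipelineResult([], [], [], None, empty_plate=True)

    # seed bodies (frame 0, dilated) are excluded from root length
    seed_body = ndi.binary_dilation(
        seed_mask > 0, iterations=max(1, p.seed_dilate_px)
    )

    lengths = {inst.seed_id: [] for inst in instances}
    for t, hour in enumerate(series.hours):
        root_mask = segment(series.frames[t], root_model) > 0
        update_tracks(instances, root_mask, float(hour), margin_px=margin_px)
        clean = root_mask & ~seed_body
        for inst in instances:
            x0, y0, x1, y1 = inst.bbox
            lengths[inst.seed_id].append(
                skeleton_length(clean[y0:y1, x0:x1], scale)
            )
    logger.info("plate %s: tracked %d frames", plate, series.n_frames)

    length_series: list[LengthSeries] = []
    summaries: list[GrowthSummary] = []
    interval = (
        float(series.hours[1] - series.hours[0]) if series.n_frames > 1 else 1.0
    )
    for inst in instances:
        hours = np.array([h for h, _ in inst.area_history])
        areas = np.array([a for _, a in inst.area_history], dtype=float)
        lm = np.array(lengths[inst.seed_id])
        ser = LengthSeries(inst.seed_id, hours, lm)
        length_series.append(ser)

        germ_h = None
        if inst.status != "lost":
            # after an overlap the box admits the neighbor's pixels, so the
            # area signal is only trusted strictly before overlap_h
            n_ok = len(hours)
            if inst.overlap_h is not None:
                n_ok = int(np.searchsorted(hours, inst.overlap_h, side="left"))
            if n_ok >= p.germ_persist:
                ix0, iy0, ix1, iy1 = inst.initial_bbox
                germ_h = estimate_germination_from_area(
                    hours[:n_ok],
                    areas[:n_ok],
                    min_excess_px=p.min_excess_px,
                    persist_frames=p.germ_persist,
                    width_px=p.root_width_px,
                    seed_semi_px=(iy1 - iy0) / 2.0,
                )
        end_h = float(hours[-1])
        if inst.overlap_h is not None:
            end_h = max(float(hours[0]), float(inst.overlap_h) - interval)
        rate = None
        if germ_h is not None:
            # fit over the measurable portion: zeros before the radicle
            # clears the seed body would bias the slope downward
            positive = np.flatnonzero(
                (lm > p.min_fit_length_mm) & (hours >= germ_h) & (hours <= end_h)
            )
            if len(positive):
                fit_start = float(hours[positive[0]])
                rate, _ = fit_growth_rate(ser, fit_start, end_h)
        t_end = int(np.searchsorted(hours, end_h, side="right") - 1)
        summaries.append(
            GrowthSummary(
                seed_id=inst.seed_id,
                germ_h=germ_h,
                last_h=float(hours[t_end]),
                final_length_mm=float(lm[t_end]),
                rate_mm_per_h=rate,
                status=inst.status,
            )
        )

    gi = germination_index(summaries)
    logger.info(
        "plate %s: germination index %.2f%%, %d/%d seeds rated",
        plate,
        gi,
        sum(1 for s in summaries if s.rate_mm_per_h is not None),
        len(summaries),
    )

    outputs = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs["summaries"] = rio.write_summaries(
            summaries, out_dir / f"{plate}_summaries.csv"
        )
        fig, csv = rio.render_dashboard(
            summaries,
            length_series,
            out_dir / f"{plate}_dashboard.png",
            out_dir / f"{plate}_lengths.csv",
        )
        outputs["dashboard"] = fig
        outputs["lengths"] = csv
    return PipelineResult(instances, length_series, summaries, gi, outputs=outputs)
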
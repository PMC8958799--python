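"""Synthetic plate time-lapse generator with exact ground truth.

Emulates a square Petri dish of Arabidopsis seeds sown on dark
(charcoal-supplemented) agar in a regular grid and imaged hourly: per-seed
germination delays, per-seed elongation rates, optionally agravitropic
(curling) root paths, neighbor-root overlap events and rigid seed drift from
agar shrinkage.  Every rendered pixel is backed by a :class:`TruthRecord`
so each downstream stage (segmentation, tracking, measurement, statistics)
can be scored against exact truth.

The geometric model is deliberately simple: a seed is a filled ellipse
(~0.45 x 0.30 mm, long axis horizontal), a root is a constant-width tube
swept along a polyline that starts at the seed centroid and extends
incrementally frame by frame.  Heading starts straight down (gravitropic)
and receives Gaussian angular perturbations scaled by ``curl``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .plate import PlateTimeSeries

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "generate_plate_series",
    "rasterize_root",
    "truth_table",
]

_STEP_MM = 0.1  # tip extension step for the incremental root path


def _as_range(spec) -> tuple[float, float]:
    """Normalise a per-seed draw spec: scalar -> degenerate range."""
    if np.isscalar(spec):
        return float(spec), float(spec)
    lo, hi = spec
    if hi < lo:
        raise ValueError("distribution range must satisfy low <= high")
    return float(lo), float(hi)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic plate.

    Per-seed draws (``germ_delay_h``, ``rate_mm_per_h``) accept either a
    scalar (every seed identical) or a ``(low, high)`` uniform range.
    ``frame_shape`` may be left ``None`` to auto-size the canvas so the grid
    plus the longest possible root fits with margin.
    """

    rows: int = 8
    cols: int = 8
    spacing_mm: float = 10.0
    scale_px_per_mm: float = 58.4
    frame_interval_h: float = 1.0
    n_frames: int = 96
    germ_delay_h: object = (0.0, 24.0)
    germ_prob: float = 0.95
    rate_mm_per_h: object = (0.10, 0.17)
    curl: float = 0.0
    root_width_px: int = 3
    noise_sd: float = 8.0
    drift_px_per_frame: float = 0.0
    rng_seed: int = 0
    seed_axes_mm: tuple[float, float] = (0.45, 0.30)
    bg_level: int = 30
    fg_level: int = 180
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.germ_prob <= 1.0):
            raise ValueError("germ_prob must lie in [0, 1]")
        if self.curl < 0:
            raise ValueError("curl must be >= 0")
        lo, _ = _as_range(self.rate_mm_per_h)
        if lo < 0:
            raise ValueError("growth rates must be >= 0")
        dlo, _ = _as_range(self.germ_delay_h)
        if dlo < 0:
            raise ValueError("germination delays must be >= 0")
        if self.scale_px_per_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("scale and spacing must be positive")
        if self.root_width_px < 1:
            raise ValueError("root_width_px must be >= 1")
        shape = self.resolved_frame_shape()
        # grid must fit with at least 2 * root_width_px of margin all round
        margin = 2 * self.root_width_px
        grid_w = (self.cols - 1) * self.spacing_mm * self.scale_px_per_mm
        grid_h = (self.rows - 1) * self.spacing_mm * self.scale_px_per_mm
        x0, y0 = self.grid_origin_px()
        if (
            x0 < margin
            or y0 < margin
            or x0 + grid_w > shape[1] - margin
            or y0 + grid_h > shape[0] - margin
        ):
            raise ValueError(
                f"{self.rows}x{self.cols} grid does not fit a "
                f"{shape[0]}x{shape[1]} frame with {margin} px margin"
            )

    # -- geometry helpers ------------------------------------------------
    @property
    def duration_h(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_h

    def max_root_mm(self) -> float:
        _, rate_hi = _as_range(self.rate_mm_per_h)
        return rate_hi * self.duration_h

    def grid_origin_px(self) -> tuple[float, float]:
        """(x, y) of seed (0, 0) in pixels."""
        half = self.spacing_mm / 2.0
        return (
            half * self.scale_px_per_mm,
            half * self.scale_px_per_mm,
        )

    def resolved_frame_shape(self) -> tuple[int, int]:
        if self.frame_shape is not None:
            return tuple(self.frame_shape)
        s = self.scale_px_per_mm
        half = self.spacing_mm / 2.0
        w = ((self.cols - 1) * self.spacing_mm + 2 * half) * s
        h = ((self.rows - 1) * self.spacing_mm + 2 * half) * s
        # roots grow mostly downward: reserve room for the longest root
        h += (self.max_root_mm() + 2.0) * s
        drift = abs(self.drift_px_per_frame) * (self.n_frames - 1)
        return int(math.ceil(h + 2 * drift)), int(math.ceil(w + 2 * drift))


@dataclass
class TruthRecord:
    """Exact per-seed ground truth for one synthetic plate.

    ``polyline_per_frame`` reconstructs, for every frame, the root midline in
    millimetres (image coordinates, y down), starting at the seed centroid
    and including any drift applied up to that frame.  ``true_length_mm``
    is the arc length of that midline, i.e. 0 before germination and
    ``rate * (t - germ_h)`` afterwards (until the tip reaches the canvas
    edge, after which it plateaus).
    """

    seed_id: tuple[int, int]
    germ_h: float | None
    rate_mm_per_h: float | None
    center_mm: np.ndarray  # (x, y) of the seed centroid at frame 0
    hours: np.ndarray
    true_length_mm: np.ndarray  # per frame
    overlapped_from_h: float | None = None
    path_mm: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    points_per_frame: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    drift_mm_per_frame: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    @property
    def true_length_mm_per_frame(self) -> np.ndarray:
        return self.true_length_mm

    def polyline_at(self, frame: int) -> np.ndarray:
        """Root midline (k, 2) in mm at a given frame, centroid first."""
        n = int(self.points_per_frame[frame])
        pts = np.vstack([self.center_mm[None, :], self.path_mm[:n]])
        return pts + self.drift_mm_per_frame[frame]

    @property
    def polyline_per_frame(self) -> list[np.ndarray]:
        return [self.polyline_at(t) for t in range(len(self.hours))]


def rasterize_root(
    polyline_mm: np.ndarray,
    width_px: int,
    scale_px_per_mm: float,
    canvas_shape: tuple[int, int],
) -> np.ndarray:
    """Render root midline(s) as a binary tube of the given pixel width.

    The tube is the union of disks of diameter ``width_px`` stamped along
    the densified polyline, so ends are round-capped.  A list of polylines
    renders their union (disconnected root fragments); an empty polyline
    yields an empty mask.
    """
    mask = np.zeros(canvas_shape, dtype=bool)
    if isinstance(polyline_mm, (list, tuple)):
        parts = polyline_mm
    else:
        parts = [polyline_mm]
    radius = width_px / 2.0
    for part in parts:
        pts = np.asarray(part, dtype=float).reshape(-1, 2)
        if len(pts) == 0:
            continue
        px = pts * scale_px_per_mm  # (x, y) in pixels
        for y, x in _densify(px[:, 1], px[:, 0], step=0.7):
            rr, cc = draw_disk((y, x), radius, shape=canvas_shape)
            mask[rr, cc] = True
    return mask


def _densify(ys: np.ndarray, xs: np.ndarray, step: float = 0.7):
    """Resample a polyline (pixel coords) at roughly ``step`` px spacing."""
    out = [(float(ys[0]), float(xs[0]))]
    for i in range(1, len(ys)):
        dy, dx = ys[i] - ys[i - 1], xs[i] - xs[i - 1]
        dist = math.hypot(dy, dx)
        n = max(1, int(math.ceil(dist / step)))
        for k in range(1, n + 1):
            f = k / n
            out.append((float(ys[i - 1] + f * dy), float(xs[i - 1] + f * dx)))
    return out


class _SeedSim:
    """Mutable growth state of one seed during rendering."""

    def __init__(self, cfg: SyntheticConfig, idx: int, row: int, col: int,
                 germ_h: float | None, rate: float, drift_dir: np.ndarray):
        self.cfg = cfg
        self.row, self.col = row, col
        self.germ_h = germ_h
        self.rate = rate
        self.drift_dir = drift_dir  # unit vector, px
        s = cfg.scale_px_per_mm
        x0, y0 = cfg.grid_origin_px()
        self.center_px = np.array([x0 + col * cfg.spacing_mm * s,
                                   y0 + row * cfg.spacing_mm * s])
        # local canvas centered on the seed; roots can wander sideways
        reach = int(math.ceil(cfg.max_root_mm() * s)) + 4 * cfg.root_width_px
        half_w = max(reach, 8 * cfg.root_width_px) + int(0.5 * cfg.seed_axes_mm[0] * s) + 4
        self.ox = half_w          # local x of the seed center
        self.oy = half_w          # local y of the seed center
        self.local = np.zeros((half_w + reach + 8, 2 * half_w + 1), dtype=bool)
        ay = 0.5 * cfg.seed_axes_mm[1] * s
        ax = 0.5 * cfg.seed_axes_mm[0] * s
        rr, cc = draw_ellipse(self.oy, self.ox, max(ay, 1.0), max(ax, 1.0),
                              shape=self.local.shape)
        self.local[rr, cc] = True
        # tight bounds of rendered content, local px, half-open
        self.content = [int(cc.min()), int(rr.min()),
                        int(cc.max()) + 1, int(rr.max()) + 1]
        self.heading = math.pi / 2.0  # down, y positive
        self.tip = np.array([float(self.ox), float(self.oy)])  # local px (x, y)
        self.path_local_px: list[np.ndarray] = []  # tip after each step
        self.length_mm = 0.0
        self.stopped = False
        self.rng = default_rng(SeedSequence(cfg.rng_seed, spawn_key=(1, idx)))
        self.points_per_frame: list[int] = []
        self.length_per_frame: list[float] = []
        self.overlapped_from_h: float | None = None

    def grow_to(self, hour: float) -> None:
        cfg = self.cfg
        if self.germ_h is None or hour < self.germ_h or self.stopped:
            return
        target = self.rate * (hour - self.germ_h)
        s = cfg.scale_px_per_mm
        radius = cfg.root_width_px / 2.0
        while self.length_mm < target - 1e-12 and not self.stopped:
            step = min(_STEP_MM, target - self.length_mm)
            if cfg.curl > 0:
                self.heading += cfg.curl * self.rng.normal() * math.sqrt(step)
            nxt = self.tip + step * s * np.array(
                [math.cos(self.heading), math.sin(self.heading)]
            )
            if not self._inside(nxt):
                self.stopped = True
                break
            # stamp the new segment into the local canvas
            for y, x in _densify(
                np.array([self.tip[1], nxt[1]]),
                np.array([self.tip[0], nxt[0]]),
                step=0.7,
            ):
                rr, cc = draw_disk((y, x), radius, shape=self.local.shape)
                self.local[rr, cc] = True
                if len(rr):
                    self.content[0] = min(self.content[0], int(cc.min()))
                    self.content[1] = min(self.content[1], int(rr.min()))
                    self.content[2] = max(self.content[2], int(cc.max()) + 1)
                    self.content[3] = max(self.content[3], int(rr.max()) + 1)
            self.tip = nxt
            self.path_local_px.append(nxt.copy())
            self.length_mm += step

    def _inside(self, pt: np.ndarray) -> bool:
        m = 2 * self.cfg.root_width_px
        h, w = self.local.shape
        return m <= pt[0] < w - m and m <= pt[1] < h - m

    def drift_px(self, frame: int) -> np.ndarray:
        return self.drift_dir * self.cfg.drift_px_per_frame * frame

    def origin(self, frame: int) -> tuple[int, int]:
        """(x, y) frame position of the local canvas origin."""
        off = self.center_px + self.drift_px(frame)
        return int(round(off[0])) - self.ox, int(round(off[1])) - self.oy

    def content_bbox(self, frame: int) -> tuple[int, int, int, int]:
        """Tight (x0, y0, x1, y1) of rendered pixels in frame coordinates."""
        ox, oy = self.origin(frame)
        cx0, cy0, cx1, cy1 = self.content
        return ox + cx0, oy + cy0, ox + cx1, oy + cy1


def generate_plate_series(
    config: SyntheticConfig, return_masks: bool = False
) -> tuple[PlateTimeSeries, list[TruthRecord]] | tuple[
    PlateTimeSeries, list[TruthRecord], np.ndarray
]:
    """Render a synthetic plate time-lapse and its exact truth records.

    Returns ``(series, records)`` or, with ``return_masks=True``,
    ``(series, records, masks)`` where ``masks`` is the (T, H, W) boolean
    foreground (seed + root) stack — the pixel-level labels downstream
    segmentation is scored against.

    All randomness derives from ``config.rng_seed``: the master stream draws
    per-seed germination, delay, rate and drift direction in row-major seed
    order; each seed's path noise and each frame's intensity noise use
    deterministically spawned child streams, so identical configs give
    bit-identical output.
    """
    cfg = config
    H, W = cfg.resolved_frame_shape()
    master = default_rng(SeedSequence(cfg.rng_seed, spawn_key=(0,)))
    dlo, dhi = _as_range(cfg.germ_delay_h)
    rlo, rhi = _as_range(cfg.rate_mm_per_h)

    sims: list[_SeedSim] = []
    idx = 0
    for r in range(cfg.rows):
        for c in range(cfg.cols):
            germinates = master.uniform() < cfg.germ_prob
            delay = master.uniform(dlo, dhi)
            rate = master.uniform(rlo, rhi)
            ang = master.uniform(0, 2 * math.pi)
            drift_dir = np.array([math.cos(ang), math.sin(ang)])
            sims.append(
                _SeedSim(cfg, idx, r, c,
                         germ_h=delay if germinates else None,
                         rate=rate, drift_dir=drift_dir)
            )
            idx += 1

    hours = np.arange(cfg.n_frames) * cfg.frame_interval_h
    frames = np.empty((cfg.n_frames, H, W), dtype=np.uint8)
    masks = np.zeros((cfg.n_frames, H, W), dtype=bool) if return_masks else None
    struct = np.ones((3, 3), dtype=bool)

    for t, hour in enumerate(hours):
        fg = np.zeros((H, W), dtype=bool)
        placements = []
        for sim in sims:
            sim.grow_to(hour)
            sim.points_per_frame.append(len(sim.path_local_px))
            sim.length_per_frame.append(sim.length_mm)
            x0, y0, x1, y1 = sim.content_bbox(t)
            cx0, cy0 = sim.content[0], sim.content[1]
            # clip paste to canvas
            dx0, dy0 = max(0, x0), max(0, y0)
            dx1, dy1 = min(W, x1), min(H, y1)
            if dx1 > dx0 and dy1 > dy0:
                crop = sim.local[
                    cy0 + (dy0 - y0) : cy0 + (dy1 - y0),
                    cx0 + (dx0 - x0) : cx0 + (dx1 - x0),
                ]
                fg[dy0:dy1, dx0:dx1] |= crop
            placements.append((x0, y0, x1, y1))
        _record_overlaps(sims, placements, hour, struct)

        noise = default_rng(SeedSequence(cfg.rng_seed, spawn_key=(2, t)))
        if cfg.noise_sd > 0:
            img = noise.normal(cfg.bg_level, cfg.noise_sd, size=(H, W))
            img[fg] = noise.normal(cfg.fg_level, cfg.noise_sd, size=int(fg.sum()))
        else:
            img = np.full((H, W), float(cfg.bg_level))
            img[fg] = cfg.fg_level
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)
        if masks is not None:
            masks[t] = fg

    records = []
    for sim in sims:
        path_px = (
            np.array(sim.path_local_px)
            if sim.path_local_px
            else np.zeros((0, 2))
        )
        # local px -> global mm relative to the (undrifted) placement
        path_mm = (
            path_px - np.array([sim.ox, sim.oy]) + sim.center_px
        ) / cfg.scale_px_per_mm
        drift_mm = np.array(
            [sim.drift_px(t) / cfg.scale_px_per_mm for t in range(cfg.n_frames)]
        )
        records.append(
            TruthRecord(
                seed_id=(sim.row, sim.col),
                germ_h=sim.germ_h,
                rate_mm_per_h=sim.rate if sim.germ_h is not None else None,
                center_mm=sim.center_px / cfg.scale_px_per_mm,
                hours=hours.copy(),
                true_length_mm=np.array(sim.length_per_frame),
                overlapped_from_h=sim.overlapped_from_h,
                path_mm=path_mm,
                points_per_frame=np.array(sim.points_per_frame, dtype=int),
                drift_mm_per_frame=drift_mm,
            )
        )

    series = PlateTimeSeries(frames, hours, cfg.scale_px_per_mm)
    if return_masks:
        return series, records, masks
    return series, records


def _window(sim, placement, x0, y0, x1, y1) -> np.ndarray:
    """Seed footprint over a frame-coordinate window, zero-padded."""
    ox = placement[0] - sim.content[0]
    oy = placement[1] - sim.content[1]
    out = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    h, w = sim.local.shape
    lx0, ly0 = x0 - ox, y0 - oy
    sx0, sy0 = max(0, lx0), max(0, ly0)
    sx1, sy1 = min(w, x1 - ox), min(h, y1 - oy)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - ly0 : sy1 - ly0, sx0 - lx0 : sx1 - lx0] = sim.local[
            sy0:sy1, sx0:sx1
        ]
    return out


def _record_overlaps(sims, placements, hour, struct) -> None:
    """First hour at which two seeds' dilated footprints intersect."""
    n = len(sims)
    for i in range(n):
        ax0, ay0, ax1, ay1 = placements[i]
        for j in range(i + 1, n):
            if (
                sims[i].overlapped_from_h is not None
                and sims[j].overlapped_from_h is not None
            ):
                continue
            bx0, by0, bx1, by1 = placements[j]
            # dilating one footprint by 1 px -> expand its box by 1
            x0, y0 = max(ax0, bx0 - 1), max(ay0, by0 - 1)
            x1, y1 = min(ax1, bx1 + 1), min(ay1, by1 + 1)
            if x1 <= x0 or y1 <= y0:
                continue
            a = _window(sims[i], placements[i], x0, y0, x1, y1)
            if not a.any():
                continue
            b = _window(sims[j], placements[j], x0 - 1, y0 - 1, x1 + 1, y1 + 1)
            if not b.any():
                continue
            b = ndi.binary_dilation(b, structure=struct)[1:-1, 1:-1]
            if (a & b).any():
                for k in (i, j):
                    if sims[k].overlapped_from_h is None:
                        sims[k].overlapped_from_h = hour


def truth_table(records: list[TruthRecord]) -> pd.DataFrame:
    """Tabulate truth records as one row per seed (CSV-ready).

    Columns mirror the per-seed growth summary: grid id, germination hour,
    last measurable hour (truncated at the first overlap), final root length
    at that hour, and the true elongation rate.  Non-germinated seeds have
    empty germination columns and zero length.
    """
    rows = []
    for rec in records:
        hours = rec.hours
        if rec.germ_h is None:
            rows.append(
                {
                    "seed_row": rec.seed_id[0],
                    "seed_col": rec.seed_id[1],
                    "germ_h": np.nan,
                    "last_h": np.nan,
                    "final_length_mm": 0.0,
                    "rate_mm_per_h": np.nan,
                    "overlapped_from_h": np.nan,
                }
            )
            continue
        if rec.overlapped_from_h is not None:
            interval = hours[1] - hours[0] if len(hours) > 1 else 1.0
            last_h = max(hours[0], rec.overlapped_from_h - interval)
        else:
            last_h = hours[-1]
        t_last = int(np.searchsorted(hours, last_h, side="right") - 1)
        rows.append(
            {
                "seed_row": rec.seed_id[0],
                "seed_col": rec.seed_id[1],
                "germ_h": rec.germ_h,
                "last_h": hours[t_last],
                "final_length_mm": rec.true_length_mm[t_last],
                "rate_mm_per_h": rec.rate_mm_per_h,
                "overlapped_from_h": (
                    np.nan
                    if rec.overlapped_from_h is None
                    else rec.overlapped_from_h
                ),
            }
        )
    return pd.DataFrame(rows)
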
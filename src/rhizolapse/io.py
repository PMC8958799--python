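"""Readers/writers, plate configuration and the germination dashboard."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
import yaml

from .measurement import GrowthSummary, LengthSeries
from .plate import PlateTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PlateConfig",
    "SCHEMA_VERSION",
    "load_series",
    "save_series",
    "write_summaries",
    "read_summaries",
    "write_length_series",
    "read_length_series",
    "render_dashboard",
]

SCHEMA_VERSION = "rhizolapse-csv v1"


@dataclass
class PlateConfig:
    """Metadata of one plate: identity, genotype, grid and calibration.

    Plate identity comes from configuration (stand-in for a QR/barcode
    tag); hours are derived from frame index x interval.
    """

    plate_id: str
    genotype: str
    rows: int
    cols: int
    scale_px_per_mm: float = 58.4
    frame_interval_h: float = 1.0
    frames_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scale_px_per_mm <= 0:
            raise ValueError("scale_px_per_mm must be positive")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path


def save_series(series: PlateTimeSeries, frames_dir: str | Path) -> Path:
    """Write frames as zero-padded 8-bit grayscale TIFFs."""
    frames_dir = Path(frames_dir)
    frames_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(series.frames):
        tifffile.imwrite(frames_dir / f"frame_{i:03d}.tif", frame.astype(np.uint8))
    return frames_dir


def load_series(config: PlateConfig) -> PlateTimeSeries:
    """Load a frame directory into an ordered plate time-lapse.

    Frames must be named sortably (``frame_%03d.tif``) and share one size;
    an unreadable or odd-sized frame raises an error naming the file.
    """
    if config.frames_dir is None:
        raise ValueError("config.frames_dir is not set")
    frames_dir = Path(config.frames_dir)
    paths = sorted(frames_dir.glob("frame_*.tif")) + sorted(
        frames_dir.glob("frame_*.png")
    )
    if not paths:
        raise FileNotFoundError(f"no frames found in {frames_dir}")
    frames = []
    shape = None
    for p in paths:
        try:
            img = tifffile.imread(p) if p.suffix == ".tif" else plt.imread(p)
        except Exception as exc:  # noqa: BLE001 - rewrap with the file name
            raise OSError(f"unreadable frame {p.name}: {exc}") from exc
        img = np.asarray(img)
        if img.ndim == 3:
            img = img.mean(axis=2)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"frame {p.name} has size {img.shape}, expected {shape}"
            )
        frames.append(img.astype(np.uint8))
    hours = np.arange(len(frames)) * config.frame_interval_h
    logger.info(
        "plate %s: loaded %d frames of %s", config.plate_id, len(frames), shape
    )
    return PlateTimeSeries(
        np.stack(frames), hours, config.scale_px_per_mm, config.plate_id
    )


# ---------------------------------------------------------------------------
# CSV schemas (all files carry a schema-version header line)
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, name: str) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} {name}\n")
        # .17g guarantees float64 round-trips exactly through the CSV
        df.to_csv(
            fh,
            index=False,
            lineterminator="\n",
            float_format=lambda v: format(v, ".17g"),
        )
    return path


def write_summaries(summaries: list[GrowthSummary], path: str | Path) -> Path:
    rows = [
        {
            "seed_row": s.seed_id[0],
            "seed_col": s.seed_id[1],
            "germ_h": np.nan if s.germ_h is None else s.germ_h,
            "last_h": s.last_h,
            "final_length_mm": s.final_length_mm,
            "rate_mm_per_h": np.nan if s.rate_mm_per_h is None else s.rate_mm_per_h,
            "status": s.status,
        }
        for s in summaries
    ]
    return _write_csv(pd.DataFrame(rows), Path(path), "summaries")


def read_summaries(path: str | Path) -> list[GrowthSummary]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for _, r in df.iterrows():
        out.append(
            GrowthSummary(
                seed_id=(int(r.seed_row), int(r.seed_col)),
                germ_h=None if pd.isna(r.germ_h) else float(r.germ_h),
                last_h=float(r.last_h),
                final_length_mm=float(r.final_length_mm),
                rate_mm_per_h=(
                    None if pd.isna(r.rate_mm_per_h) else float(r.rate_mm_per_h)
                ),
                status=str(r.status),
            )
        )
    return out


def write_length_series(series_list: list[LengthSeries], path: str | Path) -> Path:
    rows = []
    for s in series_list:
        for h, l in zip(s.hours, s.length_mm):
            rows.append(
                {
                    "seed_row": s.seed_id[0],
                    "seed_col": s.seed_id[1],
                    "hour": h,
                    "length_mm": l,
                }
            )
    return _write_csv(pd.DataFrame(rows), Path(path), "length_series")


def read_length_series(path: str | Path) -> list[LengthSeries]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    out = []
    for (r, c), grp in df.groupby(["seed_row", "seed_col"], sort=True):
        grp = grp.sort_values("hour")
        out.append(
            LengthSeries(
                (int(r), int(c)), grp.hour.to_numpy(), grp.length_mm.to_numpy()
            )
        )
    return out


# ---------------------------------------------------------------------------
# germination dashboard
# ---------------------------------------------------------------------------

def render_dashboard(
    summaries: list[GrowthSummary],
    series_list: list[LengthSeries],
    fig_path: str | Path,
    csv_path: str | Path,
) -> tuple[Path, Path]:
    """Grid of per-seed length-vs-time panels plus the full datasheet.

    Each panel is headed by the five-number summary (id, germination hour,
    last hour, final length, rate); non-germinated seeds are drawn as a
    flat red horizontal line.  The CSV datasheet holds every
    (seed, hour, mm) triple.
    """
    if not summaries:
        raise ValueError("dashboard needs at least one seed")
    by_id = {s.seed_id: s for s in series_list}
    n = len(summaries)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 1.8 * nrows), squeeze=False
    )
    ymax = max(
        (float(s.length_mm.max()) for s in series_list if len(s.length_mm)),
        default=1.0,
    )
    for ax, summ in zip(axes.flat, summaries):
        ser = by_id.get(summ.seed_id)
        if summ.germ_h is None:
            ax.axhline(0.0, color="red", lw=1.5)
            head = f"{summ.seed_id} n.g."
        else:
            if ser is not None:
                ax.plot(ser.hours, ser.length_mm, lw=1.0, color="tab:green")
            rate = "?" if summ.rate_mm_per_h is None else f"{summ.rate_mm_per_h:.3f}"
            head = (
                f"{summ.seed_id} {summ.germ_h:.0f}h {summ.last_h:.0f}h "
                f"{summ.final_length_mm:.1f}mm {rate}"
            )
        ax.set_title(head, fontsize=6)
        ax.set_ylim(-0.05 * ymax - 1e-6, ymax * 1.05 + 1e-6)
        ax.tick_params(labelsize=5)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig_path = Path(fig_path)
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)
    csv_path = write_length_series(series_list, csv_path)
    logger.info("dashboard: %d panels -> %s, datasheet -> %s", n, fig_path, csv_path)
    return fig_path, csv_path
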
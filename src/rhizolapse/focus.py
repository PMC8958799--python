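"""Depth-from-focus profilometry: depth maps, composites, surface meshes.

A focus stack is a series of images of the same scene taken at regular z
steps (e.g. 70 snaps at a 10-um step spanning 700 um).  Per pixel, the
slice in which the pixel is sharpest — measured as the local variance of
the Laplacian response — gives the surface height ``slice_index * z_step``;
picking each pixel from its sharpest slice yields an all-in-focus
composite, and triangulating the height field over a region of interest
yields a surface mesh of the root topography.

Any monotone sharpness functional would do; variance-of-Laplacian is used
because it is cheap and satisfies the blur-ordering property (blurring an
edge strictly lowers its score).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage as ndi

__all__ = [
    "FocusStack",
    "DepthMap",
    "focus_measure",
    "depth_map",
    "composite",
    "surface_mesh",
    "save_mesh",
    "load_mesh",
]


@dataclass
class FocusStack:
    """Ordered same-sized grayscale slices separated by ``z_step_um``."""

    slices: np.ndarray  # (N, H, W)
    z_step_um: float

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or len(self.slices) < 1:
            raise ValueError("stack needs >= 1 slice of uniform dims")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class DepthMap:
    """Per-pixel surface height (um) with the argmax slice index."""

    height_um: np.ndarray
    valid: np.ndarray
    slice_index: np.ndarray


def focus_measure(image: np.ndarray, window_px: int = 9) -> np.ndarray:
    """Local variance of the Laplacian response — a per-pixel sharpness."""
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    lap = ndi.laplace(img)
    mean = ndi.uniform_filter(lap, window_px)
    mean_sq = ndi.uniform_filter(lap * lap, window_px)
    return np.clip(mean_sq - mean * mean, 0.0, None)


def depth_map(
    stack: FocusStack,
    window_px: int = 9,
    flat_field: np.ndarray | None = None,
    noise_floor: float | None = None,
    median_smooth: bool = False,
) -> DepthMap:
    """Per-pixel height as the z of the sharpest slice.

    Validity requires the best sharpness to exceed a noise floor: the 95th
    percentile of a flat-field calibration's sharpness when provided, or
    1e-6 absolute, whichever is larger.  A single-slice stack maps to
    height 0 everywhere, all valid.  Optional 3x3 median filtering of the
    argmax index suppresses isolated misassignments (dust trails).
    """
    sharp = np.stack([focus_measure(s, window_px) for s in stack.slices])
    idx = np.argmax(sharp, axis=0)
    if median_smooth:
        idx = ndi.median_filter(idx, size=3)
    best = np.take_along_axis(sharp, idx[None], axis=0)[0]
    if stack.n_slices == 1:
        valid = np.ones(idx.shape, dtype=bool)
    else:
        floor = 1e-6
        if flat_field is not None:
            floor = max(
                floor, float(np.percentile(focus_measure(flat_field, window_px), 95))
            )
        if noise_floor is not None:
            floor = max(floor, noise_floor)
        valid = best > floor
    return DepthMap(idx.astype(float) * stack.z_step_um, valid, idx)


def composite(stack: FocusStack, depth: DepthMap) -> np.ndarray:
    """All-in-focus image: each pixel taken from its sharpest slice."""
    if depth.slice_index.shape != stack.slices.shape[1:]:
        raise ValueError("depth map dims do not match the stack")
    return np.take_along_axis(stack.slices, depth.slice_index[None], axis=0)[0]


def surface_mesh(
    depth: DepthMap,
    roi: np.ndarray,
    xy_scale_mm_per_px: float,
) -> trimesh.Trimesh:
    """Regular-grid triangulation of the valid ROI height field.

    Each quad of four mutually adjacent valid ROI pixels contributes two
    triangles, so a full w x h grid yields ``(w-1)(h-1)*2`` faces.
    Vertices are in mm: x, y from the pixel scale, z from height (um ->
    mm).  Vertices are stored as float32 so a binary PLY write/read
    round-trips bit-identically.
    """
    roi = np.asarray(roi) > 0
    if roi.shape != depth.height_um.shape:
        raise ValueError("roi dims do not match the depth map")
    keep = roi & depth.valid
    if not keep.any():
        raise ValueError("empty region of interest")
    ys, xs = np.nonzero(keep)
    index = -np.ones(keep.shape, dtype=int)
    index[ys, xs] = np.arange(len(ys))
    verts = np.column_stack(
        [
            xs * xy_scale_mm_per_px,
            ys * xy_scale_mm_per_px,
            depth.height_um[ys, xs] / 1000.0,
        ]
    ).astype(np.float32)
    faces = []
    h, w = keep.shape
    quad_ok = np.zeros((h - 1, w - 1), dtype=bool) if h > 1 and w > 1 else None
    if quad_ok is not None:
        quad_ok = keep[:-1, :-1] & keep[:-1, 1:] & keep[1:, :-1] & keep[1:, 1:]
        qys, qxs = np.nonzero(quad_ok)
        for y, x in zip(qys, qxs):
            a, b = index[y, x], index[y, x + 1]
            c, d = index[y + 1, x], index[y + 1, x + 1]
            faces.append((a, b, c))
            faces.append((b, d, c))
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    """Write a binary PLY."""
    path = Path(path)
    path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="binary"))
    return path


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    return trimesh.load(str(path), process=False)
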
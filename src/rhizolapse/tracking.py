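"""Seed instance detection and bounding-box tracking through a time series.

The first frame's seed mask is split into connected components, one per
sown seed, and each component's tight bounding box seeds a
:class:`SeedInstance`.  On every subsequent frame the instance's box grows
to the union of its previous box and the tight boxes of root components
that touch it (within a small margin), so the box monotonically expands
with the root.  When two instances claim the same component, or their boxes
intersect, both are flagged as overlapped — from that hour on, their length
measurements are no longer attributable to a single root, so the
measurement window is closed (the flag is irreversible even if the boxes
later separate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = [
    "SeedInstance",
    "detect_seed_instances",
    "update_tracks",
    "root_pixels_of",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # roots are thin diagonal structures


@dataclass
class SeedInstance:
    """One tracked seed/root instance.

    Boxes are 0-based half-open pixel rectangles ``(x0, y0, x1, y1)`` with x
    along columns and y along rows (image convention, y down).
    """

    seed_id: tuple[int, int]
    bbox: tuple[int, int, int, int]
    status: str = "pre_germination"  # pre_germination|growing|overlapped|lost
    overlap_partner: tuple[int, int] | None = None
    overlap_h: float | None = None
    initial_bbox: tuple[int, int, int, int] = None
    misses: int = 0
    bbox_history: list[tuple[float, tuple[int, int, int, int]]] = field(
        default_factory=list
    )
    area_history: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError("bbox must satisfy x0 < x1 and y0 < y1")
        if self.initial_bbox is None:
            self.initial_bbox = self.bbox

    @property
    def ever_grown(self) -> bool:
        return self.bbox != self.initial_bbox

    @property
    def active(self) -> bool:
        return self.status != "lost"


def _tight_boxes(labels: np.ndarray, n: int) -> list[tuple[int, int, int, int]]:
    boxes = []
    for sl in ndi.find_objects(labels, max_label=n):
        if sl is None:
            boxes.append(None)
        else:
            boxes.append((sl[1].start, sl[0].start, sl[1].stop, sl[0].stop))
    return boxes


def detect_seed_instances(
    seed_mask: np.ndarray,
    grid_spec: tuple[int, int],
    min_size: int = 5,
) -> list[SeedInstance]:
    """Split the first-frame seed mask into grid-labelled instances.

    Components are assigned row-major grid ids ``(row, col)`` by sorting
    centroids; when the component count does not match ``rows * cols`` a
    warning is emitted, components are snapped to the nearest cell of a
    lattice inferred from the centroid extremes, and unmatched cells are
    flagged ``lost``.
    """
    rows, cols = grid_spec
    mask = np.asarray(seed_mask) > 0
    labels, n = ndi.label(mask, structure=_EIGHT)
    comps = []
    for lab in range(1, n + 1):
        ys, xs = np.nonzero(labels == lab)
        if len(ys) < min_size:
            continue
        comps.append(
            {
                "cy": ys.mean(),
                "cx": xs.mean(),
                "bbox": (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1),
            }
        )
    if not comps:
        return []

    instances: list[SeedInstance] = []
    if len(comps) == rows * cols:
        comps.sort(key=lambda c: c["cy"])
        for r in range(rows):
            row_comps = sorted(
                comps[r * cols : (r + 1) * cols], key=lambda c: c["cx"]
            )
            for c, comp in enumerate(row_comps):
                instances.append(SeedInstance((r, c), tuple(map(int, comp["bbox"]))))
    else:
        warnings.warn(
            f"found {len(comps)} seed components, expected {rows * cols}; "
            "assigning best-effort grid ids",
            stacklevel=2,
        )
        ys = np.array([c["cy"] for c in comps])
        xs = np.array([c["cx"] for c in comps])
        ry = (ys.max() - ys.min()) / max(rows - 1, 1) or 1.0
        rx = (xs.max() - xs.min()) / max(cols - 1, 1) or 1.0
        taken: dict[tuple[int, int], dict] = {}
        for comp in comps:
            r = int(round((comp["cy"] - ys.min()) / ry)) if rows > 1 else 0
            c = int(round((comp["cx"] - xs.min()) / rx)) if cols > 1 else 0
            r, c = min(max(r, 0), rows - 1), min(max(c, 0), cols - 1)
            if (r, c) not in taken:
                taken[(r, c)] = comp
        for r in range(rows):
            for c in range(cols):
                if (r, c) in taken:
                    instances.append(
                        SeedInstance((r, c), tuple(map(int, taken[(r, c)]["bbox"])))
                    )
                else:
                    # placeholder at the inferred lattice position
                    ey = int(ys.min() + r * ry)
                    ex = int(xs.min() + c * rx)
                    instances.append(
                        SeedInstance(
                            (r, c), (ex, ey, ex + 1, ey + 1), status="lost"
                        )
                    )
    return instances


def _boxes_intersect(a, b) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def update_tracks(
    instances: list[SeedInstance],
    root_mask: np.ndarray,
    frame_h: float,
    margin_px: int = 5,
) -> list[SeedInstance]:
    """Expand each instance's box with the root components it touches.

    A component is claimed by an instance when any of its pixels falls
    inside the instance's previous box dilated by ``margin_px`` (bridging
    small discontinuities, e.g. seed-coat occlusion).  The new box is the
    union of the old box and the claimed components' tight boxes.  A
    component claimed by two instances, or two instances' boxes
    intersecting, marks both overlapped at this frame (first occurrence
    only).  A never-germinated instance that claims nothing for three
    consecutive frames is declared lost (seed drifted away).
    """
    mask = np.asarray(root_mask) > 0
    H, W = mask.shape
    labels, n = ndi.label(mask, structure=_EIGHT)
    boxes = _tight_boxes(labels, n)
    claims: dict[int, list[SeedInstance]] = {}

    for inst in instances:
        if not inst.active:
            inst.bbox_history.append((frame_h, inst.bbox))
            inst.area_history.append((frame_h, 0))
            continue
        x0, y0, x1, y1 = inst.bbox
        dx0, dy0 = max(0, x0 - margin_px), max(0, y0 - margin_px)
        dx1, dy1 = min(W, x1 + margin_px), min(H, y1 + margin_px)
        present = np.unique(labels[dy0:dy1, dx0:dx1])
        present = present[present > 0]
        if present.size == 0:
            if not inst.ever_grown and inst.status == "pre_germination":
                inst.misses += 1
                if inst.misses >= 3:
                    inst.status = "lost"
                    logger.warning(
                        "seed %s lost after %d empty frames",
                        inst.seed_id,
                        inst.misses,
                    )
        else:
            inst.misses = 0
            nx0, ny0, nx1, ny1 = inst.bbox
            for lab in present:
                bx0, by0, bx1, by1 = boxes[lab - 1]
                nx0, ny0 = min(nx0, bx0), min(ny0, by0)
                nx1, ny1 = max(nx1, bx1), max(ny1, by1)
                claims.setdefault(int(lab), []).append(inst)
            inst.bbox = (int(nx0), int(ny0), int(nx1), int(ny1))
            if inst.ever_grown and inst.status == "pre_germination":
                inst.status = "growing"
        inst.bbox_history.append((frame_h, inst.bbox))
        bx0, by0, bx1, by1 = inst.bbox
        inst.area_history.append((frame_h, int(mask[by0:by1, bx0:bx1].sum())))

    # overlap: shared components ...
    for insts in claims.values():
        if len(insts) >= 2:
            for a in insts:
                for b in insts:
                    if a is not b:
                        _flag_overlap(a, b, frame_h)
    # ... or intersecting boxes
    active = [i for i in instances if i.active]
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            if _boxes_intersect(a.bbox, b.bbox):
                _flag_overlap(a, b, frame_h)
                _flag_overlap(b, a, frame_h)
    return instances


def _flag_overlap(inst: SeedInstance, partner: SeedInstance, frame_h: float) -> None:
    if inst.overlap_h is None:
        inst.overlap_h = frame_h
        inst.overlap_partner = partner.seed_id
        inst.status = "overlapped"


def root_pixels_of(instance: SeedInstance, root_mask: np.ndarray) -> np.ndarray:
    """All root-mask pixels inside the instance's box (fragments included).

    Returns a mask of the same shape as ``root_mask`` that is zero outside
    the box.
    """
    mask = np.asarray(root_mask)
    out = np.zeros_like(mask)
    x0, y0, x1, y1 = instance.bbox
    out[y0:y1, x0:x1] = mask[y0:y1, x0:x1]
    return out
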
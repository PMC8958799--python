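"""Patch-based binary segmentation of seed and root pixels.

Two interchangeable backends sit behind one :class:`SegmentationModel`
surface:

* ``classical`` — Otsu thresholding on a smoothed frame with morphological
  cleanup.  Parameter-free given sensible defaults, independent of any
  training data, and therefore usable as an oracle for the learned backend.
* ``learned`` — a pixel classifier (logistic regression over multi-scale
  local intensity features, trained by seeded stochastic gradient descent)
  that follows the patch contract: frames are tiled into ``patch_size``
  squares, the seed-target path optionally block-downsamples each patch
  before prediction and nearest-neighbor upsamples the mask back, and
  patch masks are stitched into a frame-sized mask.

Large frames are tiled into 256 x 256 patches by default; patch extraction
pads to a whole number of patches and stitching crops the padding back, so
``stitch_patches(*extract_patches(img))`` is the identity for any frame.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import block_reduce
from skimage.morphology import disk
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import log_loss

__all__ = [
    "PatchGrid",
    "SegmentationModel",
    "EvalScores",
    "ModelStateError",
    "extract_patches",
    "stitch_patches",
    "segment",
    "train",
    "f1_score",
    "save_model",
    "load_model",
]


class ModelStateError(RuntimeError):
    """Raised when a learned model is used before being trained."""


@dataclass
class PatchGrid:
    """Bookkeeping for tiling an image into square patches."""

    patch_size: int
    offsets: list[tuple[int, int]]  # (y, x) top-left corners on padded image
    padded_dims: tuple[int, int]
    orig_dims: tuple[int, int]


@dataclass
class EvalScores:
    precision: float
    sensitivity: float
    f1: float


@dataclass
class SegmentationModel:
    """A pluggable seed/root pixel classifier.

    ``downsample`` implements the coarse seed path: each patch is
    block-averaged by this factor before prediction and the predicted mask
    is upsampled back (factor 8 turns 256 px patches into 32 px ones, which
    suffices to locate seeds when they span ~10 or more pixels).
    """

    target: str = "root"  # {"seed", "root"}
    backend: str = "classical"  # {"classical", "learned"}
    threshold: float = 0.5
    patch_size: int = 256
    downsample: int = 1
    params: dict = field(default_factory=dict)
    clf: object | None = None
    losses_: list[float] | None = None

    def weights_hash(self) -> str:
        """SHA-1 of the learned coefficients (determinism checks)."""
        if self.clf is None:
            raise ModelStateError("model has no trained weights")
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.clf.coef_).tobytes())
        h.update(np.ascontiguousarray(self.clf.intercept_).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# patching
# ---------------------------------------------------------------------------

def extract_patches(image: np.ndarray, patch_size: int = 256):
    """Tile an image into ``ceil(H/ps) * ceil(W/ps)`` square patches.

    The image is padded to a whole number of patches by edge reflection.
    Returns ``(grid, patches)`` with ``patches`` of shape ``(N, ps, ps)``.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8")
    H, W = image.shape[:2]
    ny = -(-H // patch_size)
    nx = -(-W // patch_size)
    ph, pw = ny * patch_size, nx * patch_size
    pad = ((0, ph - H), (0, pw - W)) + ((0, 0),) * (image.ndim - 2)
    try:
        padded = np.pad(image, pad, mode="reflect")
    except ValueError:  # pad wider than the image itself
        padded = np.pad(image, pad, mode="edge")
    offsets = [
        (iy * patch_size, ix * patch_size) for iy in range(ny) for ix in range(nx)
    ]
    patches = np.stack(
        [padded[y : y + patch_size, x : x + patch_size] for y, x in offsets]
    )
    grid = PatchGrid(patch_size, offsets, (ph, pw), (H, W))
    return grid, patches


def stitch_patches(grid: PatchGrid, patch_masks: np.ndarray) -> np.ndarray:
    """Reassemble patch masks into a mask of the original image size."""
    patch_masks = np.asarray(patch_masks)
    if len(patch_masks) != len(grid.offsets):
        raise ValueError(
            f"expected {len(grid.offsets)} patches, got {len(patch_masks)}"
        )
    out = np.zeros(grid.padded_dims + patch_masks.shape[3:], dtype=patch_masks.dtype)
    ps = grid.patch_size
    for (y, x), m in zip(grid.offsets, patch_masks):
        out[y : y + ps, x : x + ps] = m
    H, W = grid.orig_dims
    return out[:H, :W]


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    return block_reduce(img.astype(float), (factor, factor), np.mean)


def _upsample_nearest(mask: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(np.repeat(mask, factor, axis=0), factor, axis=1)


# ---------------------------------------------------------------------------
# classical backend
# ---------------------------------------------------------------------------

_CLASSICAL_DEFAULTS = {
    "sigma": 0.5,
    "min_contrast": 40.0,  # gray levels between fg and bg means
    "open_radius": 0,  # opening clips the tips of few-px-wide roots
    "min_size": 5,
}


def _classical_mask(image: np.ndarray, params: dict) -> np.ndarray:
    p = {**_CLASSICAL_DEFAULTS, **params}
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() - img.min() < p["min_contrast"]:
        return np.zeros(img.shape, dtype=np.uint8)
    sm = gaussian(img, sigma=p["sigma"], preserve_range=True)
    # isodata refinement seeded at the range midpoint: with very sparse
    # foreground, histogram-shape thresholds (Otsu) drift into the
    # background noise mode; iterating t = (mean_fg + mean_bg) / 2 from the
    # midpoint lands on the half-intensity boundary instead
    t = (sm.min() + sm.max()) / 2.0
    for _ in range(8):
        fg = sm > t
        if not fg.any() or fg.all():
            break
        t_new = (sm[fg].mean() + sm[~fg].mean()) / 2.0
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    fg = sm > t
    if not fg.any() or fg.all():
        return np.zeros(img.shape, dtype=np.uint8)
    if sm[fg].mean() - sm[~fg].mean() < p["min_contrast"]:
        return np.zeros(img.shape, dtype=np.uint8)
    if p["open_radius"] > 0:
        fg = ndi.binary_opening(fg, structure=disk(p["open_radius"]))
    if p["min_size"] > 1:
        labels, n = ndi.label(fg, structure=np.ones((3, 3), bool))
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < p["min_size"])
        fg[np.isin(labels, small[small > 0])] = False
    return fg.astype(np.uint8)


# ---------------------------------------------------------------------------
# learned backend
# ---------------------------------------------------------------------------

def _pixel_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel features: raw intensity plus two Gaussian scales."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    f = np.stack(
        [
            img,
            gaussian(img, sigma=1.0, preserve_range=True),
            gaussian(img, sigma=2.0, preserve_range=True),
        ],
        axis=-1,
    )
    return f.reshape(-1, f.shape[-1]) / 255.0


def train(
    images: list[np.ndarray],
    labels: list[np.ndarray],
    target: str = "root",
    train_params: dict | None = None,
) -> SegmentationModel:
    """Train a learned pixel classifier from labeled frames.

    ``train_params`` keys (defaults): ``epochs`` (10), ``rng_seed`` (0),
    ``sample_px`` per image per class (4000), ``patch_size`` (256),
    ``downsample`` (8 for the seed target, 1 for root), ``alpha`` (1e-4).
    Training is deterministic given ``rng_seed``; the per-epoch training
    log-loss is recorded on ``model.losses_``.
    """
    p = {
        "epochs": 10,
        "rng_seed": 0,
        "sample_px": 4000,
        "patch_size": 256,
        "downsample": 8 if target == "seed" else 1,
        "alpha": 1e-4,
        **(train_params or {}),
    }
    if len(images) == 0:
        raise ValueError("at least one labeled image is required")
    if len(images) != len(labels):
        raise ValueError("images and labels must pair up")
    rng = np.random.default_rng(p["rng_seed"])
    feats, targ = [], []
    for img, lab in zip(images, labels):
        img = np.asarray(img)
        lab = np.asarray(lab)
        if img.shape[:2] != lab.shape[:2]:
            raise ValueError("image and label dimensions differ")
        f = p["downsample"]
        if f > 1:
            img = _downsample(img, f)
            lab = block_reduce(lab.astype(float), (f, f), np.max)
        X = _pixel_features(img)
        y = (np.asarray(lab).reshape(-1) > 0).astype(int)
        # balanced subsample: rare foreground is kept in full if needed
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            if len(idx) > p["sample_px"]:
                idx = rng.choice(idx, size=p["sample_px"], replace=False)
            feats.append(X[idx])
            targ.append(y[idx])
    X = np.concatenate(feats)
    y = np.concatenate(targ)
    if y.min() == y.max():
        raise ValueError("labels contain a single class; cannot train")
    clf = SGDClassifier(
        loss="log_loss",
        alpha=p["alpha"],
        random_state=int(p["rng_seed"]),
        learning_rate="optimal",
    )
    losses = []
    for _ in range(int(p["epochs"])):
        order = rng.permutation(len(y))
        clf.partial_fit(X[order], y[order], classes=np.array([0, 1]))
        losses.append(float(log_loss(y, clf.predict_proba(X)[:, 1], labels=[0, 1])))
    return SegmentationModel(
        target=target,
        backend="learned",
        threshold=0.5,
        patch_size=int(p["patch_size"]),
        downsample=int(p["downsample"]),
        params=p,
        clf=clf,
        losses_=losses,
    )


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def segment(image: np.ndarray, model: SegmentationModel) -> np.ndarray:
    """Binary {0,1} mask of the model's target pixels, same dims as input.

    The learned backend runs patch by patch (with the seed-path
    downsample/upsample inside each patch) and stitches the results; the
    classical backend thresholds the full frame, which keeps the Otsu
    statistics well-posed on patches that contain no foreground.
    """
    image = np.asarray(image)
    if model.backend == "classical":
        f = model.downsample
        if f > 1:
            small = _downsample(image, f)
            mask = _classical_mask(small, model.params)
            mask = _upsample_nearest(mask, f)[: image.shape[0], : image.shape[1]]
            return mask.astype(np.uint8)
        return _classical_mask(image, model.params)
    if model.backend != "learned":
        raise ValueError(f"unknown backend {model.backend!r}")
    if model.clf is None:
        raise ModelStateError("learned model has not been trained")
    grid, patches = extract_patches(image, model.patch_size)
    out = []
    f = model.downsample
    for patch in patches:
        img = _downsample(patch, f) if f > 1 else patch
        proba = model.clf.predict_proba(_pixel_features(img))[:, 1]
        m = (proba.reshape(img.shape[:2]) >= model.threshold).astype(np.uint8)
        if f > 1:
            m = _upsample_nearest(m, f)[: model.patch_size, : model.patch_size]
        out.append(m)
    return stitch_patches(grid, np.stack(out))


def f1_score(pred: np.ndarray, truth: np.ndarray) -> EvalScores:
    """Pixel-wise precision, sensitivity and their harmonic mean (F1)."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth dimensions differ")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    denom = precision + sensitivity
    f1 = 2 * precision * sensitivity / denom if denom else 0.0
    return EvalScores(precision, sensitivity, f1)


# ---------------------------------------------------------------------------
# persistence: native checkpoint + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: SegmentationModel, path: str | Path) -> Path:
    path = Path(path)
    joblib.dump({"clf": model.clf}, path)
    sidecar = {
        "target": model.target,
        "backend": model.backend,
        "threshold": model.threshold,
        "patch_size": model.patch_size,
        "downsample": model.downsample,
        "params": {
            k: v for k, v in model.params.items() if isinstance(v, (int, float, str))
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_model(path: str | Path) -> SegmentationModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    blob = joblib.load(path)
    return SegmentationModel(clf=blob["clf"], **meta)
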
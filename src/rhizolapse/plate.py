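"""In-memory container for a plate time-lapse."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PlateTimeSeries:
    """Ordered frames of one plate with acquisition times and calibration.

    Parameters
    ----------
    frames : np.ndarray
        ``(T, H, W)`` uint8 grayscale stack, one frame per acquisition.
    hours : np.ndarray
        Acquisition hour of each frame, strictly increasing, length ``T``.
    scale_px_per_mm : float
        Spatial calibration of the frames (pixels per millimeter).
    plate_id : str
        Identifier used in logs and output file names.
    """

    frames: np.ndarray
    hours: np.ndarray
    scale_px_per_mm: float
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.hours = np.asarray(self.hours, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if len(self.hours) != len(self.frames):
            raise ValueError("hours and frames must have the same length")
        if len(self.hours) > 1 and not np.all(np.diff(self.hours) > 0):
            raise ValueError("hours must be strictly increasing")
        if self.scale_px_per_mm <= 0:
            raise ValueError("scale_px_per_mm must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]
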
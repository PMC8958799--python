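"""Optics benchmarking arithmetic: USAF-1951 targets, modulation contrast,
field of view and sensor resolution.

The USAF-1951 resolution chart arranges line-pair triplets in groups and
elements; the resolving power of group ``g``, element ``e`` is
``2**(g + (e - 1) / 6)`` line pairs per millimetre, so each group doubles
the frequency and each element step multiplies it by ``2**(1/6)``.
Modulation contrast along an intensity line probe across such line pairs is
``(max - min) / (max + min)`` with max/min taken as the mean detected peak
and valley levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "LineProbe",
    "SensorSpec",
    "usaf_lp_per_mm",
    "round_sig",
    "modulation",
    "field_of_view",
    "megapixels",
]


@dataclass
class LineProbe:
    """Grayscale intensities sampled along a line across a test pattern."""

    intensities: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) < 3:
            raise ValueError("a line probe needs at least 3 samples")
        top = 2**self.bit_depth - 1
        if self.intensities.min() < 0 or self.intensities.max() > top:
            raise ValueError(f"intensities must lie within [0, {top}]")


@dataclass
class SensorSpec:
    """Physical sensor size (mm) and pixel counts."""

    width_mm: float
    height_mm: float
    px_w: int
    px_h: int

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.px_w, self.px_h) <= 0:
            raise ValueError("sensor dimensions must be positive")


def usaf_lp_per_mm(group: int, element: int) -> float:
    """Resolving power of a USAF-1951 group/element, in lp/mm (raw value).

    Round with :func:`round_sig` (3 significant figures) to match chart
    labels, e.g. group 6 element 6 -> 113.99 -> 114.
    """
    if not 1 <= element <= 6:
        raise ValueError("element must be in 1..6")
    return float(2.0 ** (group + (element - 1) / 6.0))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def modulation(
    probe: LineProbe | np.ndarray, smoothing_window: int = 3
) -> float:
    """Modulation contrast ``(max - min) / (max + min)`` of a line probe.

    The probe is smoothed with a moving average, peaks and valleys are
    located as local extrema (plateaus count once, at their midpoint), and
    max/min are the means of the peak and valley levels.  A constant probe
    has zero modulation; an all-zero probe (max + min = 0) is an error.
    """
    x = probe.intensities if isinstance(probe, LineProbe) else np.asarray(
        probe, dtype=float
    )
    if len(x) < 3:
        raise ValueError("a line probe needs at least 3 samples")
    if np.ptp(x) == 0:
        if x[0] == 0:
            raise ValueError("max + min = 0; modulation undefined")
        return 0.0
    w = max(1, int(smoothing_window))
    if w > 1:
        kernel = np.ones(w) / w
        xs = np.convolve(np.pad(x, w // 2, mode="edge"), kernel, mode="same")
        xs = xs[w // 2 : w // 2 + len(x)]
    else:
        xs = x
    peaks, _ = find_peaks(xs, plateau_size=1)
    valleys, _ = find_peaks(-xs, plateau_size=1)
    if len(peaks) == 0 or len(valleys) == 0:
        raise ValueError("no peaks/valleys detected after smoothing")
    hi = float(xs[peaks].mean())
    lo = float(xs[valleys].mean())
    if hi + lo == 0:
        raise ValueError("max + min = 0; modulation undefined")
    return (hi - lo) / (hi + lo)


def field_of_view(
    sensor: SensorSpec, magnification: float
) -> tuple[float, float, float]:
    """Field of view (width mm, height mm, area cm^2) at a magnification.

    Optical magnification m projects a scene region of ``sensor / m`` onto
    the sensor, e.g. a 36 x 24 mm full-frame sensor sees 36 x 24 mm at 1x
    and 150 x 100 mm (150 cm^2) at 0.24x.
    """
    if magnification <= 0:
        raise ValueError("magnification must be positive")
    w = sensor.width_mm / magnification
    h = sensor.height_mm / magnification
    return w, h, w * h / 100.0


def megapixels(px_w: int, px_h: int) -> float:
    """Sensor resolution in megapixels, to 2 decimals."""
    if px_w <= 0 or px_h <= 0:
        raise ValueError("pixel counts must be positive")
    return round(px_w * px_h / 1e6, 2)
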
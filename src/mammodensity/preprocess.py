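"""Image conditioning before tissue segmentation.

Two operations prepare a mammogram for thresholding:

1. Contrast/brightness normalization — a percentile-based histogram stretch
   (plus optional manual gain/offset) so gray levels depend on tissue density
   rather than on the acquisition.
2. Thickness-compensating brightness correction — compressed breast tissue
   thins toward the skin line, so equal-density tissue images darker near the
   edge; thick interior fat can masquerade as dense tissue. Each breast pixel
   is rescaled by ``K(d) = alpha + (1 - alpha) * d``, where ``d`` in [0, 1]
   is the within-row fractional distance from the chest-wall reference (image
   border on CC views, pectoral boundary on MLO views) to the breast edge.
   ``alpha = 1`` leaves the image untouched; smaller ``alpha`` attenuates the
   interior more strongly.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .errors import ParameterError, SegmentationError
from .raster_io import ChestSide, Mammogram, RegionMask

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CorrectionParams:
    """Tunable preprocessing parameters.

    alpha
        Thickness-correction strength in [0, 1]; 1 disables the correction.
    brightness_offset, contrast_gain
        Manual affine adjustment ``clip(gain * x + offset, 0, 1)``.
    stretch_low_pct, stretch_high_pct
        Percentiles (over nonzero pixels) mapped to 0 and 1 by the histogram
        stretch. Defaults 1/99 are robust to dead or saturated pixels; set
        0/100 to stretch on the absolute min/max.
    """

    alpha: float = 1.0
    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.contrast_gain <= 0:
            raise ParameterError(
                f"contrast_gain must be positive, got {self.contrast_gain}"
            )
        if not self.stretch_low_pct < self.stretch_high_pct:
            raise ParameterError(
                "stretch_low_pct must be below stretch_high_pct "
                f"({self.stretch_low_pct} >= {self.stretch_high_pct})"
            )


@dataclasses.dataclass(frozen=True)
class DistanceMap:
    """Per-pixel fractional chest-to-edge distance, NaN off the breast."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=np.float64)
        defined = d[np.isfinite(d)]
        if defined.size and (defined.min() < 0.0 or defined.max() > 1.0):
            raise ParameterError("distance values must lie in [0, 1]")
        object.__setattr__(self, "d", d)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.d)


def normalize_contrast(img: Mammogram, params: CorrectionParams) -> Mammogram:
    """Histogram stretch: map the chosen low/high percentiles of the nonzero
    pixels to 0 and 1, clipping the result to [0, 1].

    A degenerate image (no nonzero pixels, or equal percentiles) is returned
    unchanged with a logged warning.
    """
    px = img.pixels
    fg = px[px > 0]
    if fg.size == 0:
        logger.warning("normalize_contrast: no nonzero pixels; image unchanged")
        return img
    lo, hi = np.percentile(fg, [params.stretch_low_pct, params.stretch_high_pct])
    if hi <= lo:
        logger.warning(
            "normalize_contrast: degenerate histogram (lo=%g, hi=%g); image unchanged",
            lo,
            hi,
        )
        return img
    stretched = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return img.with_pixels(stretched)


def manual_adjust(img: Mammogram, params: CorrectionParams) -> Mammogram:
    """Apply the manual affine adjustment ``clip(gain * x + offset, 0, 1)``."""
    adjusted = np.clip(
        params.contrast_gain * img.pixels + params.brightness_offset, 0.0, 1.0
    )
    return img.with_pixels(adjusted)


def edge_distance_map(
    breast: RegionMask,
    chest_side: ChestSide,
    pectoral_boundary: np.ndarray | None = None,
) -> DistanceMap:
    """Compute the per-row fractional distance from the chest reference to
    the breast edge for every breast pixel.

    For row i, the reference column r_i is the image border column on
    ``chest_side`` (CC) or ``pectoral_boundary[i]`` when a per-row pectoral
    boundary is supplied (MLO); the edge column e_i is the breast pixel
    farthest from the chest. Then ``d = |j - r_i| / |e_i - r_i|``, so d = 0
    at the reference and d = 1 at the breast edge. Rows where the edge
    coincides with the reference get d = 1. Pixels outside the mask are NaN.
    """
    bits = breast.bits
    if not bits.any():
        raise SegmentationError(
            "edge_distance_map requires a nonempty breast mask; run segmentation first"
        )
    rows, cols = bits.shape
    if pectoral_boundary is not None:
        pectoral_boundary = np.asarray(pectoral_boundary)
        if pectoral_boundary.shape != (rows,):
            raise ParameterError(
                f"pectoral_boundary must have one column index per row "
                f"({rows},), got {pectoral_boundary.shape}"
            )
    d = np.full((rows, cols), np.nan)
    border_col = 0 if chest_side is ChestSide.LEFT else cols - 1
    for i in range(rows):
        js = np.flatnonzero(bits[i])
        if js.size == 0:
            continue
        r_i = border_col if pectoral_boundary is None else int(pectoral_boundary[i])
        e_i = js.max() if chest_side is ChestSide.LEFT else js.min()
        span = abs(int(e_i) - r_i)
        if span == 0:
            d[i, js] = 1.0
        else:
            d[i, js] = np.minimum(np.abs(js - r_i) / span, 1.0)
    return DistanceMap(d)


def correction_coefficients(dmap: DistanceMap, alpha: float) -> np.ndarray:
    """The per-pixel factor ``K(d) = alpha + (1 - alpha) * d`` (NaN off-breast)."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    return alpha + (1.0 - alpha) * dmap.d


def brightness_correction(
    img: Mammogram, dmap: DistanceMap, alpha: float
) -> Mammogram:
    """Multiply each breast pixel by ``K = alpha + (1 - alpha) * d``.

    Non-breast pixels are untouched; ``alpha = 1`` returns the input
    bit-exactly.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if img.pixels.shape != dmap.d.shape:
        raise ParameterError(
            f"distance map shape {dmap.d.shape} does not match image "
            f"shape {img.pixels.shape}"
        )
    if alpha == 1.0:
        return img
    out = img.pixels.copy()
    m = dmap.defined
    out[m] = out[m] * (alpha + (1.0 - alpha) * dmap.d[m])
    return img.with_pixels(out)
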
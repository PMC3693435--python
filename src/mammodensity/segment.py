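"""Two-threshold breast and dense-tissue segmentation.

T1 separates background from objects; the largest connected foreground
component is taken to be the breast and everything else (labels, markers) is
discarded. Regions the operator flags as non-interest (e.g. the pectoral
muscle on MLO views, or objects touching the breast) are invalidated
explicitly. T2 then splits the retained breast pixels into fat and dense
tissue. Both threshold comparisons are non-strict (>=), so boundary pixels
are classified deterministically on the bright side.
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import ParameterError, SegmentationError
from .raster_io import Mammogram, RegionMask

logger = logging.getLogger(__name__)


class Label(enum.IntEnum):
    """Per-pixel tissue classes."""

    BACKGROUND = 0
    FAT = 1
    DENSE = 2


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """The two segmentation thresholds, on the [0, 1] intensity scale.

    t1 separates background from breast; t2 separates fat from dense tissue.
    A dense pixel must also be a breast pixel, hence t1 <= t2.
    """

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t1 <= 1.0 and 0.0 <= self.t2 <= 1.0):
            raise ParameterError(
                f"thresholds must lie in [0, 1], got t1={self.t1}, t2={self.t2}"
            )
        if self.t2 < self.t1:
            raise ParameterError(
                f"t2 must be >= t1 (dense pixels are breast pixels), "
                f"got t1={self.t1}, t2={self.t2}"
            )


@dataclasses.dataclass(frozen=True)
class TissueSegmentation:
    """Exhaustive, exclusive per-pixel labeling with its provenance."""

    labels: np.ndarray  # int grid over Label values
    thresholds: Thresholds
    invalidated: RegionMask

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.invalidated.bits.shape:
            raise ParameterError("labels and invalidated mask shapes differ")
        # Invalidated pixels can never carry a tissue class.
        if (lab[self.invalidated.bits] != Label.BACKGROUND).any():
            raise ParameterError("invalidated pixels must be labeled BACKGROUND")
        object.__setattr__(self, "labels", lab)

    @property
    def dt_pixels(self) -> int:
        return int((self.labels == Label.DENSE).sum())

    @property
    def ft_pixels(self) -> int:
        return int((self.labels == Label.FAT).sum())

    @property
    def breast(self) -> RegionMask:
        return RegionMask(self.labels != Label.BACKGROUND)


def propose_t1(img: Mammogram) -> float:
    """Propose a background/object threshold by Otsu's bimodal criterion.

    The proposal is a starting point the operator may override. A constant
    image has no bimodal structure; 0 is returned with a warning.
    """
    px = img.pixels
    if px.max() == px.min():
        logger.warning("propose_t1: constant image, returning 0")
        return 0.0
    return float(threshold_otsu(px))


def _connectivity_arg(connectivity: int) -> int:
    if connectivity == 8:
        return 2
    if connectivity == 4:
        return 1
    raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")


def segment_breast(img: Mammogram, t1: float, connectivity: int = 8) -> RegionMask:
    """Threshold at t1 and keep only the largest connected component.

    Foreground is ``intensity >= t1``; everything but the biggest object is
    treated as a region of non-interest and dropped. If several components
    tie for the largest size, the one containing the smallest (row, col) in
    lexicographic order wins, making the result deterministic.
    """
    if not 0.0 <= t1 <= 1.0:
        raise ParameterError(f"t1 must be in [0, 1], got {t1}")
    fg = img.pixels >= t1
    if not fg.any():
        raise SegmentationError(
            f"no foreground pixels at t1={t1}; threshold too high"
        )
    comps = cc_label(fg, connectivity=_connectivity_arg(connectivity))
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0  # background
    biggest = sizes.max()
    candidates = set(np.flatnonzero(sizes == biggest))
    if len(candidates) == 1:
        winner = candidates.pop()
    else:
        # Tie-break: first tied component encountered in raster order.
        flat = comps.ravel()
        winner = next(int(v) for v in flat if int(v) in candidates)
    return RegionMask(comps == winner)


def invalidate(mask: RegionMask, user_regions: list[RegionMask]) -> RegionMask:
    """Remove operator-flagged regions from a mask.

    Returns ``mask AND NOT union(user_regions)``; invalidated pixels are
    excluded from both dense and fat tissue downstream.
    """
    out = mask.bits.copy()
    for region in user_regions:
        if region.bits.shape != mask.bits.shape:
            raise ParameterError(
                f"user region shape {region.bits.shape} does not match "
                f"mask shape {mask.bits.shape}"
            )
        out &= ~region.bits
    return RegionMask(out)


def classify_tissue(
    img: Mammogram,
    breast: RegionMask,
    th: Thresholds,
    invalidated: RegionMask | None = None,
) -> TissueSegmentation:
    """Split the breast into fat and dense tissue at t2.

    Within the breast (minus invalidated regions), ``intensity >= t2`` is
    DENSE and the rest is FAT; everything else is BACKGROUND.
    """
    if not breast.same_shape_as(img):
        raise ParameterError("breast mask shape does not match image")
    if not breast.bits.any():
        raise SegmentationError("classify_tissue requires a nonempty breast mask")
    if invalidated is None:
        invalidated = RegionMask(np.zeros_like(breast.bits))
    elif invalidated.bits.shape != breast.bits.shape:
        raise ParameterError("invalidated mask shape does not match breast mask")
    effective = breast.bits & ~invalidated.bits
    labels = np.full(breast.bits.shape, int(Label.BACKGROUND), dtype=np.int8)
    dense = effective & (img.pixels >= th.t2)
    labels[effective] = Label.FAT
    labels[dense] = Label.DENSE
    return TissueSegmentation(labels=labels, thresholds=th, invalidated=invalidated)
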
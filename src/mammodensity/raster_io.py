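"""Reading and writing mammogram rasters and binary masks.

Images are carried through the pipeline as :class:`Mammogram` objects holding
a float64 intensity grid scaled to [0, 1], with "brighter = radiographically
denser" enforced at ingest (MONOCHROME1 DICOM frames are inverted).
Coordinates are 0-based, row-major: pixel (i, j) is row i, column j.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, ParameterError

#: Minimum number of rows/columns for a valid mammogram or mask.
MIN_DIM = 16


class View(str, enum.Enum):
    """Standard mammographic projections."""

    CC = "CC"  # craniocaudal
    MLO = "MLO"  # mediolateral oblique (may include the pectoral muscle)


class Laterality(str, enum.Enum):
    LEFT = "L"
    RIGHT = "R"


class ChestSide(str, enum.Enum):
    """Which image column border is adjacent to the chest wall."""

    LEFT = "left"
    RIGHT = "right"


def default_chest_side(laterality: Laterality) -> ChestSide:
    """Default convention: left-breast images have the chest wall at the
    left image border, right-breast images at the right border."""
    return ChestSide.LEFT if laterality is Laterality.LEFT else ChestSide.RIGHT


@dataclasses.dataclass(frozen=True)
class Mammogram:
    """A 2-D grayscale mammogram with intensities scaled to [0, 1].

    Parameters
    ----------
    pixels
        Float array of shape (rows, cols), values in [0, 1]. Higher values
        mean radiographically denser (brighter) tissue.
    view, laterality, chest_side
        Acquisition metadata. ``chest_side`` defaults to the border implied
        by ``laterality`` (left breast -> left border).
    source_bit_depth
        Bit depth of the stored raster the intensities were scaled from.
    """

    pixels: np.ndarray
    view: View = View.CC
    laterality: Laterality = Laterality.LEFT
    chest_side: ChestSide | None = None
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ParameterError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_DIM or px.shape[1] < MIN_DIM:
            raise ParameterError(
                f"image must be at least {MIN_DIM}x{MIN_DIM}, got {px.shape}"
            )
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ParameterError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        if self.chest_side is None:
            object.__setattr__(
                self, "chest_side", default_chest_side(self.laterality)
            )

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "Mammogram":
        """Return a copy of this image carrying new pixel data."""
        return dataclasses.replace(self, pixels=pixels)


@dataclasses.dataclass(frozen=True)
class RegionMask:
    """A binary region on the same grid as a mammogram."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=bool)
        if b.ndim != 2:
            raise ParameterError(f"mask must be 2-D, got shape {b.shape}")
        if b.shape[0] < MIN_DIM or b.shape[1] < MIN_DIM:
            raise ParameterError(
                f"mask must be at least {MIN_DIM}x{MIN_DIM}, got {b.shape}"
            )
        object.__setattr__(self, "bits", b)

    @property
    def rows(self) -> int:
        return self.bits.shape[0]

    @property
    def cols(self) -> int:
        return self.bits.shape[1]

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def same_shape_as(self, other) -> bool:
        return self.bits.shape == (other.rows, other.cols)


def _collapse_channels(arr: np.ndarray, path) -> np.ndarray:
    """Reduce an (H, W, C) array to (H, W) if all channels agree."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0]
        first = arr[:, :, 0]
        if all(np.array_equal(arr[:, :, c], first) for c in range(1, arr.shape[2])):
            return first
        raise FormatError(
            f"{path}: multi-channel image with unequal channels is not a grayscale mammogram"
        )
    raise FormatError(f"{path}: unsupported array dimensionality {arr.ndim}")


def _bit_depth_of(arr: np.ndarray, path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"{path}: unsupported PNG sample type {arr.dtype}")


def read_png(
    path,
    *,
    view: View = View.CC,
    laterality: Laterality = Laterality.LEFT,
    chest_side: ChestSide | None = None,
) -> Mammogram:
    """Read an 8- or 16-bit grayscale PNG as a [0, 1]-scaled mammogram.

    Multi-channel files are accepted only when every channel is identical
    (grayscale stored as RGB). Intensities are divided by ``2**depth - 1``.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except OSError:
        raise
    except Exception as exc:  # imageio wraps decode failures variously
        raise FormatError(f"{path}: could not decode PNG ({exc})") from exc
    arr = _collapse_channels(np.asarray(arr), path)
    depth = _bit_depth_of(arr, path)
    pixels = arr.astype(np.float64) / float(2**depth - 1)
    return Mammogram(
        pixels,
        view=view,
        laterality=laterality,
        chest_side=chest_side,
        source_bit_depth=depth,
    )


def write_image(img: Mammogram, path, *, bit_depth: int = 16) -> None:
    """Write a mammogram as a grayscale PNG at the given bit depth."""
    if bit_depth not in (8, 16):
        raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    raw = np.rint(img.pixels * scale).astype(dtype)
    iio.imwrite(Path(path), raw, extension=".png")


def write_mask(mask: RegionMask, path) -> None:
    """Write a binary mask as a lossless 8-bit PNG (0 / 255)."""
    raw = np.where(mask.bits, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), raw, extension=".png")


def read_mask(path) -> RegionMask:
    """Read a mask written by :func:`write_mask`; any nonzero pixel is set."""
    arr = _collapse_channels(np.asarray(iio.imread(Path(path))), path)
    return RegionMask(arr > 0)


def read_dicom_pixels(
    path,
    *,
    view: View = View.CC,
    laterality: Laterality = Laterality.LEFT,
    chest_side: ChestSide | None = None,
) -> Mammogram:
    """Extract monochrome pixel data from a DICOM file.

    Applies RescaleSlope/RescaleIntercept, scales by the stored bit depth and
    inverts MONOCHROME1 frames so that higher intensity always means denser
    tissue. Only uncompressed / losslessly decodable monochrome frames are
    supported.
    """
    import pydicom
    from pydicom.errors import InvalidDicomError

    try:
        ds = pydicom.dcmread(str(path), force=False)
    except InvalidDicomError as exc:
        raise FormatError(f"{path}: not a DICOM file ({exc})") from exc
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise FormatError(
            f"{path}: unsupported photometric interpretation {photometric!r}"
        )
    try:
        stored = ds.pixel_array
    except Exception as exc:
        raise FormatError(
            f"{path}: cannot decode pixel data (unsupported transfer syntax: "
            f"{ds.file_meta.TransferSyntaxUID if ds.file_meta else 'unknown'})"
        ) from exc
    if stored.ndim != 2:
        raise FormatError(f"{path}: expected a single monochrome frame")

    bits = int(getattr(ds, "BitsStored", stored.dtype.itemsize * 8))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = stored.astype(np.float64) * slope + intercept
    # Theoretical output range implied by the stored bit depth and rescale.
    lo = min(intercept, slope * (2**bits - 1) + intercept)
    hi = max(intercept, slope * (2**bits - 1) + intercept)
    if hi == lo:
        pixels = np.zeros_like(values)
    else:
        pixels = (values - lo) / (hi - lo)
    if photometric == "MONOCHROME1":
        pixels = 1.0 - pixels
    pixels = np.clip(pixels, 0.0, 1.0)
    return Mammogram(
        pixels,
        view=view,
        laterality=laterality,
        chest_side=chest_side,
        source_bit_depth=bits,
    )
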
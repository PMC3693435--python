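"""Synthetic mammogram phantoms with exact ground truth.

No public mammogram collection with per-pixel dense-tissue truth exists, so
the pipeline is validated on generated phantoms that reproduce the image
properties the method relies on: a breast-shaped bright object against a
dark background (half-ellipse on the chest-wall border for CC views, plus a
bright pectoral wedge for MLO), embedded high-intensity "dense" blobs whose
pixel fraction of the breast is known exactly, a simulated breast-thickness
falloff that dims the image toward the skin line, off-breast label
artifacts, and additive Gaussian noise.

The falloff multiplies each breast pixel by ``F(d) = a / (a + (1 - a) d)``
with ``a = edge_falloff_alpha``: full brightness at the chest reference,
dimmed to a factor ``a`` at the breast edge. Because F is the algebraic
inverse of the brightness-correction profile K(d) = a + (1 - a) d (up to the
constant a), applying the correction at matching alpha restores a uniformly
rescaled copy of the clean image — the correction is exactly invertible,
which gives sharp, assertable expectations in tests.

The generator also simulates repeated PD readings by independent raters
with additive bias and Gaussian noise, for exercising the agreement
statistics against closed forms.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .agreement import RaterReadings
from .errors import ParameterError
from .preprocess import edge_distance_map
from .raster_io import (
    ChestSide,
    Laterality,
    Mammogram,
    RegionMask,
    View,
    write_image,
    write_mask,
)
from .segment import Label, Thresholds, TissueSegmentation


@dataclasses.dataclass(frozen=True)
class PectoralSpec:
    """A triangular pectoral wedge in the chest-side top corner (MLO).

    The wedge spans ``extent_rows`` rows; at row i (from the top) its
    boundary column is ``width_cols * (1 - i / extent_rows)``.
    """

    extent_rows: int = 120
    width_cols: int = 60
    level: float = 0.95


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Intensity levels must satisfy background < fat < dense so that midway
    thresholds separate the classes exactly on a noiseless image.
    ``true_dense_fraction`` is the target share of breast pixels rendered
    dense; the generator hits it to the nearest pixel. ``edge_falloff_alpha``
    simulates the thickness effect (1 = none); ``n_labels`` bright artifact
    blobs are placed fully off the breast.
    """

    rows: int = 256
    cols: int = 256
    view: View = View.CC
    background_level: float = 0.05
    fat_level: float = 0.45
    dense_level: float = 0.75
    true_dense_fraction: float = 0.20
    edge_falloff_alpha: float = 1.0
    n_labels: int = 0
    pectoral: PectoralSpec | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "view", View(self.view))
        if not (self.background_level < self.fat_level < self.dense_level):
            raise ParameterError(
                "intensity levels must satisfy background < fat < dense, got "
                f"{self.background_level}, {self.fat_level}, {self.dense_level}"
            )
        if not 0.0 <= self.true_dense_fraction < 1.0:
            raise ParameterError(
                f"true_dense_fraction must be in [0, 1), got {self.true_dense_fraction}"
            )
        if not 0.0 < self.edge_falloff_alpha <= 1.0:
            raise ParameterError(
                f"edge_falloff_alpha must be in (0, 1], got {self.edge_falloff_alpha}"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_labels < 0:
            raise ParameterError(f"n_labels must be >= 0, got {self.n_labels}")
        if self.rows < 64 or self.cols < 64:
            raise ParameterError("phantoms smaller than 64x64 are not supported")

    @property
    def midway_thresholds(self) -> Thresholds:
        """Thresholds midway between the clean intensity levels."""
        return Thresholds(
            t1=(self.background_level + self.fat_level) / 2.0,
            t2=(self.fat_level + self.dense_level) / 2.0,
        )


@dataclasses.dataclass(frozen=True)
class PhantomResult:
    """A rendered phantom plus its exact ground truth."""

    image: Mammogram
    ground_truth: TissueSegmentation  # labels on the clean (pre-falloff) image
    breast: RegionMask  # breast tissue (pectoral excluded)
    label_artifacts: RegionMask
    pectoral_mask: RegionMask
    pectoral_boundary: np.ndarray | None  # per-row reference column (MLO)
    achieved_dense_fraction: float
    spec: PhantomSpec


def _breast_ellipse(rows: int, cols: int) -> np.ndarray:
    """Half-ellipse breast flush against the left (chest) border."""
    ci = (rows - 1) / 2.0
    a = 0.42 * rows  # vertical semi-axis
    b = 0.72 * cols  # horizontal extent from the chest wall
    ii, jj = np.mgrid[0:rows, 0:cols]
    return ((ii - ci) / a) ** 2 + (jj / b) ** 2 <= 1.0


def _pectoral_wedge(rows: int, cols: int, pect: PectoralSpec) -> np.ndarray:
    ii, jj = np.mgrid[0:rows, 0:cols]
    extent = min(pect.extent_rows, rows)
    boundary = pect.width_cols * (1.0 - ii / extent)
    return (ii < extent) & (jj < boundary)


def _place_dense_blobs(
    rng: np.random.Generator, breast_core: np.ndarray, target: int
) -> np.ndarray:
    """Random disks inside the breast, trimmed to exactly `target` pixels.

    The last disk is clipped pixel-wise (raster order) so the achieved count
    matches the target exactly.
    """
    rows, cols = breast_core.shape
    dense = np.zeros_like(breast_core)
    core_idx = np.flatnonzero(breast_core)
    placed = 0
    max_radius = max(4, rows // 10)
    ii, jj = np.mgrid[0:rows, 0:cols]
    while placed < target:
        flat = core_idx[rng.integers(core_idx.size)]
        ci, cj = divmod(int(flat), cols)
        radius = int(rng.integers(3, max_radius + 1))
        disk = (ii - ci) ** 2 + (jj - cj) ** 2 <= radius**2
        new = disk & breast_core & ~dense
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if placed + n_new > target:
            keep = target - placed
            new_idx = np.flatnonzero(new)[:keep]
            new = np.zeros_like(new)
            new.ravel()[new_idx] = True
            n_new = keep
        dense |= new
        placed += n_new
    return dense


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render a phantom; identical spec and seed give a bit-identical image."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.rows, spec.cols

    breast_obj = _breast_ellipse(rows, cols)
    pect_spec = spec.pectoral
    if spec.view is View.MLO and pect_spec is None:
        pect_spec = PectoralSpec()
    if pect_spec is not None:
        pect = _pectoral_wedge(rows, cols, pect_spec)
        breast_obj |= pect
    else:
        pect = np.zeros((rows, cols), dtype=bool)
    breast_core = breast_obj & ~pect

    area = int(breast_core.sum())
    target = int(round(spec.true_dense_fraction * area))
    if target > area:
        raise ParameterError("requested dense fraction exceeds breast area")
    dense = (
        _place_dense_blobs(rng, breast_core, target)
        if target > 0
        else np.zeros_like(breast_core)
    )

    img = np.full((rows, cols), spec.background_level)
    img[breast_core] = spec.fat_level
    img[dense] = spec.dense_level
    if pect_spec is not None:
        img[pect] = pect_spec.level

    pect_boundary = None
    if pect_spec is not None:
        extent = min(pect_spec.extent_rows, rows)
        ii = np.arange(rows)
        pect_boundary = np.where(
            ii < extent,
            np.ceil(pect_spec.width_cols * (1.0 - ii / extent)).astype(int),
            0,
        )

    if spec.edge_falloff_alpha < 1.0:
        dmap = edge_distance_map(
            RegionMask(breast_core), ChestSide.LEFT, pect_boundary
        )
        a = spec.edge_falloff_alpha
        m = dmap.defined
        img[m] = img[m] * (a / (a + (1.0 - a) * dmap.d[m]))

    labels_mask = np.zeros((rows, cols), dtype=bool)
    if spec.n_labels > 0:
        labels_mask = _place_labels(rng, breast_obj, spec.n_labels)
        img[labels_mask] = 0.95

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = np.full((rows, cols), int(Label.BACKGROUND), dtype=np.int8)
    truth[breast_core] = Label.FAT
    truth[dense] = Label.DENSE
    ground_truth = TissueSegmentation(
        labels=truth,
        thresholds=spec.midway_thresholds,
        invalidated=RegionMask(pect),
    )
    return PhantomResult(
        image=Mammogram(
            img,
            view=spec.view,
            laterality=Laterality.LEFT,
            chest_side=ChestSide.LEFT,
            source_bit_depth=16,
        ),
        ground_truth=ground_truth,
        breast=RegionMask(breast_core),
        label_artifacts=RegionMask(labels_mask),
        pectoral_mask=RegionMask(pect),
        pectoral_boundary=pect_boundary,
        achieved_dense_fraction=target / area if area else 0.0,
        spec=spec,
    )


def _place_labels(
    rng: np.random.Generator, breast_obj: np.ndarray, n_labels: int
) -> np.ndarray:
    """Bright rectangular artifacts fully outside the breast.

    Labels are placed in disjoint horizontal bands of a strip near the far
    (non-chest) border, so they never touch the breast or each other even
    under 8-connectivity.
    """
    rows, cols = breast_obj.shape
    # Column strip beyond the breast's horizontal extent, with a safety gap.
    breast_extent = int(np.flatnonzero(breast_obj.any(axis=0)).max())
    strip_lo = breast_extent + 3
    strip_hi = cols - 2
    if strip_hi - strip_lo < 6:
        raise ParameterError("image too narrow to place off-breast labels")
    mask = np.zeros((rows, cols), dtype=bool)
    band = rows // n_labels
    for k in range(n_labels):
        h = int(rng.integers(4, 9))
        w = int(rng.integers(4, min(9, strip_hi - strip_lo)))
        r0 = k * band + int(rng.integers(1, max(2, band - h - 2)))
        c0 = strip_lo + int(rng.integers(0, strip_hi - strip_lo - w + 1))
        mask[r0 : r0 + h, c0 : c0 + w] = True
    return mask


def simulate_raters(
    true_pd: Sequence[float],
    rater_bias: Sequence[float],
    rater_sd: Sequence[float],
    seed: int,
) -> RaterReadings:
    """Simulate repeated PD readings of the same images.

    Rater r reads image t as ``clip(true_pd + bias_r + N(0, sd_r), 0, 100)``.
    Reproducible under the seed.
    """
    true_pd = np.asarray(true_pd, dtype=float)
    rater_bias = np.asarray(rater_bias, dtype=float)
    rater_sd = np.asarray(rater_sd, dtype=float)
    if rater_bias.shape != rater_sd.shape:
        raise ParameterError("rater_bias and rater_sd must have equal length")
    if (rater_sd < 0).any():
        raise ParameterError("rater noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    readings = {}
    for r, (bias, sd) in enumerate(zip(rater_bias, rater_sd), start=1):
        noise = rng.normal(0.0, sd, size=true_pd.shape) if sd > 0 else 0.0
        readings[f"rater{r}"] = np.clip(true_pd + bias + noise, 0.0, 100.0)
    return RaterReadings(
        image_ids=list(range(true_pd.size)), readings=readings
    )


def write_phantom(result: PhantomResult, out_dir, stem: str = "phantom") -> dict:
    """Write the phantom image, ground-truth label PNG, breast mask and a
    JSON sidecar with the spec and achieved dense fraction. Returns the
    mapping of artifact names to paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "truth": out_dir / f"{stem}_truth.png",
        "breast": out_dir / f"{stem}_breast.png",
        "sidecar": out_dir / f"{stem}.json",
    }
    write_image(result.image, paths["image"], bit_depth=16)
    import imageio.v3 as iio

    iio.imwrite(
        paths["truth"],
        result.ground_truth.labels.astype(np.uint8),
        extension=".png",
    )
    write_mask(result.breast, paths["breast"])
    spec_dict = dataclasses.asdict(result.spec)
    spec_dict["view"] = result.spec.view.value
    sidecar = {
        "spec": spec_dict,
        "achieved_dense_fraction": result.achieved_dense_fraction,
        "thresholds_midway": dataclasses.asdict(result.spec.midway_thresholds),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return {k: str(v) for k, v in paths.items()}
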
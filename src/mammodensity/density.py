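"""Percent density and its categorical scales.

Percent density is the share of the segmented breast occupied by dense
tissue, PD = 100 * DT / (DT + FT), where DT and FT are dense- and
fat-tissue pixel counts. PD maps onto the semiquantitative six-category
Boyd scale (0%, <10%, 10-25%, 25-50%, 50-75%, >75%) and, generically, onto
any ordered cut-off list (e.g. control-group quartiles).
"""

from __future__ import annotations

import dataclasses
import enum
from fractions import Fraction
from typing import Sequence

import numpy as np

from .errors import DensityUndefinedError, ParameterError
from .segment import Thresholds, TissueSegmentation


class BoydCategory(enum.IntEnum):
    """Six-category semiquantitative PD scale, in increasing density order."""

    C0 = 0  # exactly 0%
    C_LT10 = 1  # (0, 10)
    C10_25 = 2  # [10, 25)
    C25_50 = 3  # [25, 50)
    C50_75 = 4  # [50, 75]
    C_GT75 = 5  # (75, 100]

    @property
    def label(self) -> str:
        return _BOYD_LABELS[self]


_BOYD_LABELS = {
    BoydCategory.C0: "0%",
    BoydCategory.C_LT10: "<10%",
    BoydCategory.C10_25: "10-25%",
    BoydCategory.C25_50: "25-50%",
    BoydCategory.C50_75: "50-75%",
    BoydCategory.C_GT75: ">75%",
}

#: The five Boyd cut-offs on the PD scale.
BOYD_CUTOFFS = (0.0, 10.0, 25.0, 50.0, 75.0)


@dataclasses.dataclass(frozen=True)
class DensityResult:
    """PD with the counts and thresholds that produced it."""

    dt_pixels: int
    ft_pixels: int
    pd_percent: float
    boyd_category: BoydCategory
    thresholds: Thresholds

    @property
    def pd_display(self) -> float:
        """PD rounded to 0.1%, the precision used in reports."""
        return round(self.pd_percent, 1)


def compute_pd(seg: TissueSegmentation) -> DensityResult:
    """Compute PD = 100 * DT / (DT + FT) from a tissue segmentation.

    The ratio is evaluated as an exact rational before conversion to float.
    """
    dt, ft = seg.dt_pixels, seg.ft_pixels
    if dt + ft == 0:
        raise DensityUndefinedError(
            "PD undefined: segmentation contains no breast pixels"
        )
    pd = float(Fraction(100 * dt, dt + ft))
    return DensityResult(
        dt_pixels=dt,
        ft_pixels=ft,
        pd_percent=pd,
        boyd_category=categorize_boyd(pd),
        thresholds=seg.thresholds,
    )


def categorize_boyd(pd: float) -> BoydCategory:
    """Assign a PD value to its Boyd category.

    Boundary convention: exact 0 is its own category; 10, 25 and 50 belong
    to the category they open (left-closed); 75 stays in 50-75.
    """
    if not 0.0 <= pd <= 100.0:
        raise ParameterError(f"PD must be in [0, 100], got {pd}")
    if pd == 0.0:
        return BoydCategory.C0
    if pd < 10.0:
        return BoydCategory.C_LT10
    if pd < 25.0:
        return BoydCategory.C10_25
    if pd < 50.0:
        return BoydCategory.C25_50
    if pd <= 75.0:
        return BoydCategory.C50_75
    return BoydCategory.C_GT75


def categorize_cutoffs(pd: float, cutoffs: Sequence[float]) -> int:
    """Generic left-closed binning of a PD value against ordered cut-offs.

    With n cut-offs c_1 < ... < c_n inside (0, 100) the bins are
    [0, c_1), [c_1, c_2), ..., [c_n, 100]: a value equal to a cut-off falls
    in the bin that cut-off opens. Returns the 0-based bin index.
    """
    cuts = np.asarray(cutoffs, dtype=float)
    if cuts.ndim != 1 or cuts.size == 0:
        raise ParameterError("cutoffs must be a nonempty 1-D sequence")
    if not np.all(np.diff(cuts) > 0):
        raise ParameterError(f"cutoffs must be strictly increasing, got {cutoffs}")
    if not 0.0 <= pd <= 100.0:
        raise ParameterError(f"PD must be in [0, 100], got {pd}")
    return int(np.searchsorted(cuts, pd, side="right"))
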
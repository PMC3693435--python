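"""Rater-agreement and scale-comparison statistics.

These are the statistics used to validate a density-assessment tool against
repeated readings: Lin's concordance correlation coefficient (CCC) for
continuous PD, Bland-Altman paired-difference summaries (mean difference
with empirical 5th/95th percentiles and classical limits of agreement), and
quadratic-weighted kappa for agreement on an ordered categorical scale such
as Boyd's. A per-category PD distribution summary supports comparing a
quantitative reader against visual scales.

Conventions (documented because published reports rarely state them):
percentiles use the empirical-distribution type-7 linear interpolation
(numpy's default); the CCC confidence interval uses Lin's Fisher
z-transformation with the asymptotic variance from Lin (1989); the weighted
kappa interval uses the Fleiss-Cohen large-sample standard error. Readings
missing for either member of a pair are dropped pairwise with a logged count.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AgreementUndefinedError, ParameterError

logger = logging.getLogger(__name__)

#: Name of the CCC interval construction, reported in output metadata.
CCC_CI_METHOD = "Fisher z-transform (Lin 1989 asymptotic variance)"
KAPPA_CI_METHOD = "Fleiss-Cohen large-sample standard error"


@dataclasses.dataclass(frozen=True)
class RaterReadings:
    """Aligned per-image PD readings from two or more raters."""

    image_ids: Sequence
    readings: Mapping[str, np.ndarray]  # rater id -> PD values in [0, 100]

    def __post_init__(self) -> None:
        n = len(self.image_ids)
        clean = {}
        for rater, vals in self.readings.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (n,):
                raise ParameterError(
                    f"rater {rater!r} has {arr.shape} readings for {n} images"
                )
            clean[rater] = arr
        object.__setattr__(self, "readings", clean)

    @property
    def raters(self) -> list[str]:
        return list(self.readings)

    def pair(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        """Aligned readings for two raters, missing rows dropped pairwise."""
        x, y = self.readings[a], self.readings[b]
        keep = np.isfinite(x) & np.isfinite(y)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "pairwise deletion: dropped %d of %d images for (%s, %s)",
                dropped,
                keep.size,
                a,
                b,
            )
        return x[keep], y[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(self.readings), index=list(self.image_ids))


@dataclasses.dataclass(frozen=True)
class AgreementSummary:
    """Paired-comparison summary: Bland-Altman differences plus CCC."""

    n: int
    mean_difference: float
    p05_diff: float
    p95_diff: float
    sd_diff: float
    loa_low: float  # classical limits mean +/- 1.96 sd, for plotting
    loa_high: float
    ccc: float | None = None
    ccc_ci: tuple[float, float] | None = None


def _moments(x: np.ndarray, y: np.ndarray):
    """Population (1/n) moment estimators used by the CCC."""
    xm, ym = x.mean(), y.mean()
    sx2 = np.mean((x - xm) ** 2)
    sy2 = np.mean((y - ym) ** 2)
    sxy = np.mean((x - xm) * (y - ym))
    return xm, ym, sx2, sy2, sxy


def lin_ccc(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with its confidence interval.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population (1/n)
    moments. The interval is computed on the Fisher z scale with Lin's
    asymptotic variance and back-transformed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("series must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError(f"need at least 3 paired readings, got {n}")
    xm, ym, sx2, sy2, sxy = _moments(x, y)
    if sx2 == 0.0 and sy2 == 0.0:
        raise AgreementUndefinedError(
            "CCC undefined: both series are constant (zero total variance)"
        )
    ccc = 2.0 * sxy / (sx2 + sy2 + (xm - ym) ** 2)

    # Interval on the z scale; degenerate when |ccc| = 1 or either series is
    # constant (Pearson r undefined).
    if sx2 == 0.0 or sy2 == 0.0 or abs(ccc) >= 1.0:
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / math.sqrt(sx2 * sy2)
    if r == 0.0:
        return float(ccc), (float("nan"), float("nan"))
    u2 = (xm - ym) ** 2 / math.sqrt(sx2 * sy2)
    c2 = ccc * ccc
    var_z = (
        (1.0 - r * r) * c2 / ((1.0 - c2) * r * r)
        + 2.0 * ccc**3 * (1.0 - ccc) * u2 / (r * (1.0 - c2) ** 2)
        - ccc**4 * u2 * u2 / (2.0 * r * r * (1.0 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    from scipy.stats import norm  # local import keeps scipy optional elsewhere

    zcrit = norm.ppf(0.5 + conf / 2.0)
    z = math.atanh(ccc)
    half = zcrit * math.sqrt(var_z)
    return float(ccc), (math.tanh(z - half), math.tanh(z + half))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Paired-difference summary of two readings of the same images.

    Differences are ``d = x - y`` (first-listed rater minus second). Returns
    their mean, empirical 5th/95th percentiles, and the classical limits of
    agreement mean +/- 1.96 sd for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("series must have equal length")
    if x.size < 2:
        raise ParameterError(f"need at least 2 paired readings, got {x.size}")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    p05, p95 = np.percentile(d, [5.0, 95.0])
    return AgreementSummary(
        n=int(d.size),
        mean_difference=mean,
        p05_diff=float(p05),
        p95_diff=float(p95),
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
    )


def pairwise_agreement(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Bland-Altman differences and CCC for one rater pair, in one record."""
    summary = bland_altman(x, y)
    ccc, ci = lin_ccc(x, y)
    return dataclasses.replace(summary, ccc=ccc, ccc_ci=ci)


def quadratic_weights(k: int) -> np.ndarray:
    """Agreement weights w_ij = 1 - (i - j)^2 / (k - 1)^2."""
    if k < 2:
        raise ParameterError(f"need at least 2 categories, got {k}")
    idx = np.arange(k)
    return 1.0 - (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def weighted_kappa(
    a: Sequence[int],
    b: Sequence[int],
    k: int,
    conf: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Quadratic-weighted kappa between two ordered categorical series.

    Categories are coded 0..k-1. kappa = (p_o - p_e) / (1 - p_e) with
    weighted observed and expected agreement from the k x k contingency
    table; the interval uses the Fleiss-Cohen large-sample standard error.
    If both raters are constant and identical (p_e = 1) the statistic is
    undefined and NaN is returned with a diagnostic.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ParameterError("series must have equal length")
    n = a.size
    if n < k:
        raise ParameterError(f"need at least k={k} pairs, got {n}")
    if a.min() < 0 or a.max() >= k or b.min() < 0 or b.max() >= k:
        raise ParameterError(f"categories must be coded 0..{k - 1}")

    table = np.zeros((k, k))
    np.add.at(table, (a, b), 1.0)
    p = table / n
    pi = p.sum(axis=1)  # rater a margins
    pj = p.sum(axis=0)  # rater b margins
    w = quadratic_weights(k)
    p_o = float((w * p).sum())
    p_e = float((w * (pi[:, None] * pj[None, :])).sum())
    if p_e >= 1.0:
        logger.warning(
            "weighted_kappa undefined: expected agreement is 1 "
            "(both raters constant in the same category)"
        )
        nan = float("nan")
        return nan, (nan, nan)
    kappa = (p_o - p_e) / (1.0 - p_e)

    wbar_i = (w * pj[None, :]).sum(axis=1)  # row-wise expected weights
    wbar_j = (w * pi[:, None]).sum(axis=0)
    penalty = w - (wbar_i[:, None] + wbar_j[None, :]) * (1.0 - kappa)
    var = (
        float((p * penalty**2).sum()) - (kappa - p_e * (1.0 - kappa)) ** 2
    ) / (n * (1.0 - p_e) ** 2)
    var = max(var, 0.0)
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + conf / 2.0)
    half = zcrit * math.sqrt(var)
    return float(kappa), (kappa - half, kappa + half)


def per_category_summary(
    pd_values: Sequence[float], categories: Sequence
) -> pd.DataFrame:
    """Distribution of PD readings within each visual-scale category.

    Returns one row per category (in sorted category order) with n, mean PD
    and the empirical 5th/95th percentiles — the standard layout for
    comparing a quantitative reader against a visual scale. Categories with
    no readings get n = 0 and NaN summaries.
    """
    values = np.asarray(pd_values, dtype=float)
    cats = pd.Series(categories)  # preserves Categorical dtype and its order
    if values.shape != (len(cats),):
        raise ParameterError("pd values and categories must be aligned")
    if isinstance(cats.dtype, pd.CategoricalDtype):
        levels = list(cats.cat.categories)
    else:
        levels = sorted(cats.unique())
    rows = []
    for level in levels:
        sel = values[(cats == level).to_numpy()]
        if sel.size == 0:
            rows.append((level, 0, np.nan, np.nan, np.nan))
        else:
            rows.append(
                (
                    level,
                    int(sel.size),
                    float(sel.mean()),
                    float(np.percentile(sel, 5.0)),
                    float(np.percentile(sel, 95.0)),
                )
            )
    return pd.DataFrame(
        rows, columns=["category", "n", "mean_pd", "p05", "p95"]
    ).set_index("category")


def bland_altman_plot(x, y, ax=None, label_x="rater 1", label_y="rater 2"):
    """Classical Bland-Altman plot: difference vs mean, with limits of
    agreement and the empirical 5th/95th percentile band."""
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    summary = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=8, alpha=0.6)
    ax.axhline(summary.mean_difference, color="k", lw=1)
    for val, style in (
        (summary.loa_low, "--"),
        (summary.loa_high, "--"),
        (summary.p05_diff, ":"),
        (summary.p95_diff, ":"),
    ):
        ax.axhline(val, color="gray", ls=style, lw=1)
    ax.set_xlabel(f"mean PD of {label_x} and {label_y} (%)")
    ax.set_ylabel(f"PD {label_x} - PD {label_y} (%)")
    return ax
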
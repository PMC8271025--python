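"""Agreement and distribution summaries for report tables and figures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlandAltmanStats",
    "bland_altman",
    "DistributionSummary",
    "distribution_summary",
    "significance_stars",
]


@dataclass(frozen=True)
class BlandAltmanStats:
    """Limits-of-agreement statistics of paired measurements.

    Differences follow the x - y convention (scan1 - scan2, or
    reader1 - reader2); the limits are mean +/- 1.96 SD with the n-1
    standard deviation.
    """

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(x, y) -> BlandAltmanStats:
    """Bland--Altman limits of agreement for paired samples (x - y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired samples must be 1-D, equally long, n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanStats(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=int(x.size),
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Box-whisker summary with 5--95 percentile whiskers.

    ``outliers`` lists the individual values outside [p5, p95], the dots
    of a 5--95-percentile box plot.
    """

    n: int
    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    outliers: tuple[float, ...]


def distribution_summary(values) -> DistributionSummary:
    """Summarise a sample for a 5--95 percentile box-whisker display.

    Percentiles use linear interpolation between closest ranks (the numpy
    default).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("distribution summary requires a nonempty sample")
    p5, q1, med, q3, p95 = np.percentile(v, [5, 25, 50, 75, 95])
    outliers = tuple(float(o) for o in np.sort(v[(v < p5) | (v > p95)]))
    return DistributionSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        p5=float(p5),
        p95=float(p95),
        outliers=outliers,
    )


def significance_stars(p: float) -> str:
    """Conventional significance markers: * < 0.05, ** < 0.01, *** < 0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
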
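"""Scan--rescan robustness: concordance correlation, dynamic range, stratification.

Robustness of a feature is quantified on paired samples ``x`` (first scan)
and ``y`` (rescan after repositioning), one value per object, both
segmented in the same session.  Two statistics are used:

* Lin's concordance correlation coefficient (CCC),

  .. math:: \\mathrm{CCC} = \\frac{2 s_{xy}}{s_x^2 + s_y^2 + (\\bar x - \\bar y)^2},

  which penalises both imprecision and location/scale shift; 1 means
  perfect agreement (x_i = y_i), -1 perfect anticorrelation (x_i = -y_i).

* the dynamic range (DR),

  .. math:: \\mathrm{DR} = 1 - \\frac{\\tfrac1n\\sum_i |x_i - y_i|}{\\max(x \\cup y) - \\min(x \\cup y)},

  which is 1 for identical samples with nonzero spread and 0 when every
  within-pair difference is as large as the pooled range (two distinct
  constant samples).

A feature counts as robust at cutoff c when both CCC >= c and DR >= c;
the conventional cutoffs are 0.85 (relaxed), 0.90 and 0.95 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog

__all__ = [
    "DEFAULT_CUTOFFS",
    "concordance_cc",
    "dynamic_range",
    "corrected_ccc",
    "robustness_table",
    "RobustnessStratification",
    "stratify",
]

DEFAULT_CUTOFFS = (0.85, 0.90, 0.95)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("paired samples must be one-dimensional and equally long")
    if x.size < 2:
        raise ValueError("paired samples need at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("paired samples must be finite")
    return x, y


def concordance_cc(x, y, *, moment: str = "population") -> float:
    """Lin's concordance correlation coefficient of two paired samples.

    Parameters
    ----------
    x, y
        Paired measurements in identical object order.
    moment
        ``"population"`` (default) uses 1/n variances and covariance, the
        convention of Lin's original estimator; ``"sample"`` uses 1/(n-1).
        The choice cancels in the correlation part but not in the shift
        penalty term.

    Returns
    -------
    float
        CCC in [-1, 1]; NaN when the denominator is zero (both samples
        constant with equal means), which callers flag as undefined.
    """
    x, y = _paired(x, y)
    ddof = {"population": 0, "sample": 1}[moment]
    n = x.size
    sxy = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    sx2 = x.var(ddof=ddof)
    sy2 = y.var(ddof=ddof)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        return float("nan")
    return float(2.0 * sxy / denom)


def dynamic_range(x, y) -> float:
    """Dynamic range of a scan--rescan pair.

    One minus the mean absolute within-pair difference, normalised by the
    pooled range of both samples.  Values lie in [0, 1]; NaN when the
    pooled range is zero (feature constant everywhere), flagged as
    undefined by callers.
    """
    x, y = _paired(x, y)
    pooled = np.concatenate([x, y])
    rng = pooled.max() - pooled.min()
    if rng == 0.0:
        return float("nan")
    return float(1.0 - np.abs(x - y).mean() / rng)


def corrected_ccc(ccc: float, icc_intra: float) -> float:
    """Bias-corrected CCC: ``CCC + (1 - intra-observer ICC)``.

    Compensates robustness estimates for subtle intra-reader segmentation
    variance.  The arithmetic is exact and deliberately not clipped, so
    values slightly above 1 can occur.
    """
    return float(ccc) + (1.0 - float(icc_intra))


def robustness_table(
    matrix: pd.DataFrame,
    session: str = "R1S1",
    *,
    moment: str = "population",
) -> pd.DataFrame:
    """Per-(feature, sequence) CCC and DR from scan-1 vs scan-2 pairs.

    For every feature and sequence, ``x`` collects the scan-1 values and
    ``y`` the scan-2 values of all objects (fixed object order), using the
    segmentations of the chosen ``session``.  Rows missing either scan for
    any object are flagged ``incomplete``; degenerate rows carry NaN.

    Returns a DataFrame with columns ``feature_name, sequence, ccc, dr,
    n, incomplete``.
    """
    sub = matrix[matrix["session"] == session]
    if sub.empty:
        raise ValueError(f"no records for session {session!r}")
    wide = sub.pivot_table(
        index=["feature_name", "sequence", "object_id"],
        columns="scan",
        values="value",
        aggfunc="first",
    )
    if not {1, 2}.issubset(wide.columns):
        raise ValueError("robustness requires both scan 1 and scan 2")
    rows = []
    for (feat, seq), block in wide.groupby(level=["feature_name", "sequence"], sort=True):
        block = block.sort_index(level="object_id")
        x = block[1].to_numpy()
        y = block[2].to_numpy()
        incomplete = bool(np.isnan(x).any() or np.isnan(y).any())
        if incomplete:
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
        if x.size >= 2:
            ccc = concordance_cc(x, y, moment=moment)
            dr = dynamic_range(x, y)
        else:
            ccc = dr = float("nan")
        rows.append(
            {
                "feature_name": feat,
                "sequence": seq,
                "ccc": ccc,
                "dr": dr,
                "n": int(x.size),
                "incomplete": incomplete,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RobustnessStratification:
    """Pass flags and robust-feature fractions at nested cutoffs.

    Attributes
    ----------
    flags
        Per (feature, sequence): ``pass_085 / pass_090 / pass_095``
        booleans (NaN statistics never pass and are tallied separately).
    by_sequence
        Fraction of defined features robust at each cutoff, per sequence.
    by_class_sequence
        The same per (feature class, sequence).
    by_class
        Per-class fractions combined over sequences; with
        ``combine="mean"`` (default) the unweighted mean of the five
        per-sequence fractions, with ``combine="pool"`` the pooled
        fraction over all (feature, sequence) rows.
    n_undefined
        Number of rows with undefined (NaN) CCC or DR, excluded from all
        fractions.
    """

    flags: pd.DataFrame
    by_sequence: pd.DataFrame
    by_class_sequence: pd.DataFrame
    by_class: pd.DataFrame
    n_undefined: int
    cutoffs: tuple[float, ...]


def _cut_col(c: float) -> str:
    return f"pass_{int(round(c * 100)):03d}"


def stratify(
    table: pd.DataFrame,
    catalog: FeatureCatalog,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    *,
    combine: str = "mean",
) -> RobustnessStratification:
    """Stratify a CCC/DR table at the given cutoffs (inclusive >=).

    A row passes cutoff c iff ``ccc >= c`` and ``dr >= c``.  Undefined rows
    (NaN in either statistic) are excluded from every fraction and counted
    in ``n_undefined``.
    """
    if combine not in ("mean", "pool"):
        raise ValueError("combine must be 'mean' or 'pool'")
    cutoffs = tuple(sorted(cutoffs))
    flags = table.loc[:, ["feature_name", "sequence", "ccc", "dr"]].copy()
    flags["feature_class"] = [catalog.feature_class(f) for f in flags["feature_name"]]
    defined = flags["ccc"].notna() & flags["dr"].notna()
    for c in cutoffs:
        flags[_cut_col(c)] = defined & (flags["ccc"] >= c) & (flags["dr"] >= c)
    pass_cols = [_cut_col(c) for c in cutoffs]

    def _fractions(group: pd.DataFrame) -> pd.Series:
        d = group[group["ccc"].notna() & group["dr"].notna()]
        out = {f"frac_{col[5:]}": (d[col].mean() if len(d) else np.nan) for col in pass_cols}
        out["n_defined"] = len(d)
        return pd.Series(out)

    by_sequence = flags.groupby("sequence").apply(_fractions, include_groups=False)
    by_class_sequence = flags.groupby(["feature_class", "sequence"]).apply(
        _fractions, include_groups=False
    )
    if combine == "mean":
        frac_cols = [c for c in by_class_sequence.columns if c.startswith("frac_")]
        by_class = by_class_sequence.groupby(level="feature_class")[frac_cols].mean()
    else:
        by_class = flags.groupby("feature_class").apply(_fractions, include_groups=False)
    return RobustnessStratification(
        flags=flags,
        by_sequence=by_sequence,
        by_class_sequence=by_class_sequence,
        by_class=by_class,
        n_undefined=int((~defined).sum()),
        cutoffs=cutoffs,
    )
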
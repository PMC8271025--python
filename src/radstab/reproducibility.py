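"""Observer reproducibility: intraclass correlation and feature selection.

Intra-observer reliability compares reader 1's two segmentation sessions
(``R1S1`` vs ``R1S2``); inter-observer reliability compares reader 1's
first session against reader 2 (``R1S1`` vs ``R2``).  Both use the
two-way ANOVA intraclass correlation for single measurements, with the
absolute-agreement form as default: the study design crosses the same
subjects (object--scan combinations) with two fixed raters, and a
systematic offset between readers must count against reliability.

ICC values are categorised with the conventional bands
excellent >= 0.75, good 0.60--0.74, moderate 0.40--0.59, poor <= 0.39.
A feature is "robust and reproducible" (rrf) for a sequence when it
jointly satisfies CCC >= 0.90, DR >= 0.90 and intra-/inter-observer
ICC >= 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data import INTER_OBSERVER_PAIR, INTRA_OBSERVER_PAIR

__all__ = [
    "icc",
    "anova_two_way",
    "icc_tables",
    "categorize_icc",
    "ICC_CATEGORIES",
    "ReproducibleSet",
    "select_rrf",
]

ICC_CATEGORIES = ("excellent", "good", "moderate", "poor")


def anova_two_way(values: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows, columns, error) of a complete two-way layout.

    ``values`` is a subjects x raters grid with one observation per cell.
    Returns ``(MSR, MSC, MSE)`` where MSR is the between-subject, MSC the
    between-rater and MSE the residual mean square.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("ratings block must be a 2-D subjects x raters grid")
    n, k = values.shape
    if n < 3 or k < 2:
        raise ValueError("ratings block needs >= 3 subjects and >= 2 raters")
    if not np.isfinite(values).all():
        raise ValueError("ratings block must be complete and finite")
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((values - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(values, variant: str = "absolute_agreement_single") -> float:
    """Two-way single-measurement intraclass correlation of a ratings grid.

    Parameters
    ----------
    values
        Complete subjects x raters grid (>= 3 subjects, >= 2 raters).
    variant
        ``"absolute_agreement_single"`` (default): two-way random-effects
        absolute agreement, ICC(2,1) =
        ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
        ``"consistency_single"``: two-way mixed consistency, ICC(3,1) =
        ``(MSR - MSE) / (MSR + (k-1) MSE)``, insensitive to fixed rater
        offsets.

    Returns
    -------
    float
        ICC <= 1; NaN when the grid is fully degenerate (all values
        identical), flagged as undefined by callers.
    """
    values = np.asarray(values, dtype=float)
    msr, msc, mse = anova_two_way(values)
    n, k = values.shape
    if variant == "absolute_agreement_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "consistency_single":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    if denom == 0.0:
        return float("nan")
    return float((msr - mse) / denom)


def _session_pair_icc(
    matrix: pd.DataFrame,
    sessions: tuple[str, str],
    variant: str,
    subjects: str,
) -> pd.DataFrame:
    sub = matrix[matrix["session"].isin(sessions)]
    wide = sub.pivot_table(
        index=["feature_name", "sequence", "object_id", "scan"],
        columns="session",
        values="value",
        aggfunc="first",
    )
    missing = [s for s in sessions if s not in wide.columns]
    if missing:
        raise ValueError(f"matrix lacks session(s) {missing}")
    rows = []
    for (feat, seq), block in wide.groupby(level=["feature_name", "sequence"], sort=True):
        block = block.sort_index()
        if subjects == "object_mean":
            block = block.groupby(level="object_id").mean()
        grid = block[list(sessions)].to_numpy()
        complete = ~np.isnan(grid).any(axis=1)
        grid = grid[complete]
        incomplete = bool((~complete).any())
        value = icc(grid, variant) if grid.shape[0] >= 3 else float("nan")
        rows.append(
            {
                "feature_name": feat,
                "sequence": seq,
                "icc": value,
                "n_subjects": int(grid.shape[0]),
                "incomplete": incomplete,
            }
        )
    return pd.DataFrame(rows)


def icc_tables(
    matrix: pd.DataFrame,
    *,
    variant: str = "absolute_agreement_single",
    subjects: str = "object_scan",
) -> pd.DataFrame:
    """Intra- and inter-observer ICC per feature and sequence.

    ``subjects="object_scan"`` (default) treats every object--scan
    combination as a subject (n = 32 in the full design, both scans'
    segmentations were repeated); ``"object_mean"`` averages the two scans
    first (n = 16).

    Returns columns ``feature_name, sequence, icc_intra, icc_inter,
    n_subjects, incomplete``.
    """
    if subjects not in ("object_scan", "object_mean"):
        raise ValueError("subjects must be 'object_scan' or 'object_mean'")
    intra = _session_pair_icc(matrix, INTRA_OBSERVER_PAIR, variant, subjects)
    inter = _session_pair_icc(matrix, INTER_OBSERVER_PAIR, variant, subjects)
    out = intra.rename(columns={"icc": "icc_intra"}).merge(
        inter.rename(columns={"icc": "icc_inter"}),
        on=["feature_name", "sequence"],
        suffixes=("", "_inter"),
    )
    out["incomplete"] = out["incomplete"] | out.pop("incomplete_inter")
    out["n_subjects"] = out[["n_subjects", "n_subjects_inter"]].min(axis=1)
    return out.drop(columns=["n_subjects_inter"])


def categorize_icc(value: float) -> str:
    """Reliability category of an ICC value.

    The printed bands are two-decimal bands (0.60--0.74 vs >= 0.75), so the
    value is rounded half-up to 2 decimals before banding; otherwise the
    open interval (0.745, 0.75) would be unassigned.
    """
    if not np.isfinite(value):
        raise ValueError("ICC category requires a finite value")
    v = float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))
    if v >= 0.75:
        return "excellent"
    if v >= 0.60:
        return "good"
    if v >= 0.40:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class ReproducibleSet:
    """Robust-and-reproducible features per sequence and their intersection."""

    per_sequence: dict[str, list[str]]
    intersection: list[str]
    n_undefined: int
    cutoffs: dict[str, float]

    def counts(self) -> dict[str, int]:
        out = {seq: len(feats) for seq, feats in self.per_sequence.items()}
        out["intersection"] = len(self.intersection)
        return out


def select_rrf(
    stability: pd.DataFrame,
    *,
    ccc_cut: float = 0.90,
    dr_cut: float = 0.90,
    icc_cut: float = 0.75,
) -> ReproducibleSet:
    """Select robust-and-reproducible features (rrf) per sequence.

    A (feature, sequence) row qualifies when ``ccc >= ccc_cut``,
    ``dr >= dr_cut``, ``icc_intra >= icc_cut`` and ``icc_inter >= icc_cut``
    (all inclusive).  Rows with any undefined statistic are excluded and
    tallied.  The intersection collects features qualifying in every
    sequence present in the table.
    """
    cols = ["ccc", "dr", "icc_intra", "icc_inter"]
    defined = stability[cols].notna().all(axis=1)
    ok = (
        defined
        & (stability["ccc"] >= ccc_cut)
        & (stability["dr"] >= dr_cut)
        & (stability["icc_intra"] >= icc_cut)
        & (stability["icc_inter"] >= icc_cut)
    )
    per_sequence: dict[str, list[str]] = {}
    for seq, block in stability.groupby("sequence", sort=True):
        per_sequence[seq] = sorted(block.loc[ok.loc[block.index], "feature_name"])
    if per_sequence:
        inter = set.intersection(*(set(v) for v in per_sequence.values()))
    else:
        inter = set()
    return ReproducibleSet(
        per_sequence=per_sequence,
        intersection=sorted(inter),
        n_undefined=int((~defined).sum()),
        cutoffs={"ccc": ccc_cut, "dr": dr_cut, "icc": icc_cut},
    )
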
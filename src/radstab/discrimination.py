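"""Pairwise discriminative screening with exact Mann--Whitney Gini scores.

For every pair of phantom objects, every feature and every sequence, the
six replicate values of one object (3 segmentation sessions x 2 scans)
are compared with the six of the other through the Mann--Whitney U
statistic, rescaled to AUC = U / (n1 n2) and to the Gini score
Gini = 2 AUC - 1.  A perfect score (complete separation of the two
replicate sets, in either direction) lets a single measured value decide
which object it came from.

Significance of a perfect score is combinatorial and exact: under the
null of exchangeable ranks, all C(n1+n2, n1) rank splits are equally
likely and exactly one puts every value of group B above group A, so
p = n1! n2! / (n1+n2)!  (1/924 for 6 vs 6).  Screening m features
inflates the chance of a spurious perfect score to 1 - (1-p)^m, and the
probability that all object pairs succeed by chance is bounded by that
quantity raised to the number of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog

__all__ = [
    "mann_whitney_auc",
    "gini_score",
    "pairwise_gini_grid",
    "success_counts",
    "feature_ranking",
    "perfect_separation_pvalue",
    "group_fdr",
    "all_pairs_bound",
    "NullModel",
    "null_model",
]


def mann_whitney_auc(a, b) -> tuple[float, float]:
    """Mann--Whitney U of group ``b`` over group ``a`` and the derived AUC.

    U counts the pairs (a_i, b_j) with b_j > a_i, ties counting 1/2
    (equivalent to the midrank convention).  AUC = U / (n1 n2) estimates
    P(B > A) + P(B = A)/2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    gt = (b[:, None] > a[None, :]).sum()
    eq = (b[:, None] == a[None, :]).sum()
    u = float(gt) + 0.5 * float(eq)
    return u, u / (a.size * b.size)


def gini_score(auc: float) -> float:
    """Gini score 2 AUC - 1: 0 means no predictive power, |1| perfect."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    return 2.0 * auc - 1.0


def _replicate_array(
    matrix: pd.DataFrame, catalog: FeatureCatalog
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[str]]:
    """Reshape a long table into (object, sequence, feature, replicate)."""
    features = [f for f in catalog.analysis_names if f in set(matrix["feature_name"])]
    objects = sorted(matrix["object_id"].unique())
    sequences = sorted(matrix["sequence"].unique())
    wide = matrix.pivot_table(
        index=["object_id", "sequence", "feature_name"],
        columns=["scan", "session"],
        values="value",
        aggfunc="first",
    )
    full = wide.reindex(
        pd.MultiIndex.from_product(
            [objects, sequences, features], names=["object_id", "sequence", "feature_name"]
        )
    )
    arr = full.to_numpy().reshape(len(objects), len(sequences), len(features), -1)
    complete = ~np.isnan(arr).any(axis=-1)
    return arr, complete, objects, sequences, features


def pairwise_gini_grid(matrix: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Gini results for every unordered object pair, feature and sequence.

    Each object contributes its six replicates (3 sessions x 2 scans).
    With 16 objects, 106 features and 5 sequences the grid has
    120 x 106 x 5 = 63,600 entries.  Entries whose replicate sets are
    incomplete are flagged and carry NaN statistics; a tie straddling the
    two groups vetoes the perfect flag by construction (it caps AUC away
    from 0 and 1).

    Returns columns ``object_a, object_b, feature_name, sequence, n1, n2,
    u, auc, gini, perfect, incomplete``.
    """
    arr, complete, objects, sequences, features = _replicate_array(matrix, catalog)
    n_rep = arr.shape[-1]
    frames = []
    for ia, ib in combinations(range(len(objects)), 2):
        va = arr[ia]  # (seq, feat, rep)
        vb = arr[ib]
        gt = (vb[..., :, None] > va[..., None, :]).sum(axis=(-1, -2))
        eq = (vb[..., :, None] == va[..., None, :]).sum(axis=(-1, -2))
        u = gt + 0.5 * eq
        auc = u / (n_rep * n_rep)
        ok = complete[ia] & complete[ib]
        frame = pd.DataFrame(
            {
                "object_a": objects[ia],
                "object_b": objects[ib],
                "sequence": np.repeat(sequences, len(features)),
                "feature_name": np.tile(features, len(sequences)),
                "n1": n_rep,
                "n2": n_rep,
                "u": u.ravel(),
                "auc": auc.ravel(),
                "incomplete": ~ok.ravel(),
            }
        )
        frames.append(frame)
    grid = pd.concat(frames, ignore_index=True)
    bad = grid["incomplete"]
    grid.loc[bad, ["u", "auc"]] = np.nan
    grid["gini"] = 2.0 * grid["auc"] - 1.0
    grid["perfect"] = (~bad) & ((grid["auc"] == 0.0) | (grid["auc"] == 1.0))
    return grid


def success_counts(
    grid: pd.DataFrame,
    catalog: FeatureCatalog,
    group_by: str = "sequence",
) -> pd.DataFrame:
    """Number of object pairs distinguished by each feature group.

    A group succeeds for a pair when at least one of its features attains
    a perfect Gini score for that pair.  ``group_by`` is ``"sequence"``,
    ``"class"`` (feature class within sequence) or ``"feature"`` (single
    features within sequence).  Flagged-incomplete entries never count.

    Returns columns naming the group plus ``n_successes, n_pairs,
    success_rate``.
    """
    grid = grid.copy()
    grid["pair"] = list(zip(grid["object_a"], grid["object_b"]))
    n_pairs = grid["pair"].nunique()
    if group_by == "sequence":
        keys = ["sequence"]
    elif group_by == "class":
        grid["feature_class"] = [catalog.feature_class(f) for f in grid["feature_name"]]
        keys = ["sequence", "feature_class"]
    elif group_by == "feature":
        keys = ["sequence", "feature_name"]
    else:
        raise ValueError("group_by must be 'sequence', 'class' or 'feature'")
    agg = (
        grid.groupby(keys + ["pair"], sort=True)["perfect"]
        .any()
        .groupby(level=keys)
        .sum()
        .rename("n_successes")
        .reset_index()
    )
    agg["n_pairs"] = n_pairs
    agg["success_rate"] = agg["n_successes"] / n_pairs
    return agg


def feature_ranking(grid: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Per-(feature, sequence) success ranking, competition style.

    Rows are ordered by descending success count, ties share a rank and
    the next rank is skipped (1, 2, 2, 4, ...); within a tie the order is
    alphabetical by feature then sequence for determinism.
    """
    counts = success_counts(grid, catalog, group_by="feature")
    counts["feature_class"] = [catalog.feature_class(f) for f in counts["feature_name"]]
    counts = counts.sort_values(
        ["n_successes", "feature_name", "sequence"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    counts["rank"] = (
        counts["n_successes"].rank(method="min", ascending=False).astype(int)
    )
    return counts[
        ["rank", "feature_name", "sequence", "feature_class",
         "n_successes", "n_pairs", "success_rate"]
    ]


def perfect_separation_pvalue(n1: int, n2: int, *, two_sided: bool = False) -> float:
    """Exact null probability of complete separation of two rank groups.

    Under exchangeable ranks each of the C(n1+n2, n1) splits is equally
    likely; exactly one puts group B entirely above group A, giving the
    one-sided p = n1! n2! / (n1+n2)!  With ``two_sided=True`` both
    orientations count and the probability doubles (capped at 1).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    p = Fraction(factorial(n1) * factorial(n2), factorial(n1 + n2))
    if two_sided:
        p = min(2 * p, Fraction(1))
    return float(p)


def group_fdr(p: float, m: int) -> float:
    """Chance of >= 1 spurious perfect score among m independent features."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - p) ** m


def all_pairs_bound(fdr: float, n_pairs: int) -> float:
    """Independence bound on all n_pairs succeeding by chance: fdr**n_pairs."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError("fdr must lie in [0, 1]")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return fdr**n_pairs


@dataclass(frozen=True)
class NullModel:
    """Exact combinatorial null for perfect-separation screening."""

    n1: int
    n2: int
    m: int
    n_pairs: int
    p_perfect: float
    fdr_single: float
    p_all_pairs: float


def null_model(n1: int = 6, n2: int = 6, m: int = 106, n_pairs: int = 120) -> NullModel:
    """Assemble the null-model numbers for a screening configuration."""
    p = perfect_separation_pvalue(n1, n2)
    fdr = group_fdr(p, m)
    return NullModel(
        n1=n1,
        n2=n2,
        m=m,
        n_pairs=n_pairs,
        p_perfect=p,
        fdr_single=fdr,
        p_all_pairs=all_pairs_bound(fdr, n_pairs),
    )
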
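"""Model-style front end: analyses built from a feature table, fitted to Results.

Two entry points mirror the two arms of a feature-stability study:

* :class:`StabilityAnalysis` -- robustness (CCC, DR, bias-corrected CCC
  from scan--rescan pairs) and reproducibility (intra-/inter-observer
  ICC), fitted into a :class:`StabilityResults` holding the per-(feature,
  sequence) table, cutoff stratification, ICC categories and the
  robust-and-reproducible feature selection.

* :class:`DiscriminationAnalysis` -- the exact Mann--Whitney Gini grid
  over all object pairs, fitted into :class:`DiscriminationResults` with
  success counts, the ranked feature report and the combinatorial null.

Both accept a long-format feature table (DataFrame or CSV) validated
against the feature catalog.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import discrimination as _disc
from . import reproducibility as _repro
from . import robustness as _rob
from .catalog import FeatureCatalog, build_feature_catalog
from .data import read_feature_table, validate_feature_table
from .reporting import BlandAltmanStats, bland_altman, distribution_summary

__all__ = [
    "StabilityAnalysis",
    "StabilityResults",
    "DiscriminationAnalysis",
    "DiscriminationResults",
]


class StabilityAnalysis:
    """Robustness and reproducibility analysis of a feature table.

    Parameters
    ----------
    data
        Long-format feature table (one record per object, sequence, scan,
        session and feature).
    catalog
        Feature catalog; defaults to the pinned 107-feature catalog.
    robust_session
        Segmentation session whose scan--rescan pairs enter CCC/DR
        (default ``"R1S1"``).
    icc_variant
        ``"absolute_agreement_single"`` (default) or
        ``"consistency_single"``.
    icc_subjects
        ``"object_scan"`` (default: each object--scan combination is a
        subject) or ``"object_mean"``.
    ccc_moment
        ``"population"`` (1/n, default) or ``"sample"`` moments in CCC.
    gate_on_corrected
        If True, downstream selection gates on the bias-corrected CCC
        instead of the raw CCC.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        catalog: FeatureCatalog | None = None,
        *,
        robust_session: str = "R1S1",
        icc_variant: str = "absolute_agreement_single",
        icc_subjects: str = "object_scan",
        ccc_moment: str = "population",
        gate_on_corrected: bool = False,
    ) -> None:
        self.catalog = catalog or build_feature_catalog()
        self.data = validate_feature_table(data, self.catalog)
        self.robust_session = robust_session
        self.icc_variant = icc_variant
        self.icc_subjects = icc_subjects
        self.ccc_moment = ccc_moment
        self.gate_on_corrected = gate_on_corrected

    @classmethod
    def from_csv(cls, path, catalog: FeatureCatalog | None = None, **kwargs):
        catalog = catalog or build_feature_catalog()
        return cls(read_feature_table(path, catalog), catalog, **kwargs)

    def fit(self) -> "StabilityResults":
        """Compute CCC/DR/CCC_corr and intra-/inter-ICC per feature and sequence."""
        rob = _rob.robustness_table(
            self.data, self.robust_session, moment=self.ccc_moment
        )
        icc = _repro.icc_tables(
            self.data, variant=self.icc_variant, subjects=self.icc_subjects
        )
        table = rob.merge(
            icc, on=["feature_name", "sequence"], suffixes=("", "_icc")
        )
        table["ccc_corr"] = table["ccc"] + (1.0 - table["icc_intra"])
        table = table[
            ["feature_name", "sequence", "ccc", "dr", "ccc_corr",
             "icc_intra", "icc_inter", "n", "n_subjects", "incomplete"]
        ]
        return StabilityResults(self, table)


class StabilityResults:
    """Fitted per-(feature, sequence) stability statistics.

    Attributes
    ----------
    table
        DataFrame with columns ``feature_name, sequence, ccc, dr,
        ccc_corr, icc_intra, icc_inter, n, n_subjects, incomplete``.
    """

    def __init__(self, model: StabilityAnalysis, table: pd.DataFrame,
                 from_fixture: bool = False) -> None:
        self.model = model
        self.table = table
        self._from_fixture = from_fixture

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   catalog: FeatureCatalog | None = None) -> "StabilityResults":
        """Wrap an externally computed stability table (e.g. a printed fixture)."""
        model = StabilityAnalysis.__new__(StabilityAnalysis)
        model.catalog = catalog or build_feature_catalog()
        model.gate_on_corrected = False
        return cls(model, table.copy(), from_fixture=True)

    @property
    def _gate_ccc_col(self) -> str:
        return "ccc_corr" if self.model.gate_on_corrected else "ccc"

    def stratify(
        self,
        cutoffs: tuple[float, ...] = _rob.DEFAULT_CUTOFFS,
        *,
        combine: str = "mean",
    ) -> _rob.RobustnessStratification:
        """Robust-feature fractions at nested CCC & DR cutoffs."""
        table = self.table
        if self.model.gate_on_corrected:
            table = table.assign(ccc=table["ccc_corr"])
        return _rob.stratify(table, self.model.catalog, cutoffs, combine=combine)

    def select(
        self,
        *,
        ccc_cut: float = 0.90,
        dr_cut: float = 0.90,
        icc_cut: float = 0.75,
    ) -> _repro.ReproducibleSet:
        """Robust-and-reproducible feature sets per sequence + intersection."""
        table = self.table
        if self.model.gate_on_corrected:
            table = table.assign(ccc=table["ccc_corr"])
        return _repro.select_rrf(
            table, ccc_cut=ccc_cut, dr_cut=dr_cut, icc_cut=icc_cut
        )

    def icc_categories(self, arm: str = "inter") -> pd.DataFrame:
        """Tally reliability categories of intra- or inter-observer ICCs."""
        col = {"intra": "icc_intra", "inter": "icc_inter"}[arm]
        vals = self.table[col].dropna()
        cats = pd.Categorical(
            [_repro.categorize_icc(v) for v in vals],
            categories=list(_repro.ICC_CATEGORIES),
        )
        return (
            pd.Series(cats).value_counts().rename_axis("category")
            .rename("count").reset_index()
        )

    def icc_distribution(self, arm: str = "inter", by: str = "sequence"):
        """5--95 percentile box-whisker summaries of ICCs per group."""
        col = {"intra": "icc_intra", "inter": "icc_inter"}[arm]
        table = self.table.copy()
        if by == "class":
            table["group"] = [
                self.model.catalog.feature_class(f) for f in table["feature_name"]
            ]
        else:
            table["group"] = table[by]
        return {
            g: distribution_summary(block[col].dropna().to_numpy())
            for g, block in table.groupby("group")
        }

    def bland_altman(
        self, feature_name: str, sequence: str, arm: str = "scan"
    ) -> BlandAltmanStats:
        """Limits of agreement for one feature and sequence.

        ``arm="scan"`` compares scan 1 vs scan 2 (session R1S1);
        ``"intra"`` and ``"inter"`` compare segmentation sessions across
        both scans.
        """
        data = self.model.data
        sub = data[
            (data["feature_name"] == feature_name) & (data["sequence"] == sequence)
        ]
        if sub.empty:
            raise ValueError(f"no records for {feature_name!r} / {sequence!r}")
        if arm == "scan":
            sub = sub[sub["session"] == "R1S1"]
            wide = sub.pivot_table(index="object_id", columns="scan", values="value")
            x, y = wide[1].to_numpy(), wide[2].to_numpy()
        elif arm in ("intra", "inter"):
            s2 = {"intra": "R1S2", "inter": "R2"}[arm]
            wide = sub.pivot_table(
                index=["object_id", "scan"], columns="session", values="value"
            )
            x, y = wide["R1S1"].to_numpy(), wide[s2].to_numpy()
        else:
            raise ValueError("arm must be 'scan', 'intra' or 'inter'")
        return bland_altman(x, y)

    def summary(self) -> str:
        """Human-readable overview of the fitted stability statistics."""
        t = self.table
        strat = self.stratify()
        sel = self.select()
        lines = [
            "Feature stability results",
            "=" * 25,
            f"rows (feature x sequence): {len(t)}",
            f"sequences: {', '.join(sorted(t['sequence'].unique()))}",
            f"undefined CCC/DR rows: {strat.n_undefined}",
            "",
            "Robust fraction per sequence (CCC & DR >= cutoff):",
            strat.by_sequence.round(4).to_string(),
            "",
            "Robust and reproducible features "
            f"(CCC >= {sel.cutoffs['ccc']}, DR >= {sel.cutoffs['dr']}, "
            f"ICC >= {sel.cutoffs['icc']}):",
        ]
        for seq, feats in sel.per_sequence.items():
            lines.append(f"  {seq}: {len(feats)}")
        lines.append(f"  intersection across sequences: {len(sel.intersection)}")
        if 0 < len(sel.intersection) <= 12:
            lines.append("  " + ", ".join(sel.intersection))
        return "\n".join(lines)

    def plot_icc_box(self, arm: str = "inter", by: str = "sequence", ax=None):
        """Box-whisker plot (5--95 percentile whiskers) of ICC values."""
        import matplotlib.pyplot as plt

        col = {"intra": "icc_intra", "inter": "icc_inter"}[arm]
        table = self.table.copy()
        if by == "class":
            table["group"] = [
                self.model.catalog.feature_class(f) for f in table["feature_name"]
            ]
        else:
            table["group"] = table[by]
        groups = sorted(table["group"].unique())
        data = [table.loc[table["group"] == g, col].dropna().to_numpy() for g in groups]
        if ax is None:
            _, ax = plt.subplots()
        ax.boxplot(data, tick_labels=groups, whis=(5, 95))
        ax.set_ylabel(f"{arm}-observer ICC")
        return ax

    def plot_class_fractions(self, cutoff: float = 0.90, ax=None):
        """Bar plot of the robust-feature fraction per feature class."""
        import matplotlib.pyplot as plt

        strat = self.stratify()
        col = f"frac_{int(round(cutoff * 100)):03d}"
        fr = strat.by_class[col]
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(fr.index, fr.to_numpy())
        ax.set_ylabel(f"fraction robust (CCC & DR >= {cutoff})")
        ax.set_ylim(0, 1)
        return ax


class DiscriminationAnalysis:
    """Pairwise Gini discriminative screening of a feature table."""

    def __init__(
        self, data: pd.DataFrame, catalog: FeatureCatalog | None = None
    ) -> None:
        self.catalog = catalog or build_feature_catalog()
        self.data = validate_feature_table(data, self.catalog)

    @classmethod
    def from_csv(cls, path, catalog: FeatureCatalog | None = None, **kwargs):
        catalog = catalog or build_feature_catalog()
        return cls(read_feature_table(path, catalog), catalog, **kwargs)

    def fit(self) -> "DiscriminationResults":
        grid = _disc.pairwise_gini_grid(self.data, self.catalog)
        return DiscriminationResults(self, grid)


class DiscriminationResults:
    """Fitted Gini grid with success counting and exact significance."""

    def __init__(self, model: DiscriminationAnalysis, grid: pd.DataFrame) -> None:
        self.model = model
        self.grid = grid

    def success_counts(self, by: str = "sequence") -> pd.DataFrame:
        """Pairs distinguished per group (``"sequence"``, ``"class"`` or ``"feature"``)."""
        return _disc.success_counts(self.grid, self.model.catalog, group_by=by)

    def ranking(self) -> pd.DataFrame:
        """Competition-ranked per-(feature, sequence) success report."""
        return _disc.feature_ranking(self.grid, self.model.catalog)

    def null_model(self, m: int | None = None) -> _disc.NullModel:
        """Exact combinatorial null for the fitted grid's group sizes."""
        g = self.grid.dropna(subset=["u"])
        n1 = int(g["n1"].iloc[0]) if len(g) else 6
        n2 = int(g["n2"].iloc[0]) if len(g) else 6
        n_features = self.grid["feature_name"].nunique()
        pairs = self.grid.groupby(["object_a", "object_b"]).ngroups
        return _disc.null_model(
            n1=n1, n2=n2, m=m if m is not None else n_features, n_pairs=pairs
        )

    def summary(self) -> str:
        nm = self.null_model()
        seq = self.success_counts("sequence")
        lines = [
            "Pairwise Gini discrimination results",
            "=" * 36,
            f"grid entries: {len(self.grid)} "
            f"({nm.n_pairs} pairs x {nm.m} features x "
            f"{self.grid['sequence'].nunique()} sequences)",
            f"perfect scores: {int(self.grid['perfect'].sum())}",
            "",
            f"exact p of a perfect score ({nm.n1} vs {nm.n2}): {nm.p_perfect:.3e}",
            f"false-discovery rate over {nm.m} features: {nm.fdr_single:.3%}",
            f"all-{nm.n_pairs}-pairs chance bound: {nm.p_all_pairs:.2e}",
            "",
            "Successes per sequence:",
            seq.to_string(index=False),
        ]
        return "\n".join(lines)
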
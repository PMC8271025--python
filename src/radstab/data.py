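"""Long-format feature tables: validation, CSV I/O and packaged fixtures.

A feature table holds one record per (object, sequence, scan, segmentation
session, feature).  A complete scan--rescan design with three segmentation
sessions carries six replicate values per object, feature and sequence:
two scans, each segmented in reader-1 session 1 (``R1S1``), reader-1
session 2 (``R1S2``, one month later) and by reader 2 (``R2``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, build_feature_catalog

__all__ = [
    "FEATURE_TABLE_COLUMNS",
    "OBJECT_TYPES",
    "SESSIONS",
    "SEQUENCES",
    "INTRA_OBSERVER_PAIR",
    "INTER_OBSERVER_PAIR",
    "FeatureTableError",
    "validate_feature_table",
    "read_feature_table",
    "write_feature_table",
    "load_printed_fixture",
]

FEATURE_TABLE_COLUMNS = (
    "object_id",
    "object_type",
    "sequence",
    "scan",
    "session",
    "feature_name",
    "value",
)

#: Phantom object types (four replicates of each in the default design).
OBJECT_TYPES = ("apple", "lime", "onion", "kiwi")

#: Segmentation sessions: reader 1 twice (one month apart) and reader 2.
SESSIONS = ("R1S1", "R1S2", "R2")

#: Session pairs entering intra- and inter-observer reliability.
INTRA_OBSERVER_PAIR = ("R1S1", "R1S2")
INTER_OBSERVER_PAIR = ("R1S1", "R2")

#: The five MRI acquisition techniques compared by the study design.
SEQUENCES = ("HASTE", "T2w TSE", "FLAIR", "T2 map", "T1w TSE")

_KEY = ["object_id", "sequence", "scan", "session", "feature_name"]


class FeatureTableError(ValueError):
    """A feature table violates its schema or catalog contract."""


def validate_feature_table(
    table: pd.DataFrame, catalog: FeatureCatalog | None = None
) -> pd.DataFrame:
    """Check schema, key uniqueness and catalog membership.

    Returns the table unchanged on success so the call can be chained.
    """
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FeatureTableError(
            f"feature table is missing required columns: {', '.join(missing)}"
        )
    dup = table.duplicated(subset=_KEY)
    if dup.any():
        first = table.loc[dup, _KEY].iloc[0].to_dict()
        raise FeatureTableError(
            f"duplicate (object, sequence, scan, session, feature) key: {first}"
        )
    if catalog is not None:
        unknown = set(table["feature_name"]) - set(catalog.names)
        if unknown:
            raise FeatureTableError(
                "feature names absent from catalog: "
                + ", ".join(sorted(unknown)[:5])
                + ("..." if len(unknown) > 5 else "")
            )
    bad_session = set(table["session"]) - set(SESSIONS)
    if bad_session:
        raise FeatureTableError(f"unknown session labels: {sorted(bad_session)}")
    return table


def read_feature_table(path, catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Read and validate a long-format feature table from CSV."""
    table = pd.read_csv(path, dtype={"scan": int})
    return validate_feature_table(table, catalog)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table to CSV with 12-significant-digit values."""
    out = table.loc[:, list(FEATURE_TABLE_COLUMNS)].copy()
    out["value"] = [np.format_float_positional(v, precision=12, unique=True,
                                               fractional=False, trim="-")
                    for v in out["value"].to_numpy(float)]
    out.to_csv(path, index=False)


def load_printed_fixture(table_id: str) -> pd.DataFrame:
    """Load a packaged per-feature stability table transcribed from print.

    ``"table1"`` is the T2 map robust-and-reproducible feature set (84 rows,
    values at 7--8 decimals).  ``"table2"`` is the cross-sequence set of
    8 features x 5 sequences (40 rows, values rounded to 2 decimals as
    printed).  Both carry columns ``feature_name, sequence, ccc, dr,
    icc_intra, icc_inter`` plus a ``ccc_corr`` column of NaN: the printed
    tables do not report the bias-corrected coefficient.
    """
    files = {
        "table1": "table1_t2map.csv",
        "table2": "table2_cross_sequence.csv",
    }
    if table_id not in files:
        raise ValueError(f"unknown fixture table id {table_id!r}; expected one of {sorted(files)}")
    ref = resources.files("radstab.fixtures") / files[table_id]
    with resources.as_file(ref) as p:
        table = pd.read_csv(p)
    table.insert(3, "ccc_corr", np.nan)
    catalog = build_feature_catalog()
    unknown = set(table["feature_name"]) - set(catalog.names)
    if unknown:  # defensive: fixtures are pinned at packaging time
        raise FeatureTableError(f"fixture names absent from catalog: {sorted(unknown)}")
    return table
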
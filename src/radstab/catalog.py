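"""Radiomic feature catalog.

The analysis operates on the 107 "original" radiomic features that standard
extraction software computes per volume of interest: 14 shape descriptors,
18 first-order intensity statistics, and 75 texture features from five
gray-level matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM).  The catalog is
pinned as a static table so the analysis pipeline carries no extraction
dependency.  One feature, ``shape_LeastAxisLength``, is flagged as excluded
from analysis: segmenting only the middle portion of each object
systematically biases the least-axis estimate, leaving 106 analysis
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FEATURE_CLASSES",
    "EXCLUDED_FEATURES",
    "CatalogEntry",
    "FeatureCatalog",
    "parse_feature_name",
    "build_feature_catalog",
]

#: The seven feature classes, in conventional reporting order.
FEATURE_CLASSES: tuple[str, ...] = (
    "shape",
    "firstorder",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
)

#: Features excluded from analysis (systematically biased by the
#: mid-object segmentation protocol).
EXCLUDED_FEATURES: frozenset[str] = frozenset({"shape_LeastAxisLength"})

_SHORT_NAMES: dict[str, tuple[str, ...]] = {
    "shape": (
        "Elongation",
        "Flatness",
        "LeastAxisLength",
        "MajorAxisLength",
        "Maximum2DDiameterColumn",
        "Maximum2DDiameterRow",
        "Maximum2DDiameterSlice",
        "Maximum3DDiameter",
        "MeshVolume",
        "MinorAxisLength",
        "Sphericity",
        "SurfaceArea",
        "SurfaceVolumeRatio",
        "VoxelVolume",
    ),
    "firstorder": (
        "10Percentile",
        "90Percentile",
        "Energy",
        "Entropy",
        "InterquartileRange",
        "Kurtosis",
        "Maximum",
        "Mean",
        "MeanAbsoluteDeviation",
        "Median",
        "Minimum",
        "Range",
        "RobustMeanAbsoluteDeviation",
        "RootMeanSquared",
        "Skewness",
        "TotalEnergy",
        "Uniformity",
        "Variance",
    ),
    "glcm": (
        "Autocorrelation",
        "ClusterProminence",
        "ClusterShade",
        "ClusterTendency",
        "Contrast",
        "Correlation",
        "DifferenceAverage",
        "DifferenceEntropy",
        "DifferenceVariance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "InverseVariance",
        "JointAverage",
        "JointEnergy",
        "JointEntropy",
        "MCC",
        "MaximumProbability",
        "SumAverage",
        "SumEntropy",
        "SumSquares",
    ),
    "glrlm": (
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance",
        "HighGrayLevelRunEmphasis",
        "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis",
        "RunEntropy",
        "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized",
        "RunPercentage",
        "RunVariance",
        "ShortRunEmphasis",
        "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ),
    "glszm": (
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance",
        "HighGrayLevelZoneEmphasis",
        "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis",
        "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized",
        "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis",
        "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy",
        "ZonePercentage",
        "ZoneVariance",
    ),
    "gldm": (
        "DependenceEntropy",
        "DependenceNonUniformity",
        "DependenceNonUniformityNormalized",
        "DependenceVariance",
        "GrayLevelNonUniformity",
        "GrayLevelVariance",
        "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ),
    "ngtdm": (
        "Busyness",
        "Coarseness",
        "Complexity",
        "Contrast",
        "Strength",
    ),
}


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split ``"<class>_<ShortName>"`` into its class and short name.

    The class token is lower-cased and validated against the seven known
    feature classes.

    Raises
    ------
    ValueError
        If the name has no underscore or the class prefix is unknown.
    """
    if "_" not in name:
        raise ValueError(
            f"feature name {name!r} does not follow the '<class>_<ShortName>' convention"
        )
    cls, short = name.split("_", 1)
    cls = cls.lower()
    if cls not in FEATURE_CLASSES:
        raise ValueError(
            f"unknown feature class {cls!r} in {name!r}; "
            f"expected one of {', '.join(FEATURE_CLASSES)}"
        )
    return cls, short


@dataclass(frozen=True)
class CatalogEntry:
    """One feature in the catalog."""

    feature_name: str
    feature_class: str
    excluded: bool = False


@dataclass(frozen=True)
class FeatureCatalog:
    """The pinned feature namespace with class labels and exclusion flags.

    Iterating yields :class:`CatalogEntry` objects; ``len`` gives the total
    entry count (107 for the default catalog).
    """

    entries: tuple[CatalogEntry, ...]
    _by_name: dict[str, CatalogEntry] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name = {e.feature_name: e for e in self.entries}
        if len(by_name) != len(self.entries):
            raise ValueError("duplicate feature names in catalog")
        object.__setattr__(self, "_by_name", by_name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> CatalogEntry:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        """All feature names, catalog order."""
        return [e.feature_name for e in self.entries]

    @property
    def analysis_names(self) -> list[str]:
        """Names of non-excluded features (106 for the default catalog)."""
        return [e.feature_name for e in self.entries if not e.excluded]

    def feature_class(self, name: str) -> str:
        return self._by_name[name].feature_class

    def class_counts(self, analysis_only: bool = False) -> dict[str, int]:
        """Number of features per class, keyed in reporting order."""
        counts = {c: 0 for c in FEATURE_CLASSES}
        for e in self.entries:
            if analysis_only and e.excluded:
                continue
            counts[e.feature_class] += 1
        return counts


def build_feature_catalog() -> FeatureCatalog:
    """Return the default 107-feature catalog (106 analysis features)."""
    entries = []
    for cls in FEATURE_CLASSES:
        for short in _SHORT_NAMES[cls]:
            name = f"{cls}_{short}"
            entries.append(
                CatalogEntry(
                    feature_name=name,
                    feature_class=cls,
                    excluded=name in EXCLUDED_FEATURES,
                )
            )
    return FeatureCatalog(entries=tuple(entries))
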
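"""The radiomic feature catalog.

The default catalog enumerates exactly 385 features in five families:

* 42 histogram (first-order) statistics of the ROI intensities,
* 9 form-factor (size/shape) descriptors of the binary mask,
* 144 GLCM texture features: 8 base statistics x 6 direction variants
  (four in-plane angles plus their mean and population SD) x 3 offsets
  (1, 4, 7 voxels),
* 10 Haralick sum/difference statistics at offset 1, averaged over the
  four directions,
* 180 run-length (RLM) features: 10 base statistics x 6 direction
  variants x 3 offsets.

Texture feature names use the "<Base>_angle<t>_offset<d>" /
"<Base>_All Direction_offset<d>[_SD]" dialect, e.g.
``"Long Run Emphasis_All Direction_offset7_SD"``.  The composition is
declared in a plain config dict so alternate catalogs can be swapped
in without code changes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

ANGLES = (0, 45, 90, 135)
OFFSETS = (1, 4, 7)

HISTOGRAM_PERCENTILES = [1, 5, 10, 15, 20, 25, 30, 35, 40, 45,
                         55, 60, 65, 70, 75, 80, 85, 90, 95, 99]

HISTOGRAM_FEATURES = (
    [
        "Mean",
        "Variance",
        "Std Deviation",
        "Skewness",
        "Kurtosis",
        "Min Intensity",
        "Max Intensity",
        "Range",
        "Median",
        "RMS",
        "Mean Absolute Deviation",
        "Median Absolute Deviation",
        "Robust Mean Absolute Deviation",
        "Interquartile Range",
        "Energy",
        "Entropy",
        "Uniformity",
        "Maximum Probability",
    ]
    + [f"Percentile{p}" for p in HISTOGRAM_PERCENTILES]
    + ["Sum", "Mode", "Quantile0.025", "Quantile0.975"]
)

SHAPE_FEATURES = [
    "Maximum 3D Diameter",
    "Surface Area",
    "Volume",
    "Surface Volume Ratio",
    "Sphericity",
    "Compactness1",
    "Compactness2",
    "Spherical Disproportion",
    "Voxel Count",
]

GLCM_BASE = [
    "GLCMEnergy",
    "GLCMEntropy",
    "Inertia",
    "Correlation",
    "Inverse Difference Moment",
    "Cluster Shade",
    "Cluster Prominence",
    "Haralick Correlation",
]

# Sum/difference statistics of the offset-1 GLCM, averaged over the
# four in-plane directions.
HARALICK_FEATURES = [
    "Haralick Sum Average",
    "Haralick Sum Entropy",
    "Haralick Sum Variance",
    "Haralick Difference Average",
    "Haralick Difference Entropy",
    "Haralick Difference Variance",
    "Haralick Information Measure 1",
    "Haralick Information Measure 2",
    "Haralick Autocorrelation",
    "Haralick Maximum Probability",
]

# Ten run-count-normalized statistics (Galloway / Chu / Dasarathy
# families).  Run Percentage is deliberately absent: it is the one
# classical RLM statistic normalized by the voxel count rather than
# the run count.
RLM_BASE = [
    "Short Run Emphasis",
    "Long Run Emphasis",
    "Gray Level Nonuniformity",
    "Run Length Nonuniformity",
    "Low Gray Level Run Emphasis",
    "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emphasis",
    "Short Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis",
    "Long Run High Gray Level Emphasis",
]

DEFAULT_CONFIG = {
    "version": "1.0",
    "gray_levels": 64,
    "angles_deg": list(ANGLES),
    "offsets": list(OFFSETS),
    "histogram": list(HISTOGRAM_FEATURES),
    "shape": list(SHAPE_FEATURES),
    "glcm_base": list(GLCM_BASE),
    "haralick": list(HARALICK_FEATURES),
    "rlm_base": list(RLM_BASE),
}


@dataclasses.dataclass(frozen=True)
class FeatureDescriptor:
    """One catalog entry: where a feature value comes from."""

    name: str
    family: str            # histogram | shape | glcm | haralick | rlm
    base: str
    variant: str | None = None   # "angle0".."angle135" | "mean" | "sd" | None
    offset: int | None = None


def _direction_variants(base: str, offset: int) -> list[FeatureDescriptor]:
    out = []
    fam = "glcm"
    for a in ANGLES:
        out.append(FeatureDescriptor(
            name=f"{base}_angle{a}_offset{offset}",
            family=fam, base=base, variant=f"angle{a}", offset=offset))
    out.append(FeatureDescriptor(
        name=f"{base}_All Direction_offset{offset}",
        family=fam, base=base, variant="mean", offset=offset))
    out.append(FeatureDescriptor(
        name=f"{base}_All Direction_offset{offset}_SD",
        family=fam, base=base, variant="sd", offset=offset))
    return out


class FeatureCatalog:
    """Ordered, named enumeration of every feature to extract."""

    def __init__(self, config: dict | None = None):
        self.config = dict(DEFAULT_CONFIG if config is None else config)
        self.gray_levels = int(self.config.get("gray_levels", 64))
        self.offsets = tuple(self.config.get("offsets", OFFSETS))
        self.descriptors: list[FeatureDescriptor] = []
        for base in self.config["histogram"]:
            self.descriptors.append(
                FeatureDescriptor(name=base, family="histogram", base=base))
        for base in self.config["shape"]:
            self.descriptors.append(
                FeatureDescriptor(name=base, family="shape", base=base))
        for base in self.config["glcm_base"]:
            for off in self.offsets:
                self.descriptors.extend(_direction_variants(base, off))
        for base in self.config["haralick"]:
            self.descriptors.append(FeatureDescriptor(
                name=f"{base}_offset1", family="haralick", base=base, offset=1))
        for base in self.config["rlm_base"]:
            for off in self.offsets:
                for d in _direction_variants(base, off):
                    self.descriptors.append(
                        dataclasses.replace(d, family="rlm"))
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("catalog contains duplicate feature names")

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.family] = counts.get(d.family, 0) + 1
        return counts

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.config, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureCatalog":
        return cls(yaml.safe_load(Path(path).read_text()))


def default_catalog() -> FeatureCatalog:
    """The 385-feature default catalog (42+9+144+10+180)."""
    return FeatureCatalog()
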
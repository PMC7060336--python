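"""Canonical radiomic feature naming and ordering.

Every feature in the bank is identified by a :class:`FeatureName` whose
string form round-trips through :func:`FeatureName.parse` /
:meth:`FeatureName.format`. The canonical per-channel order is

* 7 shape features (original image only, mask-derived),
* then for each of the 9 sub-bands (``orig`` plus the 8 stationary-wavelet
  sub-bands LLL..HHH): 17 first-order features, 132 GLCM features
  (22 base features x {mean, std} over 13 directions x distances 1..3) and
  30 GLRLM features (15 base features x {mean, std}),

for 7 + 9 x 179 = 1618 features per channel and 6472 over the four
channels CET1, FLAIR, ADC, CBV.
"""

from __future__ import annotations

from dataclasses import dataclass

CHANNELS = ("CET1", "FLAIR", "ADC", "CBV")
SUBBANDS = ("orig", "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
WAVELET_SUBBANDS = SUBBANDS[1:]
GLCM_DISTANCES = (1, 2, 3)
AGGREGATIONS = ("mean", "std")

SHAPE_FEATURES = (
    "volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness1",
    "compactness2",
    "max_3d_diameter",
)

FIRSTORDER_FEATURES = (
    "mean",
    "median",
    "min",
    "max",
    "range",
    "variance",
    "sd",
    "mean_absolute_deviation",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "uniformity",
    "rms",
    "p10",
    "p90",
    "iqr",
)

GLCM_FEATURES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "sum_entropy",
    "sum_average",
    "sum_variance",
    "homogeneity1",
    "homogeneity2",
    "imc1",
    "imc2",
    "idn",
    "idmn",
    "inverse_variance",
    "maximum_probability",
)

GLRLM_FEATURES = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "glv",
    "rlv",
    "run_entropy",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
    "run_variance_by_length",
)

N_SHAPE = len(SHAPE_FEATURES)
N_FIRSTORDER = len(FIRSTORDER_FEATURES)
N_TEXTURE = len(GLCM_FEATURES) * len(AGGREGATIONS) * len(GLCM_DISTANCES) \
    + len(GLRLM_FEATURES) * len(AGGREGATIONS)
N_PER_SUBBAND = N_FIRSTORDER + N_TEXTURE
N_WAVELET = N_PER_SUBBAND * len(WAVELET_SUBBANDS)
N_PER_CHANNEL = N_SHAPE + N_PER_SUBBAND * len(SUBBANDS)
N_TOTAL = N_PER_CHANNEL * len(CHANNELS)

assert (N_SHAPE, N_FIRSTORDER, N_TEXTURE, N_WAVELET, N_PER_CHANNEL, N_TOTAL) == \
    (7, 17, 162, 1432, 1618, 6472)


@dataclass(frozen=True)
class FeatureName:
    """Structured identity of one radiomic feature."""

    channel: str
    subband: str
    family: str  # shape | firstorder | glcm | glrlm
    feature: str
    aggregation: str = "none"  # mean | std | none
    param: int | None = None  # GLCM distance in voxels

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.subband not in SUBBANDS:
            raise ValueError(f"unknown subband {self.subband!r}")
        if self.family == "shape" and (self.subband != "orig" or self.aggregation != "none"):
            raise ValueError("shape features live on the original image without aggregation")
        if self.family == "glcm" and self.param not in GLCM_DISTANCES:
            raise ValueError(f"GLCM features need a distance in {GLCM_DISTANCES}")
        if self.family in ("glcm", "glrlm") and self.aggregation not in AGGREGATIONS:
            raise ValueError("texture features aggregate over directions (mean or std)")

    def format(self) -> str:
        parts = [self.channel, self.subband, self.family, self.feature]
        if self.param is not None:
            parts.append(f"d{self.param}")
        if self.aggregation != "none":
            parts.append(self.aggregation)
        return "|".join(parts)

    def __str__(self) -> str:
        return self.format()

    @classmethod
    def parse(cls, s: str) -> "FeatureName":
        parts = s.split("|")
        if len(parts) < 4:
            raise ValueError(f"cannot parse feature name {s!r}")
        channel, subband, family, feature = parts[:4]
        rest = parts[4:]
        param = None
        aggregation = "none"
        for token in rest:
            if token.startswith("d") and token[1:].isdigit():
                param = int(token[1:])
            elif token in AGGREGATIONS:
                aggregation = token
            else:
                raise ValueError(f"unexpected token {token!r} in {s!r}")
        return cls(channel, subband, family, feature, aggregation, param)


def subband_feature_names(channel: str, subband: str) -> list[FeatureName]:
    names = [FeatureName(channel, subband, "firstorder", f) for f in FIRSTORDER_FEATURES]
    for d in GLCM_DISTANCES:
        for f in GLCM_FEATURES:
            for agg in AGGREGATIONS:
                names.append(FeatureName(channel, subband, "glcm", f, agg, d))
    for f in GLRLM_FEATURES:
        for agg in AGGREGATIONS:
            names.append(FeatureName(channel, subband, "glrlm", f, agg))
    return names


def channel_feature_names(channel: str, subbands=SUBBANDS) -> list[FeatureName]:
    names = [FeatureName(channel, "orig", "shape", f) for f in SHAPE_FEATURES]
    for sb in subbands:
        names.extend(subband_feature_names(channel, sb))
    return names


def all_feature_names(subbands=SUBBANDS) -> list[FeatureName]:
    names: list[FeatureName] = []
    for ch in CHANNELS:
        names.extend(channel_feature_names(ch, subbands))
    return names
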
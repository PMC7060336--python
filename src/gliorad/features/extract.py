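"""Channel- and subject-level radiomic feature extraction.

Per channel the bank holds 1618 features: 7 shape, then for the original
image and each of the 8 stationary-wavelet sub-bands 17 first-order and
162 texture features. The four channels (CET1, FLAIR, ADC, CBV)
concatenate in fixed order to the 6472-feature subject vector.

Quantitative maps (ADC, CBV) get a per-ROI +/-3 SD outlier trim before
discretization; trimmed voxels are removed from the texture mask, not
filled. The same trim/discretize policy applies to sub-band values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..grids import ImageVolume
from ..harmonize import trim_outlier_voxels
from .firstorder import first_order_features
from .names import (
    CHANNELS,
    GLCM_DISTANCES,
    SUBBANDS,
    FeatureName,
    all_feature_names,
    channel_feature_names,
)
from .shape import shape_features
from .texture import discretize, glcm_features, glrlm_features
from .wavelet import DEFAULT_WAVELET, wavelet_decompose

__all__ = ["ExtractionConfig", "extract_channel", "extract_subject", "extract_cohort"]

# channels whose ROI intensities are outlier-trimmed before extraction
TRIMMED_CHANNELS = ("ADC", "CBV")


@dataclass
class ExtractionConfig:
    n_bins: int = 32
    distances: tuple[int, ...] = GLCM_DISTANCES
    wavelet: str = DEFAULT_WAVELET
    subbands: tuple[str, ...] = SUBBANDS
    trimmed_channels: tuple[str, ...] = TRIMMED_CHANNELS
    min_mask_voxels: int = 8


def _crop_to_bbox(volume: np.ndarray, mask: np.ndarray, margin: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return volume[sl], mask[sl]


def _subband_features(values_volume: np.ndarray, mask: np.ndarray, trim: bool,
                      config: ExtractionConfig) -> dict[tuple, float]:
    vals = values_volume[mask]
    keep_mask = mask
    if trim:
        mean = vals.mean()
        sd = vals.std()
        if sd > 0:
            keep_mask = mask & (np.abs(values_volume - mean) <= 3.0 * sd)
            vals = values_volume[keep_mask]
    out: dict[tuple, float] = {}
    for name, value in first_order_features(vals, config.n_bins).items():
        out[("firstorder", name, "none", None)] = value
    roi = discretize(values_volume, keep_mask, config.n_bins)
    for d in config.distances:
        for (fname, agg), value in glcm_features(roi, d).items():
            out[("glcm", fname, agg, d)] = value
    for (fname, agg), value in glrlm_features(roi).items():
        out[("glrlm", fname, agg, None)] = value
    return out


def extract_channel(volume: ImageVolume, mask: ImageVolume, channel: str,
                    config: ExtractionConfig | None = None) -> dict[FeatureName, float]:
    """All per-channel features, keyed by canonical FeatureName."""
    if config is None:
        config = ExtractionConfig()
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share a grid")
    m = (mask.data > 0.5) & volume.valid_mask()
    if m.sum() < config.min_mask_voxels:
        raise ValueError(
            f"mask has {int(m.sum())} usable voxels; need at least {config.min_mask_voxels}"
        )
    trim = channel in config.trimmed_channels
    out: dict[FeatureName, float] = {}
    for fname, value in shape_features(mask.data > 0.5, mask.spacing).items():
        out[FeatureName(channel, "orig", "shape", fname)] = value

    data, cmask = _crop_to_bbox(volume.data, m, margin=2)
    bands: dict[str, np.ndarray] = {}
    if "orig" in config.subbands:
        bands["orig"] = data
    wavelet_bands = [sb for sb in config.subbands if sb != "orig"]
    if wavelet_bands:
        decomp = wavelet_decompose(data, config.wavelet)
        for sb in wavelet_bands:
            bands[sb] = decomp[sb]
    for sb in config.subbands:
        for (family, fname, agg, param), value in _subband_features(
            bands[sb], cmask, trim, config
        ).items():
            out[FeatureName(channel, sb, family, fname, agg, param)] = value
    expected = channel_feature_names(channel, config.subbands)
    assert list(out) == expected, "feature ordering drifted from the canonical list"
    return out


def extract_subject(channels: dict[str, ImageVolume], mask: ImageVolume,
                    config: ExtractionConfig | None = None) -> pd.Series:
    """The per-subject feature vector over CET1, FLAIR, ADC, CBV.

    Input channel order does not matter; output order is canonical.
    """
    if config is None:
        config = ExtractionConfig()
    missing = [c for c in CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"missing channel(s): {', '.join(missing)}")
    values: dict[str, float] = {}
    for ch in CHANNELS:
        for name, value in extract_channel(channels[ch], mask, ch, config).items():
            values[name.format()] = value
    index = [n.format() for n in all_feature_names(config.subbands)]
    return pd.Series([values[k] for k in index], index=index, dtype=float)


def extract_cohort(subject_channels: dict[str, dict[str, ImageVolume]],
                   masks: dict[str, ImageVolume],
                   config: ExtractionConfig | None = None) -> pd.DataFrame:
    """Feature table (subjects x features) for a cohort."""
    rows = {sid: extract_subject(chans, masks[sid], config)
            for sid, chans in subject_channels.items()}
    return pd.DataFrame(rows).T
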
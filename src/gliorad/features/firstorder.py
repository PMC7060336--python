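"""First-order (histogram) statistics of ROI intensities."""

from __future__ import annotations

import numpy as np

from .names import FIRSTORDER_FEATURES

__all__ = ["first_order_features"]


def first_order_features(values: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """The 17 first-order features of an intensity multiset.

    Entropy (bits) and uniformity are computed on an equal-width fixed-bin
    histogram with ``n_bins`` bins over [min, max] — the same discretization
    the texture matrices use. With zero variance, skewness and kurtosis are
    reported as 0 (degenerate-statistic convention).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values for first-order features")
    mean = float(v.mean())
    var = float(v.var())
    sd = float(np.sqrt(var))
    if var > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = 0.0
        kurt = 0.0
    if v.max() > v.min():
        hist, _ = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    else:
        hist = np.array([v.size])
    p = hist[hist > 0] / v.size
    out = {
        "mean": mean,
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "variance": var,
        "sd": sd,
        "mean_absolute_deviation": float(np.mean(np.abs(v - mean))),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(v**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
        "uniformity": float(np.sum(p**2)),
        "rms": float(np.sqrt(np.mean(v**2))),
        "p10": float(np.percentile(v, 10)),
        "p90": float(np.percentile(v, 90)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }
    assert tuple(out) == FIRSTORDER_FEATURES
    return out
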
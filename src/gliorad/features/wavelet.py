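"""Single-level stationary 3D wavelet decomposition.

An undecimated (stationary) transform keeps every sub-band on the input
grid, so the tumor mask applies to all eight sub-bands without any
resampling ambiguity. Sub-band labels give the per-axis filter in axis
order (x, y, z): L = low-pass, H = high-pass, e.g. ``LLH`` is low-pass
along x and y and high-pass along z.
"""

from __future__ import annotations

import numpy as np
import pywt

from .names import WAVELET_SUBBANDS

__all__ = ["wavelet_decompose", "DEFAULT_WAVELET"]

DEFAULT_WAVELET = "coif1"


def _label_from_key(key: str) -> str:
    # pywt swtn keys use 'a' (approximation) / 'd' (detail) per axis
    return key.replace("a", "L").replace("d", "H")


def wavelet_decompose(volume: np.ndarray, wavelet: str = DEFAULT_WAVELET) -> dict[str, np.ndarray]:
    """Decompose a 3D volume into the 8 sub-bands LLL..HHH.

    Odd axes are symmetric-padded to even length for the stationary
    transform and cropped back, so every sub-band has the input shape.
    """
    data = np.asarray(volume, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3D volume")
    w = pywt.Wavelet(wavelet)
    if any(n < w.dec_len for n in data.shape):
        raise ValueError(
            f"volume shape {data.shape} smaller than the {wavelet} filter length {w.dec_len}"
        )
    pad = [(0, n % 2) for n in data.shape]
    padded = np.pad(data, pad, mode="symmetric") if any(p[1] for p in pad) else data
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    crop = tuple(slice(0, n) for n in data.shape)
    out = {_label_from_key(k): np.asarray(v)[crop] for k, v in coeffs.items()}
    assert set(out) == set(WAVELET_SUBBANDS)
    return out
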
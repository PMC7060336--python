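"""ADC and leakage-corrected, NAWM-normalized CBV map computation.

The apparent diffusion coefficient is the two-point estimate
``ADC = -ln(S(b)/S(0)) / b``. Dynamic susceptibility contrast series are
converted to relaxation-rate change ``dR2*(t) = -ln(S(t)/S_base) / TE``,
leakage-corrected with the Boxerman–Weisskoff linear model against a
non-leaky reference curve, integrated to relative CBV, and normalized by
the mean CBV in a small contralateral normal-appearing white matter ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .grids import DscSeries, DwiPair, ImageVolume, NawmRoiSpec

__all__ = [
    "LeakageFit",
    "compute_adc",
    "signal_to_delta_r2star",
    "fit_leakage",
    "compute_cbv",
    "normalize_cbv",
    "nonenhancing_mask",
    "dsc_to_ncbv",
]

log = logging.getLogger(__name__)


@dataclass
class LeakageFit:
    """Per-voxel Boxerman–Weisskoff leakage model fit.

    Each voxel's curve is modelled as ``k1 * ref(t) - k2 * cumint(ref)(t)``
    where ``ref`` is the mean curve over non-enhancing tissue; ``k2``
    captures contrast extravasation.
    """

    k1: np.ndarray
    k2: np.ndarray
    reference_curve: np.ndarray


def compute_adc(pair: DwiPair) -> ImageVolume:
    """Two-point ADC map in mm^2/s; non-positive signals are invalidated."""
    s0 = pair.s0.data
    sb = pair.sb.data
    valid = (s0 > 0) & (sb > 0)
    if not valid.any():
        raise ValueError("all voxels have non-positive signal; cannot compute ADC")
    adc = np.zeros_like(s0)
    adc[valid] = -np.log(sb[valid] / s0[valid]) / pair.b_value
    return ImageVolume(adc, pair.s0.spacing, valid=valid)


def signal_to_delta_r2star(series: DscSeries) -> tuple[np.ndarray, np.ndarray]:
    """Convert DSC signal to dR2*(t) = -ln(S(t)/S_baseline) / TE.

    Returns ``(curves, valid)`` where ``curves`` is 4D and ``valid`` marks
    voxels whose baseline mean and all timepoints are positive; baseline
    timepoints of a noise-free series average to zero by construction.
    """
    lo, hi = series.baseline_index_range
    s_base = series.signal[..., lo:hi].mean(axis=3)
    valid = (s_base > 0) & np.all(series.signal > 0, axis=3)
    curves = np.zeros_like(series.signal)
    curves[valid] = -np.log(series.signal[valid] / s_base[valid, None]) / series.te_s
    return curves, valid


def nonenhancing_mask(brain_mask: np.ndarray, tumor_mask: np.ndarray, dilation_voxels: int = 2) -> np.ndarray:
    """Default reference tissue: brain minus the dilated tumor mask."""
    dilated = ndimage.binary_dilation(tumor_mask > 0.5, iterations=dilation_voxels)
    return (brain_mask > 0.5) & ~dilated


def fit_leakage(curves: np.ndarray, nonenh: np.ndarray, tr_s: float,
                valid: np.ndarray | None = None) -> tuple[LeakageFit, np.ndarray]:
    """Fit the leakage model per voxel and return corrected curves.

    The reference curve is the mean dR2* over the non-enhancing mask. Per
    voxel, ordinary least squares solves
    ``curve(t) ~ k1 * ref(t) - k2 * cumint(ref)(t)``; the corrected curve
    adds the estimated leakage term back: ``curve + k2 * cumint(ref)``.
    """
    if not np.any(nonenh):
        raise ValueError("non-enhancing reference mask is empty")
    if valid is None:
        valid = np.ones(curves.shape[:3], dtype=bool)
    ref = curves[nonenh & valid].mean(axis=0)
    if np.allclose(ref, 0.0):
        raise ValueError("degenerate (all-zero) reference curve; no bolus signal")
    ref_int = cumulative_trapezoid(ref, dx=tr_s, initial=0.0)
    # design matrix [ref, -cumint(ref)]; solve normal equations in closed form
    x = np.stack([ref, -ref_int], axis=1)  # (t, 2)
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    flat = curves.reshape(-1, curves.shape[3])
    beta = flat @ x @ xtx_inv.T  # (n_vox, 2)
    k1 = beta[:, 0].reshape(curves.shape[:3])
    k2 = beta[:, 1].reshape(curves.shape[:3])
    corrected = curves + k2[..., None] * ref_int
    fit = LeakageFit(k1=k1, k2=k2, reference_curve=ref)
    return fit, corrected


def compute_cbv(corrected: np.ndarray, tr_s: float, baseline_index_range: tuple[int, int],
                spacing=(1.0, 1.0, 1.0), valid: np.ndarray | None = None) -> ImageVolume:
    """Relative CBV: trapezoidal integral of the corrected curve.

    The integration window runs from the end of the pre-bolus baseline to
    the final timepoint. Negative integrals are clipped to zero (CBV is
    physically non-negative); the clipped count is logged.
    """
    _, hi = baseline_index_range
    if hi >= corrected.shape[3]:
        raise ValueError("integration window lies outside the series")
    window = corrected[..., hi:]
    cbv = np.trapezoid(window, dx=tr_s, axis=3)
    n_neg = int((cbv < 0).sum())
    if n_neg:
        log.info("compute_cbv: clipped %d negative integrals to 0", n_neg)
    cbv = np.clip(cbv, 0.0, None)
    return ImageVolume(cbv, spacing, valid=valid)


def normalize_cbv(cbv: ImageVolume, roi: NawmRoiSpec, tumor_mask: np.ndarray | None = None) -> ImageVolume:
    """Divide the CBV map by its mean over the NAWM ROI sphere."""
    roi_mask = roi.voxel_mask(cbv)
    if tumor_mask is not None and np.any(roi_mask & (tumor_mask > 0.5)):
        raise ValueError("NAWM ROI overlaps the tumor mask")
    roi_mask &= cbv.valid_mask()
    if not roi_mask.any():
        raise ValueError("NAWM ROI contains no valid voxels")
    mean = float(cbv.data[roi_mask].mean())
    if mean <= 0:
        raise ValueError(f"NAWM ROI mean must be positive, got {mean}")
    return ImageVolume(cbv.data / mean, cbv.spacing, valid=cbv.valid)


def dsc_to_ncbv(series: DscSeries, brain_mask: np.ndarray, tumor_mask: np.ndarray,
                roi: NawmRoiSpec) -> tuple[ImageVolume, LeakageFit]:
    """Full DSC pipeline: dR2* -> leakage correction -> CBV -> nCBV."""
    curves, valid = signal_to_delta_r2star(series)
    nonenh = nonenhancing_mask(brain_mask, tumor_mask)
    fit, corrected = fit_leakage(curves, nonenh, series.tr_s, valid=valid)
    cbv = compute_cbv(corrected, series.tr_s, series.baseline_index_range,
                      spacing=series.spacing, valid=valid)
    return normalize_cbv(cbv, roi, tumor_mask=tumor_mask), fit
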
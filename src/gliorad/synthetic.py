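"""Synthetic glioblastoma cohort generator.

Produces phantom subjects whose four MR channels (contrast-enhanced T1,
FLAIR, ADC, normalized CBV), tumor masks, raw diffusion/perfusion signals,
clinical covariates and right-censored overall-survival outcomes carry the
statistical structure the downstream radiomics analysis assumes:

* tumors are perturbed ellipsoids with controllable intra-tumor texture
  (``heterogeneity`` interpolates the variance of band-passed Gaussian
  random fields at two length scales);
* raw DWI pairs follow the two-point mono-exponential decay
  ``S(b) = S(0) exp(-b * ADC)``;
* raw DSC series follow the leakage model
  ``dR2*(t) = CBV * C(t) - K2 * integral(C)`` with a gamma-variate bolus;
* survival times follow a proportional-hazards model with a Weibull
  baseline whose linear predictor depends on per-subject image phenotype
  proxies (tumor ADC level, tumor CBV level, volume, heterogeneity) and,
  optionally, clinical covariates.

Every generator is fully deterministic given its configuration and seed;
each subject draws from an independent stream derived from
``(cohort seed, subject index)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grids import DscSeries, DwiPair, ImageVolume, save_volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "ClinicalRecord",
    "SurvivalRecord",
    "SubjectPhantom",
    "generate_tumor_mask",
    "generate_channels",
    "generate_dwi_pair",
    "generate_dsc_series",
    "generate_survival",
    "generate_clinical",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]

# Default hazard coefficients for the image-phenotype proxies.  The source
# cohorts provide no effect sizes linking phenotype to hazard, so these are
# free parameters of the simulation: chosen to give a clearly prognostic
# imaging signal at desk-scale cohort sizes.
DEFAULT_TRUE_EFFECTS: dict[str, float] = {
    "low_adc": 0.8,   # cellularity proxy: lower tumor ADC -> higher hazard
    "high_cbv": 0.8,  # angiogenesis proxy: higher tumor CBV -> higher hazard
}

# Default clinical hazard coefficients, anchored to the univariate hazard
# ratios reported for glioblastoma cohorts: age HR ~1.02 per year, low KPS
# HR ~1.70, gross-total resection HR ~0.67 versus lesser surgery.
DEFAULT_CLINICAL_EFFECTS: dict[str, float] = {
    "age_per_year": float(np.log(1.02)),
    "kps_low": float(np.log(1.70)),
    "gtr": float(np.log(0.67)),
}

# Training-set marginals for extent of resection (GTR / STR / biopsy).
EXTENT_LEVELS = ("GTR", "STR", "biopsy")
DEFAULT_EXTENT_PROPS = (0.456, 0.361, 0.184)

# Reference scales used to standardize phenotype proxies into z-like units,
# fixed a priori so a subject's linear predictor does not depend on who else
# is in the cohort.
_ADC_TUMOR_MEAN = 0.80e-3   # mm^2/s
_ADC_TUMOR_SD = 0.12e-3
_CBV_TUMOR_MEAN = 3.0       # relative units
_CBV_TUMOR_SD = 0.8


def default_radius_range(grid: int, spacing: float = 1.0) -> tuple[float, float]:
    """Tumor radius range scaled to the grid so masks always fit."""
    extent = grid * spacing
    return (0.13 * extent, 0.19 * extent)


@dataclass
class PhantomConfig:
    """Configuration of a synthetic cohort."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 50
    tumor_radius_range_mm: tuple[float, float] = (8.0, 14.0)
    heterogeneity: float = 0.5
    true_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS))
    clinical_effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS))
    extent_props: tuple[float, float, float] = DEFAULT_EXTENT_PROPS
    baseline_median_days: float = 646.0
    censor_rate: float = 0.2
    admin_horizon_days: float | None = None
    dwi_s0_level: float = 1000.0
    dwi_b_value: float = 1000.0
    dwi_noise_sd: float = 5.0
    dsc_te_s: float = 0.040
    dsc_tr_s: float = 1.808
    dsc_n_timepoints: int = 60
    dsc_n_baseline: int = 8
    dsc_noise_sd: float = 2.0
    simulate_raw_signals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError(f"heterogeneity must be in [0, 1], got {self.heterogeneity}")
        lo, hi = self.tumor_radius_range_mm
        if not 0 < lo <= hi:
            raise ValueError(f"invalid tumor_radius_range_mm {self.tumor_radius_range_mm}")

    def subject_rng(self, index: int) -> np.random.Generator:
        """Independent, reproducible stream for one subject."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, index)))


@dataclass
class PhantomTruth:
    """Per-subject generating ground truth used by recovery tests."""

    true_adc_map: np.ndarray          # mm^2/s
    true_cbv_map: np.ndarray          # relative CBV, unitless
    true_k2: np.ndarray               # leakage coefficient per voxel
    true_linear_predictor: float
    phenotype: dict[str, float]
    generating_seed: int


@dataclass
class ClinicalRecord:
    age: float
    kps: int
    extent: str
    mgmt: str = "NA"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.kps not in range(0, 101, 10):
            raise ValueError(f"KPS must be in 0..100 in steps of 10, got {self.kps}")
        if self.extent not in EXTENT_LEVELS:
            raise ValueError(f"extent must be one of {EXTENT_LEVELS}")


@dataclass
class SurvivalRecord:
    time_days: float
    event: int

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("time_days must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class SubjectPhantom:
    """All generated artifacts for one synthetic subject."""

    subject_id: str
    mask: ImageVolume
    brain_mask: np.ndarray
    nawm_mask: np.ndarray
    ce_t1: ImageVolume
    flair: ImageVolume
    truth: PhantomTruth
    dwi: DwiPair | None
    dsc: DscSeries | None
    clinical: ClinicalRecord
    survival: SurvivalRecord | None = None


def _smooth_field(shape, rng, sigma_vox):
    """Unit-variance Gaussian random field smoothed at the given scale."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_tumor_mask(grid_shape, spacing_mm, center_mm, radii_mm, irregularity, seed) -> ImageVolume:
    """Binary tumor mask: an ellipsoid perturbed by a smoothed random field.

    The perturbation moves the implicit surface in normalized radial units;
    ``irregularity`` in [0, 1] scales its amplitude. The returned mask is the
    6-connected component containing the tumor center, with interior holes
    filled, so it is always a single connected region.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    radii_mm = tuple(float(r) for r in radii_mm)
    if irregularity < 0 or irregularity > 1:
        raise ValueError("irregularity must lie in [0, 1]")
    for n, s, c, r in zip(grid_shape, spacing_mm, center_mm, radii_mm):
        if c - r < 2 * s or c + r > (n - 1) * s - 2 * s:
            raise ValueError(
                f"tumor radii {radii_mm} mm at center {center_mm} mm do not fit "
                f"inside grid {grid_shape} with a 2-voxel margin"
            )
    rng = np.random.default_rng(seed)
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    rho = np.sqrt(
        ((gx - center_mm[0]) / radii_mm[0]) ** 2
        + ((gy - center_mm[1]) / radii_mm[1]) ** 2
        + ((gz - center_mm[2]) / radii_mm[2]) ** 2
    )
    # Perturbation amplitude 0.25 normalized-radius units at irregularity 1.
    bump = _smooth_field(grid_shape, rng, sigma_vox=3.0) * 0.25 * irregularity
    mask = rho <= 1.0 + bump
    # keep the component containing the center; fill holes
    labels, _ = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    cidx = tuple(int(round(c / s)) for c, s in zip(center_mm, spacing_mm))
    lab = labels[cidx]
    if lab == 0:  # center itself carved away: fall back to largest component
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        lab = int(sizes.argmax())
        if lab == 0:
            raise ValueError("perturbation removed the entire tumor; reduce irregularity")
    mask = ndimage.binary_fill_holes(labels == lab)
    return ImageVolume(mask.astype(float), spacing=tuple(spacing_mm))


@dataclass
class _SubjectPhenotype:
    adc_level: float
    cbv_level: float
    heterogeneity: float
    radii_mm: tuple[float, float, float]

    def proxies(self) -> dict[str, float]:
        vol = 4.0 / 3.0 * np.pi * np.prod(self.radii_mm)
        return {
            "low_adc": (_ADC_TUMOR_MEAN - self.adc_level) / _ADC_TUMOR_SD,
            "high_cbv": (self.cbv_level - _CBV_TUMOR_MEAN) / _CBV_TUMOR_SD,
            "volume": float(np.log(vol) - np.log(4.0 / 3.0 * np.pi * 11.0**3)),
            "heterogeneity": (self.heterogeneity - 0.5) / 0.25,
        }


def _draw_phenotype(config: PhantomConfig, rng) -> _SubjectPhenotype:
    lo, hi = config.tumor_radius_range_mm
    base = rng.uniform(lo, hi)
    radii = tuple(float(np.clip(base * rng.uniform(0.85, 1.15), lo * 0.8, hi)) for _ in range(3))
    het = float(np.clip(rng.normal(config.heterogeneity, 0.12), 0.0, 1.0))
    return _SubjectPhenotype(
        adc_level=float(np.clip(rng.normal(_ADC_TUMOR_MEAN, _ADC_TUMOR_SD), 0.3e-3, 1.5e-3)),
        cbv_level=float(np.clip(rng.normal(_CBV_TUMOR_MEAN, _CBV_TUMOR_SD), 0.8, 6.0)),
        heterogeneity=het,
        radii_mm=radii,
    )


def generate_channels(mask: ImageVolume, config: PhantomConfig, seed,
                      phenotype: _SubjectPhenotype | None = None):
    """Generate the four per-subject channels plus brain/NAWM compartments.

    Returns ``(ce_t1, flair, truth, brain_mask, nawm_mask)``. The background
    "brain" is an ellipsoid of smooth Gaussian texture with a brighter NAWM
    compartment; tumor voxels get a mean offset per channel plus intra-tumor
    texture whose variance scales with ``heterogeneity``.
    """
    rng = np.random.default_rng(seed)
    if phenotype is None:
        phenotype = _draw_phenotype(config, rng)
    shape = mask.shape
    spacing = mask.spacing
    tumor = mask.data > 0.5

    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    cx, cy, cz = [e / 2 for e in extent]
    brain = ((gx - cx) / (0.48 * extent[0])) ** 2 + ((gy - cy) / (0.48 * extent[1])) ** 2 \
        + ((gz - cz) / (0.45 * extent[2])) ** 2 <= 1.0
    # NAWM: a deep band on the contralateral (low-x) side, clear of the tumor
    nawm = brain & (gx < cx - 0.12 * extent[0]) & (np.abs(gy - cy) < 0.25 * extent[1]) \
        & (np.abs(gz - cz) < 0.25 * extent[2]) & ~tumor

    het = phenotype.heterogeneity
    # two band-passed length scales; heterogeneity interpolates their variance
    def tumor_texture(scale=1.0):
        fine = _smooth_field(shape, rng, 1.0) - _smooth_field(shape, rng, 2.5)
        coarse = _smooth_field(shape, rng, 2.5) - _smooth_field(shape, rng, 5.0)
        f = fine / max(fine.std(), 1e-12) + coarse / max(coarse.std(), 1e-12)
        return het * scale * f / max(f.std(), 1e-12)

    def background(level_gm, level_wm, noise_sd):
        img = np.full(shape, 0.0)
        img[brain] = level_gm + 2.0 * _smooth_field(shape, rng, 4.0)[brain]
        img[nawm] += level_wm - level_gm
        img += rng.normal(0.0, noise_sd, shape)
        return img

    noise_sd = 2.0
    ce_t1 = background(100.0, 150.0, noise_sd)
    ce_t1[tumor] = 180.0 + (25.0 * tumor_texture())[tumor] + rng.normal(0, noise_sd, shape)[tumor]
    flair = background(120.0, 90.0, noise_sd)
    flair[tumor] = 160.0 + (20.0 * tumor_texture())[tumor] + rng.normal(0, noise_sd, shape)[tumor]

    adc = np.full(shape, 0.4e-3)
    adc[brain] = 0.80e-3 + (0.02e-3 * _smooth_field(shape, rng, 4.0))[brain]
    adc[tumor] = phenotype.adc_level + (0.15e-3 * tumor_texture())[tumor]
    adc = np.clip(adc, 0.05e-3, 3.0e-3)

    cbv = np.zeros(shape)
    cbv[brain] = 1.0 + 0.05 * _smooth_field(shape, rng, 4.0)[brain]
    cbv[tumor] = phenotype.cbv_level + (0.8 * tumor_texture())[tumor]
    cbv = np.clip(cbv, 0.0, None)

    k2 = np.zeros(shape)
    k2[tumor] = np.clip(0.05 + 0.02 * _smooth_field(shape, rng, 2.0)[tumor], 0.0, None)

    truth = PhantomTruth(
        true_adc_map=adc,
        true_cbv_map=cbv,
        true_k2=k2,
        true_linear_predictor=0.0,  # filled in by generate_subject
        phenotype=phenotype.proxies(),
        generating_seed=int(seed) if np.isscalar(seed) else 0,
    )
    return (
        ImageVolume(ce_t1, spacing),
        ImageVolume(flair, spacing),
        truth,
        brain,
        nawm,
    )


def generate_dwi_pair(true_adc, s0_level, b, noise_sd, seed, spacing=(1.0, 1.0, 1.0)) -> DwiPair:
    """Simulate a b=0 / b=b signal pair from a ground-truth ADC map."""
    if b <= 0:
        raise ValueError("b must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    true_adc = np.asarray(true_adc, dtype=float)
    if np.any(true_adc < 0):
        raise ValueError("true ADC must be non-negative")
    rng = np.random.default_rng(seed)
    s0 = np.full(true_adc.shape, float(s0_level))
    sb = s0_level * np.exp(-b * true_adc)
    if noise_sd > 0:
        s0 = s0 + rng.normal(0, noise_sd, true_adc.shape)
        sb = sb + rng.normal(0, noise_sd, true_adc.shape)
    return DwiPair(ImageVolume(s0, spacing), ImageVolume(sb, spacing), b)


def gamma_variate_bolus(n_timepoints, tr_s, n_baseline, alpha=3.0, tp_s=6.0):
    """Unit-peak gamma-variate contrast bolus C(t), zero over the baseline."""
    t = np.arange(n_timepoints) * tr_s
    t0 = n_baseline * tr_s
    tau = (t - t0) / tp_s
    tau_pos = np.clip(tau, 0.0, None)
    return np.power(tau_pos, alpha) * np.exp(alpha * (1 - tau_pos)) * (tau > 0)


def generate_dsc_series(true_cbv, true_k2, te_s, tr_s, n_timepoints, n_baseline,
                        noise_sd, seed, s_base=400.0, spacing=(1.0, 1.0, 1.0)) -> DscSeries:
    """Simulate a 4D DSC signal series under the linear leakage model.

    Per voxel, ``dR2*(t) = CBV * C(t) - K2 * cumint(C)(t)`` with C(t) a
    gamma-variate bolus; the signal is ``S(t) = S_base * exp(-TE * dR2*(t))``
    plus Gaussian noise.
    """
    if te_s <= 0:
        raise ValueError("TE must be positive")
    if n_timepoints < 20:
        raise ValueError("need at least 20 timepoints")
    if n_baseline < 5:
        raise ValueError("need at least 5 pre-bolus baseline points")
    true_cbv = np.asarray(true_cbv, dtype=float)
    true_k2 = np.asarray(true_k2, dtype=float)
    rng = np.random.default_rng(seed)
    c = gamma_variate_bolus(n_timepoints, tr_s, n_baseline)
    from scipy.integrate import cumulative_trapezoid

    cint = cumulative_trapezoid(c, dx=tr_s, initial=0.0)
    dr2 = true_cbv[..., None] * c + (-true_k2[..., None]) * cint
    signal = s_base * np.exp(-te_s * dr2)
    if noise_sd > 0:
        signal = signal + rng.normal(0, noise_sd, signal.shape)
    return DscSeries(signal, te_s=te_s, tr_s=tr_s,
                     baseline_index_range=(0, n_baseline), spacing=spacing)


def weibull_baseline_scale(baseline_median_days, shape):
    """Scale lambda0 so the lp=0 median equals ``baseline_median_days``."""
    return baseline_median_days / np.log(2.0) ** (1.0 / shape)


def generate_survival(linear_predictor, baseline_median_days, censor_rate, seed,
                      weibull_shape=1.2, admin_horizon_days=None) -> list[SurvivalRecord]:
    """Draw right-censored survival records under a Weibull PH model.

    Event times are ``T = lambda0 * (-ln U * exp(-lp))**(1/k)``; censoring is
    uniform on [0, tau] with tau solved numerically so the expected censored
    fraction equals ``censor_rate``. When an administrative horizon is given,
    follow-up is additionally truncated there.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    if censor_rate >= 1.0 or censor_rate < 0.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    k = weibull_shape
    lam0 = weibull_baseline_scale(baseline_median_days, k)
    u = rng.uniform(size=lp.shape)
    t_event = lam0 * (-np.log(u) * np.exp(-lp)) ** (1.0 / k)
    t_event = np.maximum(t_event, 1e-6)

    times = t_event.copy()
    events = np.ones(lp.shape, dtype=int)
    if censor_rate > 0:
        # E[censored] for C ~ U(0, tau): mean_i min(T_i / tau, 1), decreasing in tau
        def expected(tau):
            return float(np.mean(np.minimum(t_event / tau, 1.0))) - censor_rate

        hi = float(t_event.max()) / max(censor_rate, 1e-9)
        tau = optimize.brentq(expected, 1e-9, max(hi, 1.0))
        c = rng.uniform(0.0, tau, size=lp.shape)
        censored = c < t_event
        times = np.where(censored, c, t_event)
        events = (~censored).astype(int)
    if admin_horizon_days is not None:
        over = times > admin_horizon_days
        times = np.where(over, admin_horizon_days, times)
        events = np.where(over, 0, events)
    times = np.maximum(times, 1e-6)
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]


def generate_clinical(config: PhantomConfig, rng) -> ClinicalRecord:
    age = float(np.clip(rng.normal(59.5, 11.0), 25.0, 88.0))
    kps = int(np.clip(round(rng.normal(8.5, 1.2)), 4, 10)) * 10
    extent = str(rng.choice(EXTENT_LEVELS, p=np.asarray(config.extent_props) / sum(config.extent_props)))
    mgmt = str(rng.choice(["methylated", "unmethylated", "NA"], p=[0.076, 0.158, 0.766]))
    return ClinicalRecord(age=age, kps=kps, extent=extent, mgmt=mgmt)


def clinical_linear_predictor(clinical: ClinicalRecord, effects: dict[str, float]) -> float:
    """Clinical contribution to the hazard, centered at cohort-typical values."""
    lp = effects.get("age_per_year", 0.0) * (clinical.age - 59.5)
    lp += effects.get("kps_low", 0.0) * (1.0 if clinical.kps < 80 else 0.0)
    lp += effects.get("gtr", 0.0) * (1.0 if clinical.extent == "GTR" else 0.0)
    return float(lp)


def generate_subject(config: PhantomConfig, index: int) -> SubjectPhantom:
    """Generate one complete subject (images, raw signals, clinical, truth).

    Survival is attached at cohort level so censoring can be calibrated
    across subjects; ``survival`` is None on the returned object until then.
    """
    rng = config.subject_rng(index)
    seed_mask, seed_chan, seed_dwi, seed_dsc = rng.integers(0, 2**31 - 1, size=4)
    phenotype = _draw_phenotype(config, rng)
    shape = config.grid_shape
    spacing = config.spacing_mm
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    # tumor in the high-x hemisphere, away from the NAWM band
    center = (
        0.68 * extent[0] + rng.uniform(-0.03, 0.03) * extent[0],
        0.5 * extent[1] + rng.uniform(-0.06, 0.06) * extent[1],
        0.5 * extent[2] + rng.uniform(-0.06, 0.06) * extent[2],
    )
    mask = generate_tumor_mask(shape, spacing, center, phenotype.radii_mm,
                               irregularity=0.4, seed=int(seed_mask))
    ce_t1, flair, truth, brain, nawm = generate_channels(mask, config, int(seed_chan), phenotype)
    dwi = dsc = None
    if config.simulate_raw_signals:
        dwi = generate_dwi_pair(truth.true_adc_map, config.dwi_s0_level, config.dwi_b_value,
                                config.dwi_noise_sd, int(seed_dwi), spacing)
        dsc = generate_dsc_series(truth.true_cbv_map, truth.true_k2, config.dsc_te_s,
                                  config.dsc_tr_s, config.dsc_n_timepoints,
                                  config.dsc_n_baseline, config.dsc_noise_sd,
                                  int(seed_dsc), spacing=spacing)
    clinical = generate_clinical(config, rng)
    proxies = phenotype.proxies()
    lp = sum(config.true_effects.get(k, 0.0) * v for k, v in proxies.items())
    lp += clinical_linear_predictor(clinical, config.clinical_effects)
    truth.true_linear_predictor = float(lp)
    truth.phenotype = proxies
    return SubjectPhantom(
        subject_id=f"sub-{index:04d}",
        mask=mask, brain_mask=brain, nawm_mask=nawm,
        ce_t1=ce_t1, flair=flair, truth=truth, dwi=dwi, dsc=dsc,
        clinical=clinical,
    )


def generate_cohort(config: PhantomConfig) -> list[SubjectPhantom]:
    """Generate a full cohort with calibrated censoring."""
    subjects = [generate_subject(config, i) for i in range(config.n_subjects)]
    lp = np.array([s.truth.true_linear_predictor for s in subjects])
    surv_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 10**6)))
    records = generate_survival(lp, config.baseline_median_days, config.censor_rate,
                                seed=surv_rng, admin_horizon_days=config.admin_horizon_days)
    for s, r in zip(subjects, records):
        s.survival = r
    return subjects


def write_cohort(subjects: list[SubjectPhantom], out_dir, config: PhantomConfig | None = None) -> None:
    """Write NIfTI volumes, clinical.csv and truth.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for s in subjects:
        sid = s.subject_id
        save_volume(s.ce_t1, out / f"{sid}_ce_t1.nii.gz")
        save_volume(s.flair, out / f"{sid}_flair.nii.gz")
        save_volume(s.dwi.s0, out / f"{sid}_dwi_b0.nii.gz")
        save_volume(s.dwi.sb, out / f"{sid}_dwi_b1000.nii.gz")
        save_volume(s.mask, out / f"{sid}_mask.nii.gz")
        save_volume(ImageVolume(s.brain_mask.astype(float), s.mask.spacing),
                    out / f"{sid}_brainmask.nii.gz")
        save_volume(ImageVolume(s.nawm_mask.astype(float), s.mask.spacing),
                    out / f"{sid}_nawm.nii.gz")
        import nibabel as nib

        affine = np.diag(list(s.mask.spacing) + [1.0])
        nib.save(nib.Nifti1Image(s.dsc.signal.astype(np.float32), affine),
                 str(out / f"{sid}_dsc.nii.gz"))
        rows.append({
            "subject_id": sid, "age": s.clinical.age, "kps": s.clinical.kps,
            "extent": s.clinical.extent, "mgmt": s.clinical.mgmt,
            "time_days": s.survival.time_days if s.survival else np.nan,
            "event": s.survival.event if s.survival else np.nan,
        })
        truth[sid] = {
            "true_linear_predictor": s.truth.true_linear_predictor,
            "phenotype": s.truth.phenotype,
        }
    pd.DataFrame(rows).to_csv(out / "clinical.csv", index=False)
    meta = {"subjects": truth}
    if config is not None:
        meta["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(config).items()}
    (out / "truth.json").write_text(json.dumps(meta, indent=1))
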
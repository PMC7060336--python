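"""Survival model fitting and evaluation.

Kaplan-Meier estimation, log-rank testing, Cox regression (Efron ties),
Harrell's C-index with a paired-bootstrap comparison of correlated C
statistics, the D'Agostino-Nam calibration test, leakage-safe
cross-validated performance of radiomics/clinical/combined models, and
nomogram construction with a Breslow baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import concordance_index_censored

from .signature import (
    SignatureModel,
    lasso_cox_select,
    maxstat_cutoff,
    radiomics_score,
    z_transform,
)

__all__ = [
    "CoxFit",
    "CindexResult",
    "PrognosticModel",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "harrell_cindex",
    "compare_cindex",
    "dagostino_nam_calibration",
    "crossval_cindex",
    "crossval_model_comparison",
    "build_nomogram",
    "clinical_design_matrix",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KmCurve:
    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood

    def at(self, t) -> np.ndarray:
        """Step-function evaluation S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out if out.size > 1 else float(out[0])


def km_estimate(time, event) -> KmCurve:
    """Product-limit estimator with Greenwood variance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    order = np.argsort(time)
    t_sorted = time[order]
    e_sorted = event[order]
    uniq = np.unique(t_sorted[e_sorted == 1])
    s = 1.0
    gw = 0.0
    times = [0.0]
    survs = [1.0]
    vars_ = [0.0]
    for t in uniq:
        n = (t_sorted >= t).sum()
        d = ((t_sorted == t) & (e_sorted == 1)).sum()
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
        times.append(float(t))
        survs.append(float(s))
        vars_.append(float(s**2 * gw) if s > 0 else 0.0)
    return KmCurve(np.array(times), np.array(survs), np.array(vars_))


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """K-sample log-rank test: (chi-square, df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(time, group, event)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxFit:
    """A fitted Cox proportional hazards model (Efron ties)."""

    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    hazard_ratios: pd.Series
    log_partial_likelihood: float
    ties: str = "efron"
    fitter: CoxPHFitter | None = field(default=None, repr=False)

    def linear_predictor(self, x: pd.DataFrame) -> np.ndarray:
        return x[self.covariates].to_numpy(dtype=float) @ self.coef.to_numpy()


def cox_fit(covariates: pd.DataFrame, time, event, penalizer: float = 0.0) -> CoxFit:
    """Efron-ties Cox regression.

    ``penalizer`` adds an L2 ridge term; the default 0 gives the plain
    maximum partial-likelihood fit. A small ridge is used inside
    cross-validation folds, where unpenalized fits on a handful of events
    are unstable.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < covariates.shape[1] + 1:
        raise ValueError("need more events than covariates")
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate column(s): {', '.join(const)}")
    df = covariates.copy()
    df["__time"] = time
    df["__event"] = event
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="__time", event_col="__event", show_progress=False)
    except Exception as exc:  # separation / monotone likelihood
        raise ValueError(f"Cox fit failed to converge: {exc}") from exc
    return CoxFit(
        covariates=list(covariates.columns),
        coef=cph.params_.copy(),
        se=cph.standard_errors_.copy(),
        hazard_ratios=np.exp(cph.params_),
        log_partial_likelihood=float(cph.log_likelihood_),
        fitter=cph,
    )


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class CindexResult:
    cindex: float
    concordant: int
    discordant: int
    tied_risk: int
    comparison: dict | None = None


def harrell_cindex(predictor, time, event) -> CindexResult:
    """Harrell's C over usable pairs; predictor ties count one half."""
    predictor = np.asarray(predictor, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: no usable pairs")
    c, concordant, discordant, tied_risk, _ = concordance_index_censored(
        event.astype(bool), time, predictor
    )
    return CindexResult(float(c), int(concordant), int(discordant), int(tied_risk))


def compare_cindex(pred_a, pred_b, time, event, n_boot: int = 1000, seed: int = 0
                   ) -> tuple[float, float]:
    """Paired subject-level bootstrap comparison of two C-indexes.

    Returns ``(delta, p)`` where ``delta = C(a) - C(b)`` on the full sample
    and ``p`` is the two-sided percentile-symmetrized bootstrap p-value for
    ``delta = 0``. Both predictors must score the same subjects.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if pred_a.shape != pred_b.shape:
        raise ValueError("predictors must cover the same subjects")
    delta = harrell_cindex(pred_a, time, event).cindex - \
        harrell_cindex(pred_b, time, event).cindex
    if np.array_equal(pred_a, pred_b):
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    n = len(time)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if event[idx].sum() == 0:
            continue
        ca = harrell_cindex(pred_a[idx], time[idx], event[idx]).cindex
        cb = harrell_cindex(pred_b[idx], time[idx], event[idx]).cindex
        boots.append(ca - cb)
    boots = np.asarray(boots)
    p_lo = float(np.mean(boots <= 0.0))
    p_hi = float(np.mean(boots >= 0.0))
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return float(delta), p


# ---------------------------------------------------------------------------
# Calibration


def dagostino_nam_calibration(predicted_survival, time, event, horizon,
                              n_groups: int = 10) -> tuple[float, float]:
    """D'Agostino-Nam survival calibration test at one horizon.

    Subjects are grouped by deciles of predicted S(horizon); within each
    group, the Kaplan-Meier estimate at the horizon is compared with the
    mean prediction: ``chi2 = sum n_g (KM_g - pbar_g)^2 / (pbar_g (1 -
    pbar_g))`` on ``n_groups - 1`` degrees of freedom. Deciles that end up
    empty (heavy prediction ties) are merged with a neighbor.
    """
    pred = np.asarray(predicted_survival, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any((pred <= 0) | (pred >= 1)):
        raise ValueError("predicted survival probabilities must lie in (0, 1)")
    if len(pred) < 5 * n_groups:
        raise ValueError(f"need at least {5 * n_groups} subjects for {n_groups} groups")
    edges = np.quantile(pred, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < n_groups:
        log.info("dagostino_nam: merged tied deciles, %d groups remain", len(edges) - 1)
    labels = np.clip(np.searchsorted(edges, pred, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    used = 0
    for gidx in range(len(edges) - 1):
        sel = labels == gidx
        if sel.sum() == 0:
            continue
        pbar = pred[sel].mean()
        km = km_estimate(time[sel], event[sel]).at(horizon)
        chi2 += sel.sum() * (km - pbar) ** 2 / (pbar * (1 - pbar))
        used += 1
    dfree = used - 1
    p = float(stats.chi2.sf(chi2, dfree))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Clinical design and cross-validated performance


def clinical_design_matrix(clinical: pd.DataFrame, kps_threshold: int = 80) -> pd.DataFrame:
    """Covariates {age, kps_low, extent dummies} from a clinical table.

    KPS enters as the binary ``kps < threshold`` (default 80, configurable
    to 70); extent of resection enters as GTR/STR dummies against biopsy.
    """
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"].astype(float)
    out["kps_low"] = (clinical["kps"].astype(float) < kps_threshold).astype(float)
    out["extent_GTR"] = (clinical["extent"] == "GTR").astype(float)
    out["extent_STR"] = (clinical["extent"] == "STR").astype(float)
    return out


def _stratified_folds(event, folds, rng):
    fold = np.empty(len(event), dtype=int)
    for grp in (np.where(event == 1)[0], np.where(event == 0)[0]):
        perm = rng.permutation(grp)
        fold[perm] = np.arange(len(perm)) % folds
    return fold


def crossval_cindex(features: pd.DataFrame | None, clinical: pd.DataFrame | None,
                    time, event, folds: int = 10, seed: int = 0,
                    selection_cv_folds: int = 5, n_alphas: int = 30,
                    penalizer: float = 0.1) -> dict:
    """Event-stratified K-fold cross-validated Harrell C.

    Everything that learns from data — feature standardization, LASSO-Cox
    selection, and the Cox fit combining the resulting radiomics score with
    clinical covariates — is re-run inside each training fold; C is computed
    on the held-out fold only. Pass ``features=None`` for a clinical-only
    model or ``clinical=None`` for radiomics-only.

    Returns a dict with per-fold and mean C.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < folds:
        raise ValueError("need at least one event per fold")
    if features is None and clinical is None:
        raise ValueError("need features, clinical covariates, or both")
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(event, folds, rng)
    per_fold = []
    pooled_lp = np.full(len(time), np.nan)
    for f in range(folds):
        tr = fold != f
        te = fold == f
        if event[te].sum() == 0:
            continue
        lp_te = np.zeros(int(te.sum()))
        design_tr = pd.DataFrame(index=np.where(tr)[0])
        design_te = pd.DataFrame(index=np.where(te)[0])
        if features is not None:
            ftr, params = z_transform(features.iloc[tr.nonzero()[0]])
            fte = params.apply(features.iloc[te.nonzero()[0]])
            sig = lasso_cox_select(ftr, time[tr], event[tr],
                                   cv_folds=selection_cv_folds,
                                   seed=seed + 1000 + f, n_alphas=n_alphas)
            design_tr["radscore"] = radiomics_score(ftr, sig)
            design_te["radscore"] = radiomics_score(fte, sig)
        if clinical is not None:
            ctr = clinical_design_matrix(clinical.iloc[tr.nonzero()[0]]).reset_index(drop=True)
            cte = clinical_design_matrix(clinical.iloc[te.nonzero()[0]]).reset_index(drop=True)
            for col in ctr.columns:
                if ctr[col].nunique() > 1:
                    design_tr[col] = ctr[col].to_numpy()
                    design_te[col] = cte[col].to_numpy()
        if features is not None and clinical is None and design_tr.shape[1] == 1:
            # radiomics-only: the score is already a Cox linear predictor
            lp_te = design_te["radscore"].to_numpy()
        else:
            # clinical coefficients get the full ridge; the radiomics score,
            # already a cross-fitted Cox linear predictor, gets a lighter one
            # that still tempers it in folds where selection found only noise
            pen = np.full(design_tr.shape[1], penalizer)
            if "radscore" in design_tr.columns:
                pen[list(design_tr.columns).index("radscore")] = 0.5 * penalizer
            fit = cox_fit(design_tr, time[tr], event[tr], penalizer=pen)
            lp_te = fit.linear_predictor(design_te)
        pooled_lp[te] = lp_te
        per_fold.append(harrell_cindex(lp_te, time[te], event[te]).cindex)
    have = ~np.isnan(pooled_lp)
    pooled = harrell_cindex(pooled_lp[have], time[have], event[have]).cindex
    return {"per_fold": per_fold, "mean": float(np.mean(per_fold)),
            "pooled": float(pooled), "folds": folds}


def crossval_model_comparison(features: pd.DataFrame, clinical: pd.DataFrame,
                              time, event, folds: int = 10, seed: int = 0,
                              selection_cv_folds: int = 5, n_alphas: int = 30,
                              penalizer: float = 0.5, repeats: int = 1) -> dict:
    """Cross-validated C for combined, radiomics-only and clinical-only models.

    All three models share the same event-stratified folds, and the combined
    and radiomics-only models share the per-fold signature (selection is run
    once per training fold), so their comparison isolates what the clinical
    covariates add. Held-out linear predictors are pooled across folds into
    one Harrell C per model; with ``repeats > 1`` the whole cross-validation
    is repeated on independent fold partitions and the pooled C values are
    averaged, which damps fold-assignment noise at small n.
    """
    if repeats > 1:
        runs = [crossval_model_comparison(features, clinical, time, event,
                                          folds=folds, seed=seed + 7919 * r,
                                          selection_cv_folds=selection_cv_folds,
                                          n_alphas=n_alphas, penalizer=penalizer)
                for r in range(repeats)]
        return {k: float(np.mean([run[k] for run in runs])) for k in runs[0]}
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(event, folds, rng)
    lp = {"combined": np.full(len(time), np.nan),
          "radiomics": np.full(len(time), np.nan),
          "clinical": np.full(len(time), np.nan)}
    for f in range(folds):
        tr = fold != f
        te = fold == f
        if event[te].sum() == 0:
            continue
        ftr, params = z_transform(features.iloc[tr.nonzero()[0]])
        fte = params.apply(features.iloc[te.nonzero()[0]])
        sig = lasso_cox_select(ftr, time[tr], event[tr],
                               cv_folds=selection_cv_folds,
                               seed=seed + 1000 + f, n_alphas=n_alphas)
        rs_tr = radiomics_score(ftr, sig)
        rs_te = radiomics_score(fte, sig)
        lp["radiomics"][te] = rs_te

        ctr = clinical_design_matrix(clinical.iloc[tr.nonzero()[0]]).reset_index(drop=True)
        cte = clinical_design_matrix(clinical.iloc[te.nonzero()[0]]).reset_index(drop=True)
        keep = [c for c in ctr.columns if ctr[c].nunique() > 1]
        ctr, cte = ctr[keep], cte[keep]

        cfit = cox_fit(ctr, time[tr], event[tr], penalizer=penalizer)
        lp["clinical"][te] = cfit.linear_predictor(cte)

        design_tr = ctr.copy()
        design_tr.insert(0, "radscore", rs_tr)
        design_te = cte.copy()
        design_te.insert(0, "radscore", rs_te)
        pen = np.full(design_tr.shape[1], penalizer)
        pen[0] = 0.5 * penalizer  # lighter ridge on the cross-fitted score
        mfit = cox_fit(design_tr, time[tr], event[tr], penalizer=pen)
        lp["combined"][te] = mfit.linear_predictor(design_te)
    out = {}
    for name, pred in lp.items():
        have = ~np.isnan(pred)
        out[name] = harrell_cindex(pred[have], time[have], event[have]).cindex
    return out


# ---------------------------------------------------------------------------
# Nomogram


@dataclass
class PrognosticModel:
    """Multivariable Cox model with Breslow baseline and nomogram points.

    ``points`` maps each covariate to a (value -> points) linear rule;
    100 points correspond to the largest single-covariate effect range.
    """

    fit: CoxFit
    baseline_times: np.ndarray
    baseline_survival: np.ndarray  # S0(t) at the covariate means
    covariate_means: pd.Series
    points: dict[str, dict]
    points_per_lp: float
    horizons: tuple[int, ...] = (365, 730)

    def baseline_at(self, t: float) -> float:
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.baseline_survival[idx])

    def predict_survival(self, x: pd.DataFrame, t: float) -> np.ndarray:
        """S(t | x) = S0(t) ^ exp(lp - lp_mean)."""
        lp = self.fit.linear_predictor(x)
        lp_mean = float(self.fit.coef.to_numpy() @ self.covariate_means.to_numpy())
        return self.baseline_at(t) ** np.exp(lp - lp_mean)

    def total_points(self, x: pd.DataFrame) -> np.ndarray:
        total = np.zeros(len(x))
        for cov, rule in self.points.items():
            total += (x[cov].to_numpy(dtype=float) - rule["ref"]) * rule["points_per_unit"]
        return total

    def survival_from_points(self, total_points: np.ndarray, t: float) -> np.ndarray:
        """Invert points to a linear predictor, then predict survival."""
        lp_ref = 0.0
        for cov, rule in self.points.items():
            lp_ref += self.fit.coef[cov] * rule["ref"]
        lp = np.asarray(total_points, dtype=float) / self.points_per_lp + lp_ref
        lp_mean = float(self.fit.coef.to_numpy() @ self.covariate_means.to_numpy())
        return self.baseline_at(t) ** np.exp(lp - lp_mean)


def build_nomogram(fit: CoxFit, covariates: pd.DataFrame, time, event,
                   horizons: tuple[int, ...] = (365, 730)) -> PrognosticModel:
    """Construct a nomogram from a fitted Cox model.

    Per covariate, points are ``beta * (x - x_ref)`` rescaled so the largest
    covariate effect range spans 0-100 points; ``x_ref`` is the covariate
    value at which points are zero (the range end with the lower hazard).
    The baseline survival is the Breslow estimator at the covariate means.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ranges = {}
    for cov in fit.covariates:
        beta = float(fit.coef[cov])
        x = covariates[cov].to_numpy(dtype=float)
        effect_range = abs(beta) * (x.max() - x.min())
        ranges[cov] = effect_range
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all covariate effect ranges are zero")
    points_per_lp = 100.0 / max_range
    points = {}
    for cov in fit.covariates:
        beta = float(fit.coef[cov])
        x = covariates[cov].to_numpy(dtype=float)
        ref = x.min() if beta >= 0 else x.max()  # zero points at lowest hazard
        points[cov] = {
            "ref": float(ref),
            "points_per_unit": beta * points_per_lp,
            "max_points": ranges[cov] * points_per_lp,
        }
    # Breslow baseline cumulative hazard at covariate means
    means = covariates[fit.covariates].mean()
    lp = fit.linear_predictor(covariates) - float(fit.coef.to_numpy() @ means.to_numpy())
    order = np.argsort(time)
    t_sorted = time[order]
    e_sorted = event[order]
    lp_sorted = lp[order]
    exp_lp = np.exp(lp_sorted)
    uniq = np.unique(t_sorted[e_sorted == 1])
    h0 = []
    for t in uniq:
        at_risk = t_sorted >= t
        d = ((t_sorted == t) & (e_sorted == 1)).sum()
        h0.append(d / exp_lp[at_risk].sum())
    cumh = np.cumsum(h0)
    s0 = np.exp(-cumh)
    return PrognosticModel(
        fit=fit,
        baseline_times=uniq,
        baseline_survival=s0,
        covariate_means=means,
        points=points,
        points_per_lp=points_per_lp,
        horizons=tuple(int(h) for h in horizons),
    )
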
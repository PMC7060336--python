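"""Radiomics signature: standardization, LASSO-Cox selection, score, cutoff.

The signature is a sparse linear Cox predictor over z-transformed radiomic
features: L1-penalized partial-likelihood maximization selects a small
feature subset; the radiomics score is the coefficient-weighted sum of the
selected (standardized) features; a maximally selected log-rank statistic
picks the risk cutoff. A packaged published signature (six features, six
coefficients, cutoff -0.07) supports score application without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "StandardizationParams",
    "SignatureModel",
    "z_transform",
    "lambda_max",
    "lasso_cox_select",
    "radiomics_score",
    "maxstat_cutoff",
    "stratify",
    "load_paper_signature",
]


@dataclass
class StandardizationParams:
    """Per-feature training mean and SD; zero-SD features are dropped."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    def apply(self, features: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(f"features missing standardized columns: {missing[:5]}")
        return (features[cols] - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "dropped": list(self.dropped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(mean=pd.Series(d["mean"], dtype=float),
                   sd=pd.Series(d["sd"], dtype=float),
                   dropped=list(d.get("dropped", [])))

    @classmethod
    def identity(cls, columns) -> "StandardizationParams":
        return cls(mean=pd.Series(0.0, index=columns), sd=pd.Series(1.0, index=columns))


def z_transform(features: pd.DataFrame,
                params: StandardizationParams | None = None
                ) -> tuple[pd.DataFrame, StandardizationParams]:
    """Standardize features column-wise.

    With ``params=None`` the mean/SD are fit on the given table (training
    use); otherwise the provided training parameters are applied, as they
    must be for validation data. Zero-SD columns are dropped at fit time.
    Apply this exactly once per table: re-applying re-standardizes.
    """
    if params is None:
        if len(features) < 2:
            raise ValueError("need at least 2 subjects to fit standardization")
        sd = features.std(ddof=0)
        keep = sd > 0
        dropped = list(features.columns[~keep])
        params = StandardizationParams(mean=features.loc[:, keep].mean(),
                                       sd=sd[keep], dropped=dropped)
    return params.apply(features), params


@dataclass
class SignatureModel:
    """A fitted radiomics signature."""

    features: list[str]
    coefficients: np.ndarray
    lambda_: float
    cutoff: float | None
    standardization: StandardizationParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if np.any(self.coefficients == 0):
            raise ValueError("signature coefficients must all be non-zero")

    def to_json(self, path=None) -> str:
        payload = {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "lambda": self.lambda_,
            "cutoff": self.cutoff,
            "standardization": self.standardization.to_dict(),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SignatureModel":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            features=list(payload["features"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            lambda_=float(payload["lambda"]) if payload["lambda"] is not None else 0.0,
            cutoff=payload["cutoff"],
            standardization=StandardizationParams.from_dict(payload["standardization"]),
            provenance=payload.get("provenance", {}),
        )


def load_paper_signature() -> SignatureModel:
    """The packaged published six-feature signature (cutoff -0.07).

    Its standardization is the identity: scores are computed directly on
    already-standardized feature values.
    """
    text = resources.files("gliorad.data").joinpath("paper_signature.json").read_text()
    return SignatureModel.from_json(text)


def _breslow_neg_log_partial_likelihood(lp, time, event):
    """Breslow-ties negative log partial likelihood (sum over events).

    ``lp`` may be 1D (n,) or 2D (n, k); a 2D input evaluates k linear
    predictors at once and returns an array of length k.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    squeeze = lp.ndim == 1
    if squeeze:
        lp = lp[:, None]
    order = np.argsort(-time, kind="stable")  # decreasing time
    lp = lp[order]
    t_sorted = time[order]
    e_sorted = event[order]
    log_cumsum = np.logaddexp.accumulate(lp, axis=0)
    # risk set for an event at t is everyone with time >= t; with the
    # decreasing sort, tied times share the largest index among equals
    n = len(t_sorted)
    last_tie = np.arange(n)
    same_as_next = np.zeros(n, dtype=bool)
    same_as_next[:-1] = t_sorted[1:] == t_sorted[:-1]
    for i in range(n - 2, -1, -1):  # short scalar loop, no inner work
        if same_as_next[i]:
            last_tie[i] = last_tie[i + 1]
    ev = e_sorted == 1
    nll = (log_cumsum[last_tie[ev]] - lp[ev]).sum(axis=0)
    return float(nll[0]) if squeeze else nll


def lambda_max(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Smallest penalty that forces the all-zero solution.

    With the glmnet-style 1/n objective scaling, this is the largest
    absolute component of the partial-likelihood gradient at beta = 0,
    divided by n.
    """
    x = np.asarray(x, dtype=float)
    n = len(time)
    order = np.argsort(-time)
    xo = x[order]
    to = np.asarray(time)[order]
    eo = np.asarray(event)[order]
    csum_x = np.cumsum(xo, axis=0)
    grad = np.zeros(x.shape[1])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and to[j + 1] == to[i]:
            j += 1
        risk_mean = csum_x[j] / (j + 1)
        for k in range(i, j + 1):
            if eo[k] == 1:
                grad += xo[k] - risk_mean
        i = j + 1
    return float(np.abs(grad).max() / n)


def lasso_cox_select(features: pd.DataFrame, time, event, alphas=None,
                     cv_folds: int = 10, seed: int = 0, n_alphas: int = 50,
                     rule: str = "min", tol: float = 1e-7,
                     alpha_min_ratio: float | None = None) -> SignatureModel:
    """Select features by cross-validated L1-penalized Cox regression.

    The coordinate-descent path (Breslow ties, glmnet-style scaling) is fit
    over a log-spaced penalty grid from the all-zero solution downward; the
    penalty is chosen by ``cv_folds``-fold cross-validated partial-likelihood
    deviance, folds stratified by event status. ``rule='min'`` takes the
    deviance minimizer (configurable to '1se').

    Input features must already be standardized; the returned model carries
    an identity standardization for that reason unless one is attached later.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 10:
        raise ValueError(f"need at least 10 events, got {int(event.sum())}")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    x = features.to_numpy(dtype=float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if alphas is None:
        amax = lambda_max(x, time, event)
        if alpha_min_ratio is None:
            # glmnet-style convention: a shallower path when p >= n, where
            # the dense end of the path is expensive and never selected
            alpha_min_ratio = 0.01 if x.shape[1] >= x.shape[0] else 1e-3
        alphas = np.geomspace(amax * 1.0001, amax * alpha_min_ratio, n_alphas)
    alphas = np.asarray(alphas, dtype=float)

    # event-stratified fold assignment
    rng = np.random.default_rng(seed)
    fold = np.empty(len(time), dtype=int)
    for grp in (np.where(event == 1)[0], np.where(event == 0)[0]):
        perm = rng.permutation(grp)
        fold[perm] = np.arange(len(perm)) % cv_folds

    # Verweij-van Houwelingen cross-validated partial likelihood: for each
    # fold, the held-out contribution is nll(all data) - nll(training part),
    # both at the fold model's coefficients. Using full-sample risk sets
    # keeps the criterion stable even when test folds carry few events.
    deviance = np.zeros(len(alphas))
    for f in range(cv_folds):
        tr = fold != f
        if event[tr].sum() == 0 or event[fold == f].sum() == 0:
            continue
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False,
                                       tol=tol, max_iter=200000)
        model.fit(x[tr], y[tr])
        fitted = np.asarray(model.alphas_)
        cols = np.array([int(np.argmin(np.abs(fitted - a))) for a in alphas])
        lp_all = (x @ model.coef_)[:, cols]  # (n, n_alphas)
        nll_all = _breslow_neg_log_partial_likelihood(lp_all, time, event)
        nll_tr = _breslow_neg_log_partial_likelihood(lp_all[tr], time[tr], event[tr])
        deviance += 2.0 * (nll_all - nll_tr)
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False,
                                   tol=tol, max_iter=200000)
    final.fit(x, y)
    fitted = np.asarray(final.alphas_)
    path_idx = np.array([int(np.argmin(np.abs(fitted - a))) for a in alphas])
    nonempty = np.array([np.any(final.coef_[:, k] != 0) for k in path_idx])
    if not nonempty.any():
        raise ValueError(
            "no penalty on the grid keeps any feature; the cohort carries no "
            "detectable prognostic signal at this size"
        )
    if rule == "min":
        # restrict to penalties whose full-data solution keeps >= 1 feature:
        # at very small n the CV minimizer can be the empty model, which
        # cannot define a signature
        usable = np.where(nonempty)[0]
        best = int(usable[np.argmin(deviance[usable])])
    elif rule == "1se":
        # conservative variant: largest penalty within one SD-equivalent of
        # the minimum (SD approximated across folds is not tracked; use 1%)
        thresh = deviance.min() * 1.01
        cand_idx = np.where((deviance <= thresh) & nonempty)[0]
        if cand_idx.size == 0:
            cand_idx = np.where(nonempty)[0]
        best = int(cand_idx[0])
    else:
        raise ValueError("rule must be 'min' or '1se'")

    k = path_idx[best]
    coefs = final.coef_[:, k]
    nz = np.flatnonzero(coefs)
    return SignatureModel(
        features=[features.columns[i] for i in nz],
        coefficients=coefs[nz],
        lambda_=float(alphas[best]),
        cutoff=None,
        standardization=StandardizationParams.identity(list(features.columns[nz])),
        provenance={"seed": int(seed), "cv_folds": int(cv_folds), "rule": rule,
                    "n_alphas": int(len(alphas))},
    )


def radiomics_score(features, model: SignatureModel) -> np.ndarray | float:
    """Coefficient-weighted sum of the selected standardized features."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in model.features if f not in features.columns]
        if missing:
            raise ValueError(f"missing selected feature(s): {', '.join(missing)}")
        x = features[model.features].to_numpy(dtype=float)
        return x @ model.coefficients
    if isinstance(features, pd.Series):
        missing = [f for f in model.features if f not in features.index]
        if missing:
            raise ValueError(f"missing selected feature(s): {', '.join(missing)}")
        return float(features[model.features].to_numpy(dtype=float) @ model.coefficients)
    raise TypeError("features must be a pandas Series or DataFrame")


def standardized_logrank_statistic(group_high: np.ndarray, time: np.ndarray,
                                   event: np.ndarray) -> float:
    """Two-sample standardized log-rank statistic (O - E) / sqrt(V).

    Positive when the high group fails earlier than expected. Uses the
    hypergeometric variance at each distinct event time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g = np.asarray(group_high, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


def maxstat_cutoff(scores, time, event,
                   quantile_bounds: tuple[float, float] = (0.1, 0.9)
                   ) -> tuple[float, float]:
    """Maximally selected log-rank cutpoint.

    Candidate cutpoints are midpoints of consecutive sorted unique scores
    lying within the quantile bounds; the returned cutoff
    maximizes the absolute standardized two-sample log-rank statistic, and
    the statistic is returned with it. Requires at least one event on each
    side of the optimum.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("all scores are tied; no cutpoint exists")
    lo, hi = np.quantile(scores, quantile_bounds)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cand = mids[(mids >= lo) & (mids <= hi)]
    if len(cand) < 2:
        cand = mids
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    s_sorted = scores[order]
    # split index k: ranks >= k form the high group for cutpoint c
    ks = np.searchsorted(s_sorted, cand, side="right")

    # O - E for every split at once: suffix sums of log-rank scores
    # a_j = e_j - sum_{t <= T_j} d_t / n_t (martingale residual at beta = 0)
    uniq_t = np.unique(t_sorted[e_sorted == 1])
    d = np.array([((t_sorted == t) & (e_sorted == 1)).sum() for t in uniq_t])
    n_at_risk = np.array([(t_sorted >= t).sum() for t in uniq_t])
    cumhaz_at = np.cumsum(d / n_at_risk)
    pos = np.searchsorted(uniq_t, t_sorted, side="right") - 1
    a = e_sorted - np.where(pos >= 0, cumhaz_at[np.clip(pos, 0, None)], 0.0)
    suffix_a = np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])
    o_minus_e = suffix_a[ks]

    # hypergeometric variance, accumulated per event time over all splits
    var = np.zeros(len(cand))
    for t, dt, nt in zip(uniq_t, d, n_at_risk):
        if nt <= 1:
            continue
        at_risk = (t_sorted >= t).astype(float)
        suffix_r = np.concatenate([np.cumsum(at_risk[::-1])[::-1], [0.0]])
        r = suffix_r[ks]  # high-group at-risk count per split
        var += dt * (r / nt) * (1 - r / nt) * (nt - dt) / (nt - 1)

    # events required on both sides of the split
    suffix_e = np.concatenate([np.cumsum(e_sorted[::-1])[::-1], [0]])
    high_events = suffix_e[ks]
    total_events = e_sorted.sum()
    ok = (high_events >= 1) & (total_events - high_events >= 1) & (var > 0)
    if not ok.any():
        raise ValueError("no candidate cutpoint leaves an event on both sides")
    stat = np.full(len(cand), -np.inf)
    stat[ok] = np.abs(o_minus_e[ok] / np.sqrt(var[ok]))
    best = int(np.argmax(stat))
    return float(cand[best]), float(stat[best])


def stratify(scores, cutoff: float) -> np.ndarray:
    """Risk labels: 'high' for score > cutoff, 'low' for score <= cutoff."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return np.where(scores > cutoff, "high", "low")
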
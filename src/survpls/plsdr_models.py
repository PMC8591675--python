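"""Survival model families built on PLS components.

Two constructions:

* the deviance-residual pipeline — null-model deviance residuals regressed
  on X (or on a kernel Gram matrix) by plain / sparse / group / sparse-group
  PLS, followed by a Cox fit on the retained component scores;
* the iterative PLS-Cox construction, where each component's weights are the
  per-predictor slopes of conditional Cox fits given the previous components,
  with an auto-stopping variant driven by Wald significance.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Literal

import numpy as np

from .pls_engines import (
    GroupStructure,
    KernelSpec,
    PLSFit,
    Mode,
    _score_from,
    apply_center_scale,
    center_scale,
    cross_gram,
    fit_pls,
    gram_matrix,
    median_pairwise_distance,
    predict_scores,
)
from .survival_core import (
    MAX_ABS_BETA,
    CoxFit,
    SurvivalOutcome,
    fit_cox,
    null_deviance_residuals,
)

__all__ = [
    "PLSDRModel",
    "fit_plsdr",
    "fit_pls_cox",
    "fit_auto_pls_cox",
    "predict_risk",
    "predict_survival",
]

Family = Literal[
    "plsdr", "splsdr", "gplsdr", "sgplsdr",
    "dkplsdr", "dksplsdr", "dkgplsdr", "dksgplsdr",
    "pls-cox", "auto-pls-cox",
]

_MODE_BY_FAMILY: dict[str, Mode] = {
    "plsdr": "plain", "splsdr": "sparse", "gplsdr": "group", "sgplsdr": "sparse-group",
    "dkplsdr": "plain", "dksplsdr": "sparse", "dkgplsdr": "group", "dksgplsdr": "sparse-group",
}


@dataclasses.dataclass
class PLSDRModel:
    family: str
    residuals: np.ndarray | None  # null deviance residuals (residual stage)
    pls: PLSFit | None
    final_cox: CoxFit
    kernel: KernelSpec | None = None
    X_train: np.ndarray | None = None  # kept only for kernel prediction
    impute_means: np.ndarray | None = None

    @property
    def ncomp(self) -> int:
        return self.pls.ncomp if self.pls is not None else 0

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        d = {
            "family": self.family,
            "residuals": arr(self.residuals),
            "kernel": None
            if self.kernel is None
            else {"kind": self.kernel.kind, "bandwidth": self.kernel.bandwidth},
            "X_train": arr(self.X_train),
            "impute_means": arr(self.impute_means),
            "final_cox": {
                "beta": arr(self.final_cox.beta),
                "log_pl": self.final_cox.log_pl,
                "converged": self.final_cox.converged,
                "n_iter": self.final_cox.n_iter,
                "flags": list(self.final_cox.flags),
                "ties": self.final_cox.ties,
                "baseline_times": arr(
                    None if self.final_cox.baseline_cumhaz is None else self.final_cox.baseline_cumhaz.x
                ),
                "baseline_values": arr(
                    None if self.final_cox.baseline_cumhaz is None else self.final_cox.baseline_cumhaz.y
                ),
            },
        }
        if self.pls is not None:
            f = self.pls
            d["pls"] = {
                "ncomp": f.ncomp,
                "weights": arr(f.weights),
                "directions": arr(f.directions),
                "scores": arr(f.scores),
                "x_loadings": arr(f.x_loadings),
                "y_loadings": arr(f.y_loadings),
                "center": arr(f.center),
                "scale": arr(f.scale),
                "mode": f.mode,
                "eta": f.eta,
                "truncated": f.truncated,
            }
        else:
            d["pls"] = None
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDRModel":
        from .survival_core import StepFunction

        fc = d["final_cox"]
        baseline = None
        if fc["baseline_times"] is not None:
            baseline = StepFunction(fc["baseline_times"], fc["baseline_values"])
        final_cox = CoxFit(
            np.asarray(fc["beta"], dtype=float),
            fc["log_pl"],
            baseline,
            fc["converged"],
            fc["n_iter"],
            tuple(fc["flags"]),
            fc["ties"],
        )
        pls = None
        if d["pls"] is not None:
            f = d["pls"]
            pls = PLSFit(
                ncomp=f["ncomp"],
                weights=np.asarray(f["weights"], dtype=float),
                directions=np.asarray(f["directions"], dtype=float),
                scores=np.asarray(f["scores"], dtype=float),
                x_loadings=np.asarray(f["x_loadings"], dtype=float),
                y_loadings=np.asarray(f["y_loadings"], dtype=float),
                center=np.asarray(f["center"], dtype=float),
                scale=np.asarray(f["scale"], dtype=float),
                mode=f["mode"],
                eta=f["eta"],
                truncated=f["truncated"],
            )
        kernel = None
        if d["kernel"] is not None:
            kernel = KernelSpec(d["kernel"]["kind"], d["kernel"]["bandwidth"])
        return cls(
            family=d["family"],
            residuals=None if d["residuals"] is None else np.asarray(d["residuals"], dtype=float),
            pls=pls,
            final_cox=final_cox,
            kernel=kernel,
            X_train=None if d["X_train"] is None else np.asarray(d["X_train"], dtype=float),
            impute_means=None
            if d["impute_means"] is None
            else np.asarray(d["impute_means"], dtype=float),
        )

    @classmethod
    def from_json(cls, s: str) -> "PLSDRModel":
        return cls.from_dict(json.loads(s))


def _null_model(family: str, outcome: SurvivalOutcome) -> PLSDRModel:
    final = fit_cox(np.zeros((outcome.n, 0)), outcome)
    return PLSDRModel(family=family, residuals=None, pls=None, final_cox=final)


def fit_plsdr(
    X,
    outcome: SurvivalOutcome,
    ncomp: int,
    mode: Mode = "plain",
    eta: float = 0.0,
    groups: GroupStructure | None = None,
    kernel: KernelSpec | None = None,
) -> PLSDRModel:
    """Deviance-residual PLS pipeline: residuals → PLS → Cox on scores."""
    X = np.asarray(X, dtype=float)
    family = {"plain": "plsdr", "sparse": "splsdr", "group": "gplsdr", "sparse-group": "sgplsdr"}[mode]
    if kernel is not None:
        family = "dk" + family
    if ncomp < 0:
        raise ValueError("ncomp must be >= 0")
    if ncomp == 0:
        return _null_model(family, outcome)
    d = null_deviance_residuals(outcome).values
    X_train = None
    impute_means = None
    resolved_kernel = kernel
    if kernel is not None:
        if np.any(np.isnan(X)):
            impute_means = np.nanmean(X, axis=0)
            X = np.where(np.isnan(X), impute_means, X)
        X_train = X
        if kernel.kind == "gaussian" and kernel.bandwidth is None:
            resolved_kernel = KernelSpec("gaussian", median_pairwise_distance(X))
        design = gram_matrix(X, resolved_kernel)
    else:
        design = X
    pls = fit_pls(design, d, ncomp, mode=mode, eta=eta, groups=groups)
    if pls.ncomp == 0:
        return _null_model(family, outcome)
    final = fit_cox(pls.scores, outcome)
    return PLSDRModel(
        family=family,
        residuals=d,
        pls=pls,
        final_cox=final,
        kernel=resolved_kernel,
        X_train=X_train,
        impute_means=impute_means,
    )


def _conditional_cox_slope(T_prev, xj, outcome: SurvivalOutcome):
    """Coefficient and Wald p-value of xj in a Cox fit given prior components.

    Rows with xj missing are dropped. Separation is handled by clipping the
    coefficient at ±MAX_ABS_BETA (flagged fit, finite fallback).
    """
    from scipy.stats import norm

    obs = ~np.isnan(xj)
    if obs.sum() < 2 or np.nanstd(xj) == 0:
        return 0.0, 1.0
    sub = outcome.subset(obs)
    if sub.n_events == 0:
        return 0.0, 1.0
    Z = np.column_stack([T_prev[obs], xj[obs]]) if T_prev.shape[1] else xj[obs, None]
    fit = fit_cox(Z, sub, compute_baseline=False)
    coef = float(np.clip(fit.beta[-1], -MAX_ABS_BETA, MAX_ABS_BETA))
    pval = 1.0
    if fit.cov is not None:
        se = np.sqrt(max(fit.cov[-1, -1], 0.0))
        if se > 0 and np.isfinite(se):
            pval = 2.0 * float(norm.sf(abs(fit.beta[-1]) / se))
    return coef, pval


def _fit_pls_cox_impl(
    X, outcome: SurvivalOutcome, ncomp: int, alpha: float | None, family: str
) -> PLSDRModel:
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xs, center, scale = center_scale(X)
    Xd = Xs.copy()
    max_comp = min(ncomp, n - 1, p)
    W = np.zeros((p, max_comp))
    T = np.zeros((n, max_comp))
    P = np.zeros((p, max_comp))
    m = 0
    for h in range(max_comp):
        w = np.zeros(p)
        pvals = np.ones(p)
        for j in range(p):
            w[j], pvals[j] = _conditional_cox_slope(T[:, :m], Xd[:, j], outcome)
        if alpha is not None:
            keep = pvals < alpha
            if not keep.any():
                break
            w = np.where(keep, w, 0.0)
        norm_w = np.linalg.norm(w)
        if norm_w == 0:
            break
        w /= norm_w
        t = _score_from(Xd, w)
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        obs = ~np.isnan(Xd)
        pnum = np.nansum(Xd * t[:, None], axis=0)
        pden = obs.T @ (t**2)
        load = np.where(pden > 0, pnum / np.where(pden > 0, pden, 1.0), 0.0)
        W[:, m], T[:, m], P[:, m] = w, t, load
        Xd = Xd - np.outer(t, load)
        m += 1
    if m == 0:
        return _null_model(family, outcome)
    pls = PLSFit(
        ncomp=m,
        weights=W[:, :m],
        directions=W[:, :m],
        scores=T[:, :m],
        x_loadings=P[:, :m],
        y_loadings=np.zeros(m),
        center=center,
        scale=scale,
        mode="plain",
        truncated=m < ncomp,
    )
    final = fit_cox(pls.scores, outcome)
    return PLSDRModel(family=family, residuals=None, pls=pls, final_cox=final)


def fit_pls_cox(X, outcome: SurvivalOutcome, ncomp: int) -> PLSDRModel:
    """Iterative PLS extension of the Cox model (conditional-slope weights)."""
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    return _fit_pls_cox_impl(X, outcome, ncomp, alpha=None, family="pls-cox")


def fit_auto_pls_cox(X, outcome: SurvivalOutcome, alpha: float = 0.05) -> PLSDRModel:
    """PLS-Cox with Wald-significance gating; stops when nothing is significant."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    cap = min(X.shape[0] - 1, X.shape[1])
    return _fit_pls_cox_impl(X, outcome, cap, alpha=alpha, family="auto-pls-cox")


def _new_scores(model: PLSDRModel, Xnew) -> np.ndarray:
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if model.pls is None:
        return np.zeros((Xnew.shape[0], 0))
    if model.kernel is not None:
        if model.impute_means is not None:
            Xnew = np.where(np.isnan(Xnew), model.impute_means, Xnew)
        design = cross_gram(Xnew, model.X_train, model.kernel)
    else:
        design = Xnew
    return predict_scores(model.pls, design)


def predict_risk(model: PLSDRModel, Xnew) -> np.ndarray:
    """Linear predictor β̂'·scores(Xnew); zero vector for the null model."""
    T = _new_scores(model, Xnew)
    if model.ncomp == 0:
        return np.zeros(T.shape[0])
    return T @ model.final_cox.beta


def predict_survival(model: PLSDRModel, Xnew, times) -> np.ndarray:
    """Ŝ(t|x) = exp(−Λ̂0(t)·exp(risk(x))) on the final Cox Breslow baseline.

    Returns an (n_new × n_times) matrix, rows non-increasing in t.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("negative times")
    risk = predict_risk(model, Xnew)
    cumhaz = model.final_cox.baseline_cumhaz(times)
    return np.exp(-np.outer(np.exp(risk), cumhaz))
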
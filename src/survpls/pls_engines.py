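"""NIPALS-style PLS1 regression with pairwise-complete missing-data handling,
sparse / group / sparse-group direction thresholding, and kernel Gram matrices.

The response is never deflated (regression-mode PLS1); only X is. Weights are
computed as the NIPALS regression slopes of each predictor column on the
response over pairwise-complete rows, which on complete data reduces to
w ∝ X'y at every component.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PLSFit",
    "GroupStructure",
    "KernelSpec",
    "center_scale",
    "apply_center_scale",
    "nipals_weight",
    "soft_threshold_direction",
    "group_threshold_direction",
    "fit_pls",
    "gram_matrix",
    "cross_gram",
    "predict_scores",
    "median_pairwise_distance",
]

Mode = Literal["plain", "sparse", "group", "sparse-group"]


@dataclasses.dataclass(frozen=True)
class GroupStructure:
    """Disjoint predictor-index groups; uncovered predictors act as singletons."""

    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if not self.groups:
            raise ValueError("empty group structure")
        seen: set[int] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty group")
            if seen & set(g):
                raise ValueError("groups must be disjoint")
            seen |= set(g)
        object.__setattr__(self, "groups", tuple(tuple(int(i) for i in g) for g in self.groups))

    def complete(self, p: int) -> tuple[tuple[int, ...], ...]:
        """Groups plus implicit singletons covering 1..p (0-based indices)."""
        covered = {i for g in self.groups for i in g}
        if covered and max(covered) >= p:
            raise ValueError("group index out of range")
        extras = tuple((i,) for i in range(p) if i not in covered)
        return self.groups + extras

    @classmethod
    def from_labels(cls, labels: Sequence) -> "GroupStructure":
        order: dict = {}
        for i, lab in enumerate(labels):
            order.setdefault(lab, []).append(i)
        return cls(tuple(tuple(v) for v in order.values()))


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    kind: Literal["linear", "gaussian"]
    bandwidth: float | None = None

    def __post_init__(self):
        if self.kind not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")


@dataclasses.dataclass
class PLSFit:
    ncomp: int
    weights: np.ndarray  # p × m, unit-norm columns (pre-thresholding Z)
    directions: np.ndarray  # p × m, thresholded unit-norm directions actually used
    scores: np.ndarray  # n × m
    x_loadings: np.ndarray  # p × m
    y_loadings: np.ndarray  # m
    center: np.ndarray
    scale: np.ndarray
    mode: Mode = "plain"
    eta: float = 0.0
    truncated: bool = False


def center_scale(X):
    """Standardize columns over observed entries; NaNs preserved.

    Returns (Xs, center, scale). Constant columns get scale 1 and are left
    centered only. All-missing columns raise.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    n_obs = np.sum(~np.isnan(X), axis=0)
    bad = np.where(n_obs == 0)[0]
    if bad.size:
        raise ValueError(f"column {bad[0]} is entirely missing")
    center = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0, ddof=1)
    scale = np.where((scale == 0) | ~np.isfinite(scale), 1.0, scale)
    return (X - center) / scale, center, scale


def apply_center_scale(X, center, scale):
    X = np.asarray(X, dtype=float)
    return (X - center) / scale


def nipals_weight(X, y) -> np.ndarray:
    """Unit-norm weight vector from pairwise-complete regression slopes.

    w_j = Σ_{i: x_ij observed} x_ij·y_i / Σ_{i: x_ij observed} y_i², the
    NIPALS slope of predictor j on the (centered) response. On complete data
    w ∝ X'y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = ~np.isnan(X)
    num = np.nansum(X * y[:, None], axis=0)
    den = obs.T @ (y**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    norm = np.linalg.norm(w)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("degenerate direction")
    return w / norm


def soft_threshold_direction(Z, eta: float) -> np.ndarray:
    """Componentwise soft thresholding (|Z_j| − λ)₊·sign(Z_j), λ = η·max|Z|."""
    Z = np.asarray(Z, dtype=float)
    if not 0 <= eta < 1:
        raise ValueError("eta must be in [0, 1)")
    if eta == 0:
        return Z.copy()
    lam = eta * np.max(np.abs(Z))
    out = np.sign(Z) * np.maximum(np.abs(Z) - lam, 0.0)
    norm = np.linalg.norm(out)
    if norm == 0:
        raise ValueError("degenerate direction")
    return out / norm


def group_threshold_direction(
    Z, groups: GroupStructure, eta: float, within_sparsity: float = 0.0
) -> np.ndarray:
    """Group-lasso shrinkage Z_g ← ((‖Z_g‖−λ)₊/‖Z_g‖)·Z_g with λ = η·max_g‖Z_g‖.

    ``within_sparsity`` > 0 additionally soft-thresholds inside each surviving
    group (sparse-group mode). Result renormalized to unit norm.
    """
    Z = np.asarray(Z, dtype=float)
    if not 0 <= eta < 1:
        raise ValueError("eta must be in [0, 1)")
    if not 0 <= within_sparsity < 1:
        raise ValueError("within_sparsity must be in [0, 1)")
    all_groups = groups.complete(Z.shape[0])
    out = Z.copy()
    if eta > 0:
        norms = np.array([np.linalg.norm(Z[list(g)]) for g in all_groups])
        lam = eta * norms.max()
        for g, ng in zip(all_groups, norms):
            idx = list(g)
            out[idx] = 0.0 if ng <= lam else (ng - lam) / ng * Z[idx]
    if within_sparsity > 0:
        for g in all_groups:
            idx = list(g)
            seg = out[idx]
            if np.any(seg != 0):
                lam_w = within_sparsity * np.max(np.abs(seg))
                out[idx] = np.sign(seg) * np.maximum(np.abs(seg) - lam_w, 0.0)
    norm = np.linalg.norm(out)
    if norm == 0:
        raise ValueError("degenerate direction")
    return out / norm


def _threshold(Z, mode: Mode, eta: float, groups: GroupStructure | None):
    if mode == "plain" or eta == 0:
        return Z / np.linalg.norm(Z)
    if mode == "sparse":
        return soft_threshold_direction(Z, eta)
    if groups is None:
        raise ValueError("group modes require a GroupStructure")
    if mode == "group":
        return group_threshold_direction(Z, groups, eta, 0.0)
    if mode == "sparse-group":
        return group_threshold_direction(Z, groups, eta, eta)
    raise ValueError(f"unknown mode {mode!r}")


def _score_from(X, w):
    """t = Xw with the NIPALS rescaling for missing entries.

    t_i = (Σ_{j obs} w_j x_ij) · (Σ_j w_j²) / (Σ_{j obs} w_j²).
    """
    obs = ~np.isnan(X)
    num = np.nansum(X * w, axis=1)
    wsq = w**2
    den = obs @ wsq
    total = wsq.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num * total / np.where(den > 0, den, 1.0), 0.0)
    return t


def fit_pls(
    X,
    y,
    ncomp: int,
    mode: Mode = "plain",
    eta: float = 0.0,
    groups: GroupStructure | None = None,
) -> PLSFit:
    """Regression-mode PLS1 of a continuous response on X.

    Missing entries in X are tolerated everywhere (pairwise-complete weights,
    coverage-rescaled scores, deflation only of observed cells). A degenerate
    direction before ``ncomp`` components truncates the fit with a flag.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if ncomp > min(n - 1, p):
        raise ValueError("ncomp exceeds min(n-1, p)")
    Xs, center, scale = center_scale(X)
    yc = y - y.mean()
    Xd = Xs.copy()
    W = np.zeros((p, ncomp))
    C = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    truncated = False
    m = 0
    for a in range(ncomp):
        try:
            z = nipals_weight(Xd, yc)
            c = _threshold(z, mode, eta, groups)
        except ValueError:
            truncated = True
            break
        t = _score_from(Xd, c)
        tt = float(t @ t)
        if tt <= 1e-12:
            truncated = True
            break
        obs = ~np.isnan(Xd)
        # loadings: slope of each column on t over observed rows
        pnum = np.nansum(Xd * t[:, None], axis=0)
        pden = obs.T @ (t**2)
        load = np.where(pden > 0, pnum / np.where(pden > 0, pden, 1.0), 0.0)
        W[:, a], C[:, a], T[:, a], P[:, a] = z, c, t, load
        q[a] = float(t @ yc) / tt
        Xd = Xd - np.outer(t, load)  # NaNs propagate: missing stay missing
        m += 1
    return PLSFit(
        ncomp=m,
        weights=W[:, :m],
        directions=C[:, :m],
        scores=T[:, :m],
        x_loadings=P[:, :m],
        y_loadings=q[:m],
        center=center,
        scale=scale,
        mode=mode,
        eta=eta,
        truncated=truncated,
    )


def predict_scores(fit: PLSFit, Xnew) -> np.ndarray:
    """Scores for new rows via stored centering/scaling and deflation chain."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != fit.center.shape[0]:
        raise ValueError("column-count mismatch")
    Xd = apply_center_scale(Xnew, fit.center, fit.scale)
    T = np.zeros((Xd.shape[0], fit.ncomp))
    for a in range(fit.ncomp):
        t = _score_from(Xd, fit.directions[:, a])
        T[:, a] = t
        Xd = Xd - np.outer(t, fit.x_loadings[:, a])
    return T


def median_pairwise_distance(X) -> float:
    """Default gaussian bandwidth: median Euclidean distance between rows."""
    X = np.asarray(X, dtype=float)
    from scipy.spatial.distance import pdist

    d = pdist(X)
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def gram_matrix(X, spec: KernelSpec) -> np.ndarray:
    """Kernel Gram matrix; linear K = XX', gaussian K_ij = exp(−‖xi−xj‖²/2σ²)."""
    X = np.asarray(X, dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("kernel path requires complete data; mean-impute first")
    if spec.kind == "linear":
        return X @ X.T
    sigma = spec.bandwidth or median_pairwise_distance(X)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq / (2.0 * sigma**2))


def cross_gram(Xnew, Xtrain, spec: KernelSpec) -> np.ndarray:
    """Kernel evaluations of new rows against training rows (n_new × n_train)."""
    Xnew = np.asarray(Xnew, dtype=float)
    Xtrain = np.asarray(Xtrain, dtype=float)
    if np.any(np.isnan(Xnew)) or np.any(np.isnan(Xtrain)):
        raise ValueError("kernel path requires complete data; mean-impute first")
    if spec.kind == "linear":
        return Xnew @ Xtrain.T
    sigma = spec.bandwidth or median_pairwise_distance(Xtrain)
    sq = ((Xnew[:, None, :] - Xtrain[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-sq / (2.0 * sigma**2))
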
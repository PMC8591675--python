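"""Balanced fold construction and censored-data cross-validation criteria.

The fold/split builders stratify on the ordered response (time) and the
censoring indicator. Two partial-likelihood criteria are provided — the
naive per-fold CVLL and the van Houwelingen subtraction vHCVLL — plus
criterion-driven hyperparameter selection over (ncomp, eta) grids using
any of the integrated AUC / Brier / Schmid criteria.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .pls_engines import GroupStructure, KernelSpec
from .plsdr_models import (
    PLSDRModel,
    fit_auto_pls_cox,
    fit_pls_cox,
    fit_plsdr,
    predict_risk,
    predict_survival,
)
from .survival_core import SurvivalOutcome, log_partial_likelihood_eta
from .survival_metrics import (
    brier_curve,
    event_time_grid,
    iauc,
    schmid_curve,
)

__all__ = [
    "FoldPlan",
    "CriterionResult",
    "balanced_folds",
    "balanced_split",
    "fit_family",
    "cvll",
    "vhcvll",
    "select_hyperparameters",
    "CRITERION_ORIENTATION",
    "DEFAULT_CRITERION",
    "DEFAULT_ETA_GRID",
]

logger = logging.getLogger(__name__)

# larger-is-better unless listed as "min"
CRITERION_ORIENTATION = {
    "cvll": "max",
    "vhcvll": "max",
    "iAUCCD": "max",
    "iAUCHC": "max",
    "iAUCSH": "max",
    "iAUCUno": "max",
    "iAUCHZ": "max",
    "iAUCsurvROC": "max",
    "iBSw": "min",
    "iBSunw": "min",
    "iSSw": "min",
    "iSSunw": "min",
}

_IAUC_NAME = {
    "iAUCCD": "CD",
    "iAUCHC": "HC",
    "iAUCSH": "SH",
    "iAUCUno": "Uno",
    "iAUCHZ": "HZ",
    "iAUCsurvROC": "survROC",
}

DEFAULT_ETA_GRID = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))


def DEFAULT_CRITERION(family: str) -> str:
    """Recommended CV criterion per model family."""
    return "iAUCSH" if family in ("pls-cox", "auto-pls-cox") else "iAUCsurvROC"


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    folds: tuple[np.ndarray, ...]
    seed: int

    def __post_init__(self):
        n = sum(f.size for f in self.folds)
        union = np.concatenate(self.folds)
        if np.unique(union).size != n:
            raise ValueError("folds must partition the index set")

    @property
    def n(self) -> int:
        return sum(f.size for f in self.folds)


@dataclasses.dataclass
class CriterionResult:
    ncomp: int
    eta: float
    fold_values: list[float]
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        if not self.fold_values:
            return float("nan")
        return float(np.mean(self.fold_values))


def balanced_folds(outcome: SurvivalOutcome, K: int = 7, seed: int = 0) -> FoldPlan:
    """K folds balanced on (time, status): order subjects, bin into groups of
    K neighbours, and draw one subject per bin into each fold."""
    n = outcome.n
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError("K exceeds n")
    rng = np.random.default_rng(seed)
    # status-primary ordering keeps per-fold censor rates balanced; time
    # ordering within status balances the response value
    order = np.lexsort((outcome.time, outcome.status))
    c = n // K
    folds: list[list[int]] = [[] for _ in range(K)]
    for b in range(c):
        bin_idx = order[b * K:(b + 1) * K]
        perm = rng.permutation(K)
        for f, idx in zip(perm, bin_idx):
            folds[f].append(int(idx))
    rest = order[c * K:]
    if rest.size:
        extra = rng.choice(K, size=rest.size, replace=False)
        for f, idx in zip(extra, rest):
            folds[f].append(int(idx))
    return FoldPlan(tuple(np.sort(np.asarray(f, dtype=int)) for f in folds), seed)


def balanced_split(
    outcome: SurvivalOutcome, train_fraction: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split on binned time × status."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = outcome.n
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    strata: list[np.ndarray] = []
    degenerate = False
    for s in (0, 1):
        idx = np.where(outcome.status == s)[0]
        if idx.size == 0:
            continue
        if idx.size < 4:
            degenerate = True
        idx = idx[np.argsort(outcome.time[idx])]
        n_bins = max(1, min(4, idx.size // 2))
        strata.extend(np.array_split(idx, n_bins))
    if degenerate:
        logger.warning("balanced_split: degenerate strata, falling back to simple random split")
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train: list[int] = []
    carry = 0.0
    for st in strata:
        st = rng.permutation(st)
        exact = train_fraction * st.size + carry
        take = int(round(exact))
        take = min(take, st.size)
        carry = exact - take
        train.extend(st[:take])
    train = np.asarray(sorted(train), dtype=int)
    # nudge to the exact target size
    while train.size > n_train:
        drop = rng.integers(train.size)
        train = np.delete(train, drop)
    while train.size < n_train:
        pool = np.setdiff1d(np.arange(n), train)
        train = np.sort(np.append(train, rng.choice(pool)))
    test = np.setdiff1d(np.arange(n), train)
    return train, test


def fit_family(
    family: str,
    X,
    outcome: SurvivalOutcome,
    ncomp: int = 1,
    eta: float = 0.0,
    groups: GroupStructure | None = None,
    kernel: KernelSpec | None = None,
    alpha: float = 0.05,
) -> PLSDRModel:
    """Dispatch a model-family name to its fitter."""
    mode_map = {
        "plsdr": ("plain", None), "splsdr": ("sparse", None),
        "gplsdr": ("group", None), "sgplsdr": ("sparse-group", None),
        "dkplsdr": ("plain", kernel or KernelSpec("linear")),
        "dksplsdr": ("sparse", kernel or KernelSpec("linear")),
        "dkgplsdr": ("group", kernel or KernelSpec("linear")),
        "dksgplsdr": ("sparse-group", kernel or KernelSpec("linear")),
    }
    if family in mode_map:
        mode, kern = mode_map[family]
        return fit_plsdr(X, outcome, ncomp, mode=mode, eta=eta, groups=groups, kernel=kern)
    if family == "pls-cox":
        if ncomp == 0:
            return fit_plsdr(X, outcome, 0)
        return fit_pls_cox(X, outcome, ncomp)
    if family == "auto-pls-cox":
        return fit_auto_pls_cox(X, outcome, alpha=alpha)
    raise ValueError(f"unknown model family {family!r}")


def _fold_fits(family, X, outcome, folds: FoldPlan, ncomp, eta, groups, kernel):
    """Per-fold (model, train_idx, test_idx) triples."""
    X = np.asarray(X, dtype=float)
    n = outcome.n
    out = []
    for test_idx in folds.folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = fit_family(
            family, X[train_idx], outcome.subset(train_idx),
            ncomp=ncomp, eta=eta, groups=groups, kernel=kernel,
        )
        out.append((model, train_idx, test_idx))
    return out


def cvll(
    family: str,
    X,
    outcome: SurvivalOutcome,
    folds: FoldPlan,
    ncomp: int = 1,
    eta: float = 0.0,
    groups: GroupStructure | None = None,
    kernel: KernelSpec | None = None,
) -> CriterionResult:
    """Naive CV partial likelihood: per fold, the held-out subjects' log
    partial likelihood at the linear predictor of the reduced-data fit.
    Folds with no events are excluded (logged)."""
    X = np.asarray(X, dtype=float)
    values: list[float] = []
    excluded = 0
    for model, train_idx, test_idx in _fold_fits(family, X, outcome, folds, ncomp, eta, groups, kernel):
        sub = outcome.subset(test_idx)
        if sub.n_events == 0:
            excluded += 1
            continue
        risk = predict_risk(model, X[test_idx])
        values.append(log_partial_likelihood_eta(risk, sub))
    if excluded:
        logger.warning("cvll: excluded %d folds without events", excluded)
    return CriterionResult(ncomp, eta, values, excluded)


def vhcvll(
    family: str,
    X,
    outcome: SurvivalOutcome,
    folds: FoldPlan,
    ncomp: int = 1,
    eta: float = 0.0,
    groups: GroupStructure | None = None,
    kernel: KernelSpec | None = None,
) -> CriterionResult:
    """van Houwelingen CV partial likelihood by subtraction:
    l_full(β̂₍₋ⱼ₎) − l₍₋ⱼ₎(β̂₍₋ⱼ₎) per fold (larger is better)."""
    X = np.asarray(X, dtype=float)
    values: list[float] = []
    for model, train_idx, test_idx in _fold_fits(family, X, outcome, folds, ncomp, eta, groups, kernel):
        if test_idx.size == 0:
            values.append(0.0)
            continue
        risk_all = predict_risk(model, X)
        l_full = log_partial_likelihood_eta(risk_all, outcome)
        sub = outcome.subset(train_idx)
        l_train = log_partial_likelihood_eta(risk_all[train_idx], sub)
        values.append(l_full - l_train)
    return CriterionResult(ncomp, eta, values)


def _held_out_criterion(model, X_test, sub_test, outcome_train, criterion):
    if criterion in _IAUC_NAME:
        risk = predict_risk(model, X_test)
        return iauc(risk, outcome_train, sub_test, method=_IAUC_NAME[criterion])
    if criterion in ("iBSw", "iBSunw", "iSSw", "iSSunw"):
        grid = event_time_grid(sub_test)
        if grid.size == 0:
            raise ValueError("no events in fold")
        tmax_train = float(outcome_train.time.max())
        S = predict_survival(model, X_test, np.minimum(grid, tmax_train))
        weighted = criterion.endswith("w") and not criterion.endswith("unw")
        fn = brier_curve if criterion.startswith("iBS") else schmid_curve
        return fn(S, sub_test, weighted=weighted, grid=grid).integrated
    raise ValueError(f"unknown criterion {criterion!r}")


def select_hyperparameters(
    family: str,
    X,
    outcome: SurvivalOutcome,
    grid: Sequence[dict],
    criterion: str | None = None,
    folds: FoldPlan | None = None,
    groups: GroupStructure | None = None,
    kernel: KernelSpec | None = None,
    K: int = 7,
    seed: int = 0,
) -> tuple[dict, list[CriterionResult]]:
    """Fit every (ncomp, eta) grid point per fold, score the held-out fold
    with ``criterion``, and return (best point, full results table).

    Ties break toward fewer components, then larger eta. Default criterion
    follows the per-family recommendation.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if criterion is None:
        criterion = DEFAULT_CRITERION(family)
    if criterion not in CRITERION_ORIENTATION:
        raise ValueError(f"unknown criterion {criterion!r}")
    if folds is None:
        folds = balanced_folds(outcome, K=K, seed=seed)
    X = np.asarray(X, dtype=float)
    results: list[CriterionResult] = []
    for point in grid:
        ncomp = int(point.get("ncomp", 1))
        eta = float(point.get("eta", 0.0))
        if criterion == "cvll":
            res = cvll(family, X, outcome, folds, ncomp, eta, groups, kernel)
        elif criterion == "vhcvll":
            res = vhcvll(family, X, outcome, folds, ncomp, eta, groups, kernel)
        else:
            values: list[float] = []
            excluded = 0
            for model, train_idx, test_idx in _fold_fits(
                family, X, outcome, folds, ncomp, eta, groups, kernel
            ):
                sub = outcome.subset(test_idx)
                try:
                    values.append(
                        _held_out_criterion(
                            model, X[test_idx], sub, outcome.subset(train_idx), criterion
                        )
                    )
                except ValueError:
                    excluded += 1
            res = CriterionResult(ncomp, eta, values, excluded)
        results.append(res)
    defined = [r for r in results if np.isfinite(r.mean)]
    if not defined:
        raise ValueError("criterion undefined on every grid point")
    sign = 1.0 if CRITERION_ORIENTATION[criterion] == "max" else -1.0
    best = max(defined, key=lambda r: (sign * r.mean, -r.ncomp, r.eta))
    return {"ncomp": best.ncomp, "eta": best.eta}, results
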
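"""Model-assessment machinery for censored survival predictions.

Distance-based prediction-error curves (IPCW Brier, Schmid,
Schemper–Henderson) with their integrated summaries and R²-type ratios,
likelihood-based R² coefficients, Harrell / Gönen–Heller / Uno concordance,
and six integrated time-dependent cumulative/dynamic AUC estimators.

The AUC estimators share a common pair-weighting core and differ in how
cases and controls are weighted (empirical, IPCW, or model-based) and in
the time-integration weight (event-density 2f̂(t)Ŝ(t) or uniform).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .survival_core import StepFunction, SurvivalOutcome, fit_cox

__all__ = [
    "MetricCurve",
    "km_curve",
    "km_censoring",
    "km_survival",
    "event_time_grid",
    "survival_matrix_from_km",
    "brier_curve",
    "schmid_curve",
    "schemper_henderson_curve",
    "integrate_curve",
    "r2_curve_integrated",
    "r2_likelihood",
    "harrell_c",
    "gonen_heller_c",
    "gonen_heller_c_risk",
    "iauc",
    "IAUC_METHODS",
    "uno_c",
]

logger = logging.getLogger(__name__)

IAUC_METHODS = ("CD", "HC", "SH", "Uno", "HZ", "survROC")


@dataclasses.dataclass
class MetricCurve:
    """Pointwise metric values on an event-time grid plus integration info."""

    grid: np.ndarray
    values: np.ndarray
    tmax: float
    weighted: bool = True
    n_dropped: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size == 0:
            raise ValueError("empty evaluation grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def integrated(self) -> float:
        return integrate_curve(self)


def km_curve(time, event) -> StepFunction:
    """Kaplan–Meier estimator as a right-continuous step function (value 1 at 0)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    n = time.shape[0]
    surv = []
    s = 1.0
    for k, u in enumerate(uniq):
        stop = start[k + 1] if k + 1 < uniq.size else n
        d = e_sorted[start[k]:stop].sum()
        at_risk = n - start[k]
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        surv.append(s)
    return StepFunction(uniq, np.asarray(surv), baseline=1.0)


def km_censoring(outcome: SurvivalOutcome) -> StepFunction:
    """Ĝ: Kaplan–Meier of the censoring distribution, from (t_i, 1 − δ_i)."""
    return km_curve(outcome.time, 1 - outcome.status)


def km_survival(outcome: SurvivalOutcome) -> StepFunction:
    """Kaplan–Meier of the event distribution (the covariate-free prediction)."""
    return km_curve(outcome.time, outcome.status)


def event_time_grid(outcome: SurvivalOutcome) -> np.ndarray:
    """Unique event times in (0, max t_i] — the standard evaluation grid."""
    g = np.unique(outcome.time[outcome.status == 1])
    return g[g > 0]


def survival_matrix_from_km(outcome: SurvivalOutcome, grid) -> np.ndarray:
    """Null-model prediction matrix: each row is the KM curve on the grid."""
    km = km_survival(outcome)
    row = km(np.asarray(grid, dtype=float))
    return np.tile(row, (outcome.n, 1))


def _check_pred(S_pred, outcome, grid):
    S_pred = np.asarray(S_pred, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if S_pred.shape != (outcome.n, grid.size):
        raise ValueError("S_pred must be (n_subjects × n_grid)")
    return S_pred, grid


def _ipcw_curve(outcome, grid, S_pred, power, event_denom_left, atrisk_at_t, weighted):
    """Shared IPCW prediction-error loop for Brier/Schmid/Schemper curves.

    ``power``: 2 for squared deviation, 1 for absolute.
    ``event_denom_left``: use Ĝ(t_i⁻) (True) or Ĝ(t_i) for the event term.
    ``atrisk_at_t``: use Ĝ(t) (True) or Ĝ(t_i) for the at-risk term.
    """
    t, d = outcome.time, outcome.status
    n = outcome.n
    G = km_censoring(outcome)
    g_event = G.left_limit(t) if event_denom_left else G(t)
    g_self = G(t)
    values = np.zeros(grid.size)
    dropped = 0
    for k, s in enumerate(grid):
        died = (t <= s) & (d == 1)
        alive = t > s
        dev = np.abs(alive.astype(float) - S_pred[:, k]) ** power
        term = np.zeros(n)
        if weighted:
            ok_e = died & (g_event > 0)
            ok_a = alive & ((G(s) if atrisk_at_t else g_self) > 0)
            dropped += int((died & ~ok_e).sum() + (alive & ~ok_a).sum())
            term[ok_e] = dev[ok_e] / g_event[ok_e]
            if atrisk_at_t:
                ga = G(s)
                if ga > 0:
                    term[ok_a] = dev[ok_a] / ga
            else:
                term[ok_a] = dev[ok_a] / g_self[ok_a]
        else:
            term[died | alive] = dev[died | alive]
        values[k] = term.sum() / n
    if dropped:
        logger.warning("IPCW curve: dropped %d subject-terms with Ĝ = 0", dropped)
    return values, dropped


def brier_curve(S_pred, outcome: SurvivalOutcome, weighted: bool = True, grid=None) -> MetricCurve:
    """IPCW (or unweighted) Brier prediction-error curve BS(t)."""
    if grid is None:
        grid = event_time_grid(outcome)
    S_pred, grid = _check_pred(S_pred, outcome, grid)
    values, dropped = _ipcw_curve(
        outcome, grid, S_pred, power=2, event_denom_left=False, atrisk_at_t=True, weighted=weighted
    )
    return MetricCurve(grid, values, float(outcome.time.max()), weighted, dropped)


def schmid_curve(S_pred, outcome: SurvivalOutcome, weighted: bool = True, grid=None) -> MetricCurve:
    """Absolute-deviation (Schmid) prediction-error curve SS(t).

    Event term divided by Ĝ(t_i⁻), at-risk term by Ĝ(t_i), as printed in the
    defining formula.
    """
    if grid is None:
        grid = event_time_grid(outcome)
    S_pred, grid = _check_pred(S_pred, outcome, grid)
    values, dropped = _ipcw_curve(
        outcome, grid, S_pred, power=1, event_denom_left=True, atrisk_at_t=False, weighted=weighted
    )
    return MetricCurve(grid, values, float(outcome.time.max()), weighted, dropped)


def schemper_henderson_curve(S_pred, outcome: SurvivalOutcome, weighted: bool = True, grid=None) -> MetricCurve:
    """Schemper–Henderson absolute-deviation curve SH(t) (both terms / Ĝ(t_i))."""
    if grid is None:
        grid = event_time_grid(outcome)
    S_pred, grid = _check_pred(S_pred, outcome, grid)
    t, d = outcome.time, outcome.status
    n = outcome.n
    G = km_censoring(outcome)
    g_self = G(t)
    values = np.zeros(grid.size)
    dropped = 0
    for k, s in enumerate(grid):
        died = (t <= s) & (d == 1)
        alive = t > s
        term = np.zeros(n)
        if weighted:
            ok_e = died & (g_self > 0)
            ok_a = alive & (g_self > 0)
            dropped += int((died & ~ok_e).sum())
            term[ok_e] = S_pred[ok_e, k] / g_self[ok_e]
            term[ok_a] = (1.0 - S_pred[ok_a, k]) / g_self[ok_a]
        else:
            term[died] = S_pred[died, k]
            term[alive] = 1.0 - S_pred[alive, k]
        values[k] = term.sum() / n
    if dropped:
        logger.warning("SH curve: dropped %d subject-terms with Ĝ = 0", dropped)
    return MetricCurve(grid, values, float(outcome.time.max()), weighted, dropped)


def integrate_curve(curve: MetricCurve) -> float:
    """(1/max t_i)·∫₀^{max t_i} of the curve, trapezoid rule.

    The curve is extended constantly from (0, first value) to the first grid
    point and from the last grid point to max t_i.
    """
    xs = np.concatenate(([0.0], curve.grid, [curve.tmax]))
    ys = np.concatenate(([curve.values[0]], curve.values, [curve.values[-1]]))
    keep = np.concatenate(([True], np.diff(xs) > 0))
    xs, ys = xs[keep], ys[keep]
    if curve.tmax <= 0:
        raise ValueError("tmax must be positive")
    return float(np.trapezoid(ys, xs) / curve.tmax)


def r2_curve_integrated(curve: MetricCurve, null_curve: MetricCurve) -> float:
    """Integrated R²-type ratio: ∫(1 − metric(t)/metric₀(t))dt / max t_i.

    Grid points where the null metric is 0 are excluded (logged).
    """
    if curve.grid.shape != null_curve.grid.shape or not np.allclose(curve.grid, null_curve.grid):
        raise ValueError("curves must share the evaluation grid")
    ok = null_curve.values > 0
    if not ok.any():
        raise ValueError("null curve is identically zero")
    n_excl = int((~ok).sum())
    if n_excl:
        logger.warning("r2_curve_integrated: excluded %d grid points with null metric 0", n_excl)
    r = 1.0 - curve.values[ok] / null_curve.values[ok]
    return integrate_curve(MetricCurve(curve.grid[ok], r, curve.tmax, curve.weighted))


def r2_likelihood(l0, lbeta, n=None, e=None, kind="nagelkerke", J0=None, Jbeta=None) -> float:
    """Likelihood- and Schoenfeld-based R² coefficients for Cox-type fits.

    kind 'nagelkerke': 1 − exp(−2(lβ−l0)/n); 'oxs': same with e (events)
    replacing n; 'xo': 1 − Jβ/J0 with J the (weighted) sums of squared
    Schoenfeld residuals.
    """
    if kind == "nagelkerke":
        if not n:
            raise ValueError("n required and nonzero")
        return float(1.0 - np.exp(-2.0 * (lbeta - l0) / n))
    if kind == "oxs":
        if not e:
            raise ValueError("e required and nonzero")
        return float(1.0 - np.exp(-2.0 * (lbeta - l0) / e))
    if kind == "xo":
        if J0 is None or Jbeta is None or J0 == 0:
            raise ValueError("J0/Jbeta required, J0 nonzero")
        return float(1.0 - Jbeta / J0)
    raise ValueError(f"unknown kind {kind!r}")


def harrell_c(risk, outcome: SurvivalOutcome, tie_value: float = 0.0) -> float:
    """Harrell's concordance over usable pairs (shorter time is an event).

    Tied risk scores in usable pairs contribute ``tie_value`` (default 0).
    """
    risk = np.asarray(risk, dtype=float)
    t, d = outcome.time, outcome.status
    if risk.shape != t.shape:
        raise ValueError("risk must align with outcome")
    ti, tj = t[:, None], t[None, :]
    usable = (ti < tj) & (d[:, None] == 1)  # ordered pairs (i earlier event)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs")
    ri, rj = risk[:, None], risk[None, :]
    conc = (usable & (ri > rj)).sum() + tie_value * (usable & (ri == rj)).sum()
    return float(conc / n_usable)


def gonen_heller_c_risk(eta) -> float:
    """Gönen–Heller concordance from the linear-predictor values alone."""
    eta = np.asarray(eta, dtype=float)
    n = eta.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diff = eta[None, :] - eta[:, None]  # diff[i, j] = eta_j − eta_i
    iu = np.triu_indices(n, k=1)
    dji = diff[iu]  # β'(X_j − X_i) over i<j
    with np.errstate(over="ignore"):
        total = np.sum((dji < 0) / (1.0 + np.exp(dji))) + np.sum((-dji < 0) / (1.0 + np.exp(-dji)))
    return float(2.0 * total / (n * (n - 1)))


def gonen_heller_c(beta, X) -> float:
    """Kn(β̂) computed from β̂'X differences only (no event times used)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta if beta.size else np.zeros(X.shape[0])
    return gonen_heller_c_risk(eta)


def _pairwise_auc(risk, case_w, control_w):
    """Weighted probabilistic AUC: Σ w_i v_j (I(r_i>r_j) + ½I(=)) / Σ w_i v_j."""
    ri = risk[:, None]
    rj = risk[None, :]
    conc = (ri > rj) + 0.5 * (ri == rj)
    wmat = np.outer(case_w, control_w)
    den = wmat.sum()
    if den <= 0:
        return np.nan
    return float((wmat * conc).sum() / den)


def _cox_survival_on_risk(risk, outcome):
    """Ŝ(t|risk_i) from a univariate Cox of the outcome on the (standardized)
    risk score; falls back to the KM curve when the score is degenerate."""
    sd = risk.std()
    if sd == 0:
        km = km_survival(outcome)
        return lambda s: km(s) * np.ones(outcome.n)
    z = (risk - risk.mean()) / sd
    fit = fit_cox(z[:, None], outcome)
    b = float(np.clip(fit.beta[0], -50, 50))
    rel = np.exp(np.clip(b * z, -500, 500))
    base = fit.baseline_cumhaz
    return lambda s: np.exp(-base(s) * rel)


def iauc(risk, outcome_train: SurvivalOutcome, outcome_test: SurvivalOutcome, method: str = "survROC") -> float:
    """Integrated cumulative/dynamic AUC on the test outcome's event-time grid.

    Methods (exact formulas delegated to their sources; all coincide with the
    plain empirical cumulative/dynamic AUC when there is no censoring):

    - ``survROC``: empirical cases {t_i≤t, δ=1} vs controls {t_j>t}.
    - ``HC``: IPCW, case weight 1/Ĝ(t_i), control weight 1/Ĝ(t).
    - ``Uno``: IPCW, case weight 1/Ĝ(t_i⁻), controls unweighted.
    - ``CD``: model-based, cases weighted 1−Ŝ(t|i), controls Ŝ(t|j) from a
      univariate Cox of the test outcome on the risk score.
    - ``SH``: model-based sensitivity (1−Ŝ(t|i)) with empirical controls.
    - ``HZ``: incident/dynamic — events at t vs subjects still at risk.

    Integration weight is the event density 2f̂(t)Ŝ(t) for CD/HZ/survROC and
    uniform for Uno/SH/HC. Ĝ is the censoring KM of the test outcome.
    """
    if method not in IAUC_METHODS:
        raise ValueError(f"unknown iAUC method {method!r}")
    risk = np.asarray(risk, dtype=float)
    t, d = outcome_test.time, outcome_test.status
    if risk.shape != t.shape:
        raise ValueError("risk must align with test outcome")
    grid_all = event_time_grid(outcome_test)
    if grid_all.size < 2:
        raise ValueError("need at least 2 event times in the test data")
    G = km_censoring(outcome_test)
    km = km_survival(outcome_test)
    s_of_t = None
    if method in ("CD", "SH"):
        s_of_t = _cox_survival_on_risk(risk, outcome_test)

    aucs, times = [], []
    for s in grid_all:
        alive = t > s
        if method == "HZ":
            cases = (t == s) & (d == 1)
            controls = alive
            if not cases.any() or not controls.any():
                continue
            a = _pairwise_auc(risk, cases.astype(float), controls.astype(float))
        elif method in ("survROC", "HC", "Uno"):
            cases = (t <= s) & (d == 1)
            controls = alive
            if not cases.any() or not controls.any():
                continue
            if method == "survROC":
                cw = cases.astype(float)
            elif method == "HC":
                g = G(t)
                cw = np.where(cases & (g > 0), 1.0 / np.where(g > 0, g, 1.0), 0.0)
            else:  # Uno
                g = G.left_limit(t)
                cw = np.where(cases & (g > 0), 1.0 / np.where(g > 0, g, 1.0), 0.0)
            a = _pairwise_auc(risk, cw, controls.astype(float))
        else:  # CD / SH: model-based
            S = s_of_t(s)
            cw = 1.0 - S
            vw = S if method == "CD" else alive.astype(float)
            a = _pairwise_auc(risk, cw, vw)
        if np.isnan(a):
            continue
        aucs.append(a)
        times.append(s)
    if not aucs:
        raise ValueError("no evaluable time points")
    aucs = np.asarray(aucs)
    times = np.asarray(times)
    if method in ("CD", "HZ", "survROC"):
        s_right = km(times)
        s_left = km.left_limit(times)
        w = 2.0 * (s_left - s_right) * s_right  # ∝ f̂(t)·Ŝ(t) mass at jumps
        if w.sum() <= 0:
            w = np.ones_like(aucs)
        value = float((w * aucs).sum() / w.sum())
    else:
        value = float(aucs.mean())
    return float(np.clip(value, 0.0, 1.0))


def uno_c(risk, outcome: SurvivalOutcome, tau: float | None = None, tie_value: float = 0.0) -> float:
    """IPCW concordance (censoring-robust C) truncated at ``tau``.

    Usable ordered pairs (i, j): t_i < t_j, t_i < tau, δ_i = 1, weighted
    1/Ĝ(t_i⁻)². With no censoring this reduces to Harrell's C restricted to
    pairs whose earlier time is below tau.
    """
    risk = np.asarray(risk, dtype=float)
    t, d = outcome.time, outcome.status
    if tau is None:
        tau = float(t.max())
    if tau > t.max():
        raise ValueError("tau exceeds max observed time")
    G = km_censoring(outcome)
    g = G.left_limit(t)
    if np.any((t < tau) & (d == 1) & (g <= 0)):
        raise ValueError("censoring survival reaches 0 before tau")
    w_i = np.where((d == 1) & (t < tau) & (g > 0), 1.0 / np.where(g > 0, g, 1.0) ** 2, 0.0)
    ti, tj = t[:, None], t[None, :]
    usable = (ti < tj) & (w_i[:, None] > 0)
    den = (usable * w_i[:, None]).sum()
    if den == 0:
        raise ValueError("no usable pairs")
    ri, rj = risk[:, None], risk[None, :]
    conc = (ri > rj) + tie_value * (ri == rj)
    return float((usable * w_i[:, None] * conc).sum() / den)
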
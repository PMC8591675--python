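"""Reduced-scale replication machinery for the simulation study.

For each simulated dataset: balanced 7:3 split, per family × criterion
hyperparameter selection by balanced K-fold CV on the training set, refit,
evaluation of the performance-measure panel on the test set, and emission
of selected-hyperparameter, performance, and paired-delta tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time as _time

import numpy as np
import pandas as pd

from .cross_validation import (
    CRITERION_ORIENTATION,
    balanced_folds,
    balanced_split,
    fit_family,
    select_hyperparameters,
)
from .plsdr_models import PLSDRModel, predict_risk, predict_survival
from .simulators import simulate_study
from .survival_core import SurvivalOutcome, schoenfeld_ssq
from .survival_metrics import (
    brier_curve,
    event_time_grid,
    gonen_heller_c_risk,
    harrell_c,
    iauc,
    r2_curve_integrated,
    r2_likelihood,
    schmid_curve,
    survival_matrix_from_km,
    uno_c,
)

__all__ = [
    "BenchmarkConfig",
    "run_benchmark",
    "evaluate_model",
    "read_dataset",
    "report",
    "PERFORMANCE_MEASURES",
]

logger = logging.getLogger(__name__)

# default panel mirrors the six reported indices
PERFORMANCE_MEASURES = ("R2XO", "iRSSw", "GHCI", "iAUCCD", "iAUCsurvROC", "iSSw")

_ALL_MEASURES = PERFORMANCE_MEASURES + (
    "C", "UnoC", "R2Nag", "R2OXS", "iR2BSw", "iBSw", "iSSunw", "iBSunw",
)


@dataclasses.dataclass
class BenchmarkConfig:
    schemes: tuple[str, ...] = ("factorial",)
    links: tuple[str, ...] = ("linear",)
    n_datasets: int = 10
    n: int = 100
    p: int = 1000
    K: int = 7
    families: tuple[str, ...] = ("plsdr",)
    criteria: tuple[str, ...] = ("vhcvll", "iAUCsurvROC")
    measures: tuple[str, ...] = PERFORMANCE_MEASURES
    ncomp_max: int = 5
    eta_grid: tuple[float, ...] = (0.0,)
    train_fraction: float = 0.7
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        for c in self.criteria:
            if c not in CRITERION_ORIENTATION:
                raise ValueError(f"unknown criterion {c!r}")
        for m in self.measures:
            if m not in _ALL_MEASURES:
                raise ValueError(f"unknown measure {m!r}")

    @classmethod
    def from_json(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.items()
        }
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_model(
    model: PLSDRModel,
    X_test,
    outcome_test: SurvivalOutcome,
    outcome_train: SurvivalOutcome,
    measures=PERFORMANCE_MEASURES,
) -> dict[str, float]:
    """Compute the requested performance panel on a held-out test set."""
    from .survival_core import fit_cox, log_partial_likelihood_eta

    risk = predict_risk(model, X_test)
    grid = event_time_grid(outcome_test)
    tmax_train = float(outcome_train.time.max())
    S_pred = predict_survival(model, X_test, np.minimum(grid, tmax_train))
    S_null = survival_matrix_from_km(outcome_test, grid)
    out: dict[str, float] = {}
    n, e = outcome_test.n, outcome_test.n_events
    l0 = log_partial_likelihood_eta(np.zeros(n), outcome_test)
    # test-set refit of the risk score for likelihood-type measures
    if risk.std() > 0:
        refit = fit_cox(((risk - risk.mean()) / risk.std())[:, None], outcome_test)
        lbeta = refit.log_pl
        Jb = schoenfeld_ssq(refit.beta, ((risk - risk.mean()) / risk.std())[:, None], outcome_test)
        J0 = schoenfeld_ssq(np.zeros(1), ((risk - risk.mean()) / risk.std())[:, None], outcome_test)
    else:
        lbeta, Jb, J0 = l0, 1.0, 1.0
    for m in measures:
        try:
            if m == "R2XO":
                out[m] = r2_likelihood(l0, lbeta, kind="xo", J0=J0, Jbeta=Jb)
            elif m == "R2Nag":
                out[m] = r2_likelihood(l0, lbeta, n=n, kind="nagelkerke")
            elif m == "R2OXS":
                out[m] = r2_likelihood(l0, lbeta, e=e, kind="oxs")
            elif m == "GHCI":
                out[m] = gonen_heller_c_risk(risk)
            elif m == "C":
                out[m] = harrell_c(risk, outcome_test)
            elif m == "UnoC":
                out[m] = uno_c(risk, outcome_test)
            elif m.startswith("iAUC"):
                name = m.removeprefix("iAUC")
                out[m] = iauc(risk, outcome_train, outcome_test, method=name)
            elif m in ("iBSw", "iBSunw"):
                out[m] = brier_curve(S_pred, outcome_test, weighted=m == "iBSw", grid=grid).integrated
            elif m in ("iSSw", "iSSunw"):
                out[m] = schmid_curve(S_pred, outcome_test, weighted=m == "iSSw", grid=grid).integrated
            elif m == "iRSSw":
                out[m] = r2_curve_integrated(
                    schmid_curve(S_pred, outcome_test, grid=grid),
                    schmid_curve(S_null, outcome_test, grid=grid),
                )
            elif m == "iR2BSw":
                out[m] = r2_curve_integrated(
                    brier_curve(S_pred, outcome_test, grid=grid),
                    brier_curve(S_null, outcome_test, grid=grid),
                )
            else:
                raise ValueError(f"unknown measure {m!r}")
        except ValueError as exc:
            logger.warning("measure %s failed: %s", m, exc)
            out[m] = float("nan")
    return out


def run_benchmark(config: BenchmarkConfig) -> dict[str, pd.DataFrame]:
    """Run the study; returns 'selected', 'performance', and delta tables."""
    sel_rows, perf_rows = [], []
    for si, scheme in enumerate(config.schemes):
        for li, link in enumerate(config.links):
            datasets = simulate_study(
                scheme, link, config.n_datasets, n=config.n, p=config.p,
                seed=config.seed * 9973 + 101 * si + li,
            )
            for i_ds, ds in enumerate(datasets):
                split_seed = config.seed * 10007 + i_ds
                train_idx, test_idx = balanced_split(ds.outcome, config.train_fraction, seed=split_seed)
                X_tr, X_te = ds.X[train_idx], ds.X[test_idx]
                o_tr, o_te = ds.outcome.subset(train_idx), ds.outcome.subset(test_idx)
                folds = balanced_folds(o_tr, K=config.K, seed=split_seed)
                for family in config.families:
                    sparse = family in ("splsdr", "sgplsdr", "dksplsdr", "dksgplsdr")
                    grid = [
                        {"ncomp": a, "eta": eta}
                        for a in range(0, config.ncomp_max + 1)
                        for eta in (config.eta_grid if sparse else (0.0,))
                    ]
                    for criterion in config.criteria:
                        try:
                            best, _ = select_hyperparameters(
                                family, X_tr, o_tr, grid, criterion=criterion, folds=folds
                            )
                            model = fit_family(
                                family, X_tr, o_tr, ncomp=best["ncomp"], eta=best["eta"]
                            )
                            panel = evaluate_model(model, X_te, o_te, o_tr, config.measures)
                        except ValueError as exc:
                            logger.warning(
                                "dataset %s/%s/%d family=%s criterion=%s failed: %s",
                                scheme, link, i_ds, family, criterion, exc,
                            )
                            best = {"ncomp": np.nan, "eta": np.nan}
                            panel = {m: float("nan") for m in config.measures}
                        base = {
                            "scheme": scheme, "link": link, "dataset": i_ds,
                            "family": family, "criterion": criterion,
                        }
                        sel_rows.append({**base, "ncomp": best["ncomp"], "eta": best["eta"]})
                        for m, v in panel.items():
                            perf_rows.append({**base, "measure": m, "value": v})
                logger.info("done %s/%s dataset %d", scheme, link, i_ds)
    selected = pd.DataFrame(sel_rows)
    performance = pd.DataFrame(perf_rows)
    tables = {"selected": selected, "performance": performance}
    for ref in ("cvll", "vhcvll"):
        if ref in config.criteria and len(config.criteria) > 1:
            tables[f"delta_vs_{ref}"] = _delta_table(performance, ref)
    return tables


def _delta_table(performance: pd.DataFrame, reference: str) -> pd.DataFrame:
    keys = ["scheme", "link", "dataset", "family", "measure"]
    ref = performance[performance["criterion"] == reference].set_index(keys)["value"]
    others = performance[performance["criterion"] != reference].copy()
    others["delta"] = others["value"].to_numpy() - ref.reindex(
        pd.MultiIndex.from_frame(others[keys])
    ).to_numpy()
    return others[keys + ["criterion", "delta"]]


def read_dataset(expression_path, outcome_path, groups_path=None):
    """Load delimited-text expression + outcome (+ optional group) files."""
    from .pls_engines import GroupStructure
    from .simulators import _read_delimited, read_outcome_table

    df = _read_delimited(expression_path)
    non_numeric = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna() | c.isna()).all()]
    if len(non_numeric):
        raise ValueError(f"non-numeric expression values in column {non_numeric[0]!r}")
    X = df.to_numpy(dtype=float)
    outcome = read_outcome_table(outcome_path)
    if X.shape[0] != outcome.n:
        raise ValueError("expression and outcome row counts differ")
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep=None, engine="python", header=None,
                          names=["predictor", "group"])
        name_to_idx = {c: j for j, c in enumerate(df.columns)}
        labels: dict = {}
        for _, row in gdf.iterrows():
            if row["predictor"] not in name_to_idx:
                raise ValueError(f"unknown predictor {row['predictor']!r} in group file")
            labels.setdefault(row["group"], []).append(name_to_idx[row["predictor"]])
        groups = GroupStructure(tuple(tuple(v) for v in labels.values()))
    return X, outcome, groups


def report(tables: dict[str, pd.DataFrame], config: BenchmarkConfig, out_dir) -> dict[str, str]:
    """Write delimited tables plus a manifest echoing the configuration."""
    import survpls

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"survpls": survpls.__version__, "numpy": np.__version__, "pandas": pd.__version__},
        "wall_time": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = str(mpath)
    return paths
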
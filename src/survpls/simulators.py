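"""Gene-expression survival simulators used as the fixture factory.

Three expression generators (eigengene modules, two-cluster means,
block-compound-symmetry factorial), exponential survival/censoring
attachment calibrated to a target censoring fraction, MCAR masking,
and delimited-text IO.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Literal

import numpy as np

from .survival_core import SurvivalOutcome

__all__ = [
    "SimulatedDataset",
    "simulate_eigengene",
    "simulate_cluster",
    "simulate_factorial",
    "attach_survival",
    "inject_mcar",
    "simulate_study",
    "write_dataset",
    "read_outcome_table",
]

Scheme = Literal["eigengene", "cluster", "factorial"]
Link = Literal["none", "linear", "quadratic"]

N_TRUTH = 50  # first 50 genes carry the survival link


@dataclasses.dataclass
class SimulatedDataset:
    X: np.ndarray
    outcome: SurvivalOutcome
    truth: np.ndarray  # indices of survival-linked predictors (empty if none)
    scheme: str
    link: str
    seed: int


def simulate_eigengene(
    n: int = 100,
    p: int = 1000,
    n_modules: int = 4,
    module_size: int = 25,
    r_min: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Module genes as noisy copies of a seed vector with prescribed
    rank-dependent correlations r_k = 1 − (k/n_I)(1 − r_min)."""
    if not 0 < r_min < 1:
        raise ValueError("r_min must be in (0, 1)")
    if n_modules * module_size > p:
        raise ValueError("modules exceed p")
    rng = np.random.default_rng(seed)
    X = np.empty((n, p))
    col = 0
    for _ in range(n_modules):
        seed_vec = rng.standard_normal(n)
        v_seed = seed_vec.var(ddof=1)
        for k in range(1, module_size + 1):
            r = 1.0 - (k / module_size) * (1.0 - r_min)
            eps = rng.standard_normal(n)
            a = np.sqrt(v_seed / eps.var(ddof=1)) * np.sqrt(1.0 / r**2 - 1.0)
            X[:, col] = seed_vec + a * eps
            col += 1
    X[:, col:] = rng.standard_normal((n, p - col))
    return X


def simulate_cluster(n: int = 100, p: int = 1000, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Two-cluster mean-shift scheme: first 50 genes split samples 3 vs 4,
    remaining genes centered at 3.5; unit-variance gaussian noise."""
    if p <= 50:
        raise ValueError("p must exceed 50")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    half = n // 2
    X[:half, :50] += 3.0
    X[half:, :50] += 4.0
    X[:, 50:] += 3.5
    return X


def factorial_correlation(n_groups: int = 4, group_size: int = 25, rho: float = 0.7) -> np.ndarray:
    """Block compound-symmetry population correlation of the structured genes."""
    k = n_groups * group_size
    R = np.zeros((k, k))
    for g in range(n_groups):
        sl = slice(g * group_size, (g + 1) * group_size)
        R[sl, sl] = rho
    np.fill_diagonal(R, 1.0)
    return R


def simulate_factorial(
    n: int = 100,
    p: int = 1000,
    n_groups: int = 4,
    group_size: int = 25,
    rho: float = 0.7,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Structured genes Z = F·X with F the eigendecomposition square root of
    the block compound-symmetry correlation; remaining genes iid noise."""
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    k = n_groups * group_size
    if k > p:
        raise ValueError("groups exceed p")
    rng = np.random.default_rng(seed)
    R = factorial_correlation(n_groups, group_size, rho)
    evals, evecs = np.linalg.eigh(R)
    F = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
    X = np.empty((n, p))
    X[:, :k] = rng.standard_normal((n, k)) @ F.T
    X[:, k:] = rng.standard_normal((n, p - k))
    return X


def _linear_predictor(X, link: Link, beta_scale: float) -> np.ndarray:
    if link == "none":
        return np.zeros(X.shape[0])
    if X.shape[1] < N_TRUTH:
        raise ValueError(f"link requires at least {N_TRUTH} predictors")
    beta = np.full(N_TRUTH, beta_scale / np.sqrt(N_TRUTH))
    Xt = X[:, :N_TRUTH]
    eta = Xt @ beta
    if link == "quadratic":
        eta = eta + (Xt**2 - 1.0) @ (beta / 2.0)
    elif link != "linear":
        raise ValueError(f"unknown link {link!r}")
    return eta


def _calibrate_censor_rate(eta, censor_target: float, lam_t: float) -> float:
    """λ_C solving mean_i[λ_C/(λ_C + λ_T e^{η_i})] = target (bisection).

    Exact conditional censoring probability for independent exponentials,
    evaluated on the realized linear predictor.
    """
    rates = lam_t * np.exp(eta - eta.mean())

    def frac(lam_c):
        return float(np.mean(lam_c / (lam_c + rates)))

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < censor_target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    else:
        raise RuntimeError("censoring calibration failed")
    return float(np.sqrt(lo * hi))


def attach_survival(
    X,
    link: Link = "none",
    beta_scale: float = 1.0,
    censor_target: float = 0.4,
    lam_t: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> SurvivalOutcome:
    """Exponential event and censoring times with calibrated censor fraction.

    T_i ~ Exp(λ_T·e^{η_i}); C_i ~ Exp(λ_C) with λ_C = λ_T·q/(1−q) under the
    null link (closed form) and bisection-calibrated on the realized η under
    linear/quadratic links. Observed time = min(T, C), status = I(T ≤ C).
    """
    if not 0 < censor_target < 1:
        raise ValueError("censor_target must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    eta = _linear_predictor(X, link, beta_scale)
    if link == "none" or np.allclose(eta, eta.mean()):
        lam_c = lam_t * censor_target / (1.0 - censor_target)
        rates = np.full(X.shape[0], lam_t)
    else:
        eta = eta - eta.mean()
        lam_c = _calibrate_censor_rate(eta, censor_target, lam_t)
        rates = lam_t * np.exp(eta)
    T = rng.exponential(1.0 / rates)
    C = rng.exponential(1.0 / lam_c, size=X.shape[0])
    time = np.minimum(T, C)
    status = (T <= C).astype(int)
    return SurvivalOutcome(time, status)


def inject_mcar(X, rate: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Mask each entry independently with probability ``rate`` (NaN)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    X = np.asarray(X, dtype=float)
    if rate == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    for _ in range(10):
        mask = rng.random(X.shape) < rate
        if not np.any(mask.all(axis=0)):
            out = X.copy()
            out[mask] = np.nan
            return out
    raise RuntimeError("could not avoid a fully-masked column after 10 redraws")


def simulate_study(
    scheme: Scheme,
    link: Link = "none",
    n_datasets: int = 100,
    n: int = 100,
    p: int = 1000,
    censor_target: float = 0.4,
    beta_scale: float = 1.0,
    seed: int = 0,
) -> list[SimulatedDataset]:
    """Compose a scheme generator with survival attachment, one RNG stream
    per dataset (deterministic in (scheme, link, seed, index))."""
    gens = {
        "eigengene": simulate_eigengene,
        "cluster": simulate_cluster,
        "factorial": simulate_factorial,
    }
    if scheme not in gens:
        raise ValueError(f"unknown scheme {scheme!r}")
    out = []
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        X = gens[scheme](n=n, p=p, seed=rng)
        outcome = attach_survival(
            X, link=link, beta_scale=beta_scale, censor_target=censor_target, seed=rng
        )
        truth = np.arange(N_TRUTH) if link != "none" else np.arange(0)
        out.append(SimulatedDataset(X, outcome, truth, scheme, link, i))
    return out


def write_dataset(ds: SimulatedDataset, directory) -> dict[str, str]:
    """Write expression/outcome/truth tables plus a manifest (delimited text)."""
    import pandas as pd

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    genes = [f"g{j + 1}" for j in range(ds.X.shape[1])]
    paths = {
        "expression": str(directory / "expression.tsv"),
        "outcome": str(directory / "outcome.tsv"),
        "truth": str(directory / "truth.txt"),
        "manifest": str(directory / "manifest.json"),
    }
    pd.DataFrame(ds.X, columns=genes).to_csv(
        paths["expression"], sep="\t", index=False, na_rep="", float_format="%.17g"
    )
    pd.DataFrame({"time": ds.outcome.time, "status": ds.outcome.status}).to_csv(
        paths["outcome"], sep="\t", index=False, float_format="%.17g"
    )
    np.savetxt(paths["truth"], ds.truth + 1, fmt="%d")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"scheme": ds.scheme, "link": ds.link, "seed": ds.seed,
             "n": int(ds.X.shape[0]), "p": int(ds.X.shape[1])},
            fh, indent=2,
        )
    return paths


def _read_delimited(path):
    import csv

    import pandas as pd

    with open(path) as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        sep = "\t"
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_outcome_table(path) -> SurvivalOutcome:
    df = _read_delimited(path)
    if not {"time", "status"} <= set(df.columns):
        raise ValueError("outcome table needs 'time' and 'status' columns")
    time = df["time"].to_numpy(dtype=float)
    status = df["status"].to_numpy(dtype=float)
    if np.any(time <= 0):
        raise ValueError("time must be > 0")
    if not np.all(np.isin(status, (0.0, 1.0))):
        raise ValueError("status must be 0 or 1")
    return SurvivalOutcome(time, status)
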
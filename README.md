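# survpls

Partial least squares extensions of the Cox proportional-hazards model built
on deviance residuals — PLSDR and its sparse / group / sparse-group / kernel
variants, plus the iterative PLS-Cox and autoPLS-Cox constructions — together
with censored-data cross-validation criteria (CVLL, vHCVLL, six integrated
time-dependent AUCs, IPCW Brier/Schmid prediction-error criteria), a panel of
survival performance measures (likelihood R²s, iR2BSw, iRSSw, Harrell /
Gönen–Heller / Uno concordance), and three gene-expression survival
simulators for running the method-comparison study at desk scale.

## Layout

| module | contents |
| --- | --- |
| `survpls.survival_core` | Cox fitting (Newton–Raphson, Breslow/Efron ties), Breslow baseline, martingale/deviance residuals |
| `survpls.pls_engines` | NIPALS PLS1 with pairwise-complete missing-data handling, soft/group thresholding, kernel Gram matrices |
| `survpls.plsdr_models` | PLSDR family fitters, PLS-Cox / autoPLS-Cox, risk and survival-curve prediction, JSON serialization |
| `survpls.survival_metrics` | IPCW Brier/Schmid/Schemper curves, integrated R² ratios, concordance indices, six iAUC estimators |
| `survpls.cross_validation` | balanced folds/splits, CVLL, vHCVLL, criterion-driven hyperparameter selection |
| `survpls.simulators` | eigengene / cluster / factorial generators, calibrated exponential censoring, MCAR masking |
| `survpls.benchmark` + `survpls.cli` | benchmark configuration, study runner, delta tables, command-line interface |

## CLI

```sh
# generate a simulated dataset as delimited text
survpls simulate --scheme factorial --link linear --n 100 --p 1000 --seed 1 --out data/

# fit one model family
survpls fit --expression data/dataset_000/expression.tsv \
            --outcome data/dataset_000/outcome.tsv \
            --family splsdr --ncomp 2 --eta 0.5 --out model.json

# hyperparameter selection by balanced 7-fold CV
survpls crossval --expression ... --outcome ... --family plsdr \
                 --criterion iAUCsurvROC --ncomp-max 5

# reduced-scale benchmark study + delta report
survpls benchmark --config config.json --out results/
survpls report --performance results/performance.tsv --reference vhcvll --out delta.tsv
```

A benchmark config is a JSON mapping of `BenchmarkConfig` fields, e.g.
`{"schemes": ["factorial"], "links": ["linear"], "n_datasets": 10,
"families": ["plsdr"], "criteria": ["vhcvll", "iAUCsurvROC"]}`.

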
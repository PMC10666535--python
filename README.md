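# aquameta

A tested, reusable pipeline for benchmarking meta-learning QSAR regression
on species-level aquatic toxicity (log10 LC50) — ten single-task /
multi-task / meta-learning algorithm families, ECOTOX-style preprocessing,
chemicals-disjoint evaluation, Friedman/Nemenyi algorithm comparison, and
two learning-curve experiment designs. A bundled synthetic-data generator
emulates the sparse species × chemical × duration structure of real assay
collections (nested phylum → class → species taxonomy, long-tailed assay
counts, replicate measurements, bounded endpoints) with known ground truth,
so every stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `aquameta.synth` | `SynthConfig`, taxonomy/chemical/assay generators, ground-truth sidecar |
| `aquameta.preprocess` | unit standardization, bound filtering, subspecies merge, geometric-mean replicate aggregation, duration normalization, `TableBuilder`/`ModelTable` feature assembly |
| `aquameta.learners` | registry of the ten families: `st_mean`, `st_rf`, `mt_mean`, `mt_rf`, `mt_stack`, `nn_one_output`, `multitarget_nn`, `finetune_top`, `maml`, `tml`, `tml_stacked` — one uniform fit/predict contract |
| `aquameta.evaluation` | chemical-level splits, repeated internal CV (5 subfolds × 3 repetitions → 15 estimates), RMSE + equal-weight group aggregation, Friedman χ² / Iman–Davenport / Nemenyi CD, leakage auditor |
| `aquameta.experiments` | assays-per-species learning curves (nested anchor schedule, optional auxiliary pool), auxiliary-species-count curves, percentile-bootstrap bands, `run_experiment` orchestrator + manifest |

Neural families run on a small numpy MLP with manual backprop (no
deep-learning framework required); forests/boosting/SVR come from
scikit-learn.

## CLI

```bash
aquameta generate   --config config.yaml --out data/ --seed 0
aquameta preprocess --assays data/assays.csv --out cleaned.csv
aquameta evaluate   --config config.yaml --out results/
aquameta curve-assays  --config config.yaml --out results/
aquameta curve-species --config config.yaml --out results/
aquameta report     --results results/
```

Minimal config:

```yaml
seed: 0
synth: {n_species: 35, n_chemicals: 200, n_assays: 3000}
split: {test_fraction: 0.2}
learners:
  - {family: mt_rf, hyperparameters: {n_estimators: 200}}
  - {family: st_rf, hyperparameters: {n_estimators: 200}}
internal_cv: {k: 5, repetitions: 3}
assay_curve: {anchors: [5, 8, 11, 16], n_orderings: 3, min_train_assays: 64}
```

Every run writes tidy CSV results plus `manifest.json` (config hash, every
seed consumed, library versions, leakage-audit counters). All fits are
routed through an auditor that raises if any held-out chemical reaches a
fit, imputation statistic, or feature-selection step.

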
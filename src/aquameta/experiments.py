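"""Learning-curve protocols and experiment orchestration.

Two designs are implemented:

* assay curves — fix a set of well-populated *study species*, downsample
  each to a nested schedule of per-species training-set sizes (anchors), and
  trace test RMSE as the anchor grows, with or without the remaining
  species' assays as an *auxiliary* training pool;
* species curves — fix study species by test coverage, then grow the number
  of auxiliary species (each capped to a fixed assay count) added to each
  study species' training set.

Test assays are fixed once per experiment; every fit is routed through an
optional :class:`~aquameta.evaluation.LeakageAuditor`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (LeakageAuditor, SplitPlan, aggregate, internal_cv_plan,
                         evaluate_external, run_internal_validation,
                         split_by_chemicals)
from .learners import FAMILIES, LearnerSpec, make_learner
from .preprocess import (COL_CHEMICAL, COL_SPECIES, MODE_MULTI, MODE_SINGLE,
                         TableBuilder, clean_assays)
from .synth import SynthConfig, generate_dataset

__all__ = [
    "AnchorSchedule", "DEFAULT_ANCHORS", "DEFAULT_AUX_COUNTS",
    "R2Setup", "select_study_species_r2", "assay_orderings", "build_assay_curve",
    "R3Setup", "select_species_curve_setup_r3", "build_species_curve",
    "CurveResult", "bootstrap_bands", "summarize_curve", "run_experiment",
]

#: sqrt(2)-spaced anchor fill between the printed 5 and 128 endpoints
DEFAULT_ANCHORS: tuple[int, ...] = (5, 8, 11, 16, 22, 32, 45, 64, 90, 128)

#: auxiliary-species counts for the species curve (a 1..12 grid is also valid)
DEFAULT_AUX_COUNTS: tuple[int, ...] = (0, 2, 4, 8, 16, 32, 64)


@dataclasses.dataclass(frozen=True)
class AnchorSchedule:
    anchors: tuple[int, ...] = DEFAULT_ANCHORS
    n_orderings: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.anchors, self.anchors[1:])):
            raise ValueError("anchors must be strictly increasing")
        if len(self.anchors) == 0 or self.anchors[0] < 1:
            raise ValueError("anchors must be positive")
        if self.n_orderings < 1:
            raise ValueError("need at least one ordering")


@dataclasses.dataclass
class CurveResult:
    """Long-format curve output.

    ``points``: one row per (x, ordering/seed, learner, aggregation) with the
    overall (group-mean) RMSE; ``group_errors``: the underlying per-group
    RMSEs feeding the bootstrap bands.
    """

    points: pd.DataFrame
    group_errors: pd.DataFrame
    x_column: str


# ---------------------------------------------------------------------------
# R2: assays-per-species curves
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class R2Setup:
    split: SplitPlan
    study_species: tuple[str, ...]
    train_study: pd.DataFrame    # training rows of study species
    test: pd.DataFrame           # test rows of study species (fixed test set)
    auxiliary: pd.DataFrame      # training rows of all remaining species


def select_study_species_r2(records: pd.DataFrame, test_fraction: float = 0.1,
                            min_train_assays: int = 128, seed: int = 0) -> R2Setup:
    """Chemical-level split, then study species = those with enough training
    assays; other species' training rows become the auxiliary pool and their
    test rows are discarded."""
    split = split_by_chemicals(records[COL_CHEMICAL].unique(), test_fraction, seed)
    train = records[records[COL_CHEMICAL].isin(split.train_chemicals)]
    test = records[records[COL_CHEMICAL].isin(split.test_chemicals)]
    counts = train.groupby(COL_SPECIES).size()
    study = tuple(sorted(counts.index[counts >= min_train_assays]))
    if not study:
        raise ValueError(
            f"no species reaches min_train_assays={min_train_assays}; "
            f"max available is {int(counts.max()) if len(counts) else 0}")
    is_study = train[COL_SPECIES].isin(study)
    return R2Setup(
        split=split,
        study_species=study,
        train_study=train[is_study].reset_index(drop=True),
        test=test[test[COL_SPECIES].isin(study)].reset_index(drop=True),
        auxiliary=train[~is_study].reset_index(drop=True),
    )


def assay_orderings(setup: R2Setup, n_orderings: int, seed: int) -> list[dict[str, np.ndarray]]:
    """Per-ordering, per-species permutations of training row positions.

    The anchor-``a`` sample of a species is the first ``a`` entries of its
    permutation, which makes samples nested across anchors by construction.
    """
    orderings = []
    for o in range(n_orderings):
        rng = np.random.default_rng(seed + 7919 * o)
        perms = {}
        for s in setup.study_species:
            idx = np.flatnonzero((setup.train_study[COL_SPECIES] == s).to_numpy())
            perms[s] = rng.permutation(idx)
        orderings.append(perms)
    return orderings


def _table_for(spec_cls, train_df, test_df, chemicals, taxonomy, cache, auditor):
    mode = spec_cls.table_mode
    key = (mode, id(train_df))
    if key not in cache:
        if auditor is not None:
            auditor.check(train_df[COL_CHEMICAL], context=f"{mode} table fit")
        builder = TableBuilder(mode=mode).fit(train_df, chemicals, taxonomy)
        cache[key] = (builder.transform(train_df), builder.transform(test_df))
    return cache[key]


def _score(learner, spec, test_table, auditor, train_table):
    if auditor is not None:
        auditor.check(train_table.chemical, context=f"{spec.family} fit")
    learner.fit(train_table)
    pred, mask = learner.predict_where_possible(test_table)
    return pd.DataFrame({
        "learner": spec.family,
        "species": test_table.species[mask],
        "chemical": test_table.chemical[mask],
        "y_true": test_table.y[mask],
        "y_pred": pred[mask],
    })


def _curve_rows(predictions: pd.DataFrame, meta: dict) -> tuple[list[dict], list[dict]]:
    points, groups = [], []
    for by in ("species", "chemical"):
        agg = aggregate(predictions, by=by)
        points.append({**meta, "aggregation": by, "rmse": agg.mean,
                       "n_groups": len(agg.per_group)})
        for _, row in agg.per_group.iterrows():
            groups.append({**meta, "aggregation": by, "group_id": row["group_id"],
                           "n": int(row["n"]), "rmse": row["rmse"]})
    return points, groups


def build_assay_curve(setup: R2Setup, chemicals: pd.DataFrame, taxonomy: pd.DataFrame,
                      learner_specs: Sequence[LearnerSpec],
                      schedule: AnchorSchedule = AnchorSchedule(),
                      with_auxiliary: bool = False,
                      auditor: LeakageAuditor | None = None) -> CurveResult:
    """RMSE vs per-species training-set size on the fixed test assays.

    At anchor ``a``, single-task families train on ``a`` rows per study
    species (their per-species models each see ``a`` rows); multi-task
    families additionally pool across species, plus the full auxiliary set
    when ``with_auxiliary``.  Samples are nested across anchors within an
    ordering; curves are reported per ordering.
    """
    counts = setup.train_study.groupby(COL_SPECIES).size()
    if counts.min() < max(schedule.anchors):
        raise ValueError(
            f"anchor {max(schedule.anchors)} exceeds the smallest study-species "
            f"training count ({int(counts.min())})")
    if auditor is None:
        auditor = LeakageAuditor(setup.split.test_chemicals)
    points_rows: list[dict] = []
    group_rows: list[dict] = []
    for o, perms in enumerate(assay_orderings(setup, schedule.n_orderings, schedule.seed)):
        for anchor in schedule.anchors:
            idx = np.concatenate([perms[s][:anchor] for s in setup.study_species])
            anchored = setup.train_study.iloc[np.sort(idx)].reset_index(drop=True)
            if with_auxiliary and len(setup.auxiliary):
                pooled = pd.concat([anchored, setup.auxiliary], ignore_index=True)
            else:
                pooled = anchored
            cache: dict = {}
            for spec in learner_specs:
                cls = FAMILIES[spec.family]
                train_df = pooled if cls.multi_task else anchored
                train_table, test_table = _table_for(cls, train_df, setup.test,
                                                     chemicals, taxonomy, cache, auditor)
                predictions = _score(make_learner(spec), spec, test_table,
                                     auditor, train_table)
                meta = {"anchor": anchor, "ordering": o, "learner": spec.family,
                        "with_auxiliary": with_auxiliary}
                p, g = _curve_rows(predictions, meta)
                points_rows.extend(p)
                group_rows.extend(g)
    return CurveResult(points=pd.DataFrame(points_rows),
                       group_errors=pd.DataFrame(group_rows), x_column="anchor")


# ---------------------------------------------------------------------------
# R3: auxiliary-species-count curves
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class R3Setup:
    split: SplitPlan
    study_species: tuple[str, ...]
    auxiliary_species: tuple[str, ...]
    train: pd.DataFrame          # training rows of study + auxiliary species
    test: pd.DataFrame           # test rows of study species
    aux_cap: int


def select_species_curve_setup_r3(records: pd.DataFrame, test_fraction: float = 0.25,
                                  min_test_chemicals: int = 3, aux_min_train: int = 64,
                                  aux_cap: int = 64, seed: int = 0) -> R3Setup:
    """Study species need enough *test* chemicals; auxiliary species (disjoint
    from them) need enough training assays and are later capped to
    ``aux_cap`` rows.  All other species are discarded."""
    split = split_by_chemicals(records[COL_CHEMICAL].unique(), test_fraction, seed)
    train = records[records[COL_CHEMICAL].isin(split.train_chemicals)]
    test = records[records[COL_CHEMICAL].isin(split.test_chemicals)]
    test_chems = test.groupby(COL_SPECIES)[COL_CHEMICAL].nunique()
    study = tuple(sorted(test_chems.index[test_chems >= min_test_chemicals]))
    if not study:
        raise ValueError(f"no species has >= {min_test_chemicals} test chemicals")
    train_counts = train.groupby(COL_SPECIES).size()
    aux = tuple(sorted(s for s in train_counts.index[train_counts >= aux_min_train]
                       if s not in study))
    if not aux:
        raise ValueError(f"no auxiliary species has >= {aux_min_train} training assays")
    keep = set(study) | set(aux)
    return R3Setup(
        split=split,
        study_species=study,
        auxiliary_species=aux,
        train=train[train[COL_SPECIES].isin(keep)].reset_index(drop=True),
        test=test[test[COL_SPECIES].isin(study)].reset_index(drop=True),
        aux_cap=aux_cap,
    )


def build_species_curve(setup: R3Setup, chemicals: pd.DataFrame, taxonomy: pd.DataFrame,
                        learner_specs: Sequence[LearnerSpec],
                        counts: Sequence[int] = DEFAULT_AUX_COUNTS,
                        n_seeds: int = 3, seed: int = 0,
                        auditor: LeakageAuditor | None = None) -> CurveResult:
    """RMSE vs number of auxiliary species added to each study species.

    Per pseudorandom seed, auxiliary species are downsampled to ``aux_cap``
    rows and randomly permuted; count ``n`` uses the permutation's first
    ``n`` species (a prefix, so auxiliary sets are nested in ``n``).  One
    model per (study species, count, learner) is fit on the study species'
    training rows plus the auxiliary prefix.  Single-task families are
    rejected — they cannot use the added data.
    """
    single = [s.family for s in learner_specs if not FAMILIES[s.family].multi_task]
    if single:
        raise ValueError(f"single-task families {single} are excluded from species curves")
    counts = list(counts)
    if any(c < 0 or c > len(setup.auxiliary_species) for c in counts):
        raise ValueError(
            f"counts must lie in [0, {len(setup.auxiliary_species)}], got {counts}")
    if auditor is None:
        auditor = LeakageAuditor(setup.split.test_chemicals)
    train = setup.train
    points_rows: list[dict] = []
    group_rows: list[dict] = []
    for rep in range(n_seeds):
        rng = np.random.default_rng(seed + 104729 * rep)
        capped = {}
        for s in setup.auxiliary_species:
            rows = train[train[COL_SPECIES] == s]
            take = rng.choice(len(rows), size=min(setup.aux_cap, len(rows)), replace=False)
            capped[s] = rows.iloc[np.sort(take)]
        perm = [setup.auxiliary_species[i]
                for i in rng.permutation(len(setup.auxiliary_species))]
        for n_aux in counts:
            prefix = perm[:n_aux]
            aux_rows = (pd.concat([capped[s] for s in prefix], ignore_index=True)
                        if prefix else train.iloc[0:0])
            per_learner: dict[str, list[pd.DataFrame]] = {s.family: [] for s in learner_specs}
            for target in setup.study_species:
                target_train = train[train[COL_SPECIES] == target]
                pooled = pd.concat([target_train, aux_rows], ignore_index=True)
                target_test = setup.test[setup.test[COL_SPECIES] == target]
                cache: dict = {}
                for spec in learner_specs:
                    cls = FAMILIES[spec.family]
                    train_table, test_table = _table_for(cls, pooled, target_test,
                                                         chemicals, taxonomy, cache, auditor)
                    per_learner[spec.family].append(
                        _score(make_learner(spec), spec, test_table, auditor, train_table))
            for spec in learner_specs:
                predictions = pd.concat(per_learner[spec.family], ignore_index=True)
                meta = {"n_aux": n_aux, "ordering": rep, "learner": spec.family}
                p, g = _curve_rows(predictions, meta)
                points_rows.extend(p)
                group_rows.extend(g)
    return CurveResult(points=pd.DataFrame(points_rows),
                       group_errors=pd.DataFrame(group_rows), x_column="n_aux")


# ---------------------------------------------------------------------------
# bootstrap bands and curve summaries
# ---------------------------------------------------------------------------

def bootstrap_bands(group_errors: Sequence[float], B: int = 1000, level: float = 0.90,
                    seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap band for the mean of group-level errors."""
    values = np.asarray(group_errors, dtype=float)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if len(values) == 0:
        raise ValueError("no group errors supplied")
    if len(values) == 1:
        warnings.warn("single observation: degenerate bootstrap band", UserWarning)
        return float(values[0]), float(values[0])
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(B, len(values)), replace=True).mean(axis=1)
    half = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [half, 1.0 - half])
    return float(lo), float(hi)


def summarize_curve(result: CurveResult, B: int = 1000, level: float = 0.90,
                    seed: int = 0) -> pd.DataFrame:
    """Average the per-ordering curves and attach bootstrap bands computed
    from the pooled group-level RMSEs."""
    x = result.x_column
    rows = []
    for (xv, learner, by), block in result.points.groupby([x, "learner", "aggregation"]):
        errors = result.group_errors.query(
            f"{x} == @xv and learner == @learner and aggregation == @by")["rmse"]
        lo, hi = bootstrap_bands(errors.to_numpy(), B=B, level=level, seed=seed)
        rows.append({x: xv, "learner": learner, "aggregation": by,
                     "rmse": float(block["rmse"].mean()),
                     "band_lo": lo, "band_hi": hi, "level": level})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"experiment stage [{name}] failed: {exc}") from exc
    return _StageContext()


def _learner_specs(config: Mapping) -> list[LearnerSpec]:
    specs = []
    for entry in config.get("learners", [{"family": "mt_rf"}]):
        specs.append(LearnerSpec(family=entry["family"],
                                 hyperparameters=entry.get("hyperparameters", {}),
                                 seed=int(entry.get("seed", config.get("seed", 0)))))
    return specs


def run_experiment(config: Mapping, out_dir: str | Path) -> dict:
    """Generate -> clean -> split -> fit/evaluate (-> curves), with manifest.

    Deterministic given the config: every random stage derives its seed from
    ``config['seed']``, and the manifest records all of them together with a
    hash of the config and the library versions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    seeds_used = {"master": master_seed}
    outputs: dict = {}

    with _stage("generate"):
        synth_cfg = SynthConfig(**{**config.get("synth", {}), "seed": master_seed})
        assays, chemicals, taxonomy, truth = generate_dataset(synth_cfg)
        seeds_used["synth"] = synth_cfg.seed

    with _stage("preprocess"):
        records = clean_assays(assays)

    with _stage("split"):
        split_cfg = config.get("split", {})
        split_seed = int(split_cfg.get("seed", master_seed + 1))
        plan = split_by_chemicals(records[COL_CHEMICAL].unique(),
                                  float(split_cfg.get("test_fraction", 0.2)), split_seed)
        seeds_used["split"] = split_seed
        auditor = LeakageAuditor(plan.test_chemicals)

    specs = _learner_specs(config)
    seeds_used["learners"] = {s.family: s.seed for s in specs}

    with _stage("evaluate-external"):
        external = evaluate_external(records, chemicals, taxonomy, specs, plan,
                                     auditor=auditor)
        path = out / "external_predictions.csv"
        external.to_csv(path, index=False)
        outputs["external_predictions"] = path
        summary_rows = []
        for learner, group in external.groupby("learner"):
            for by in ("species", "chemical"):
                agg = aggregate(group, by=by)
                summary_rows.append({"learner": learner, "aggregation": by,
                                     "rmse_mean": agg.mean, "rmse_median": agg.median,
                                     "n_groups": len(agg.per_group)})
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "external_summary.csv", index=False)
        outputs["external_summary"] = out / "external_summary.csv"

    if config.get("internal_cv"):
        with _stage("internal-cv"):
            cv_cfg = config["internal_cv"]
            cv_seed = int(cv_cfg.get("seed", master_seed + 2))
            plans = internal_cv_plan(plan.train_chemicals, k=int(cv_cfg.get("k", 5)),
                                     repetitions=int(cv_cfg.get("repetitions", 3)),
                                     seed=cv_seed)
            seeds_used["internal_cv"] = cv_seed
            internal = run_internal_validation(records, chemicals, taxonomy, specs,
                                               plans, auditor=auditor)
            internal.to_csv(out / "internal_validation.csv", index=False)
            outputs["internal_validation"] = out / "internal_validation.csv"

    if config.get("assay_curve"):
        with _stage("curve-assays"):
            cfg = config["assay_curve"]
            curve_seed = int(cfg.get("seed", master_seed + 3))
            setup = select_study_species_r2(
                records, test_fraction=float(cfg.get("test_fraction", 0.1)),
                min_train_assays=int(cfg.get("min_train_assays", 128)),
                seed=curve_seed)
            seeds_used["assay_curve"] = curve_seed
            schedule = AnchorSchedule(anchors=tuple(cfg.get("anchors", DEFAULT_ANCHORS)),
                                      n_orderings=int(cfg.get("n_orderings", 3)),
                                      seed=curve_seed)
            curve_auditor = LeakageAuditor(setup.split.test_chemicals)
            result = build_assay_curve(setup, chemicals, taxonomy, specs, schedule,
                                       with_auxiliary=bool(cfg.get("with_auxiliary", False)),
                                       auditor=curve_auditor)
            summarize_curve(result, seed=curve_seed).to_csv(out / "assay_curve.csv", index=False)
            result.points.to_csv(out / "assay_curve_points.csv", index=False)
            outputs["assay_curve"] = out / "assay_curve.csv"

    if config.get("species_curve"):
        with _stage("curve-species"):
            cfg = config["species_curve"]
            curve_seed = int(cfg.get("seed", master_seed + 4))
            setup = select_species_curve_setup_r3(
                records, test_fraction=float(cfg.get("test_fraction", 0.25)),
                min_test_chemicals=int(cfg.get("min_test_chemicals", 3)),
                aux_min_train=int(cfg.get("aux_min_train", 64)),
                aux_cap=int(cfg.get("aux_cap", 64)), seed=curve_seed)
            seeds_used["species_curve"] = curve_seed
            mt_specs = [s for s in specs if FAMILIES[s.family].multi_task]
            curve_auditor = LeakageAuditor(setup.split.test_chemicals)
            result = build_species_curve(setup, chemicals, taxonomy, mt_specs,
                                         counts=list(cfg.get("counts", DEFAULT_AUX_COUNTS)),
                                         n_seeds=int(cfg.get("n_seeds", 3)),
                                         seed=curve_seed, auditor=curve_auditor)
            summarize_curve(result, seed=curve_seed).to_csv(out / "species_curve.csv", index=False)
            result.points.to_csv(out / "species_curve_points.csv", index=False)
            outputs["species_curve"] = out / "species_curve.csv"

    with _stage("manifest"):
        import sklearn
        import scipy
        canonical = json.dumps(config, sort_keys=True, default=str)
        manifest = {
            "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
            "config": json.loads(canonical),
            "seeds": seeds_used,
            "audit": {"n_checks": auditor.n_checks,
                      "n_test_chemicals": len(plan.test_chemicals)},
            "versions": {
                "aquameta": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "scipy": scipy.__version__,
            },
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2))
        outputs["manifest"] = path
    return outputs
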
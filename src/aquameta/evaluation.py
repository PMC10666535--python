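"""Chemicals-disjoint evaluation: splits, repeated CV, RMSE, rank tests.

Splitting always happens at the chemical level so that every assay of a
chemical lands on exactly one side — models are only ever scored on
compounds they have never seen.  A :class:`LeakageAuditor` can be threaded
through any harness to assert that invariant at fit time.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitPlan",
    "split_by_chemicals",
    "internal_cv_plan",
    "rmse",
    "raw_fold_error",
    "aggregate",
    "AggregateResult",
    "friedman_nemenyi",
    "FriedmanResult",
    "LeakageAuditor",
    "LeakageError",
    "run_internal_validation",
    "evaluate_external",
]


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """A disjoint train/test partition of the chemical universe."""

    train_chemicals: frozenset
    test_chemicals: frozenset
    seed: int
    repetition: int = 0
    fold: int = 0

    def __post_init__(self) -> None:
        if self.train_chemicals & self.test_chemicals:
            raise ValueError("train and test chemical sets overlap")


def split_by_chemicals(chemicals: Iterable, test_fraction: float, seed: int) -> SplitPlan:
    """Uniform random chemical-level partition; test size = round(fraction * n)."""
    chems = np.asarray(sorted(set(chemicals)), dtype=object)
    if len(chems) < 2:
        raise ValueError("need at least 2 chemicals to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(chems))
    n_test = max(1, int(round(test_fraction * len(chems))))
    n_test = min(n_test, len(chems) - 1)
    test = frozenset(chems[perm[:n_test]])
    train = frozenset(chems[perm[n_test:]])
    return SplitPlan(train_chemicals=train, test_chemicals=test, seed=seed)


def internal_cv_plan(train_chemicals: Iterable, k: int = 5, repetitions: int = 3,
                     seed: int = 0) -> list[SplitPlan]:
    """k disjoint, near-equal subfolds per repetition -> k * repetitions plans.

    Each plan holds one subfold out as test chemicals.  Within a repetition
    the subfolds partition the training chemicals and sizes differ by <= 1.
    """
    chems = np.asarray(sorted(set(train_chemicals)), dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(chems) < k:
        raise ValueError(f"need at least k={k} chemicals, got {len(chems)}")
    plans = []
    for rep in range(repetitions):
        rng = np.random.default_rng(seed + 1000 * rep)
        perm = rng.permutation(len(chems))
        folds = np.array_split(perm, k)
        for fold_idx, fold in enumerate(folds):
            test = frozenset(chems[fold])
            train = frozenset(chems[np.concatenate([f for j, f in enumerate(folds) if j != fold_idx])])
            plans.append(SplitPlan(train_chemicals=train, test_chemicals=test,
                                   seed=seed, repetition=rep, fold=fold_idx))
    return plans


def rmse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    y = np.asarray(y_true, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yh.shape}")
    if y.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((y - yh) ** 2)))


def raw_fold_error(log10_error: float) -> float:
    """Multiplicative factor on the raw concentration scale implied by a
    log10-scale absolute error (an error of 1.0 is a factor of 10)."""
    return float(10.0 ** log10_error)


@dataclasses.dataclass
class AggregateResult:
    per_group: pd.DataFrame  # columns: group_id, n, rmse
    mean: float
    median: float


def aggregate(results: pd.DataFrame, by: str = "species") -> AggregateResult:
    """Group per-row predictions, compute one RMSE per group, then summarize.

    The overall mean/median weigh every group equally regardless of size.
    ``results`` needs columns ``y_true``, ``y_pred`` and the grouping key
    (``species``, ``chemical`` or ``fold``).
    """
    if by not in results.columns:
        raise ValueError(f"grouping column {by!r} not in results")
    if len(results) == 0:
        raise ValueError("cannot aggregate empty results")
    rows = []
    for group_id, group in results.groupby(by, sort=True):
        rows.append({
            "group_id": group_id,
            "n": len(group),
            "rmse": rmse(group["y_true"], group["y_pred"]),
        })
    per_group = pd.DataFrame(rows)
    return AggregateResult(per_group=per_group,
                           mean=float(per_group["rmse"].mean()),
                           median=float(per_group["rmse"].median()))


# ---------------------------------------------------------------------------
# Friedman / Nemenyi
# ---------------------------------------------------------------------------

# two-tailed Nemenyi critical values q_alpha = studentized range / sqrt(2)
_Q_ALPHA = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
           7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589,
           7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


@dataclasses.dataclass
class FriedmanResult:
    mean_ranks: pd.Series            # per algorithm, lower = better
    chi2: float
    p_value: float
    iman_davenport: float
    iman_davenport_p: float
    critical_difference: float
    significant: pd.DataFrame        # boolean algorithms x algorithms matrix
    n_datasets: int
    n_algorithms: int


def friedman_nemenyi(errors: pd.DataFrame, alpha: float = 0.05) -> FriedmanResult:
    """Rank-based comparison of algorithms over datasets.

    ``errors``: rows = datasets, columns = algorithms, lower is better.
    Ties receive average ranks.  Returns the Friedman chi-square, its
    Iman-Davenport F correction, and the Nemenyi critical difference with
    the pairwise significance matrix at ``alpha``.
    """
    if errors.isna().any().any():
        raise ValueError("missing cells are not allowed")
    N, k = errors.shape
    if k < 2 or N < 2:
        raise ValueError("need at least 2 algorithms and 2 datasets")
    if alpha not in _Q_ALPHA:
        raise ValueError(f"alpha must be one of {sorted(_Q_ALPHA)}")
    if k > max(_Q_ALPHA[alpha]):
        raise ValueError(f"critical values tabulated only for k <= {max(_Q_ALPHA[alpha])}")

    ranks = errors.rank(axis=1, method="average")
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * N / (k * (k + 1)) * (float((mean_ranks ** 2).sum()) - k * (k + 1) ** 2 / 4.0)
    chi2 = max(chi2, 0.0)
    if chi2 == 0.0:
        p_value = 1.0
        ff = 0.0
        ff_p = 1.0
    else:
        p_value = float(stats.chi2.sf(chi2, k - 1))
        denom = N * (k - 1) - chi2
        if denom <= 0:
            ff = float("inf")
            ff_p = 0.0
        else:
            ff = (N - 1) * chi2 / denom
            ff_p = float(stats.f.sf(ff, k - 1, (k - 1) * (N - 1)))
    cd = _Q_ALPHA[alpha][k] * np.sqrt(k * (k + 1) / (6.0 * N))
    algos = list(errors.columns)
    sig = pd.DataFrame(False, index=algos, columns=algos)
    for a, b in itertools.combinations(algos, 2):
        is_sig = abs(mean_ranks[a] - mean_ranks[b]) > cd
        sig.loc[a, b] = sig.loc[b, a] = bool(is_sig)
    return FriedmanResult(mean_ranks=mean_ranks, chi2=float(chi2), p_value=p_value,
                          iman_davenport=float(ff), iman_davenport_p=ff_p,
                          critical_difference=float(cd), significant=sig,
                          n_datasets=N, n_algorithms=k)


# ---------------------------------------------------------------------------
# leakage audit
# ---------------------------------------------------------------------------

class LeakageError(RuntimeError):
    pass


class LeakageAuditor:
    """Asserts that fits never see held-out chemicals.

    Harnesses call :meth:`check` with the chemicals of every table used for
    fitting (learner training, imputation statistics, feature selection).
    """

    def __init__(self, test_chemicals: Iterable):
        self.test_chemicals = frozenset(test_chemicals)
        self.n_checks = 0

    def check(self, chemicals_seen: Iterable, context: str = "fit") -> None:
        seen = set(chemicals_seen)
        overlap = seen & self.test_chemicals
        if overlap:
            raise LeakageError(
                f"{context}: {len(overlap)} held-out chemicals leaked into fitting "
                f"(e.g. {sorted(overlap)[:3]})")
        self.n_checks += 1


# ---------------------------------------------------------------------------
# harnesses
# ---------------------------------------------------------------------------

def _fit_predict_plan(records, chemicals, taxonomy, learner_specs, plan,
                      auditor=None, learner_kwargs=None):
    """Fit every learner on a plan's training chemicals, score its test rows."""
    from .learners import make_learner
    from .preprocess import COL_CHEMICAL, MODE_MULTI, MODE_SINGLE, TableBuilder

    train_rows = records[records[COL_CHEMICAL].isin(plan.train_chemicals)]
    test_rows = records[records[COL_CHEMICAL].isin(plan.test_chemicals)]
    if len(train_rows) == 0 or len(test_rows) == 0:
        raise ValueError("plan produced an empty train or test table")
    if auditor is not None:
        auditor.check(train_rows[COL_CHEMICAL], context="table-builder fit")
    tables = {}
    for mode in (MODE_SINGLE, MODE_MULTI):
        builder = TableBuilder(mode=mode).fit(train_rows, chemicals, taxonomy)
        tables[mode] = (builder.transform(train_rows), builder.transform(test_rows))

    out = []
    for spec in learner_specs:
        learner = make_learner(spec)
        train_table, test_table = tables[learner.table_mode]
        if auditor is not None:
            auditor.check(train_table.chemical, context=f"{spec.family} fit")
        learner.fit(train_table)
        pred, mask = learner.predict_where_possible(test_table)
        frame = pd.DataFrame({
            "learner": spec.family,
            "species": test_table.species[mask],
            "chemical": test_table.chemical[mask],
            "y_true": test_table.y[mask],
            "y_pred": pred[mask],
            "fold": plan.fold,
            "repetition": plan.repetition,
        })
        frame["coverage"] = float(mask.mean())
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def run_internal_validation(records, chemicals, taxonomy, learner_specs, plans,
                            auditor=None, by: str = "chemical") -> pd.DataFrame:
    """One RMSE estimate per (learner, repetition, fold): the stability harness.

    With the default k=5 subfolds and 3 repetitions this yields 15 estimates
    per learner.
    """
    rows = []
    for plan in plans:
        predictions = _fit_predict_plan(records, chemicals, taxonomy,
                                        learner_specs, plan, auditor)
        for learner, group in predictions.groupby("learner"):
            agg = aggregate(group, by=by)
            rows.append({
                "learner": learner,
                "repetition": plan.repetition,
                "fold": plan.fold,
                "n": len(group),
                "n_groups": len(agg.per_group),
                "rmse": agg.mean,
                "coverage": float(group["coverage"].iloc[0]),
            })
    return pd.DataFrame(rows)


def evaluate_external(records, chemicals, taxonomy, learner_specs, plan,
                      auditor=None) -> pd.DataFrame:
    """Per-row predictions of every learner on the external test chemicals."""
    return _fit_predict_plan(records, chemicals, taxonomy, learner_specs, plan,
                             auditor)
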
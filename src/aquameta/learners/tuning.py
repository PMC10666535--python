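"""Small grid-search harness over chemicals-disjoint internal folds."""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .base import LearnerSpec

__all__ = ["grid_search"]


def grid_search(family: str, grid: Mapping[str, Sequence], records: pd.DataFrame,
                chemicals: pd.DataFrame, taxonomy: pd.DataFrame | None = None,
                k: int = 3, seed: int = 0, by: str = "chemical") -> tuple[LearnerSpec, pd.DataFrame]:
    """Exhaustive grid search; returns (best spec, per-candidate results).

    Candidates are scored by mean RMSE over ``k`` chemicals-disjoint folds of
    the provided records (which should already exclude any external test
    chemicals).
    """
    from ..evaluation import internal_cv_plan, run_internal_validation
    from ..preprocess import COL_CHEMICAL

    keys = list(grid)
    candidates = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    plans = internal_cv_plan(records[COL_CHEMICAL].unique(), k=k, repetitions=1, seed=seed)
    rows = []
    for i, hyper in enumerate(candidates):
        spec = LearnerSpec(family=family, hyperparameters=hyper, seed=seed)
        result = run_internal_validation(records, chemicals, taxonomy, [spec], plans, by=by)
        rows.append({"candidate": i, **hyper, "rmse": float(result["rmse"].mean())})
    table = pd.DataFrame(rows)
    best = table.loc[table["rmse"].idxmin()]
    best_hyper = candidates[int(best["candidate"])]
    return LearnerSpec(family=family, hyperparameters=best_hyper, seed=seed), table
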
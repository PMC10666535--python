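"""Stacked ensemble: linear meta-combination of three base regressors.

The meta linear regression is trained on out-of-fold base predictions
(grouped by chemical, k=5 internal folds) to keep the combination weights
leakage-free.  Base learners are injectable for testing; the defaults are
support vector regression, gradient boosted trees and a random forest, all
consuming the full multi-task feature table.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVR

from ..preprocess import MODE_MULTI, ModelTable
from .base import Learner
from .forests import DEFAULT_FOREST

__all__ = ["StackedEnsemble"]

log = logging.getLogger(__name__)


def _default_bases(seed: int) -> list:
    return [
        ("svr", SVR(kernel="rbf", C=1.0)),
        ("gbt", GradientBoostingRegressor(n_estimators=500, max_depth=3,
                                          learning_rate=0.05, random_state=seed)),
        ("rf", RandomForestRegressor(random_state=seed, n_jobs=1, **DEFAULT_FOREST)),
    ]


class StackedEnsemble(Learner):
    family = "mt_stack"
    table_mode = MODE_MULTI

    def __init__(self, seed: int = 0, base_estimators=None, k_folds: int = 5):
        super().__init__(seed)
        self.k_folds = int(k_folds)
        self._base_spec = base_estimators

    def _fit(self, table: ModelTable) -> None:
        X = table.feature_matrix()
        y = table.y
        bases = self._base_spec if self._base_spec is not None else _default_bases(self.seed)
        n_groups = len(np.unique(table.chemical))
        k = min(self.k_folds, n_groups)
        if len(table) < 2 * k or k < 2:
            raise ValueError(
                f"stacked ensemble needs >= {2 * self.k_folds} rows over >= 2 chemicals")

        oof = np.full((len(table), len(bases)), np.nan)
        splitter = GroupKFold(n_splits=k)
        for train_idx, test_idx in splitter.split(X, y, groups=table.chemical):
            for j, (_, estimator) in enumerate(bases):
                model = clone(estimator)
                model.fit(X[train_idx], y[train_idx])
                oof[test_idx, j] = model.predict(X[test_idx])

        meta = LinearRegression()
        # collinear base predictions make the meta design rank deficient
        design = np.column_stack([oof, np.ones(len(oof))])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            log.warning("mt_stack: collinear base predictions; ridge fallback")
            meta = Ridge(alpha=1e-6)
        meta.fit(oof, y)
        self.meta_ = meta

        self.bases_ = []
        for name, estimator in bases:
            model = clone(estimator)
            model.fit(X, y)
            self.bases_.append((name, model))

    def base_predictions(self, table: ModelTable) -> np.ndarray:
        X = table.feature_matrix()
        return np.column_stack([model.predict(X) for _, model in self.bases_])

    def _predict(self, table: ModelTable) -> np.ndarray:
        return self.meta_.predict(self.base_predictions(table))
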
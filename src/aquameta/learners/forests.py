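"""Random-forest families: one forest per species vs one shared forest."""

from __future__ import annotations

import logging

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ..preprocess import MODE_MULTI, MODE_SINGLE, ModelTable
from .base import Learner

__all__ = ["SingleTaskForest", "MultiTaskForest", "DEFAULT_FOREST"]

log = logging.getLogger(__name__)

#: documented default grid anchor (supplement-free defaults)
DEFAULT_FOREST = dict(n_estimators=500, max_features=1.0 / 3.0, min_samples_leaf=1)


def _make_forest(seed: int, **overrides) -> RandomForestRegressor:
    params = {**DEFAULT_FOREST, **overrides}
    return RandomForestRegressor(random_state=seed, n_jobs=1, **params)


class SingleTaskForest(Learner):
    """Independent forest per species on chemical + duration features.

    Species with fewer than two training rows fall back to a constant
    (their mean target), which is logged.
    """

    family = "st_rf"
    table_mode = MODE_SINGLE
    multi_task = False

    def __init__(self, seed: int = 0, **forest_params):
        super().__init__(seed)
        self.forest_params = forest_params

    def _fit(self, table: ModelTable) -> None:
        X = table.feature_matrix()
        self.models_: dict = {}
        for i, s in enumerate(np.unique(table.species)):
            rows = table.species == s
            ys = table.y[rows]
            if rows.sum() < 2:
                log.info("st_rf: species %s has <2 rows; falling back to mean", s)
                self.models_[s] = float(ys.mean())
            else:
                forest = _make_forest(self.seed + i, **self.forest_params)
                forest.fit(X[rows], ys)
                self.models_[s] = forest

    def predictable_mask(self, species: np.ndarray) -> np.ndarray:
        return np.isin(np.asarray(species, dtype=object), list(self.models_))

    def _predict(self, table: ModelTable) -> np.ndarray:
        X = table.feature_matrix()
        out = np.empty(len(table))
        for s in np.unique(table.species):
            rows = table.species == s
            model = self.models_[s]
            out[rows] = model if isinstance(model, float) else model.predict(X[rows])
        return out


class MultiTaskForest(Learner):
    """One forest over all species, with taxonomy encodings as features.

    Unseen species carry all-zero species indicators, so the forest falls
    back to their class/phylum information.
    """

    family = "mt_rf"
    table_mode = MODE_MULTI

    def __init__(self, seed: int = 0, **forest_params):
        super().__init__(seed)
        self.forest_params = forest_params

    def _fit(self, table: ModelTable) -> None:
        self.model_ = _make_forest(self.seed, **self.forest_params)
        self.model_.fit(table.feature_matrix(), table.y)

    def _predict(self, table: ModelTable) -> np.ndarray:
        return self.model_.predict(table.feature_matrix())
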
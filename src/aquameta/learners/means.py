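"""Mean-prediction baselines."""

from __future__ import annotations

import numpy as np

from ..preprocess import MODE_MULTI, MODE_SINGLE, ModelTable
from .base import Learner

__all__ = ["SingleTaskMean", "MultiTaskMean"]


class SingleTaskMean(Learner):
    """Predicts each species' training-target mean; refuses unseen species."""

    family = "st_mean"
    table_mode = MODE_SINGLE
    multi_task = False

    def _fit(self, table: ModelTable) -> None:
        self.means_: dict = {}
        for s in np.unique(table.species):
            self.means_[s] = float(table.y[table.species == s].mean())

    def predictable_mask(self, species: np.ndarray) -> np.ndarray:
        return np.isin(np.asarray(species, dtype=object), list(self.means_))

    def _predict(self, table: ModelTable) -> np.ndarray:
        return np.array([self.means_[s] for s in table.species])


class MultiTaskMean(Learner):
    """Predicts the pooled training-target mean for any species, seen or not."""

    family = "mt_mean"
    table_mode = MODE_MULTI

    def _fit(self, table: ModelTable) -> None:
        self.mean_ = float(np.mean(table.y))

    def _predict(self, table: ModelTable) -> np.ndarray:
        return np.full(len(table), self.mean_)
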
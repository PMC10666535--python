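"""Transformational representation learning over per-species forests.

Stage 1 fits one forest per training species; a compound's representation is
the vector of those models' predictions for it (dimension = number of
first-stage models).  Stage 2 fits one forest per species on the
representations.  The stacked variant averages the stage-2 prediction with
the target species' own stage-1 prediction.
"""

from __future__ import annotations

import logging

import numpy as np

from ..preprocess import MODE_SINGLE, ModelTable
from .base import Learner, UnknownSpeciesError
from .forests import _make_forest

__all__ = ["TmlForest", "TmlStackedForest"]

log = logging.getLogger(__name__)


class TmlForest(Learner):
    family = "tml"
    table_mode = MODE_SINGLE

    def __init__(self, seed: int = 0, include_own_model: bool = True, **forest_params):
        super().__init__(seed)
        self.include_own_model = include_own_model
        self.forest_params = forest_params

    def _fit(self, table: ModelTable) -> None:
        X = table.feature_matrix()
        species = list(np.unique(table.species))
        self.first_stage_: dict = {}
        for i, s in enumerate(species):
            rows = table.species == s
            if rows.sum() < 1:  # cannot happen via unique(); guards external calls
                log.warning("tml: species %s has no rows; excluded from representation", s)
                continue
            forest = _make_forest(self.seed + i, **self.forest_params)
            forest.fit(X[rows], table.y[rows])
            self.first_stage_[s] = forest
        self.representation_species_ = list(self.first_stage_)

        self.second_stage_: dict = {}
        for i, s in enumerate(species):
            rows = table.species == s
            rep = self._represent_rows(X[rows], exclude=None if self.include_own_model else s)
            forest = _make_forest(self.seed + 1000 + i, **self.forest_params)
            forest.fit(rep, table.y[rows])
            self.second_stage_[s] = forest

    def _represent_rows(self, X: np.ndarray, exclude=None) -> np.ndarray:
        cols = []
        for s in self.representation_species_:
            if exclude is not None and s == exclude:
                cols.append(np.zeros(len(X)))
            else:
                cols.append(self.first_stage_[s].predict(X))
        return np.column_stack(cols)

    def represent(self, table: ModelTable) -> np.ndarray:
        """Cross-task representation: one column per first-stage model."""
        self._check_predict_input(table)
        return self._represent_rows(table.feature_matrix())

    @property
    def representation_dim(self) -> int:
        return len(self.representation_species_)

    def predictable_mask(self, species: np.ndarray) -> np.ndarray:
        return np.isin(np.asarray(species, dtype=object), list(self.second_stage_))

    def _first_stage_predict(self, s, X: np.ndarray) -> np.ndarray:
        if s not in self.first_stage_:
            raise UnknownSpeciesError(s)
        return self.first_stage_[s].predict(X)

    def _predict(self, table: ModelTable) -> np.ndarray:
        X = table.feature_matrix()
        out = np.empty(len(table))
        for s in np.unique(table.species):
            rows = table.species == s
            rep = self._represent_rows(X[rows], exclude=None if self.include_own_model else s)
            out[rows] = self.second_stage_[s].predict(rep)
        return out


class TmlStackedForest(TmlForest):
    """Unweighted mean of the stage-2 prediction and the species' own
    stage-1 single-task forest prediction."""

    family = "tml_stacked"

    def _predict(self, table: ModelTable) -> np.ndarray:
        second = super()._predict(table)
        X = table.feature_matrix()
        first = np.empty(len(table))
        for s in np.unique(table.species):
            rows = table.species == s
            first[rows] = self._first_stage_predict(s, X[rows])
        return 0.5 * (first + second)
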
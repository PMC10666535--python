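"""Uniform fit/predict contract shared by all ten algorithm families."""

from __future__ import annotations

import abc
import dataclasses
from typing import Any, Mapping

import numpy as np

from ..preprocess import ModelTable

__all__ = ["Learner", "LearnerSpec", "SchemaMismatchError", "UnknownSpeciesError"]


class SchemaMismatchError(ValueError):
    """Prediction input whose feature schema differs from training."""


class UnknownSpeciesError(KeyError):
    """Prediction requested for a species this learner cannot handle."""


@dataclasses.dataclass(frozen=True)
class LearnerSpec:
    """Declarative learner description: family + hyperparameters + seed."""

    family: str
    hyperparameters: Mapping[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0


class Learner(abc.ABC):
    """Base class: every family predicts one real value per
    (chemical features, duration, species) row of a :class:`ModelTable`.

    ``table_mode`` declares which table flavour the family consumes
    ("single_task" tables carry no taxonomy columns).  Training rows are
    canonicalized (sorted by species/chemical/duration) before fitting so
    that row order never affects a seeded fit.
    """

    family: str = "abstract"
    table_mode: str = "multi_task"
    #: whether the family exploits other species' assays (everything except
    #: the two single-task baselines; independent of table_mode, since e.g.
    #: the multitarget net shares data while consuming a taxonomy-free table)
    multi_task: bool = True

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._fingerprint: str | None = None
        self._fitted = False

    # subclasses implement these two
    @abc.abstractmethod
    def _fit(self, table: ModelTable) -> None: ...

    @abc.abstractmethod
    def _predict(self, table: ModelTable) -> np.ndarray: ...

    def fit(self, table: ModelTable) -> "Learner":
        if table.mode != self.table_mode:
            raise ValueError(
                f"{self.family} requires a {self.table_mode} table, got {table.mode}")
        if table.y is None:
            raise ValueError("training table lacks targets")
        if len(table) == 0:
            raise ValueError("cannot fit on an empty table")
        self._fingerprint = table.fingerprint
        self._fit(table.canonical_order())
        self._fitted = True
        return self

    def _check_predict_input(self, table: ModelTable) -> None:
        if not self._fitted:
            raise RuntimeError(f"{self.family} is not fitted")
        if table.fingerprint != self._fingerprint:
            raise SchemaMismatchError(
                f"{self.family}: input schema fingerprint {table.fingerprint[:8]} "
                f"differs from training schema {self._fingerprint[:8]}")

    def predict(self, table: ModelTable) -> np.ndarray:
        self._check_predict_input(table)
        mask = self.predictable_mask(table.species)
        if not mask.all():
            missing = sorted(set(np.asarray(table.species, dtype=object)[~mask]))
            raise UnknownSpeciesError(
                f"{self.family} cannot predict for species {missing[:5]}")
        return np.asarray(self._predict(table), dtype=float)

    def predict_where_possible(self, table: ModelTable) -> tuple[np.ndarray, np.ndarray]:
        """(predictions, mask); rows outside the learner's coverage are NaN."""
        self._check_predict_input(table)
        mask = self.predictable_mask(table.species)
        pred = np.full(len(table), np.nan)
        if mask.any():
            pred[mask] = np.asarray(self._predict(table.subset(mask)), dtype=float)
        return pred, mask

    def predictable_mask(self, species: np.ndarray) -> np.ndarray:
        return np.ones(len(species), dtype=bool)
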
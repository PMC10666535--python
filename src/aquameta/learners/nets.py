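"""Neural-network families: shared one-output net, multitarget net,
and head-only fine-tuning."""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import GroupShuffleSplit

from ..preprocess import MODE_MULTI, MODE_SINGLE, ModelTable
from . import _mlp
from .base import Learner

__all__ = ["OneOutputNet", "MultiTargetNet", "FineTuneTop", "DEFAULT_NET"]

DEFAULT_NET = dict(hidden=(256, 256), epochs=200, batch_size=128, lr=1e-3,
                   val_fraction=0.1, patience=20)


class _Scaler:
    def fit(self, X: np.ndarray) -> "_Scaler":
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_


class _NetBase(Learner):
    def __init__(self, seed: int = 0, **hyper):
        super().__init__(seed)
        self.hyper = {**DEFAULT_NET, **hyper}

    def _features(self, table: ModelTable) -> np.ndarray:
        return table.feature_matrix()

    def _split_validation(self, table: ModelTable, X, Y, mask):
        """Hold out a chemicals-disjoint validation slice for early stopping."""
        frac = self.hyper["val_fraction"]
        chems = np.unique(table.chemical)
        if frac <= 0 or len(chems) < 5:
            return X, Y, mask, None, None, None
        splitter = GroupShuffleSplit(n_splits=1, test_size=frac,
                                     random_state=self.seed)
        train_idx, val_idx = next(splitter.split(X, groups=table.chemical))
        return (X[train_idx], Y[train_idx],
                None if mask is None else mask[train_idx],
                X[val_idx], Y[val_idx],
                None if mask is None else mask[val_idx])

    def _train(self, table: ModelTable, Y, mask=None, n_out=1):
        X_raw = self._features(table)
        self.x_scaler_ = _Scaler().fit(X_raw)
        X = self.x_scaler_.transform(X_raw)
        rng = np.random.default_rng(self.seed)
        params = _mlp.init_params([X.shape[1], *self.hyper["hidden"], n_out], rng)
        Xt, Yt, mt, Xv, Yv, mv = self._split_validation(table, X, Y, mask)
        params, _ = _mlp.adam_train(
            params, Xt, Yt, mt,
            epochs=self.hyper["epochs"], batch_size=self.hyper["batch_size"],
            lr=self.hyper["lr"], rng=rng, X_val=Xv, Y_val=Yv, mask_val=mv,
            patience=self.hyper["patience"])
        return params

    def _forward(self, params, table: ModelTable) -> np.ndarray:
        X = self.x_scaler_.transform(self._features(table))
        return _mlp.forward(params, X)


class OneOutputNet(_NetBase):
    """One shared network over all tasks; taxonomy features distinguish
    species, a single output node emits the prediction."""

    family = "nn_one_output"
    table_mode = MODE_MULTI

    def _fit(self, table: ModelTable) -> None:
        self.y_mean_ = float(np.mean(table.y))
        self.y_std_ = float(np.std(table.y)) or 1.0
        Y = ((table.y - self.y_mean_) / self.y_std_).reshape(-1, 1)
        self.params_ = self._train(table, Y)

    def _predict(self, table: ModelTable) -> np.ndarray:
        out = self._forward(self.params_, table)[:, 0]
        return out * self.y_std_ + self.y_mean_


class MultiTargetNet(_NetBase):
    """One output node per training species; loss masked to observed pairs.

    Consumes only chemical + duration features — the species enters solely
    through which head is read out, so unseen species have no prediction.
    """

    family = "multitarget_nn"
    table_mode = MODE_SINGLE

    def _fit(self, table: ModelTable) -> None:
        self.species_index_ = {s: i for i, s in enumerate(np.unique(table.species))}
        n_out = len(self.species_index_)
        self.y_mean_ = float(np.mean(table.y))
        self.y_std_ = float(np.std(table.y)) or 1.0
        Y = np.zeros((len(table), n_out))
        mask = np.zeros((len(table), n_out), dtype=bool)
        cols = np.array([self.species_index_[s] for s in table.species])
        rows = np.arange(len(table))
        Y[rows, cols] = (table.y - self.y_mean_) / self.y_std_
        mask[rows, cols] = True
        self.params_ = self._train(table, Y, mask, n_out=n_out)

    @property
    def n_outputs(self) -> int:
        return len(self.species_index_)

    def predictable_mask(self, species: np.ndarray) -> np.ndarray:
        return np.isin(np.asarray(species, dtype=object), list(self.species_index_))

    def _predict(self, table: ModelTable) -> np.ndarray:
        out = self._forward(self.params_, table)
        cols = np.array([self.species_index_[s] for s in table.species])
        return out[np.arange(len(table)), cols] * self.y_std_ + self.y_mean_


class FineTuneTop(OneOutputNet):
    """Pretrain the one-output net on all tasks, then retrain only the final
    linear layer per species; all other layers stay bitwise frozen."""

    family = "finetune_top"
    table_mode = MODE_MULTI

    def __init__(self, seed: int = 0, ft_epochs: int = 50, ft_lr: float = 1e-3, **hyper):
        super().__init__(seed, **hyper)
        self.ft_epochs = int(ft_epochs)
        self.ft_lr = float(ft_lr)

    def _fit(self, table: ModelTable) -> None:
        super()._fit(table)  # pretrained shared network in self.params_
        X = self.x_scaler_.transform(self._features(table))
        Y = ((table.y - self.y_mean_) / self.y_std_).reshape(-1, 1)
        trainable = [False] * len(self.params_)
        trainable[-2] = trainable[-1] = True  # head weight matrix + bias
        self.heads_: dict = {}
        rng = np.random.default_rng(self.seed + 1)
        for s in np.unique(table.species):
            rows = table.species == s
            params, _ = _mlp.adam_train(
                self.params_, X[rows], Y[rows],
                epochs=self.ft_epochs, batch_size=min(self.hyper["batch_size"], int(rows.sum())),
                lr=self.ft_lr, rng=rng, trainable=trainable)
            self.heads_[s] = params

    def _predict(self, table: ModelTable) -> np.ndarray:
        out = np.empty(len(table))
        for s in np.unique(table.species):
            rows = table.species == s
            params = self.heads_.get(s, self.params_)
            sub = table.subset(rows)
            out[rows] = self._forward(params, sub)[:, 0]
        return out * self.y_std_ + self.y_mean_
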
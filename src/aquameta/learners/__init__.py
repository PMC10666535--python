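"""Learner registry: ten algorithm families behind one fit/predict contract."""

from __future__ import annotations

from .base import Learner, LearnerSpec, SchemaMismatchError, UnknownSpeciesError
from .forests import MultiTaskForest, SingleTaskForest
from .io import load_learner, save_learner
from .maml import (MamlConfig, MamlDivergence, MamlLearner, MamlState,
                   MLPRegressionProblem, inner_adapt, maml_fit)
from .means import MultiTaskMean, SingleTaskMean
from .nets import FineTuneTop, MultiTargetNet, OneOutputNet
from .stacking import StackedEnsemble
from .tml import TmlForest, TmlStackedForest
from .tuning import grid_search

FAMILIES: dict[str, type[Learner]] = {
    "st_mean": SingleTaskMean,
    "st_rf": SingleTaskForest,
    "mt_mean": MultiTaskMean,
    "mt_rf": MultiTaskForest,
    "mt_stack": StackedEnsemble,
    "nn_one_output": OneOutputNet,
    "multitarget_nn": MultiTargetNet,
    "finetune_top": FineTuneTop,
    "maml": MamlLearner,
    "tml": TmlForest,
    "tml_stacked": TmlStackedForest,
}


def make_learner(spec: LearnerSpec) -> Learner:
    """Instantiate a learner from its declarative spec."""
    if spec.family not in FAMILIES:
        raise ValueError(f"unknown learner family {spec.family!r}; "
                         f"choose from {sorted(FAMILIES)}")
    return FAMILIES[spec.family](seed=spec.seed, **dict(spec.hyperparameters))


__all__ = [
    "FAMILIES", "make_learner", "Learner", "LearnerSpec",
    "SchemaMismatchError", "UnknownSpeciesError",
    "SingleTaskMean", "MultiTaskMean", "SingleTaskForest", "MultiTaskForest",
    "StackedEnsemble", "OneOutputNet", "MultiTargetNet", "FineTuneTop",
    "MamlLearner", "MamlConfig", "MamlState", "MamlDivergence",
    "MLPRegressionProblem", "inner_adapt", "maml_fit",
    "TmlForest", "TmlStackedForest",
    "save_learner", "load_learner", "grid_search",
]
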
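"""Fitted-learner serialization: a small versioned pickle container."""

from __future__ import annotations

import pickle
from pathlib import Path

from .base import Learner

FORMAT_VERSION = 1


def save_learner(learner: Learner, path: str | Path) -> None:
    if not getattr(learner, "_fitted", False):
        raise ValueError("refusing to serialize an unfitted learner")
    payload = {
        "format_version": FORMAT_VERSION,
        "family": learner.family,
        "fingerprint": learner._fingerprint,
        "learner": learner,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_learner(path: str | Path) -> Learner:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported container version {payload.get('format_version')}")
    return payload["learner"]
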
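"""Shared fixtures: small synthetic datasets and the trained tiny models."""

from __future__ import annotations

import numpy as np
import pytest

import contactattn as ca
from contactattn.training import TrainSchedule, train


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A handful of short synthetic proteins for fast unit tests."""
    cfg = ca.SynthConfig(n_proteins=4, L_min=20, L_max=28, seed=7)
    return ca.make_dataset(cfg)


@pytest.fixture(scope="session")
def study_split():
    """The desk-scale study condition: 30 train / 6 val / 8 held-out,
    lengths 24-48, signal-to-noise 5."""
    make = lambda n, seed: ca.make_dataset(
        ca.SynthConfig(n_proteins=n, L_min=24, L_max=48,
                       signal_to_noise=5.0, seed=seed))
    return {"train": make(30, 101), "val": make(6, 102), "test": make(8, 103)}


@pytest.fixture(scope="session")
def trained_models(study_split, tmp_path_factory):
    """Both tiny-preset branches trained 10 epochs on the study split."""
    out = tmp_path_factory.mktemp("checkpoints")
    schedule = TrainSchedule(stop_epoch=10)
    models = {}
    states = {}
    for module in ("sequence", "regional"):
        state = train(study_split["train"], study_split["val"],
                      ca.ModelConfig.tiny(module), schedule, seed=1,
                      out_dir=out / module)
        models[module] = ca.load_model(state.best_checkpoint)
        states[module] = state
    return {"models": models, "states": states, "out_dir": out}
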
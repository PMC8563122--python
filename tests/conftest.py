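"""Shared fixtures.

The expensive fixture is ``recovery_run``: one full training of the small
two-task model on 400 synthetic records, shared (session-scoped) by the
parameter-recovery, localization and checkpoint tests so the network is
trained exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from palmdx import (GeneratorConfig, ModelConfig, TrainConfig, build_model,
                    generate_dataset, split_records, train)
from palmdx.training import prepare_arrays

RECOVERY_SEED = 11
RECOVERY_N = 400
RECOVERY_EPOCHS = 30


@pytest.fixture(scope="session")
def recovery_data():
    """400 synthetic records (lesion contrast 0.5, noise 0.1), split 80/20."""
    cfg = GeneratorConfig(n_records=RECOVERY_N, lesion_contrast=0.5, noise_sd=0.1,
                          seed=RECOVERY_SEED)
    rs = generate_dataset(cfg)
    sp = split_records(rs, train_fraction=0.8, seed=RECOVERY_SEED)
    tr = prepare_arrays(sp.train, input_side=64)
    va = prepare_arrays(sp.val, patch_size=tr["patch_size"], input_side=64,
                        with_masks=True)
    return {"train": tr, "val": va, "splits": sp}


@pytest.fixture(scope="session")
def recovery_run(recovery_data):
    """Small full-variant model trained 30 epochs on the recovery dataset."""
    model = build_model(ModelConfig(preset="small", variant="full", seed=RECOVERY_SEED))
    state, hist = train(model,
                        {"train": recovery_data["train"], "val": recovery_data["val"]},
                        TrainConfig(epochs=RECOVERY_EPOCHS, seed=RECOVERY_SEED))
    return {"model": model, "state": state, "history": hist,
            "val": recovery_data["val"], "train": recovery_data["train"]}


@pytest.fixture()
def tiny_records():
    cfg = GeneratorConfig(n_records=16, seed=5)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
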
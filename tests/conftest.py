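"""Shared fixtures. Heavy artifacts (the planted-signal screen and its
trained classifier) are session-scoped so several tests share one training
run."""

from __future__ import annotations

import numpy as np
import pytest

import epiguide as eg
from epiguide.encode import encode_screen
from epiguide.model import SplitPlan, pwm_oracle, train
from epiguide.nn import ModelConfig


@pytest.fixture(scope="session")
def worked():
    return eg.make_worked_example()


@pytest.fixture(scope="session")
def smoke_screen():
    return eg.simulate_screen(eg.preset("smoke", seed=1))


@pytest.fixture(scope="session")
def smoke_samples(smoke_screen):
    ds, tracks, _ = smoke_screen
    labels = eg.assign_labels(ds)
    return encode_screen(ds, tracks, labels=labels)


@pytest.fixture(scope="session")
def planted_seq_bundle():
    """The planted-signal study: 2000 genes x 10 guides (n = 20,000), seed 7;
    classification CNN trained with early stopping, plus the position-weight-
    matrix oracle on the identical gene-grouped split."""
    cfg = eg.preset("planted-seq", seed=7)
    ds, tracks, truth = eg.simulate_screen(cfg)
    labels = eg.assign_labels(ds)
    samples = encode_screen(ds, tracks, labels=labels)
    split = SplitPlan(seed=7)
    mcfg = ModelConfig(task="classification", max_epochs=20, patience=5, seed=7)
    model, report = train(samples, split, mcfg)
    oracle = pwm_oracle(samples, split)
    return {
        "dataset": ds,
        "tracks": tracks,
        "truth": truth,
        "samples": samples,
        "split": split,
        "model_cfg": mcfg,
        "model": model,
        "report": report,
        "oracle": oracle,
    }
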
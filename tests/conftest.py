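"""Shared fixtures: fold engines, RNG streams, and the desk-scale training run."""

from types import SimpleNamespace

import numpy as np
import pytest

from rnaforge.fold import NussinovEngine, ViennaEngine
from rnaforge.training import (
    TrainingConfig,
    generate_targets,
    holdout_easy,
    train,
)

#: Desk-scale study conditions: the published pipeline (self-generated targets
#: from folding uniform-random sequences, two-phase curriculum, A3C with the
#: decaying learning rate) scaled to length-12 hairpin-family targets and a
#: 20,000-step single-worker run.  At this length the target population is
#: small (~30 structures, no singletons), so the validation holdout is empty
#: and held-out evaluation targets come from `holdout_easy` instead.
SMOKE_CONFIG = dict(
    total_steps=20_000,
    phase1_steps=10_000,
    lr0=1e-3,
    lr_decay=0.8,
    lr_interval=5_000,
    validation_interval=4_000,
    n_validation=0,
    target_length=12,
    n_target_sequences=10_000,
    gamma=0.95,
    entropy_coef=0.01,
    value_loss_weight=0.5,
    n_step=20,
    n_workers=1,
    step_cap=60,
    validation_step_cap=50,
    channels=80,
    n_blocks=3,
    engine="vienna",
    seed=7,
)

N_HELD_OUT = 20


@pytest.fixture(scope="session")
def vienna():
    return ViennaEngine()


@pytest.fixture(scope="session")
def nussinov():
    return NussinovEngine()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def smoke_run(vienna):
    """One full desk-scale training run, shared by the tests that probe it."""
    cfg = TrainingConfig(**SMOKE_CONFIG)
    gen_rng = np.random.default_rng([cfg.seed, 2897])
    targets = generate_targets(cfg.n_target_sequences, cfg.target_length, vienna, gen_rng)
    train_targets, held_out = holdout_easy(targets, N_HELD_OUT)
    params, log = train(cfg, train_targets, vienna)
    return SimpleNamespace(
        cfg=cfg,
        target_set=targets,
        train_targets=train_targets,
        held_out=held_out,
        params=params,
        log=log,
    )
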
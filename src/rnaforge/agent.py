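"""scikit-learn-style estimator wrapping the full design pipeline.

``RNADesignAgent.fit`` generates (or accepts) a target set, runs the
curriculum + actor-critic training, and stores the best checkpoint;
``predict`` designs sequences for new dot-bracket targets of any length
with the trained policy.  The estimator follows sklearn conventions
(``get_params``/``set_params``, clonability, fitted attributes with a
trailing underscore), so it composes with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .analysis import solve
from .fold import PairMap, get_engine, parse_dot_bracket
from .training import TargetSet, TrainingConfig, generate_targets, train

__all__ = ["RNADesignAgent"]


class RNADesignAgent(BaseEstimator):
    """RNA inverse-folding agent: graph-convolutional policy trained by A3C.

    Parameters mirror :class:`~rnaforge.training.TrainingConfig`; see its
    docstring for semantics and defaults.  ``engine`` names the MFE fold
    predictor (``'vienna'`` for the Turner energy model, ``'nussinov'``
    for the hermetic maximum-pairing reference), ``random_state`` seeds
    every source of randomness, and ``solve_max_steps`` bounds each design
    rollout at predict time.

    Attributes
    ----------
    network_params_ : NetworkParams
        Best checkpoint selected by validation during :meth:`fit`.
    target_set_ : TargetSet
        Structures (with occurrence counts) the agent trained on.
    training_log_ : pandas.DataFrame
        Per-interval solve rates, losses and validation scores.
    """

    def __init__(
        self,
        total_steps: int = 1_500_000,
        phase1_steps: int = 500_000,
        lr0: float = 1e-5,
        lr_decay: float = 0.8,
        lr_interval: int = 100_000,
        validation_interval: int = 100_000,
        n_validation: int = 500,
        target_length: int = 32,
        n_target_sequences: int = 100_000,
        gamma: float = 0.95,
        entropy_coef: float = 0.01,
        value_loss_weight: float = 0.5,
        n_step: int = 20,
        n_workers: int = 1,
        step_cap: int = 400,
        validation_step_cap: int = 1_000,
        solve_reward: float = 1.0,
        channels: int = 80,
        n_blocks: int = 3,
        engine: str = "vienna",
        solve_max_steps: int = 10_000,
        solve_attempts: int = 1,
        random_state: int = 0,
    ) -> None:
        self.total_steps = total_steps
        self.phase1_steps = phase1_steps
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.lr_interval = lr_interval
        self.validation_interval = validation_interval
        self.n_validation = n_validation
        self.target_length = target_length
        self.n_target_sequences = n_target_sequences
        self.gamma = gamma
        self.entropy_coef = entropy_coef
        self.value_loss_weight = value_loss_weight
        self.n_step = n_step
        self.n_workers = n_workers
        self.step_cap = step_cap
        self.validation_step_cap = validation_step_cap
        self.solve_reward = solve_reward
        self.channels = channels
        self.n_blocks = n_blocks
        self.engine = engine
        self.solve_max_steps = solve_max_steps
        self.solve_attempts = solve_attempts
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            total_steps=self.total_steps,
            phase1_steps=self.phase1_steps,
            lr0=self.lr0,
            lr_decay=self.lr_decay,
            lr_interval=self.lr_interval,
            validation_interval=self.validation_interval,
            n_validation=self.n_validation,
            target_length=self.target_length,
            n_target_sequences=self.n_target_sequences,
            gamma=self.gamma,
            entropy_coef=self.entropy_coef,
            value_loss_weight=self.value_loss_weight,
            n_step=self.n_step,
            n_workers=self.n_workers,
            step_cap=self.step_cap,
            validation_step_cap=self.validation_step_cap,
            solve_reward=self.solve_reward,
            channels=self.channels,
            n_blocks=self.n_blocks,
            engine=self.engine,
            seed=self.random_state,
        )

    @staticmethod
    def _as_pairmaps(X) -> list[PairMap]:
        out = []
        for i, item in enumerate(X):
            if isinstance(item, PairMap):
                out.append(item)
            else:
                try:
                    out.append(parse_dot_bracket(str(item)))
                except ValueError as exc:
                    raise ValueError(f"target {i}: {exc}") from None
        return out

    def fit(self, X=None, y=None, target_set: TargetSet | None = None):
        """Train the agent.

        ``X`` is unused in the self-generated regime (the default): the
        target set is built by folding ``n_target_sequences`` random
        sequences of ``target_length``.  Pass ``target_set`` to train on a
        pre-generated (or loaded) set instead.  ``y`` is ignored; present
        for sklearn API compatibility.
        """
        cfg = self._config()
        eng = get_engine(self.engine)
        if target_set is None:
            rng = np.random.default_rng([cfg.seed, 2897])
            target_set = generate_targets(
                cfg.n_target_sequences, cfg.target_length, eng, rng
            )
        self.target_set_ = target_set
        self.network_params_, self.training_log_ = train(cfg, target_set, eng)
        return self

    def predict(self, X) -> np.ndarray:
        """Design one sequence per target structure (dot-bracket or PairMap).

        Returns an object array of sequences, with ``None`` where no
        solution was found within the per-target step budget.  The policy
        is length-agnostic, so targets may have any lengths.
        """
        check_is_fitted(self, "network_params_")
        targets = self._as_pairmaps(X)
        eng = get_engine(self.engine)
        out = []
        for idx, target in enumerate(targets):
            rng = np.random.default_rng([self.random_state, 6551, idx])
            res = solve(
                self.network_params_,
                target,
                eng,
                rng,
                max_steps=self.solve_max_steps,
                attempts=self.solve_attempts,
            )
            out.append(res.sequence if res.solved else None)
        return np.asarray(out, dtype=object)

    def score(self, X, y=None) -> float:
        """Fraction of targets solved within the per-target step budget."""
        preds = self.predict(X)
        return float(np.mean([p is not None for p in preds]))
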
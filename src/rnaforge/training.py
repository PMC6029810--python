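"""Curriculum generation and actor-critic training.

Training targets are self-generated: fold a large batch of uniform-random
sequences and keep the distinct structures with their occurrence counts.
A structure's count is a difficulty proxy — many sequences folding to it
means a solution is easy to find — and drives a two-phase curriculum:
phase 1 trains only on structures seen three or more times, phase 2 on
everything except a validation holdout of singleton (hardest) structures.

The optimizer is advantage actor-critic with n-step returns and entropy
regularization (A3C); workers are threads sharing the parameter arrays
without locking, so exact reproducibility holds in single-worker mode.
The learning rate starts at ``lr0`` and decays by ``lr_decay`` every
``lr_interval`` environment steps.  Every ``validation_interval`` steps
the current policy solves the whole validation set and the parameter
snapshot with the lowest cumulative step count is kept as the best
network.
"""

from __future__ import annotations

import csv
import threading
from collections import Counter
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .environment import (
    DesignState,
    RewardSpec,
    action_mask,
    env_step,
    random_sequence,
    reset,
)
from .fold import FoldEngine, PairMap, get_engine, parse_dot_bracket
from .network import (
    NetworkParams,
    backward_pass,
    forward_pass,
    masked_softmax,
    policy_forward,
    sample_action,
)

__all__ = [
    "TrainingConfig",
    "TargetSet",
    "CurriculumSplit",
    "EpisodeTrace",
    "generate_targets",
    "curriculum_split",
    "holdout_easy",
    "learning_rate",
    "compute_a3c_losses",
    "policy_gradients",
    "RMSProp",
    "train",
    "validate",
    "evaluate_policy",
    "uniform_policy",
    "network_policy",
]


@dataclass
class TrainingConfig:
    """Every knob of the training run, with the published defaults.

    ``total_steps``, ``phase1_steps``, the learning-rate schedule
    (``lr0``, ``lr_decay``, ``lr_interval``), the validation cadence and
    holdout size, and the target-set recipe (100,000 random length-32
    sequences) follow the published protocol.  The remaining actor-critic
    hyperparameters (``gamma``, ``entropy_coef``, ``value_loss_weight``,
    ``n_step``, worker count, episode caps, optimizer settings) are this
    package's own defaults and are all overridable.
    """

    total_steps: int = 1_500_000
    phase1_steps: int = 500_000
    lr0: float = 1e-5
    lr_decay: float = 0.8
    lr_interval: int = 100_000
    validation_interval: int = 100_000
    n_validation: int = 500
    target_length: int = 32
    n_target_sequences: int = 100_000
    gamma: float = 0.95
    entropy_coef: float = 0.01
    value_loss_weight: float = 0.5
    n_step: int = 20
    n_workers: int = 8
    step_cap: int = 400
    validation_step_cap: int = 1_000
    solve_reward: float = 1.0
    channels: int = 80
    n_blocks: int = 3
    rmsprop_decay: float = 0.99
    rmsprop_eps: float = 1e-6
    engine: str = "vienna"
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "engine" and not isinstance(v, (int, float)):
                raise TypeError(f"{f.name} must be numeric, got {v!r}")
        if not 0 < self.lr_decay < 1:
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.phase1_steps > self.total_steps:
            raise ValueError("phase1_steps cannot exceed total_steps")
        for name in (
            "lr_interval",
            "validation_interval",
            "target_length",
            "n_target_sequences",
            "n_step",
            "n_workers",
            "step_cap",
            "validation_step_cap",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kw) -> "TrainingConfig":
        return replace(self, **{k: v for k, v in kw.items() if v is not None})


@dataclass
class TargetSet:
    """Distinct target structures with occurrence counts.

    ``sum(count) == n_sequences`` of the generating experiment; only the
    structures are kept, never the sequences that produced them.
    """

    entries: list[tuple[PairMap, int]]
    source_params: dict = field(default_factory=dict)

    @property
    def structures(self) -> list[PairMap]:
        return [pm for pm, _ in self.entries]

    @property
    def counts(self) -> dict[PairMap, int]:
        return {pm: c for pm, c in self.entries}

    def occurrence_histogram(self) -> dict[str, int]:
        """Summary counts: unique, singletons, doubletons, count >= 3."""
        c = [n for _, n in self.entries]
        return {
            "unique": len(c),
            "singletons": sum(1 for v in c if v == 1),
            "doubletons": sum(1 for v in c if v == 2),
            "three_or_more": sum(1 for v in c if v >= 3),
        }

    def save(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["structure", "count"])
            for pm, n in self.entries:
                w.writerow([pm.to_dot_bracket(), n])

    @classmethod
    def load(cls, path) -> "TargetSet":
        entries = []
        with open(path) as fh:
            for row in csv.DictReader(fh):
                entries.append(
                    (parse_dot_bracket(row["structure"]), int(row["count"]))
                )
        return cls(entries)


@dataclass
class CurriculumSplit:
    """Phase pools and the validation holdout (disjoint from phase 2)."""

    phase1: list[PairMap]
    phase2: list[PairMap]
    validation: list[PairMap]


@dataclass
class EpisodeTrace:
    """Per-step records of one rollout segment used by the A3C losses.

    ``rewards`` are all zero except possibly the final transition;
    ``bootstrap_value`` is 0 after a solve and the critic's estimate of
    the next state after a truncation.
    """

    log_probs: list[float]
    values: list[float]
    rewards: list[float]
    entropies: list[float]
    bootstrap_value: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.rewards)
        if not (len(self.log_probs) == len(self.values) == len(self.entropies) == n):
            raise ValueError("trace field lengths differ")
        if n == 0:
            raise ValueError("empty trace")


def generate_targets(
    n_sequences: int,
    length: int,
    engine: FoldEngine,
    rng: np.random.Generator,
) -> TargetSet:
    """Fold ``n_sequences`` uniform-random sequences and tally the structures."""
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    tally: Counter[str] = Counter()
    for i in range(n_sequences):
        seq = random_sequence(length, rng)
        try:
            tally[engine.fold(seq).structure.to_dot_bracket()] += 1
        except Exception as exc:
            raise RuntimeError(f"fold engine failed on sequence {i}: {exc}") from exc
    entries = [(parse_dot_bracket(s), c) for s, c in sorted(tally.items())]
    return TargetSet(
        entries,
        source_params={
            "n_sequences": n_sequences,
            "length": length,
            "engine": engine.name,
        },
    )


def curriculum_split(
    ts: TargetSet, n_validation: int, rng: np.random.Generator
) -> CurriculumSplit:
    """Bucket a target set into phase pools and a singleton validation holdout.

    Phase 1 holds the easy structures (count ≥ 3); the validation set is
    ``n_validation`` structures sampled without replacement from the
    singletons (the hardest); phase 2 is everything else.
    """
    singles = [pm for pm, c in ts.entries if c == 1]
    if len(singles) < n_validation:
        raise ValueError(
            f"need {n_validation} singleton structures for validation, "
            f"have {len(singles)}"
        )
    pick = rng.choice(len(singles), size=n_validation, replace=False) if n_validation else []
    validation = {singles[i] for i in np.sort(np.asarray(pick, dtype=np.int64))}
    phase1 = [pm for pm, c in ts.entries if c >= 3]
    phase2 = [pm for pm, _ in ts.entries if pm not in validation]
    return CurriculumSplit(
        phase1=phase1, phase2=phase2, validation=sorted(
            validation, key=lambda pm: pm.to_dot_bracket()
        )
    )


def holdout_easy(
    ts: TargetSet, k: int, exclude_trivial: bool = True
) -> tuple[TargetSet, list[PairMap]]:
    """Split off the ``k`` highest-occurrence structures as an evaluation set.

    The all-unpaired structure is excluded by default (it is solved at
    reset by almost any sequence and carries no signal).  Returns the
    reduced target set and the held-out structures, which never appear as
    training episode targets.
    """
    ranked = sorted(ts.entries, key=lambda e: (-e[1], e[0].to_dot_bracket()))
    held: list[PairMap] = []
    for pm, _ in ranked:
        if exclude_trivial and not pm.pairs:
            continue
        held.append(pm)
        if len(held) == k:
            break
    if len(held) < k:
        raise ValueError(f"only {len(held)} eligible structures for a holdout of {k}")
    held_set = set(held)
    remaining = [(pm, c) for pm, c in ts.entries if pm not in held_set]
    return TargetSet(remaining, source_params=dict(ts.source_params)), held


def learning_rate(step: int, cfg: TrainingConfig) -> float:
    """Closed-form schedule: ``lr0 · lr_decay^⌊step / lr_interval⌋``."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.lr0 * cfg.lr_decay ** (step // cfg.lr_interval)


def compute_a3c_losses(
    trace: EpisodeTrace, gamma: float, beta: float
) -> tuple[float, float, float]:
    """Policy loss, value loss and entropy of one rollout segment.

    n-step discounted returns ``R_t`` are backed up from the bootstrap
    value; the advantage ``A_t = R_t − V(s_t)`` is treated as a constant
    with respect to the policy parameters.  The total training objective is
    ``policy_loss + value_loss_weight · value_loss − beta · entropy``.
    """
    returns = discounted_returns(trace.rewards, trace.bootstrap_value, gamma)
    adv = returns - np.asarray(trace.values)
    policy_loss = float(-(np.asarray(trace.log_probs) * adv).sum())
    value_loss = float((adv**2).sum())
    entropy = float(np.sum(trace.entropies))
    return policy_loss, value_loss, entropy


def discounted_returns(
    rewards, bootstrap_value: float, gamma: float
) -> np.ndarray:
    """n-step returns ``R_t = r_t + γ R_{t+1}`` seeded by the bootstrap."""
    out = np.empty(len(rewards))
    acc = bootstrap_value
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def policy_gradients(
    params: NetworkParams,
    steps: list[dict],
    bootstrap_value: float,
    cfg: TrainingConfig,
) -> tuple[dict[str, np.ndarray], tuple[float, float, float]]:
    """Accumulated parameter gradients of the A3C objective over a segment.

    Each step record holds the forward cache, the masked action
    distribution, the flat index of the sampled action, its reward and the
    critic value.  Returns the summed gradients and the (policy, value,
    entropy) loss components for logging.
    """
    rewards = [s["reward"] for s in steps]
    values = [s["value"] for s in steps]
    returns = discounted_returns(rewards, bootstrap_value, cfg.gamma)
    total: dict[str, np.ndarray] = {}
    log_probs, entropies = [], []
    for s, ret in zip(steps, returns):
        probs = s["probs"]
        flat = probs.reshape(-1)
        pos = flat > 0.0
        logp = np.zeros_like(flat)
        logp[pos] = np.log(flat[pos])
        ent = float(-(flat[pos] * logp[pos]).sum())
        adv = ret - s["value"]
        log_probs.append(float(logp[s["action_index"]]))
        entropies.append(ent)

        dflat = adv * flat
        dflat[s["action_index"]] -= adv
        # entropy bonus: d(−β·H)/dlogits = β·π·(log π + H)
        dflat[pos] += cfg.entropy_coef * flat[pos] * (logp[pos] + ent)
        dlogits = dflat.reshape(probs.shape)
        dvalue = 2.0 * cfg.value_loss_weight * (s["value"] - ret)
        grads = backward_pass(params, s["cache"], dlogits, dvalue)
        for k, g in grads.items():
            if k in total:
                total[k] += g
            else:
                total[k] = g
    trace = EpisodeTrace(log_probs, values, rewards, entropies, bootstrap_value)
    return total, compute_a3c_losses(trace, cfg.gamma, cfg.entropy_coef)


class RMSProp:
    """Adaptive gradient descent with statistics shared across workers."""

    def __init__(
        self, params: NetworkParams, decay: float = 0.99, eps: float = 1e-6
    ) -> None:
        self.decay = decay
        self.eps = eps
        self.ms = {k: np.zeros_like(v) for k, v in params.arrays.items()}

    def apply(
        self, params: NetworkParams, grads: dict[str, np.ndarray], lr: float
    ) -> None:
        for k, g in grads.items():
            ms = self.ms[k]
            ms *= self.decay
            ms += (1.0 - self.decay) * g * g
            params.arrays[k] -= lr * g / (np.sqrt(ms) + self.eps)


def network_policy(params: NetworkParams):
    """Stochastic policy: sample from the network's masked distribution."""

    def act(state: DesignState, rng: np.random.Generator):
        probs, _ = policy_forward(params, state)
        return sample_action(probs, rng)

    return act


def uniform_policy(state: DesignState, rng: np.random.Generator):
    """Baseline: uniform over the 3N allowed (non-no-op) mutations."""
    mask = action_mask(state).astype(float)
    return sample_action(mask / mask.sum(), rng)


def evaluate_policy(
    policy,
    structures,
    step_cap: int,
    engine: FoldEngine,
    rng: np.random.Generator,
) -> list[int]:
    """Steps-to-solve per structure under a stochastic rollout.

    Each structure gets one episode from a fresh random sequence; a failure
    is charged the full ``step_cap``.
    """
    out = []
    for target in structures:
        state = reset(target, rng, engine)
        steps = 0
        while not state.solved and steps < step_cap:
            action = policy(state, rng)
            state, _, done = env_step(
                state, action, engine, RewardSpec(), step_cap=step_cap
            )
            steps += 1
            if done:
                break
        out.append(steps if state.solved else step_cap)
    return out


def validate(
    params: NetworkParams,
    structures,
    step_cap: int,
    engine: FoldEngine,
    rng: np.random.Generator,
) -> int:
    """Total steps the policy needs to solve the whole validation set.

    The per-interval checkpoint selection keeps the snapshot minimizing
    this number; unsolved structures are charged ``step_cap`` each.
    """
    return int(sum(evaluate_policy(network_policy(params), structures, step_cap, engine, rng)))


class _Shared:
    """Mutable training state shared by workers (bookkeeping under a lock)."""

    def __init__(self, params, opt, split):
        self.params = params
        self.opt = opt
        self.split = split
        self.global_step = 0
        self.lock = threading.Lock()
        self.interval_records: list[dict] = []
        self.episodes = 0
        self.solved_episodes = 0
        self.loss_accum = np.zeros(3)
        self.loss_count = 0
        self.next_validation = None
        self.best_score = None
        self.best_params = None
        self.episode_targets: list[tuple[int, int, str]] = []
        self.error: BaseException | None = None


def _run_episode(shared: _Shared, cfg: TrainingConfig, engine, rng) -> None:
    with shared.lock:
        step_now = shared.global_step
    in_phase1 = step_now < cfg.phase1_steps and bool(shared.split.phase1)
    pool = shared.split.phase1 if in_phase1 else shared.split.phase2
    target = pool[int(rng.integers(len(pool)))]
    with shared.lock:
        shared.episode_targets.append(
            (step_now, 1 if in_phase1 else 2, target.to_dot_bracket())
        )
    state = reset(target, rng, engine)
    reward_spec = RewardSpec(solve_reward=cfg.solve_reward)
    done = state.solved
    solved = state.solved
    episode_steps = 0

    while not done:
        segment: list[dict] = []
        while not done and len(segment) < cfg.n_step:
            cache = forward_pass(
                shared.params, state.sequence, state.target, state.current_fold,
                want_value=True,
            )
            probs = masked_softmax(cache["logits"], action_mask(state))
            action = sample_action(probs, rng)
            nxt, reward, done = env_step(
                state, action, engine, reward_spec, step_cap=cfg.step_cap
            )
            segment.append(
                {
                    "cache": cache,
                    "probs": probs,
                    "action_index": action.position * 4
                    + "ACGU".index(action.new_base),
                    "reward": reward,
                    "value": cache["value"],
                }
            )
            state = nxt
            episode_steps += 1
        solved = state.solved
        if solved:
            bootstrap = 0.0
        else:
            boot_cache = forward_pass(
                shared.params, state.sequence, state.target, state.current_fold,
                want_value=True,
            )
            bootstrap = boot_cache["value"]
        grads, losses = policy_gradients(shared.params, segment, bootstrap, cfg)
        with shared.lock:
            lr = learning_rate(shared.global_step, cfg)
            shared.global_step += len(segment)
            shared.loss_accum += np.asarray(losses)
            shared.loss_count += 1
            reached_total = shared.global_step >= cfg.total_steps
        shared.opt.apply(shared.params, grads, lr)
        if reached_total:
            done = True
            solved = state.solved

    with shared.lock:
        shared.episodes += 1
        if solved:
            shared.solved_episodes += 1


def _maybe_validate(shared: _Shared, cfg: TrainingConfig, engine) -> None:
    """Close out any validation interval the step counter has crossed."""
    while True:
        with shared.lock:
            boundary = (len(shared.interval_records) + 1) * cfg.validation_interval
            if shared.global_step < boundary:
                return
            interval_idx = len(shared.interval_records)
            episodes = shared.episodes
            solved = shared.solved_episodes
            losses = (
                shared.loss_accum / max(shared.loss_count, 1)
            ).tolist()
            shared.episodes = 0
            shared.solved_episodes = 0
            shared.loss_accum[:] = 0.0
            shared.loss_count = 0
            snapshot = shared.params.copy()
            step_now = shared.global_step
        rng_val = np.random.default_rng([cfg.seed, 7919, interval_idx])
        score = (
            validate(
                snapshot,
                shared.split.validation,
                cfg.validation_step_cap,
                engine,
                rng_val,
            )
            if shared.split.validation
            else 0
        )
        with shared.lock:
            record = {
                "interval": interval_idx,
                "step": step_now,
                "phase": 1 if step_now <= cfg.phase1_steps else 2,
                "lr": learning_rate(step_now, cfg),
                "episodes": episodes,
                "solved_episodes": solved,
                "solve_rate": solved / episodes if episodes else np.nan,
                "policy_loss": losses[0],
                "value_loss": losses[1],
                "entropy": losses[2],
                "validation_score": score,
            }
            shared.interval_records.append(record)
            if shared.split.validation and (
                shared.best_score is None or score < shared.best_score
            ):
                shared.best_score = score
                shared.best_params = snapshot
            if shared.global_step >= cfg.total_steps:
                return


def _worker(shared: _Shared, cfg: TrainingConfig, engine, worker_id: int) -> None:
    rng = np.random.default_rng([cfg.seed, 104729, worker_id])
    try:
        while True:
            with shared.lock:
                if shared.global_step >= cfg.total_steps or shared.error:
                    break
            _run_episode(shared, cfg, engine, rng)
            _maybe_validate(shared, cfg, engine)
    except BaseException as exc:  # propagate to the driver
        with shared.lock:
            shared.error = exc


def train(
    cfg: TrainingConfig,
    ts: TargetSet,
    engine: FoldEngine | None = None,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Full training run; returns the best checkpoint and the interval log.

    The best checkpoint is the snapshot with the lowest validation score
    across all intervals (the final parameters if validation never ran).
    Episode targets are drawn uniformly from the active curriculum phase;
    validation structures are never drawn.
    """
    engine = engine or get_engine(cfg.engine)
    rng_split = np.random.default_rng([cfg.seed, 15485863])
    split = curriculum_split(ts, cfg.n_validation, rng_split)
    if not split.phase2:
        raise ValueError("empty phase-2 pool: nothing to train on")
    params = NetworkParams.initialize(
        np.random.default_rng([cfg.seed, 32452843]),
        channels=cfg.channels,
        n_blocks=cfg.n_blocks,
        n_train=cfg.target_length,
    )
    opt = RMSProp(params, decay=cfg.rmsprop_decay, eps=cfg.rmsprop_eps)
    shared = _Shared(params, opt, split)

    if cfg.total_steps > 0:
        if cfg.n_workers == 1:
            _worker(shared, cfg, engine, 0)
        else:
            threads = [
                threading.Thread(
                    target=_worker, args=(shared, cfg, engine, i), daemon=True
                )
                for i in range(cfg.n_workers)
            ]
            for t in threads:
                t.start()
            for t in threads:
                t.join()
        if shared.error is not None:
            raise shared.error

    log = pd.DataFrame(shared.interval_records)
    # per-episode draw audit: (step at episode start, phase, target structure)
    log.attrs["episode_targets"] = list(shared.episode_targets)
    best = shared.best_params if shared.best_params is not None else shared.params
    return best, log
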
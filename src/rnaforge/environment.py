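"""The RNA-design reinforcement-learning environment.

A state is a candidate sequence for a fixed target structure, together with
the MFE fold of that sequence (refreshed once per step).  An action mutates
a single base; if the mutated base is paired in the *target* and the
resulting duo could not pair, the target partner is rewritten to the
Watson–Crick complement of the just-set base, so one action may change two
bases.  No-op actions (setting a base to its current type — 25% of the raw
N×4 action space) are masked out.  The reward is sparse and terminal: a
fixed positive reward when the fold first equals the target, 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold import (
    BASES,
    WATSON_CRICK,
    FoldEngine,
    PairMap,
    clean_sequence,
    is_legal_pair,
)

__all__ = [
    "Action",
    "RewardSpec",
    "DesignState",
    "random_sequence",
    "action_mask",
    "apply_action",
    "env_step",
    "reset",
]

BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Action:
    """Mutate ``position`` to ``new_base`` (must differ from the current base)."""

    position: int
    new_base: str


@dataclass(frozen=True)
class RewardSpec:
    """Sparse terminal reward: ``solve_reward`` on success, 0 otherwise."""

    solve_reward: float = 1.0
    step_reward: float = 0.0

    def __post_init__(self) -> None:
        if self.solve_reward <= 0:
            raise ValueError("solve_reward must be positive")
        if self.step_reward != 0:
            raise ValueError("non-solving transitions must yield exactly 0")


@dataclass(frozen=True)
class DesignState:
    """Immutable snapshot: target, candidate sequence, its fold, and progress."""

    target: PairMap
    sequence: str
    current_fold: PairMap
    steps_taken: int = 0

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.target) == len(self.current_fold)):
            raise ValueError("sequence, target and fold lengths differ")

    @property
    def solved(self) -> bool:
        return self.current_fold == self.target

    def __len__(self) -> int:
        return len(self.sequence)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. sequence over ACGU; reproducible under a fixed seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def action_mask(state: DesignState) -> np.ndarray:
    """N×4 boolean mask; entry (i, b) allowed iff base b differs from sequence[i].

    Exactly 3N of the 4N entries are allowed: the N no-op mutations are
    excluded so the policy cannot waste probability mass on them.
    """
    n = len(state)
    mask = np.ones((n, 4), dtype=bool)
    cols = np.fromiter((BASE_INDEX[c] for c in state.sequence), dtype=np.int64, count=n)
    mask[np.arange(n), cols] = False
    return mask


def apply_action(state: DesignState, action: Action, engine: FoldEngine) -> DesignState:
    """Apply a mutation, fixing the target partner if the duo could not pair.

    After setting ``sequence[position] := new_base``: if the target pairs
    ``position`` with ``j`` and ``{new_base, sequence[j]}`` is not one of
    GC, AU or GU, ``sequence[j]`` becomes the Watson–Crick complement of
    ``new_base`` (G→C, C→G, A→U, U→A), guaranteeing a GC or AU pair.  At
    most two positions change.  The fold of the new sequence is recomputed.
    """
    i = action.position
    b = action.new_base
    if not 0 <= i < len(state):
        raise ValueError(f"position {i} out of range for length {len(state)}")
    if b not in BASE_INDEX:
        raise ValueError(f"invalid base {b!r}")
    if state.sequence[i] == b:
        raise ValueError(
            f"no-op action at position {i} (base already {b}); "
            "no-op actions are masked and must not be applied"
        )
    seq = list(state.sequence)
    seq[i] = b
    j = int(state.target.partner[i])
    if j >= 0 and not is_legal_pair(b, seq[j]):
        seq[j] = WATSON_CRICK[b]
    new_seq = "".join(seq)
    fold = engine.fold(new_seq).structure
    return DesignState(
        target=state.target,
        sequence=new_seq,
        current_fold=fold,
        steps_taken=state.steps_taken + 1,
    )


def env_step(
    state: DesignState,
    action: Action,
    engine: FoldEngine,
    reward_spec: RewardSpec = RewardSpec(),
    step_cap: int = 400,
) -> tuple[DesignState, float, bool]:
    """One environment transition: ``(next_state, reward, done)``.

    Reward is ``solve_reward`` iff the refreshed fold equals the target;
    ``done`` on success or when the episode step cap is reached.
    """
    if state.solved:
        raise ValueError("cannot step a terminal (solved) state")
    if state.steps_taken >= step_cap:
        raise ValueError("cannot step a terminal (step-capped) state")
    nxt = apply_action(state, action, engine)
    solved = nxt.solved
    reward = reward_spec.solve_reward if solved else 0.0
    done = solved or nxt.steps_taken >= step_cap
    return nxt, reward, done


def reset(
    target: PairMap,
    rng: np.random.Generator,
    engine: FoldEngine,
    sequence: str | None = None,
) -> DesignState:
    """Fresh episode: a uniform-random initial sequence, folded once.

    A lucky start whose fold already equals the target is a terminal
    0-action solve (``state.solved`` is true immediately); callers that
    choose not to credit the initial evaluation simply step anyway.
    ``sequence`` overrides the random draw (tests, warm starts).
    """
    seq = clean_sequence(sequence) if sequence is not None else random_sequence(
        len(target), rng
    )
    fold = engine.fold(seq).structure
    return DesignState(target=target, sequence=seq, current_fold=fold)
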
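"""Length-agnostic graph-convolutional policy/value network.

The network maps a one-hot encoded candidate sequence (N×4, column order
A, C, G, U) to an N×4 matrix of mutation probabilities.  Structure enters
only through the *conv7* layer, a graph convolution whose seven inputs per
base are the five consecutive chain neighbours centred on the base, the
base's partner in the target structure, and its partner in the current
fold — so the receptive graph changes whenever the candidate refolds.
Missing neighbours (chain ends, unpaired bases) contribute zeros.

Architecture: one conv7 layer widening 4→80 channels, three residual
blocks ``y = x + conv1(conv7(x))``, a conv1 policy head (80→4) feeding a
masked softmax over the flattened N×4 action space, and — during training
only — a dense value head reading the flattened output of the last block
(its parameter count is the one length-specific part of the model).

Everything, including the backward pass used by the actor-critic trainer,
is implemented directly in NumPy; gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import json

import numpy as np

from .environment import Action, DesignState, action_mask
from .fold import BASES, PairMap, UNPAIRED

__all__ = [
    "MISSING",
    "N_NEIGHBORS",
    "one_hot_encode",
    "decode_one_hot",
    "build_neighbor_index",
    "conv1_apply",
    "conv7_apply",
    "residual_block_apply",
    "masked_softmax",
    "NetworkParams",
    "policy_forward",
    "forward_pass",
    "backward_pass",
    "sample_action",
]

#: Sentinel for a neighbour that does not exist.
MISSING = -1

#: conv7 gathers, per base i: chain offsets −2,−1,0,+1,+2, the target
#: partner, and the current-fold partner — in this fixed column order.
N_NEIGHBORS = 7

#: Checkpoint format constants.
FORMAT_VERSION = 1
DEFAULT_CHANNELS = 80
DEFAULT_BLOCKS = 3

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def one_hot_encode(seq: str) -> np.ndarray:
    """N×4 one-hot matrix of a sequence, column order (A, C, G, U)."""
    n = len(seq)
    out = np.zeros((n, 4))
    out[np.arange(n), [_BASE_INDEX[c] for c in seq]] = 1.0
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`."""
    return "".join(BASES[i] for i in np.argmax(mat, axis=1))


def build_neighbor_index(
    n: int, target: PairMap, current_fold: PairMap
) -> np.ndarray:
    """N×7 gather table for conv7.

    Row ``i`` is ``(i−2, i−1, i, i+1, i+2, target partner, fold partner)``
    with out-of-range offsets and unpaired partners replaced by
    :data:`MISSING`.
    """
    if len(target) != n or len(current_fold) != n:
        raise ValueError("target/current_fold length does not match n")
    idx = np.arange(n)
    cols = [idx + off for off in (-2, -1, 0, 1, 2)]
    cols = [np.where((c >= 0) & (c < n), c, MISSING) for c in cols]
    cols.append(np.where(target.partner != UNPAIRED, target.partner, MISSING))
    cols.append(
        np.where(current_fold.partner != UNPAIRED, current_fold.partner, MISSING)
    )
    return np.stack(cols, axis=1).astype(np.int64)


def _gather(x: np.ndarray, nbr: np.ndarray) -> np.ndarray:
    """(N, 7, C) neighbour features with zeros for MISSING entries."""
    safe = np.where(nbr >= 0, nbr, 0)
    g = x[safe]
    g[nbr < 0] = 0.0
    return g


def conv7_apply(
    w: np.ndarray, b: np.ndarray, x: np.ndarray, nbr: np.ndarray
) -> np.ndarray:
    """Graph convolution: per-base affine map of 7 gathered inputs, then ReLU.

    ``w`` has shape (7, C_in, C_out); missing neighbours contribute zero.
    """
    g = _gather(x, nbr)
    z = np.einsum("nkc,kcd->nd", g, w) + b
    return np.maximum(z, 0.0)


def conv1_apply(w: np.ndarray, b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-base linear map (no activation): ``out[i] = x[i] @ w + b``."""
    return x @ w + b


def residual_block_apply(
    w7: np.ndarray,
    b7: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    x: np.ndarray,
    nbr: np.ndarray,
) -> np.ndarray:
    """One residual block: ``y = x + conv1(conv7(x))``."""
    return x + conv1_apply(w1, b1, conv7_apply(w7, b7, x, nbr))


def masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Softmax over the flattened N×4 logits with masked entries forced to 0.

    Masked logits are set to −∞ before normalization, so disallowed
    (no-op) actions carry exactly zero probability and the rest sum to 1.
    """
    z = np.where(mask, logits, -np.inf)
    z = z - z.max()
    e = np.exp(z, where=mask, out=np.zeros_like(logits))
    return e / e.sum()


class NetworkParams:
    """All learnable weights, stored as a flat name→array mapping.

    Every component except the dense value head is independent of sequence
    length; the value head records its training length ``n_train`` and
    refuses other lengths.  Checkpoints (``.npz``) store the format
    version, channel width, block count, ``n_train`` and the column-order
    constants alongside the arrays.
    """

    def __init__(
        self,
        arrays: dict[str, np.ndarray],
        channels: int = DEFAULT_CHANNELS,
        n_blocks: int = DEFAULT_BLOCKS,
        n_train: int | None = None,
    ) -> None:
        self.arrays = arrays
        self.channels = int(channels)
        self.n_blocks = int(n_blocks)
        self.n_train = None if n_train is None else int(n_train)

    @property
    def has_value_head(self) -> bool:
        return "value.W" in self.arrays

    @classmethod
    def initialize(
        cls,
        rng: np.random.Generator,
        channels: int = DEFAULT_CHANNELS,
        n_blocks: int = DEFAULT_BLOCKS,
        n_train: int | None = None,
    ) -> "NetworkParams":
        """Variance-scaled (He) random initialization; biases start at zero."""
        c = channels
        a: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        a["input.W"] = he((N_NEIGHBORS, 4, c), N_NEIGHBORS * 4)
        a["input.b"] = np.zeros(c)
        for k in range(n_blocks):
            a[f"block{k}.conv7.W"] = he((N_NEIGHBORS, c, c), N_NEIGHBORS * c)
            a[f"block{k}.conv7.b"] = np.zeros(c)
            a[f"block{k}.conv1.W"] = he((c, c), c)
            a[f"block{k}.conv1.b"] = np.zeros(c)
        a["policy.W"] = he((c, 4), c)
        a["policy.b"] = np.zeros(4)
        if n_train is not None:
            a["value.W"] = he(n_train * c, n_train * c)
            a["value.b"] = np.zeros(())
        return cls(a, channels=c, n_blocks=n_blocks, n_train=n_train)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            {k: v.copy() for k, v in self.arrays.items()},
            channels=self.channels,
            n_blocks=self.n_blocks,
            n_train=self.n_train,
        )

    def without_value_head(self) -> "NetworkParams":
        """Inference checkpoint: drop the length-specific value head."""
        arrays = {
            k: v.copy() for k, v in self.arrays.items() if not k.startswith("value.")
        }
        return NetworkParams(
            arrays, channels=self.channels, n_blocks=self.n_blocks, n_train=None
        )

    def save(self, path) -> None:
        meta = {
            "format_version": FORMAT_VERSION,
            "channels": self.channels,
            "n_blocks": self.n_blocks,
            "n_train": self.n_train,
            "base_order": BASES,
            "neighbor_columns": "-2,-1,0,+1,+2,target_partner,fold_partner",
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **self.arrays)

    @classmethod
    def load(cls, path) -> "NetworkParams":
        try:
            with np.load(path) as data:
                meta = json.loads(bytes(data["__meta__"]).decode())
                arrays = {k: data[k] for k in data.files if k != "__meta__"}
        except Exception as exc:
            raise ValueError(f"corrupt or unreadable checkpoint {path!r}: {exc}") from exc
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta.get('format_version')!r}"
            )
        return cls(
            arrays,
            channels=meta["channels"],
            n_blocks=meta["n_blocks"],
            n_train=meta["n_train"],
        )


def forward_pass(
    params: NetworkParams,
    sequence: str,
    target: PairMap,
    current_fold: PairMap,
    want_value: bool = False,
) -> dict:
    """Run the network, keeping every intermediate needed by the backward pass.

    Returns a cache dict with ``logits`` (N×4) and, when requested,
    ``value`` (scalar).  The value head requires ``len(sequence)`` to equal
    the head's training length.
    """
    a = params.arrays
    n = len(sequence)
    x0 = one_hot_encode(sequence)
    nbr = build_neighbor_index(n, target, current_fold)

    cache: dict = {"nbr": nbr, "x0": x0}
    g0 = _gather(x0, nbr)
    z0 = np.einsum("nkc,kcd->nd", g0, a["input.W"]) + a["input.b"]
    h = np.maximum(z0, 0.0)
    cache["input"] = (g0, z0)

    for k in range(params.n_blocks):
        w7, b7 = a[f"block{k}.conv7.W"], a[f"block{k}.conv7.b"]
        w1, b1 = a[f"block{k}.conv1.W"], a[f"block{k}.conv1.b"]
        g = _gather(h, nbr)
        z = np.einsum("nkc,kcd->nd", g, w7) + b7
        h7 = np.maximum(z, 0.0)
        h = h + conv1_apply(w1, b1, h7)
        cache[f"block{k}"] = (g, z, h7)

    cache["h_final"] = h
    cache["logits"] = conv1_apply(a["policy.W"], a["policy.b"], h)

    if want_value:
        if not params.has_value_head:
            raise ValueError("checkpoint has no value head")
        if params.n_train != n:
            raise ValueError(
                f"value head was trained for length {params.n_train}, got {n}"
            )
        cache["value"] = float(a["value.W"] @ h.reshape(-1) + a["value.b"])
    return cache


def backward_pass(
    params: NetworkParams,
    cache: dict,
    dlogits: np.ndarray,
    dvalue: float | None = None,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter.

    ``dlogits`` is ∂loss/∂logits (N×4) and ``dvalue`` ∂loss/∂value; the
    caller derives both from the actor-critic objective.
    """
    a = params.arrays
    grads: dict[str, np.ndarray] = {}
    nbr = cache["nbr"]
    h = cache["h_final"]

    grads["policy.W"] = h.T @ dlogits
    grads["policy.b"] = dlogits.sum(axis=0)
    dh = dlogits @ a["policy.W"].T

    if dvalue is not None:
        grads["value.W"] = dvalue * h.reshape(-1)
        grads["value.b"] = np.asarray(float(dvalue))
        dh = dh + (dvalue * a["value.W"]).reshape(h.shape)

    for k in reversed(range(params.n_blocks)):
        g, z, h7 = cache[f"block{k}"]
        w7 = a[f"block{k}.conv7.W"]
        w1 = a[f"block{k}.conv1.W"]
        # conv1 branch
        grads[f"block{k}.conv1.W"] = h7.T @ dh
        grads[f"block{k}.conv1.b"] = dh.sum(axis=0)
        dh7 = dh @ w1.T
        # conv7 (ReLU then affine over gathered inputs)
        dz = dh7 * (z > 0.0)
        grads[f"block{k}.conv7.W"] = np.einsum("nkc,nd->kcd", g, dz)
        grads[f"block{k}.conv7.b"] = dz.sum(axis=0)
        dg = np.einsum("nd,kcd->nkc", dz, w7)
        dx = np.zeros_like(dh)
        valid = nbr >= 0
        np.add.at(dx, nbr[valid], dg[valid])
        dh = dh + dx  # residual skip + conv path

    g0, z0 = cache["input"]
    dz0 = dh * (z0 > 0.0)
    grads["input.W"] = np.einsum("nkc,nd->kcd", g0, dz0)
    grads["input.b"] = dz0.sum(axis=0)
    return grads


def policy_forward(
    params: NetworkParams, state: DesignState, want_value: bool = False
) -> tuple[np.ndarray, float | None]:
    """Masked action distribution (N×4) and optionally the value estimate.

    The policy path runs on any sequence length; the value estimate is
    produced only when a value head is present and the length matches its
    training length.
    """
    cache = forward_pass(
        params, state.sequence, state.target, state.current_fold, want_value
    )
    probs = masked_softmax(cache["logits"], action_mask(state))
    return probs, cache.get("value")


def sample_action(probs: np.ndarray, rng: np.random.Generator) -> Action:
    """Draw a mutation from an N×4 action distribution."""
    flat = probs.reshape(-1)
    total = flat.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate action distribution (all-zero)")
    k = int(rng.choice(flat.size, p=flat / total))
    return Action(position=k // 4, new_base=BASES[k % 4])
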
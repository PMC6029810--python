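"""Secondary-structure representation, dot-bracket I/O, and MFE fold engines.

The canonical in-memory form of a secondary structure is the :class:`PairMap`,
a partner table: entry ``i`` holds the 0-based index of the base paired with
``i``, or :data:`UNPAIRED`.  Structures are nested (pseudoknot-free) and obey
the minimum-hairpin rule of thermodynamic folders: a pair ``(i, j)`` encloses
at least three unpaired bases, i.e. ``j - i >= 4``.

Two fold engines implement a common contract (:class:`FoldEngine`):

* :class:`ViennaEngine` — the production Turner nearest-neighbour energy
  model via the ViennaRNA Python bindings, default parameters.
* :class:`NussinovEngine` — a self-contained maximum-base-pairing folder
  with a declared score of −1 kcal/mol per pair, used as a hermetic
  reference so the test suite does not depend on an external library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UNPAIRED",
    "BASES",
    "LEGAL_PAIRS",
    "WATSON_CRICK",
    "clean_sequence",
    "PairMap",
    "parse_dot_bracket",
    "to_dot_bracket",
    "FoldResult",
    "FoldEngine",
    "ViennaEngine",
    "NussinovEngine",
    "get_engine",
    "fold_mfe",
    "free_energy",
    "nussinov_fold",
    "find_hairpin_4loops",
]

#: Sentinel partner index for an unpaired base.
UNPAIRED = -1

#: Fixed base alphabet and one-hot column order.
BASES = "ACGU"

#: Legal pair types (unordered): Watson–Crick plus the GU wobble.
LEGAL_PAIRS = frozenset(
    {frozenset("AU"), frozenset("GC"), frozenset("GU")}
)

#: Watson–Crick complement used by the environment's pair-fixing rule.
WATSON_CRICK = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN_LOOP = 3


def clean_sequence(text: str) -> str:
    """Normalize an RNA sequence: uppercase, DNA ``T`` becomes ``U``.

    Raises
    ------
    ValueError
        If the result is empty or contains a character outside ``ACGU``.
    """
    seq = text.strip().upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(BASES)
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"invalid base {seq[pos]!r} at position {pos}; expected one of {BASES}"
        )
    return seq


def is_legal_pair(a: str, b: str) -> bool:
    """Unordered pair-type test: GC, AU or GU in either orientation."""
    return frozenset((a, b)) in LEGAL_PAIRS


class PairMap:
    """A nested secondary structure as a partner table.

    Parameters
    ----------
    partner : array-like of int
        ``partner[i]`` is the 0-based partner of base ``i`` or
        :data:`UNPAIRED`.

    The constructor validates symmetry, the no-self-pairing rule, the
    minimum hairpin loop (``|i - j| >= 4``) and nestedness.
    """

    __slots__ = ("partner",)

    def __init__(self, partner) -> None:
        arr = np.asarray(partner, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("partner table must be a non-empty 1-D array")
        self.partner = arr
        self._validate()
        self.partner.setflags(write=False)

    def _validate(self) -> None:
        p = self.partner
        n = len(p)
        paired = p != UNPAIRED
        idx = np.nonzero(paired)[0]
        if ((p[idx] < 0) | (p[idx] >= n)).any():
            raise ValueError("partner index out of range")
        if (p[p[idx]] != idx).any():
            raise ValueError("partner table is not symmetric")
        if (p[idx] == idx).any():
            raise ValueError("base paired with itself")
        if (np.abs(p[idx] - idx) < MIN_HAIRPIN_LOOP + 1).any():
            i = idx[np.abs(p[idx] - idx) < MIN_HAIRPIN_LOOP + 1][0]
            raise ValueError(
                f"pair ({i},{p[i]}) violates the minimum hairpin loop "
                f"({MIN_HAIRPIN_LOOP} unpaired bases)"
            )
        # nestedness: (i,j), (k,l) with i<k<j<l is a crossing
        opened: list[int] = []
        for i in range(n):
            j = p[i]
            if j == UNPAIRED:
                continue
            if j > i:
                opened.append(j)
            else:
                if not opened or opened[-1] != i:
                    raise ValueError(
                        f"crossing (pseudoknotted) pair ({j},{i})"
                    )
                opened.pop()

    def __len__(self) -> int:
        return len(self.partner)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairMap):
            return NotImplemented
        return np.array_equal(self.partner, other.partner)

    def __hash__(self) -> int:
        return hash(self.partner.tobytes())

    def __repr__(self) -> str:
        return f"PairMap({self.to_dot_bracket()!r})"

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """All pairs ``(i, j)`` with ``i < j``, ascending in ``i``."""
        return [
            (int(i), int(j))
            for i, j in enumerate(self.partner)
            if j != UNPAIRED and j > i
        ]

    @classmethod
    def from_pairs(cls, n: int, pairs) -> "PairMap":
        partner = np.full(n, UNPAIRED, dtype=np.int64)
        for i, j in pairs:
            partner[i], partner[j] = j, i
        return cls(partner)

    def to_dot_bracket(self) -> str:
        return to_dot_bracket(self)


def parse_dot_bracket(text: str) -> PairMap:
    """Parse a Vienna dot-bracket string into a :class:`PairMap`.

    Only ``.``, ``(`` and ``)`` are accepted; crossing pairs cannot be
    expressed with a single bracket type, so any balanced input is nested.

    Raises
    ------
    ValueError
        On a foreign character, an unmatched bracket (the error names the
        offending position), or a hairpin loop shorter than three bases.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty structure string")
    partner = np.full(len(text), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(text):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unmatched ')' at position {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(
                f"invalid character {c!r} at position {i}; expected '.', '(' or ')'"
            )
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[0]}")
    return PairMap(partner)


def to_dot_bracket(pm: PairMap) -> str:
    """Encode a :class:`PairMap` as a dot-bracket string (inverse of parse)."""
    out = []
    for i, j in enumerate(pm.partner):
        if j == UNPAIRED:
            out.append(".")
        else:
            out.append("(" if j > i else ")")
    return "".join(out)


@dataclass(frozen=True)
class FoldResult:
    """MFE prediction: the single best structure and its free energy (kcal/mol)."""

    structure: PairMap
    energy: float


class FoldEngine:
    """Contract for MFE fold predictors.

    An engine returns exactly one minimum-free-energy structure per
    sequence (no suboptimal ensemble) and is deterministic for a fixed
    engine, version and input.
    """

    name: str = "abstract"

    def fold(self, seq: str) -> FoldResult:
        raise NotImplementedError

    def energy(self, seq: str, pm: PairMap) -> float:
        """Free energy of ``seq`` constrained to structure ``pm``."""
        raise NotImplementedError

    def _check_structure(self, seq: str, pm: PairMap) -> None:
        if len(seq) != len(pm):
            raise ValueError(
                f"sequence length {len(seq)} != structure length {len(pm)}"
            )
        for i, j in pm.pairs:
            if not is_legal_pair(seq[i], seq[j]):
                raise ValueError(
                    f"illegal pair {seq[i]}-{seq[j]} at positions ({i},{j})"
                )


class ViennaEngine(FoldEngine):
    """Turner nearest-neighbour energy model via ViennaRNA, default parameters."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - depends on install
            raise ImportError(
                "ViennaRNA Python bindings are not available; install the "
                "'viennarna' package or select the hermetic reference engine "
                "with get_engine('nussinov')"
            ) from exc
        self._rna = RNA

    def fold(self, seq: str) -> FoldResult:
        seq = clean_sequence(seq)
        db, energy = self._rna.fold(seq)
        return FoldResult(parse_dot_bracket(db), float(energy))

    def energy(self, seq: str, pm: PairMap) -> float:
        seq = clean_sequence(seq)
        self._check_structure(seq, pm)
        return float(self._rna.energy_of_struct(seq, pm.to_dot_bracket()))


class NussinovEngine(FoldEngine):
    """Maximum-base-pairing folder with a declared score of −1 kcal/mol per pair.

    A hermetic stand-in energy model: legal pairs are AU, GC and GU
    (unordered), the minimum hairpin loop is ``min_loop`` unpaired bases,
    and the reported free energy is minus the pair count.  Ties in the
    dynamic program are broken deterministically: leaving base ``i``
    unpaired is preferred at equal score, then the smallest partner ``j``.
    """

    name = "nussinov"

    def __init__(self, min_loop: int = MIN_HAIRPIN_LOOP) -> None:
        self.min_loop = int(min_loop)

    def fold(self, seq: str) -> FoldResult:
        pm = nussinov_fold(seq, self.min_loop)
        return FoldResult(pm, -float(len(pm.pairs)))

    def energy(self, seq: str, pm: PairMap) -> float:
        seq = clean_sequence(seq)
        self._check_structure(seq, pm)
        return -float(len(pm.pairs))


def nussinov_fold(seq: str, min_loop: int = MIN_HAIRPIN_LOOP) -> PairMap:
    """Nested structure maximizing the number of legal pairs.

    Dynamic program over intervals; ``best[i][j]`` is the maximum pair
    count on ``seq[i..j]``.  Traceback prefers leaving ``i`` unpaired at
    equal score, and otherwise pairs ``i`` with the smallest optimal ``j``.
    """
    seq = clean_sequence(seq)
    n = len(seq)
    best = np.zeros((n + 1, n + 1), dtype=np.int64)  # best[i][j], j exclusive

    def pairable(i: int, j: int) -> bool:
        return is_legal_pair(seq[i], seq[j])

    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # exclusive end
            score = best[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j):
                if pairable(i, k):
                    cand = 1 + best[i + 1][k] + best[k + 1][j]
                    if cand > score:
                        score = cand
            best[i][j] = score

    partner = np.full(n, UNPAIRED, dtype=np.int64)
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        if best[i][j] == best[i + 1][j]:  # i unpaired preferred
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j):
            if pairable(i, k) and best[i][j] == 1 + best[i + 1][k] + best[k + 1][j]:
                partner[i], partner[k] = k, i
                stack.append((i + 1, k))
                stack.append((k + 1, j))
                break
    return PairMap(partner)


_ENGINES = {"vienna": ViennaEngine, "nussinov": NussinovEngine}


def get_engine(name: str = "vienna") -> FoldEngine:
    """Instantiate a fold engine by name (``'vienna'`` or ``'nussinov'``)."""
    try:
        cls = _ENGINES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown engine {name!r}; choose from {sorted(_ENGINES)}"
        ) from None
    return cls()


def fold_mfe(seq: str, engine: FoldEngine) -> FoldResult:
    """Predict the single MFE structure of ``seq`` under ``engine``."""
    return engine.fold(seq)


def free_energy(seq: str, pm: PairMap, engine: FoldEngine) -> float:
    """Free energy (kcal/mol) of ``seq`` constrained to structure ``pm``."""
    return engine.energy(seq, pm)


def find_hairpin_4loops(pm: PairMap) -> list[tuple[tuple[int, int], list[int]]]:
    """Locate hairpin 4-loops: pairs ``(i, i+5)`` enclosing four unpaired bases.

    Returns ``(closing_pair, loop_positions)`` records with the loop listed
    5'→3'.  These are the loops Eterna players "boost" by placing a G at the
    5'-most loop position.
    """
    out = []
    p = pm.partner
    for i, j in pm.pairs:
        if j == i + 5 and all(p[k] == UNPAIRED for k in range(i + 1, j)):
            out.append(((i, j), list(range(i + 1, j))))
    return out
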
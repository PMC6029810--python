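"""Inference-time solving, benchmarking, and solution analyses.

Solving rolls out the trained stochastic policy from a fresh random
sequence until the candidate's MFE fold equals the target; a benchmark run
applies the same protocol to a puzzle file (Eterna100-style CSV) with a
configurable attempt count and wall limit per attempt.  Two analyses probe
what the agent learned:

* the boost survey — across solved structures containing hairpin 4-loops,
  how often the 5'-most loop base is a G (the Eterna "boost"), and how
  much forcing that G changes the free energy of the solution on its
  target;
* the base-pair perturbation scan — for each designed pair, swap the two
  bases or rewrite the pair as GC and check whether the sequence still
  folds to the target.
"""

from __future__ import annotations

import csv
import logging
import math
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import RewardSpec, env_step, reset
from .fold import (
    FoldEngine,
    PairMap,
    find_hairpin_4loops,
    free_energy,
    parse_dot_bracket,
)
from .network import NetworkParams, policy_forward, sample_action

__all__ = [
    "SolveResult",
    "BoostSurveyResult",
    "solve",
    "run_benchmark",
    "read_puzzles",
    "write_solutions",
    "read_solutions",
    "boost_survey",
    "pair_perturbation_scan",
]

logger = logging.getLogger(__name__)

SOLUTION_COLUMNS = ["name", "structure", "solved", "sequence", "steps", "seconds", "attempt"]


@dataclass(frozen=True)
class SolveResult:
    """Outcome of solving one target (possibly over several attempts)."""

    name: str
    solved: bool
    sequence: str  # empty when unsolved
    steps: int
    seconds: float
    attempt: int  # 1-based index of the successful (or last) attempt


def solve(
    params: NetworkParams,
    target: PairMap,
    engine: FoldEngine,
    rng: np.random.Generator,
    max_steps: int = 10_000,
    wall_limit: float | None = None,
    attempts: int = 1,
    name: str = "target",
    greedy: bool = False,
    evaluate_initial: bool = True,
) -> SolveResult:
    """Design a sequence folding to ``target`` with the trained policy.

    Each attempt starts from a fresh uniform-random sequence and samples
    mutations from the policy until the fold matches the target, or
    ``max_steps`` / ``wall_limit`` (seconds, per attempt) runs out.  A
    success is re-verified with an independent fold call before being
    reported.  ``greedy`` switches to argmax action selection (an extra
    mode, not part of the published protocol).
    """
    t0 = time.monotonic()
    last = SolveResult(name, False, "", 0, 0.0, attempts)
    for attempt in range(1, attempts + 1):
        attempt_t0 = time.monotonic()
        state = reset(target, rng, engine)
        steps = 0
        solved = evaluate_initial and state.solved
        while not solved and steps < max_steps:
            if wall_limit is not None and time.monotonic() - attempt_t0 > wall_limit:
                break
            probs, _ = policy_forward(params, state)
            if greedy:
                k = int(np.argmax(probs))
                from .environment import Action
                from .fold import BASES

                action = Action(k // 4, BASES[k % 4])
            else:
                action = sample_action(probs, rng)
            state, _, done = env_step(
                state, action, engine, RewardSpec(), step_cap=max_steps
            )
            steps += 1
            solved = state.solved
            if done:
                break
        elapsed = time.monotonic() - t0
        if solved and engine.fold(state.sequence).structure == target:
            return SolveResult(name, True, state.sequence, steps, elapsed, attempt)
        last = SolveResult(name, False, "", steps, elapsed, attempt)
    return last


def read_puzzles(path, on_error: str = "raise") -> list[tuple[str, PairMap | None, str | None]]:
    """Load named targets from a puzzle file.

    Two formats are accepted: a CSV with header ``name,structure`` and a
    FASTA-like layout of ``>name`` lines each followed by a dot-bracket
    line.  Every structure is validated by the dot-bracket parser; with
    ``on_error='raise'`` a bad row aborts with its row number, with
    ``'record'`` it yields ``(name, None, message)``.
    """
    if on_error not in ("raise", "record"):
        raise ValueError("on_error must be 'raise' or 'record'")
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    if lines[0].startswith(">"):
        name = None
        for lineno, ln in enumerate(lines, 1):
            if ln.startswith(">"):
                name = ln[1:].strip()
            elif name is None:
                raise ValueError(f"line {lineno}: structure before any '>' name line")
            else:
                rows.append((name, ln, lineno))
                name = None
    else:
        reader = csv.DictReader(text.splitlines())
        if reader.fieldnames is None or "structure" not in reader.fieldnames:
            raise ValueError("puzzle CSV must have a 'name,structure' header")
        for lineno, row in enumerate(reader, 2):
            rows.append((row.get("name") or f"row{lineno}", row["structure"], lineno))
    out = []
    for name, struct, lineno in rows:
        try:
            out.append((name, parse_dot_bracket(struct), None))
        except ValueError as exc:
            msg = f"row {lineno} ({name}): {exc}"
            if on_error == "raise":
                raise ValueError(msg) from None
            logger.warning("skipping malformed puzzle: %s", msg)
            out.append((name, None, str(exc)))
    return out


def write_solutions(results: list[tuple[SolveResult, str]], path) -> None:
    """Write a solutions CSV (one row per puzzle, unsolved rows blank-sequence)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SOLUTION_COLUMNS)
        for res, structure in results:
            w.writerow(
                [
                    res.name,
                    structure,
                    res.solved,
                    res.sequence if res.solved else "",
                    res.steps,
                    f"{res.seconds:.3f}",
                    res.attempt,
                ]
            )


def read_solutions(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"name": str, "structure": str, "sequence": str}, keep_default_na=False
    )
    missing = set(SOLUTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"solutions file lacks columns: {sorted(missing)}")
    df["solved"] = df["solved"].astype(str).str.lower().isin(("true", "1"))
    return df


def run_benchmark(
    params: NetworkParams,
    puzzle_path,
    engine: FoldEngine,
    out_path,
    seed: int = 0,
    attempts: int = 5,
    wall_limit: float | None = 86_400.0,
    max_steps: int = 10_000_000,
    resume: bool = True,
) -> pd.DataFrame:
    """Solve every puzzle in a file and write a results CSV.

    Rows keep the input order; each puzzle gets its own deterministic
    random stream derived from ``seed`` and its position, so an
    interrupted run rerun with ``resume`` (which skips names already in
    the output file) produces the identical final file.  Defaults mirror
    the published protocol of five attempts of 24 hours each.
    """
    puzzles = read_puzzles(puzzle_path, on_error="record")
    done: dict[str, dict] = {}
    if resume:
        try:
            prev = read_solutions(out_path)
            done = {r["name"]: r for _, r in prev.iterrows()}
        except (FileNotFoundError, ValueError):
            done = {}
    rows: list[tuple[SolveResult, str]] = []
    for idx, (name, target, err) in enumerate(puzzles):
        if err is not None:
            rows.append((SolveResult(name, False, "", 0, 0.0, 0), "ERROR: " + err))
            continue
        structure = target.to_dot_bracket()
        if name in done:
            r = done[name]
            rows.append(
                (
                    SolveResult(
                        name, bool(r["solved"]), r["sequence"], int(r["steps"]),
                        float(r["seconds"]), int(r["attempt"]),
                    ),
                    structure,
                )
            )
            continue
        rng = np.random.default_rng([seed, 15551, idx])
        rows.append(
            (
                solve(
                    params, target, engine, rng,
                    max_steps=max_steps, wall_limit=wall_limit,
                    attempts=attempts, name=name,
                ),
                structure,
            )
        )
    write_solutions(rows, out_path)
    df = read_solutions(out_path)
    n_ok = int(df["solved"].sum())
    logger.info("benchmark: solved %d/%d puzzles", n_ok, len(df))
    return df


@dataclass
class BoostSurveyResult:
    """Per-4-loop records plus aggregates recomputable from them.

    ``records`` columns: ``structure``, ``closing_i``, ``closing_j``,
    ``boost_position`` (the 5'-most loop base), ``base``, ``ddg``
    (kcal/mol; NaN where the base is already G).  ``ineligible`` counts
    input structures containing no hairpin 4-loop.
    """

    records: pd.DataFrame
    ineligible: int

    def aggregate(self) -> dict:
        rec = self.records
        n = len(rec)
        n_g = int((rec["base"] == "G").sum()) if n else 0
        ddg = rec["ddg"].dropna()
        return {
            "n_loops": n,
            "n_boosted": n_g,
            "fraction_g": n_g / n if n else math.nan,
            "ddg_mean": float(ddg.mean()) if len(ddg) else math.nan,
            "ddg_sd": float(ddg.std(ddof=1)) if len(ddg) > 1 else math.nan,
            "fraction_stabilizing": float((ddg < 0).mean()) if len(ddg) else math.nan,
            "ineligible": self.ineligible,
        }


def boost_survey(
    solutions: list[tuple[str, PairMap]], engine: FoldEngine
) -> BoostSurveyResult:
    """Survey boosting across solved structures with hairpin 4-loops.

    For every 4-loop of every target: record the base the solution places
    at the boost position (closing-pair 5' index + 1).  Where that base is
    not already G, force it to G and record
    ``ΔΔG = E(boosted | target) − E(original | target)``; negative values
    mean the boost stabilizes the design.
    """
    records = []
    ineligible = 0
    for seq, target in solutions:
        if engine.fold(seq).structure != target:
            raise ValueError("solution sequence does not fold to its target")
        loops = find_hairpin_4loops(target)
        if not loops:
            ineligible += 1
            continue
        for (i, j), loop_positions in loops:
            pos = loop_positions[0]  # 5'-most unpaired base of the loop
            base = seq[pos]
            ddg = math.nan
            if base != "G":
                boosted = seq[:pos] + "G" + seq[pos + 1 :]
                ddg = free_energy(boosted, target, engine) - free_energy(
                    seq, target, engine
                )
            records.append(
                {
                    "structure": target.to_dot_bracket(),
                    "closing_i": i,
                    "closing_j": j,
                    "boost_position": pos,
                    "base": base,
                    "ddg": ddg,
                }
            )
    columns = ["structure", "closing_i", "closing_j", "boost_position", "base", "ddg"]
    return BoostSurveyResult(
        records=pd.DataFrame(records, columns=columns), ineligible=ineligible
    )


def pair_perturbation_scan(
    sequence: str, target: PairMap, engine: FoldEngine
) -> list[tuple[int, int]]:
    """Pairs of a solution that survive both standard design perturbations.

    For each target pair ``(i, j)``: variant 1 swaps the two bases,
    variant 2 rewrites the pair as G (5') and C (3').  The pair is robust
    iff **both** variants still fold exactly to the target.  Returns
    robust pairs ascending in ``i``.
    """
    if engine.fold(sequence).structure != target:
        raise ValueError("sequence does not fold to the target structure")
    robust = []
    for i, j in target.pairs:
        seq = list(sequence)
        seq[i], seq[j] = seq[j], seq[i]
        swapped = "".join(seq)
        seq = list(sequence)
        seq[i], seq[j] = "G", "C"
        gc = "".join(seq)
        if (
            engine.fold(swapped).structure == target
            and engine.fold(gc).structure == target
        ):
            robust.append((i, j))
    return robust
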
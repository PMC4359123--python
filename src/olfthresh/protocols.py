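"""Simulated administration of threshold-test protocols.

Two protocol families are implemented:

* **Method of constant stimuli** — every subject receives the same fixed
  multiset of dilution steps (repeats allowed); one 3AFC response is
  drawn per presentation.
* **Single staircase** (Sniffin' Sticks rules) — the test starts at one
  of the two weakest pens (15 or 16, chosen at random).  A correct
  response triggers a confirmation presentation of the same step; two
  consecutive corrects at a step move the test one step weaker; any
  incorrect response moves it one step stronger.  Each change of
  movement direction is a *reversal*; the run stops after a fixed number
  of reversals (default 7) and is scored as the mean of the steps at the
  last 4 reversals.

Reversal bookkeeping (the sources describing the test do not pin this
down, so it is a declared convention here): the first movement
establishes a direction without logging a reversal; a reversal is logged
at the step being presented when the direction flips.

By default the simulated staircase walks an *unlimited* virtual dilution
series: a subject whose threshold lies beyond the physical pens keeps
moving past step 1 or 16 instead of bouncing against the end of the
range, so the estimated reliability reflects the staircase rules rather
than range censoring.  Set ``clamp=True`` to emulate the physical 16-pen
administration: an incorrect response at the strongest pen then
re-presents that pen (the repeated presentation does not itself create a
reversal), two consecutive corrects at the weakest pen re-present it,
and scores are confined to the pen range (the familiar ceiling at pen
16).  Runs that hit the presentation cap are flagged censored and carry
a capped score (mean of whatever reversals exist, else the final step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .scale import GUESS_FLOOR

__all__ = [
    "ConstantStimuliProtocol",
    "StaircaseProtocol",
    "StaircaseRun",
    "CensoredRunError",
    "NSHAP_STEPS",
    "simulate_constant_stimuli",
    "simulate_staircase",
    "replay_staircase",
    "score_staircase",
    "staircase_scores",
]

#: NSHAP Wave-2 dilution steps, administered weakest to strongest.
NSHAP_STEPS = (6, 5, 4, 2, 1, 0)


class CensoredRunError(ValueError):
    """Raised when a staircase run has too few reversals to score."""


@dataclass(frozen=True)
class ConstantStimuliProtocol:
    """Fixed stimulus set given identically to every subject.

    ``order_policy`` may be ``"as_given"`` or ``"random_per_subject"``;
    under the response model order carries no information (no
    habituation or learning), so it only affects presentation metadata.
    ``target_positions`` optionally records, per presentation, which of
    the three pens holds the odorant (administrative metadata only).
    """

    steps: tuple
    order_policy: str = "as_given"
    target_positions: tuple | None = None

    def __post_init__(self):
        steps = tuple(float(s) for s in self.steps)
        if len(steps) == 0:
            raise ValueError("protocol must contain at least one dilution step")
        if not all(math.isfinite(s) for s in steps):
            raise ValueError("all dilution steps must be finite")
        if self.order_policy not in ("as_given", "random_per_subject"):
            raise ValueError(f"unknown order_policy {self.order_policy!r}")
        if self.target_positions is not None:
            tp = tuple(int(p) for p in self.target_positions)
            if len(tp) != len(steps) or not all(p in (1, 2, 3) for p in tp):
                raise ValueError("target_positions must give one value in {1,2,3} "
                                 "per presentation")
            object.__setattr__(self, "target_positions", tp)
        object.__setattr__(self, "steps", steps)

    @property
    def n_presentations(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class StaircaseProtocol:
    """Single-staircase rules on a contiguous integer step range.

    ``step_min``/``step_max`` describe the physical pen range; with
    ``clamp=False`` (default) the simulated walk may leave that range
    (virtual pens), with ``clamp=True`` it is confined to it.
    """

    step_min: int = 1
    step_max: int = 16
    start_steps: tuple = (15, 16)
    reversals_to_stop: int = 7
    reversals_to_score: int = 4
    max_presentations: int = 200
    clamp: bool = False

    def __post_init__(self):
        if self.step_min >= self.step_max:
            raise ValueError("step_min must be below step_max")
        if not all(self.step_min <= s <= self.step_max for s in self.start_steps):
            raise ValueError("start steps must lie inside the step range")
        if self.reversals_to_score > self.reversals_to_stop:
            raise ValueError("cannot score more reversals than the stopping count")


@dataclass
class StaircaseRun:
    """One simulated staircase administration."""

    presentations: list = field(default_factory=list)  # (step, response) pairs
    reversal_steps: list = field(default_factory=list)
    terminated_by: str = "reversals"  # or "cap"
    score: float = math.nan
    censored: bool = False


def simulate_constant_stimuli(thresholds, pop_beta, protocol: ConstantStimuliProtocol,
                              seed):
    """Simulate a constant-stimuli administration.

    Returns a pandas DataFrame with columns ``subject_id``,
    ``presentation_index``, ``dilution_step``, ``response`` (1/0) and,
    when the protocol defines a target-position schedule,
    ``target_position``.
    """
    import pandas as pd

    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    if not pop_beta > 0:
        raise ValueError("pop_beta must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = thresholds.size
    steps = np.asarray(protocol.steps, dtype=float)
    m = steps.size
    step_matrix = np.broadcast_to(steps, (n, m)).copy()
    if protocol.order_policy == "random_per_subject":
        perm = rng.permuted(np.tile(np.arange(m), (n, 1)), axis=1)
        step_matrix = np.take_along_axis(step_matrix, perm, axis=1)

    p = GUESS_FLOOR + (2.0 / 3.0) * expit(
        pop_beta * (thresholds[:, None] - step_matrix))
    y = (rng.random((n, m)) < p).astype(np.int8)

    out = pd.DataFrame({
        "subject_id": np.repeat(np.arange(n), m),
        "presentation_index": np.tile(np.arange(m), n),
        "dilution_step": step_matrix.ravel(),
        "response": y.ravel(),
    })
    if protocol.target_positions is not None and protocol.order_policy == "as_given":
        out["target_position"] = np.tile(
            np.asarray(protocol.target_positions, dtype=np.int8), n)
    return out


def _run_staircase(responder, start_step: int, protocol: StaircaseProtocol) -> StaircaseRun:
    """Drive the staircase with ``responder(step, k) -> bool`` for the k-th presentation."""
    run = StaircaseRun()
    d = int(start_step)
    direction = 0          # +1 moving weaker, -1 moving stronger, 0 undetermined
    consec = 0
    for k in range(protocol.max_presentations):
        correct = bool(responder(d, k))
        run.presentations.append((d, int(correct)))
        if correct:
            consec += 1
            if consec < 2:
                continue  # confirmation presentation of the same step
            # pair complete: move weaker
            consec = 0
            if direction == -1:
                run.reversal_steps.append(d)
                if len(run.reversal_steps) >= protocol.reversals_to_stop:
                    direction = +1
                    break
            direction = +1
            if not (protocol.clamp and d >= protocol.step_max):
                d += 1
        else:
            consec = 0
            if direction == +1:
                run.reversal_steps.append(d)
                if len(run.reversal_steps) >= protocol.reversals_to_stop:
                    direction = -1
                    break
            direction = -1
            if not (protocol.clamp and d <= protocol.step_min):
                d -= 1

    if len(run.reversal_steps) >= protocol.reversals_to_stop:
        run.terminated_by = "reversals"
        run.score = float(np.mean(run.reversal_steps[-protocol.reversals_to_score:]))
    else:
        run.terminated_by = "cap"
        run.censored = True
        if run.reversal_steps:
            tail = run.reversal_steps[-protocol.reversals_to_score:]
            run.score = float(np.mean(tail))
        else:
            run.score = float(run.presentations[-1][0])
    return run


def simulate_staircase(thresholds, pop_beta, protocol: StaircaseProtocol = None,
                       seed=None):
    """Simulate one staircase run per subject; returns a list of StaircaseRun."""
    if protocol is None:
        protocol = StaircaseProtocol()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    if not pop_beta > 0:
        raise ValueError("pop_beta must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    starts = rng.choice(protocol.start_steps, size=thresholds.size)
    runs = []
    beta = float(pop_beta)
    for t, start in zip(thresholds, starts):
        u = rng.random(protocol.max_presentations)

        def responder(d, k, _t=float(t), _u=u):
            p = GUESS_FLOOR + (2.0 / 3.0) / (1.0 + math.exp(-beta * (_t - d)))
            return _u[k] < p

        runs.append(_run_staircase(responder, start, protocol))
    return runs


def replay_staircase(responses, start_step: int,
                     protocol: StaircaseProtocol = None) -> StaircaseRun:
    """Apply the staircase rules to a scripted 0/1 response sequence.

    Useful for hand-traced verification and deterministic fixtures.  The
    sequence is consumed in order; the run may terminate before it is
    exhausted.
    """
    if protocol is None:
        protocol = StaircaseProtocol()
    responses = [int(r) for r in responses]

    def responder(d, k):
        if k >= len(responses):
            raise IndexError("scripted response sequence exhausted")
        return responses[k]

    return _run_staircase(responder, start_step, protocol)


def score_staircase(run: StaircaseRun, protocol: StaircaseProtocol = None) -> float:
    """Standard score: mean of the last ``reversals_to_score`` reversal steps.

    Raises :class:`CensoredRunError` when the run has fewer reversals
    than required (e.g. terminated by the presentation cap).
    """
    if protocol is None:
        protocol = StaircaseProtocol()
    if len(run.reversal_steps) < protocol.reversals_to_score:
        raise CensoredRunError(
            f"run has {len(run.reversal_steps)} reversals; "
            f"{protocol.reversals_to_score} required to score")
    return float(np.mean(run.reversal_steps[-protocol.reversals_to_score:]))


def staircase_scores(runs) -> np.ndarray:
    """Scores of a list of runs, censored runs contributing their capped score."""
    return np.array([r.score for r in runs], dtype=float)


def runs_to_table(runs):
    """Full response histories of staircase runs as a response DataFrame.

    Enables IRT fitting of staircase data using every presentation
    (including confirmation presentations), not just the last reversals.
    """
    import pandas as pd

    sid, idx, step, resp = [], [], [], []
    for i, run in enumerate(runs):
        for j, (d, y) in enumerate(run.presentations):
            sid.append(i)
            idx.append(j)
            step.append(float(d))
            resp.append(int(y))
    return pd.DataFrame({
        "subject_id": sid,
        "presentation_index": idx,
        "dilution_step": step,
        "response": np.asarray(resp, dtype=np.int8),
    })
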
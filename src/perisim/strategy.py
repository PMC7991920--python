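"""Double-crossover threshold staircases and the anchor-then-propagate plan.

Each location's threshold is bracketed by an adaptive staircase: the
stimulus starts at a configurable level, steps 4 dB dimmer after each
"seen" and 4 dB brighter after each "not seen"; the first response
reversal (a *crossing*) halves the step to 2 dB, and the second crossing
finishes the staircase.  The threshold estimate is the last level the
observer reported seeing.  Levels clamp to the reportable [0, 49] dB
range; two consecutive misses at 0 dB terminate the run floored
(estimate 0), two consecutive hits at 49 dB terminate it ceilinged
(estimate 49).

A test plan runs the four anchor locations (one per quadrant) first,
from a fixed start level; every other location unlocks once at least one
of its lattice neighbors has finished and starts at the estimate of its
nearest finished neighbor, so established thresholds propagate outward
across the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import DB_MAX, DB_MIN
from .errors import (
    DomainError,
    ExhaustedStaircaseError,
    IncompleteStaircaseError,
)
from .observer import Observer, respond
from .patterns import Eye, TestPattern, neighbors

STEP_COARSE = 4
STEP_FINE = 2
DEFAULT_START_LEVEL = 25


def _clamp(level: float) -> int:
    return int(min(max(level, DB_MIN), DB_MAX))


@dataclass
class StaircaseState:
    """Mutable per-location staircase state."""

    location_id: int
    current_level: int
    step: int = STEP_COARSE
    crossings: int = 0
    history: list[tuple[int, bool]] = field(default_factory=list)
    last_seen_level: int | None = None
    finished: bool = False
    floored: bool = False
    ceilinged: bool = False


def init_staircase(location_id: int, start_level: int = DEFAULT_START_LEVEL) -> StaircaseState:
    if not (DB_MIN <= start_level <= DB_MAX):
        raise DomainError(f"start level {start_level} outside [{DB_MIN}, {DB_MAX}]")
    return StaircaseState(location_id=location_id, current_level=int(start_level))


def next_level(state: StaircaseState) -> int:
    """The dB level of the next presentation."""
    if state.finished:
        raise ExhaustedStaircaseError(f"staircase at location {state.location_id} finished")
    return state.current_level


def record_response(state: StaircaseState, seen: bool) -> StaircaseState:
    """Advance the staircase by one presentation at ``current_level``.

    A crossing is any response differing from the immediately preceding
    one; the first presentation cannot be a crossing.  Mutates and
    returns ``state``.
    """
    if state.finished:
        raise ExhaustedStaircaseError(f"staircase at location {state.location_id} finished")
    level = state.current_level
    prev = state.history[-1] if state.history else None
    state.history.append((level, seen))
    if seen:
        state.last_seen_level = level

    if prev is not None and prev[1] != seen:
        state.crossings += 1
        if state.crossings == 1:
            state.step = STEP_FINE
        if state.crossings >= 2:
            state.finished = True
            return state

    # bound terminations: two consecutive identical responses pinned at a clamp
    if prev is not None and prev == (level, seen):
        if level == DB_MIN and not seen:
            state.finished = True
            state.floored = True
            return state
        if level == DB_MAX and seen:
            state.finished = True
            state.ceilinged = True
            return state

    state.current_level = _clamp(level + state.step if seen else level - state.step)
    return state


def estimate(state: StaircaseState) -> int:
    """Threshold estimate of a finished staircase: the last seen level."""
    if not state.finished:
        raise IncompleteStaircaseError(
            f"staircase at location {state.location_id} not finished"
        )
    if state.last_seen_level is None:
        state.floored = True
        return 0
    return state.last_seen_level


@dataclass
class TestPlan:
    """Anchor-first plan over (location, eye) pairs with neighbor seeding."""

    patterns: dict[Eye, TestPattern]
    seeding_default: int = DEFAULT_START_LEVEL
    states: dict[tuple[Eye, int], StaircaseState] = field(default_factory=dict)

    @property
    def pairs(self) -> list[tuple[Eye, int]]:
        return [(eye, loc.id) for eye, pat in self.patterns.items() for loc in pat.locations]

    def is_anchor(self, eye: Eye, loc_id: int) -> bool:
        return loc_id in self.patterns[eye].anchor_ids

    def _finished_ids(self, eye: Eye) -> set[int]:
        return {
            lid for (e, lid), st in self.states.items() if e == eye and st.finished
        }

    def seed_level(self, eye: Eye, loc_id: int) -> int:
        """Start level for a pair: default for anchors, else the nearest
        finished lattice neighbor's estimate (Euclidean ties -> mean of the
        tied estimates, rounded half-to-even)."""
        if self.is_anchor(eye, loc_id):
            return self.seeding_default
        pat = self.patterns[eye]
        loc = pat.location(loc_id)
        finished = self._finished_ids(eye)
        cands = [n for n in neighbors(pat, loc) if n.id in finished]
        if not cands:
            return self.seeding_default
        dists = [np.hypot(n.x - loc.x, n.y - loc.y) for n in cands]
        dmin = min(dists)
        tied = [estimate(self.states[(eye, n.id)])
                for n, d in zip(cands, dists) if d <= dmin + 1e-9]
        return int(round(float(np.mean(tied))))

    def ready_pairs(self) -> list[tuple[Eye, int]]:
        """Unfinished pairs that may present now: started staircases plus
        unstarted locations with >= 1 finished lattice neighbor (anchors
        are always ready)."""
        out = []
        for eye, pat in self.patterns.items():
            finished = self._finished_ids(eye)
            for loc in pat.locations:
                key = (eye, loc.id)
                st = self.states.get(key)
                if st is not None:
                    if not st.finished:
                        out.append(key)
                    continue
                if self.is_anchor(eye, loc.id) or any(
                    n.id in finished for n in neighbors(pat, loc)
                ):
                    out.append(key)
        return out

    def staircase(self, eye: Eye, loc_id: int) -> StaircaseState:
        """The pair's staircase, created (and seeded) on first access."""
        key = (eye, loc_id)
        if key not in self.states:
            self.states[key] = init_staircase(loc_id, self.seed_level(eye, loc_id))
        return self.states[key]

    @property
    def complete(self) -> bool:
        return len(self.states) == len(self.pairs) and all(
            st.finished for st in self.states.values()
        )

    def estimates(self) -> dict[Eye, dict[int, int]]:
        out: dict[Eye, dict[int, int]] = {eye: {} for eye in self.patterns}
        for (eye, lid), st in self.states.items():
            out[eye][lid] = estimate(st)
        return out


def make_plan(
    pattern: TestPattern | Mapping[Eye, TestPattern],
    eyes: tuple[Eye, ...] = ("OD", "OS"),
    seeding_default: int = DEFAULT_START_LEVEL,
) -> TestPlan:
    """Build a test plan covering every (location, eye) pair exactly once.

    A single pattern is reused for all eyes; a mapping supplies per-eye
    patterns (the T-24 blind-spot exclusions mirror between eyes).
    """
    if not (DB_MIN <= seeding_default <= DB_MAX):
        raise DomainError(f"seeding default {seeding_default} outside [{DB_MIN}, {DB_MAX}]")
    if isinstance(pattern, TestPattern):
        patterns = {eye: pattern for eye in eyes}
    else:
        patterns = {eye: pattern[eye] for eye in eyes}
    return TestPlan(patterns=patterns, seeding_default=seeding_default)


@dataclass(frozen=True)
class SuprathresholdTrial:
    """Single-presentation screening trial at a fixed suprathreshold level."""

    location_id: int
    eye: Eye
    level: int
    seen: bool
    response_time_ms: float | None


def run_suprathreshold(
    patterns: Mapping[Eye, TestPattern],
    level: int,
    observers: Mapping[Eye, Observer],
    rng: np.random.Generator,
) -> list[SuprathresholdTrial]:
    """One presentation per location per eye at a constant level.

    Screening mode: the outcome measures are the seen flag and response
    time, not a threshold.
    """
    if not (DB_MIN <= level <= DB_MAX):
        raise DomainError(f"suprathreshold level {level} outside [{DB_MIN}, {DB_MAX}]")
    trials = []
    for eye, pat in patterns.items():
        obs = observers[eye]
        for loc in pat.locations:
            seen, rt = respond(obs.surface, obs.params, loc.x, loc.y, level, rng)
            trials.append(SuprathresholdTrial(
                location_id=loc.id, eye=eye, level=int(level), seen=seen,
                response_time_ms=rt,
            ))
    return trials
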
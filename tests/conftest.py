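"""Shared fixtures: scripted agents, direct log builders, re-scan oracles."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from signalgame.agents import DEFAULT_ANCHORS
from signalgame.engine import GameLog, REFERENTS, RoundRecord
from signalgame.signal_space import PadPoint, render_view


class AnchorSender:
    """Noiseless sender: always sends the referent's anchor point."""

    def __init__(self, anchors: Optional[Dict[str, PadPoint]] = None) -> None:
        self.anchors = anchors or DEFAULT_ANCHORS

    def produce(self, referent, sees_color, rng):
        return self.anchors[referent]


class DecodingReceiver:
    """Oracle receiver: decodes the view back to the nearest anchor.

    With a noiseless :class:`AnchorSender` this always guesses the target,
    in every condition (both the color and the dot view are deterministic
    functions of the sent point).
    """

    def __init__(self, anchors: Optional[Dict[str, PadPoint]] = None) -> None:
        self.anchors = anchors or DEFAULT_ANCHORS

    def guess(self, view, rng):
        if view.kind == "dot":
            u, v = view.payload.u, view.payload.v
            key = lambda r: (self.anchors[r].u - u) ** 2 + (self.anchors[r].v - v) ** 2
        else:
            c = view.payload
            ref = {r: render_view("high", "sender", a).payload
                   for r, a in self.anchors.items()}
            key = lambda r: (ref[r].L - c.L) ** 2 + (ref[r].a - c.a) ** 2 + (ref[r].b - c.b) ** 2
        return min(REFERENTS, key=key)

    def learn(self, view, referent, rng=None):
        pass


class FixedGuessReceiver:
    """Always guesses the same referent (correct only when it is the target)."""

    def __init__(self, guess: str = "banana") -> None:
        self._guess = guess

    def guess(self, view, rng):
        return self._guess

    def learn(self, view, referent, rng=None):
        pass


class UniformRandomReceiver:
    """Guesses uniformly at random; never learns."""

    def guess(self, view, rng):
        return REFERENTS[rng.integers(len(REFERENTS))]

    def learn(self, view, referent, rng=None):
        pass


def build_log(
    targets: Sequence[str],
    corrects: Sequence[bool],
    n_practice: int = 0,
    condition: str = "low",
    durations: Optional[Sequence[float]] = None,
    points: Optional[Sequence[Optional[PadPoint]]] = None,
    won: bool = False,
    dyad_id: str = "test",
    guesses: Optional[Sequence[Optional[str]]] = None,
) -> GameLog:
    """Assemble a GameLog directly from outcome scripts (no engine)."""
    n = len(targets)
    durations = list(durations) if durations is not None else [10.0] * n
    points = list(points) if points is not None else [None] * n
    rounds: List[RoundRecord] = []
    for i in range(n):
        target = targets[i]
        if guesses is not None:
            guess = guesses[i]
        else:
            other = next(r for r in REFERENTS if r != target)
            guess = target if corrects[i] else other
        sv = render_view(condition, "sender", points[i])
        rv = render_view(condition, "receiver", points[i])
        rounds.append(RoundRecord(
            i + 1, i < n_practice, target, points[i], sv, rv,
            guess, bool(corrects[i]), durations[i],
        ))
    return GameLog(dyad_id, condition, rounds, won, sum(durations))


def random_log(
    rng: np.random.Generator,
    n_rounds: int = 100,
    n_practice: int = 0,
    p_correct: float = 0.5,
    condition: str = "low",
) -> GameLog:
    targets = [REFERENTS[i] for i in rng.integers(0, len(REFERENTS), n_rounds)]
    corrects = list(rng.random(n_rounds) < p_correct)
    return build_log(targets, corrects, n_practice=n_practice, condition=condition)


def rescan_established_series(targets: Sequence[str], corrects: Sequence[bool]) -> List[int]:
    """Exhaustive from-scratch oracle for the per-round established count."""
    out = []
    for t in range(len(targets)):
        s = 0
        for r in REFERENTS:
            hist = [c for tt, c in zip(targets[: t + 1], corrects[: t + 1]) if tt == r]
            if len(hist) >= 4 and sum(hist[-4:]) >= 3:
                s += 1
        out.append(s)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A short-session cohort of 2 dyads per condition (fast, deterministic)."""
    from signalgame.agents import generate_cohort
    from signalgame.engine import GameConfig

    return generate_cohort(
        (2, 2, 2), config=GameConfig(condition="high", session_s=400.0), seed=20240901
    )
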
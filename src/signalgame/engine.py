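"""Game engine: runs a full dyadic session and emits a :class:`GameLog`.

A session consists of 8 practice rounds (90 s cap each) followed by main
rounds (30 s cap + 2 s feedback) until either the winning condition is met
or 60 minutes of cumulative play have elapsed.  Each round the server picks
a target referent uniformly at random, the sender produces a pad point, the
views are rendered per condition, the receiver guesses, and both agents
receive feedback.

The winning condition requires every referent to be *established*: at
least 3 of the 4 most recent rounds in which it was the target were
guessed correctly.  It is checked only immediately after a correct guess,
and practice rounds never count towards it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np

from .signal_space import (
    CONDITIONS,
    PadPoint,
    SignalView,
    pad_to_lab,
    render_view,
)

__all__ = [
    "REFERENTS",
    "RoundRecord",
    "GameLog",
    "GameConfig",
    "ReliableLedger",
    "ConfigurationError",
    "referent_established",
    "winning_condition_met",
    "run_game",
    "run_receiver_only_session",
]

#: The six referents communicated in every game.
REFERENTS = ("banana", "eggplant", "strawberry", "blueberry", "orange", "kiwi")


class ConfigurationError(ValueError):
    """Raised when config and agents are mutually inconsistent."""


@dataclass(frozen=True)
class RoundRecord:
    """One trial: target, signal, views, guess, outcome, and wall time."""

    round_index: int
    is_practice: bool
    target: str
    sent_point: Optional[PadPoint]
    sender_view: SignalView
    receiver_view: SignalView
    guess: Optional[str]
    correct: bool
    duration_s: float

    def __post_init__(self) -> None:
        if self.target not in REFERENTS:
            raise ValueError(f"unknown target referent {self.target!r}")
        if self.guess is not None and self.guess not in REFERENTS:
            raise ValueError(f"unknown guessed referent {self.guess!r}")
        if self.correct != (self.guess == self.target):
            raise ValueError("correct flag inconsistent with guess/target")
        if self.duration_s <= 0:
            raise ValueError("round duration must be positive")


@dataclass
class GameLog:
    """One dyad's full session: ordered rounds plus session-level outcome."""

    dyad_id: str
    condition: str
    rounds: List[RoundRecord]
    won: bool
    total_time_s: float
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def main_rounds(self) -> List[RoundRecord]:
        return [r for r in self.rounds if not r.is_practice]

    @property
    def practice_rounds(self) -> List[RoundRecord]:
        return [r for r in self.rounds if r.is_practice]

    def validate(self) -> None:
        """Check internal consistency (round ordering, total time, win flag)."""
        idx = [r.round_index for r in self.rounds]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"log {self.dyad_id}: round indices not 1..n")
        n_pr = len(self.practice_rounds)
        if any(not r.is_practice for r in self.rounds[:n_pr]):
            raise ValueError(f"log {self.dyad_id}: practice rounds must precede main rounds")
        total = sum(r.duration_s for r in self.rounds)
        if abs(total - self.total_time_s) > 1e-6 * max(1.0, total):
            raise ValueError(f"log {self.dyad_id}: total_time_s does not equal summed durations")
        if self.won:
            ledger = ReliableLedger()
            for r in self.main_rounds:
                ledger.record(r.target, r.correct)
            if not winning_condition_met(ledger):
                raise ValueError(f"log {self.dyad_id}: won=True but winning condition not met")


class ReliableLedger:
    """Per-referent append-only history of guess outcomes (most recent last)."""

    def __init__(self) -> None:
        self._hist: Dict[str, List[bool]] = {r: [] for r in REFERENTS}

    def record(self, referent: str, correct: bool) -> None:
        if referent not in self._hist:
            raise ValueError(f"unknown referent {referent!r}")
        self._hist[referent].append(bool(correct))

    def history(self, referent: str) -> Sequence[bool]:
        if referent not in self._hist:
            raise ValueError(f"unknown referent {referent!r}")
        return tuple(self._hist[referent])


def referent_established(ledger: ReliableLedger, referent: str) -> bool:
    """True iff the referent has >= 4 outcomes and >= 3 of the last 4 correct.

    A referent with fewer than four recorded target occurrences is never
    established, so no dyad can start a game with any referent established.
    """
    hist = ledger.history(referent)
    if len(hist) < 4:
        return False
    return sum(hist[-4:]) >= 3


def winning_condition_met(ledger: ReliableLedger) -> bool:
    """True iff all six referents are simultaneously established."""
    return all(referent_established(ledger, r) for r in REFERENTS)


@dataclass(frozen=True)
class GameConfig:
    """Session parameters.

    ``latency_mu``/``latency_sigma`` parameterize the lognormal response
    latency (log-scale mean and SD); the defaults give a median response of
    ~7.4 s and a mean round length of ~10 s including feedback.
    ``session_s`` is the cumulative-time cutoff after which no new main
    round begins (the round in progress always completes).
    """

    condition: str
    n_practice: int = 8
    practice_cap_s: float = 90.0
    main_cap_s: float = 30.0
    feedback_s: float = 2.0
    session_s: float = 3600.0
    latency_mu: float = 2.0
    latency_sigma: float = 0.45

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )


def _as_seedseq(seed: Union[int, np.random.SeedSequence]) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _check_agent(agent: object, condition: str, who: str) -> None:
    declared = getattr(agent, "condition", None)
    if declared is not None and declared != condition:
        raise ConfigurationError(
            f"{who} declares condition {declared!r} but config says {condition!r}"
        )


def _round_duration(rng: np.random.Generator, cap_s: float, cfg: GameConfig) -> float:
    latency = float(rng.lognormal(cfg.latency_mu, cfg.latency_sigma))
    return min(latency, cap_s) + cfg.feedback_s


def run_game(
    config: GameConfig,
    sender_agent,
    receiver_agent,
    seed: Union[int, np.random.SeedSequence],
    dyad_id: str = "dyad",
) -> GameLog:
    """Play one full dyadic session and return its log.

    ``sender_agent`` must implement ``produce(referent, sees_color, rng)``
    and ``receiver_agent`` must implement ``guess(view, rng)`` and
    ``learn(view, referent, rng)``.  All randomness (target schedule, agents,
    latencies) derives from ``seed`` via named substreams, so the same seed
    always yields an identical log.
    """
    _check_agent(sender_agent, config.condition, "sender agent")
    _check_agent(receiver_agent, config.condition, "receiver agent")

    ss = _as_seedseq(seed)
    rng_sched, rng_send, rng_recv, rng_lat = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    sender_sees_color = config.condition in ("high", "one_sided")

    rounds: List[RoundRecord] = []
    elapsed = 0.0
    idx = 0

    def play(is_practice: bool) -> RoundRecord:
        nonlocal idx
        idx += 1
        target = REFERENTS[rng_sched.integers(len(REFERENTS))]
        point = sender_agent.produce(target, sender_sees_color, rng_send)
        sender_view = render_view(config.condition, "sender", point)
        receiver_view = render_view(config.condition, "receiver", point)
        guess = receiver_agent.guess(receiver_view, rng_recv)
        correct = guess == target
        # feedback: the receiver always learns the true pairing
        receiver_agent.learn(receiver_view, target, rng_recv)
        cap = config.practice_cap_s if is_practice else config.main_cap_s
        duration = _round_duration(rng_lat, cap, config)
        return RoundRecord(
            idx, is_practice, target, point, sender_view, receiver_view,
            guess, correct, duration,
        )

    for _ in range(config.n_practice):
        rec = play(True)
        rounds.append(rec)
        elapsed += rec.duration_s

    # practice outcomes are excluded from the winning ledger and score
    ledger = ReliableLedger()
    won = False
    while elapsed < config.session_s:
        rec = play(False)
        rounds.append(rec)
        elapsed += rec.duration_s
        ledger.record(rec.target, rec.correct)
        if rec.correct and winning_condition_met(ledger):
            won = True
            break

    return GameLog(dyad_id, config.condition, rounds, won, elapsed)


def run_receiver_only_session(
    receiver_agent,
    signal_bank: Mapping[str, Sequence[PadPoint]],
    signal_kind: str = "color",
    log_enabled: bool = False,
    log_panel_size: int = 4,
    duration_s: float = 900.0,
    seed: Union[int, np.random.SeedSequence] = 0,
    dyad_id: str = "solo",
    round_cap_s: float = 30.0,
    feedback_s: float = 2.0,
    latency_mu: float = 2.0,
    latency_sigma: float = 0.45,
) -> GameLog:
    """Single-receiver follow-up session with a fixed bank of 18 signals.

    Each round one bank signal (referent, point) is drawn uniformly at
    random and shown as a color or a dot per ``signal_kind``; the receiver
    guesses and is then told the correct referent.  With ``log_enabled``,
    ``log_panel_size`` referents are pre-selected at random and, for each,
    the first signal shown for it is pinned to a persistent on-screen log
    after that round; the log never updates afterwards.  The session ends
    once cumulative time reaches ``duration_s`` (the round in progress
    completes).
    """
    if signal_kind not in ("color", "dot"):
        raise ValueError(f"signal_kind must be 'color' or 'dot', got {signal_kind!r}")
    if set(signal_bank) != set(REFERENTS):
        raise ValueError("signal bank must cover exactly the six referents")
    for r, pts in signal_bank.items():
        if len(pts) != 3 or not all(isinstance(p, PadPoint) for p in pts):
            raise ValueError(f"signal bank needs exactly 3 PadPoints per referent (bad: {r})")

    ss = _as_seedseq(seed)
    rng_sched, rng_recv, rng_lat = (np.random.default_rng(c) for c in ss.spawn(3))

    bank = [(r, p) for r in REFERENTS for p in signal_bank[r]]
    log_referents: List[str] = []
    if log_enabled:
        sel = rng_sched.choice(len(REFERENTS), size=log_panel_size, replace=False)
        log_referents = [REFERENTS[i] for i in sorted(sel)]
    panel_log: Dict[str, Dict[str, object]] = {}

    rounds: List[RoundRecord] = []
    elapsed = 0.0
    idx = 0
    while elapsed < duration_s:
        idx += 1
        target, point = bank[rng_sched.integers(len(bank))]
        if signal_kind == "color":
            view = SignalView("color", pad_to_lab(point))
        else:
            view = render_view("low", "receiver", point)
        guess = receiver_agent.guess(view, rng_recv)
        correct = guess == target
        receiver_agent.learn(view, target, rng_recv)
        if log_enabled and target in log_referents and target not in panel_log:
            panel_log[target] = {
                "round_index": idx, "u": point.u, "v": point.v, "kind": view.kind,
            }
            pin = getattr(receiver_agent, "pin", None)
            if pin is not None:
                pin(view, target)
        latency = float(rng_lat.lognormal(latency_mu, latency_sigma))
        duration = min(latency, round_cap_s) + feedback_s
        rounds.append(
            RoundRecord(idx, False, target, point, SignalView("blank"), view,
                        guess, correct, duration)
        )
        elapsed += duration

    return GameLog(
        dyad_id,
        f"followup_{signal_kind}",
        rounds,
        False,
        elapsed,
        meta={
            "log_enabled": log_enabled,
            "log_referents": list(log_referents),
            "panel_log": panel_log,
        },
    )
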
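"""Bespoke measures computed from game logs.

The central quantity is the per-round *established count* ``s_t``: the
number of referents (0–6) that are established at round ``t`` under the
3-of-the-last-4 criterion, applied to all rounds in scope up to and
including ``t``.  From it derive the success index

    index = (Σ_t s_t) / (6 · n_rounds),

a dimensionless score in [0, 1) that rewards both how many reliable
signals a dyad establishes and how quickly.  Because a game ends early
once all six referents are established, won games are padded with
*dummy rounds* (s = 6) up to the full hour so that fast dyads are not
penalized for playing fewer rounds; the number of dummy rounds is
estimated from the mean length of the game's final four rounds.

Signal *stability* is the Euclidean distance (in pad units, unit square)
between successive sent points for the same referent; lower distances
mean the sender keeps hitting the same spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .engine import GameLog, REFERENTS, ReliableLedger, referent_established

__all__ = [
    "SuccessIndexResult",
    "established_series",
    "success_index_from_series",
    "dummy_round_count",
    "success_index",
    "stability_observations",
    "accuracy",
    "signal_set_proportions",
    "time_taken",
    "per_dyad_summary",
    "round_table",
]

FULL_SESSION_S = 3600.0


@dataclass(frozen=True)
class SuccessIndexResult:
    """Success index plus its bookkeeping decomposition."""

    index: float
    n_rounds_used: int
    n_dummy: int
    include_practice: bool
    include_dummy: bool


def _rounds_in_scope(log: GameLog, include_practice: bool):
    return log.rounds if include_practice else log.main_rounds


def established_series(log: GameLog, include_practice: bool = True) -> List[int]:
    """Per-round established counts ``s_t`` over the rounds in scope.

    With ``include_practice`` the outcome histories feeding the criterion
    include practice rounds (the success-index convention); without, only
    main rounds count — matching the in-game winning ledger, so the final
    entry of a won game is 6.
    """
    rounds = _rounds_in_scope(log, include_practice)
    if not rounds:
        raise ValueError(f"log {log.dyad_id}: no rounds in scope")
    ledger = ReliableLedger()
    series: List[int] = []
    for rec in rounds:
        ledger.record(rec.target, rec.correct)
        series.append(sum(referent_established(ledger, r) for r in REFERENTS))
    return series


def success_index_from_series(series: Sequence[int], n_dummy: int = 0) -> float:
    """Apply the success-index formula to an established-count series,
    optionally appending ``n_dummy`` fully-established (s = 6) rounds."""
    n = len(series) + n_dummy
    if n == 0:
        raise ValueError("empty round set")
    return (sum(series) + 6 * n_dummy) / (6.0 * n)


def dummy_round_count(log: GameLog) -> int:
    """Extra rounds a winning dyad would have played in the remaining time.

    Estimated as floor of remaining session time divided by the mean
    length of the game's final four rounds (feedback included, since wall
    time is what fills the hour); always 0 for games that ran the full
    session.  A partial round does not count, hence the floor.
    """
    if not log.won:
        return 0
    if len(log.rounds) < 4:
        raise ValueError(f"log {log.dyad_id}: need >= 4 rounds to estimate round length")
    mean_len = sum(r.duration_s for r in log.rounds[-4:]) / 4.0
    if mean_len <= 0:
        raise ValueError(f"log {log.dyad_id}: non-positive mean round length")
    remaining = FULL_SESSION_S - log.total_time_s
    if remaining <= 0:
        return 0
    return int(math.floor(remaining / mean_len))


def success_index(
    log: GameLog,
    include_practice: bool = True,
    include_dummy: bool = True,
) -> SuccessIndexResult:
    """Compute the success index for one dyad.

    The default (practice and dummy rounds both included) is the headline
    variant; the flags reproduce the sensitivity variants.
    """
    series = established_series(log, include_practice=include_practice)
    n_dummy = dummy_round_count(log) if include_dummy else 0
    idx = success_index_from_series(series, n_dummy)
    return SuccessIndexResult(
        idx, len(series) + n_dummy, n_dummy, include_practice, include_dummy
    )


def stability_observations(
    logs: Iterable[GameLog],
    include_practice: bool = True,
    send_select: str = "last",
) -> pd.DataFrame:
    """Successive same-referent signal distances, one row per observation.

    Columns: dyad_id, condition, referent, round_index, distance (pad
    units).  The first occurrence of each referent yields no observation;
    rounds without a sent signal are skipped.  ``send_select`` is kept for
    symmetry with the log adapter: engine logs carry one send per round.
    """
    if send_select not in ("last", "first"):
        raise ValueError("send_select must be 'last' or 'first'")
    rows = []
    for log in logs:
        prev: Dict[str, Tuple[float, float]] = {}
        for rec in _rounds_in_scope(log, include_practice):
            if rec.sent_point is None:
                continue
            cur = (rec.sent_point.u, rec.sent_point.v)
            if rec.target in prev:
                pu, pv = prev[rec.target]
                dist = math.hypot(cur[0] - pu, cur[1] - pv)
                rows.append(
                    (log.dyad_id, log.condition, rec.target, rec.round_index, dist)
                )
            prev[rec.target] = cur
    return pd.DataFrame(
        rows, columns=["dyad_id", "condition", "referent", "round_index", "distance"]
    )


def accuracy(log: GameLog, scope: str = "main_only") -> float:
    """Fraction of correct guesses; timeouts (no guess) count as incorrect.

    ``scope`` is ``"main_only"`` (default) or ``"all"`` (practice included).
    """
    if scope == "main_only":
        rounds = log.main_rounds
    elif scope == "all":
        rounds = log.rounds
    else:
        raise ValueError("scope must be 'main_only' or 'all'")
    if not rounds:
        raise ValueError(f"log {log.dyad_id}: no rounds in scope")
    return sum(r.correct for r in rounds) / len(rounds)


def signal_set_proportions(
    logs: Iterable[GameLog], include_practice: bool = True
) -> pd.DataFrame:
    """Proportion of rounds spent with each established-set size, pooled
    over dyads within condition.

    Returns a DataFrame indexed by condition with integer columns 0..6;
    each row sums to 1.  Dummy rounds are never included.
    """
    counts: Dict[str, List[int]] = {}
    for log in logs:
        c = counts.setdefault(log.condition, [0] * 7)
        for s in established_series(log, include_practice=include_practice):
            c[s] += 1
    if not counts:
        raise ValueError("need at least one log")
    df = pd.DataFrame.from_dict(counts, orient="index", columns=range(7))
    df.index.name = "condition"
    return df.div(df.sum(axis=1), axis=0)


def time_taken(log: GameLog) -> Tuple[float, int]:
    """Total game time in seconds and total number of rounds (practice
    plus main)."""
    return log.total_time_s, len(log.rounds)


def per_dyad_summary(logs: Iterable[GameLog]) -> pd.DataFrame:
    """Tidy per-dyad table of the headline measures and their variants.

    One row per dyad: success index (all four practice/dummy variants),
    accuracy over main and all rounds, total time, round count, win flag.
    """
    rows = []
    for log in logs:
        si = success_index(log)
        rows.append(
            {
                "dyad_id": log.dyad_id,
                "condition": log.condition,
                "success_index": si.index,
                "success_index_no_practice": success_index(log, include_practice=False).index,
                "success_index_no_dummy": success_index(log, include_dummy=False).index,
                "success_index_plain": success_index(
                    log, include_practice=False, include_dummy=False
                ).index,
                "n_dummy": si.n_dummy,
                "accuracy": accuracy(log, "main_only"),
                "accuracy_all": accuracy(log, "all"),
                "game_length_s": log.total_time_s,
                "n_rounds": len(log.rounds),
                "won": log.won,
            }
        )
    if not rows:
        raise ValueError("need at least one log")
    return pd.DataFrame(rows)


def round_table(logs: Iterable[GameLog], include_practice: bool = True) -> pd.DataFrame:
    """Per-round long table for the round-by-round models.

    Columns: dyad_id, condition, round_index, s (established count),
    presence (1 if s > 0), round_scaled (z-score of round_index over the
    pooled table).  Dummy rounds are excluded.
    """
    rows = []
    for log in logs:
        series = established_series(log, include_practice=include_practice)
        rounds = _rounds_in_scope(log, include_practice)
        for rec, s in zip(rounds, series):
            rows.append(
                (log.dyad_id, log.condition, rec.round_index, s, int(s > 0))
            )
    if not rows:
        raise ValueError("need at least one log")
    df = pd.DataFrame(
        rows, columns=["dyad_id", "condition", "round_index", "s", "presence"]
    )
    sd = df["round_index"].std(ddof=1) if len(df) > 1 else 0.0
    df["round_scaled"] = (df["round_index"] - df["round_index"].mean()) / (sd if sd > 0 else 1.0)
    return df
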
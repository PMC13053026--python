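"""Reliable-signal ledger, winning condition, and full-session engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from signalgame.agents import Receiver, Sender
from signalgame.engine import (
    ConfigurationError,
    GameConfig,
    REFERENTS,
    ReliableLedger,
    referent_established,
    run_game,
    run_receiver_only_session,
    winning_condition_met,
)
from signalgame.signal_space import PadPoint

from conftest import (
    AnchorSender,
    DecodingReceiver,
    FixedGuessReceiver,
    UniformRandomReceiver,
)

C, W = True, False


def ledger_with(history, referent="banana"):
    led = ReliableLedger()
    for outcome in history:
        led.record(referent, outcome)
    return led


@pytest.mark.parametrize(
    "history,expected",
    [
        ([C, C, W, C], True),          # 3 of the last 4
        ([C, C, C], False),            # fewer than four occasions ever
        ([W, C, C, W, C, C, C], True), # last four are W,C,C,C
        ([C, W, W, C], False),         # only 2 of 4
        ([C, C, C, C, W, W], False),   # early streak revoked by recent misses
        ([], False),
    ],
)
def test_referent_established(history, expected):
    assert referent_established(ledger_with(history), "banana") is expected


def test_ledger_rejects_unknown_referent():
    led = ReliableLedger()
    with pytest.raises(ValueError):
        led.record("durian", True)
    with pytest.raises(ValueError):
        referent_established(led, "durian")


def test_winning_condition_requires_all_six():
    led = ReliableLedger()
    for r in REFERENTS:
        for outcome in [C, C, C, C]:
            led.record(r, outcome)
    assert winning_condition_met(led)
    led2 = ReliableLedger()
    for r in REFERENTS[:-1]:
        for outcome in [C, C, C, C]:
            led2.record(r, outcome)
    for outcome in [C, W, W, C]:
        led2.record(REFERENTS[-1], outcome)
    assert not winning_condition_met(led2)


@given(
    seq=st.lists(
        st.tuples(st.integers(0, 5), st.booleans()), min_size=1, max_size=120
    )
)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_incremental_criterion_matches_rescan(seq):
    """Appending to the ledger reproduces an exhaustive re-scan at each step."""
    led = ReliableLedger()
    targets, outcomes = [], []
    for ref_idx, outcome in seq:
        r = REFERENTS[ref_idx]
        led.record(r, outcome)
        targets.append(r)
        outcomes.append(outcome)
        for check in REFERENTS:
            hist = [o for t, o in zip(targets, outcomes) if t == check]
            expected = len(hist) >= 4 and sum(hist[-4:]) >= 3
            assert referent_established(led, check) is expected
        assert winning_condition_met(led) is all(
            referent_established(led, r2) for r2 in REFERENTS
        )


def test_oracle_dyad_wins_at_earliest_possible_round():
    """A perfect dyad wins exactly when every referent has 4 occurrences."""
    log = run_game(GameConfig(condition="high"), AnchorSender(), DecodingReceiver(), seed=11)
    assert log.won
    assert all(r.correct for r in log.rounds)
    # brute force over the log's own target schedule: first main round at
    # which all six referents have been the target at least 4 times
    counts = {r: 0 for r in REFERENTS}
    earliest = None
    for i, rec in enumerate(log.main_rounds, start=1):
        counts[rec.target] += 1
        if all(c >= 4 for c in counts.values()):
            earliest = i
            break
    assert earliest == len(log.main_rounds)
    assert earliest >= 24  # 6 referents x 4 occurrences


def test_hopeless_dyad_plays_full_hour():
    log = run_game(
        GameConfig(condition="low"), AnchorSender(), FixedGuessReceiver("banana"), seed=3
    )
    assert not log.won
    assert log.total_time_s >= 3600.0
    # the final round started before the 60-minute mark
    assert log.total_time_s - log.rounds[-1].duration_s < 3600.0


def test_round_structure_and_durations():
    log = run_game(GameConfig(condition="one_sided"), Sender(), Receiver(), seed=9)
    practice = log.practice_rounds
    assert len(practice) == 8
    assert [r.round_index for r in log.rounds] == list(range(1, len(log.rounds) + 1))
    assert all(not r.is_practice for r in log.rounds[8:])
    for r in log.rounds:
        assert r.duration_s <= (92.0 if r.is_practice else 32.0)
    for r in log.rounds:  # one-sided: sender sees color, receiver sees dot
        assert r.sender_view.kind == "color" and r.receiver_view.kind == "dot"
    log.validate()


def test_practice_outcomes_do_not_count_towards_winning():
    """Even a perfect dyad cannot win before 24 main rounds, although its 8
    practice rounds were all correct."""
    log = run_game(GameConfig(condition="high"), AnchorSender(), DecodingReceiver(), seed=2)
    assert all(r.correct for r in log.practice_rounds)
    assert len(log.main_rounds) >= 24


def test_same_seed_reproduces_log_exactly():
    a = run_game(GameConfig(condition="low"), Sender(), Receiver(), seed=42)
    b = run_game(GameConfig(condition="low"), Sender(), Receiver(), seed=42)
    assert len(a.rounds) == len(b.rounds)
    assert a.won == b.won and a.total_time_s == b.total_time_s
    for x, y in zip(a.rounds, b.rounds):
        assert x == y


def test_agent_condition_mismatch_rejected():
    sender = AnchorSender()
    sender.condition = "high"
    with pytest.raises(ConfigurationError):
        run_game(GameConfig(condition="low"), sender, DecodingReceiver(), seed=0)


def test_no_main_round_starts_after_cutoff():
    cfg = GameConfig(condition="low", session_s=300.0)
    log = run_game(cfg, Sender(), UniformRandomReceiver(), seed=7)
    start = sum(r.duration_s for r in log.practice_rounds)
    for rec in log.main_rounds:
        assert start < 300.0
        start += rec.duration_s


# ---------------------------------------------------------- follow-up mode


def _bank():
    rng = np.random.default_rng(1)
    return {
        r: [PadPoint(float(u), float(v)) for u, v in rng.random((3, 2))]
        for r in REFERENTS
    }


def test_receiver_only_rejects_malformed_bank():
    bank = _bank()
    bank["banana"] = bank["banana"][:2]
    with pytest.raises(ValueError):
        run_receiver_only_session(DecodingReceiver(), bank, seed=0)
    with pytest.raises(ValueError):
        run_receiver_only_session(DecodingReceiver(), _bank(), signal_kind="sound", seed=0)


def test_receiver_only_oracle_and_duration():
    from signalgame.agents import DEFAULT_ANCHORS

    bank = {r: [DEFAULT_ANCHORS[r]] * 3 for r in REFERENTS}
    log = run_receiver_only_session(
        DecodingReceiver(), bank, signal_kind="dot", duration_s=300.0, seed=5
    )
    assert all(r.correct for r in log.rounds)
    assert log.total_time_s >= 300.0
    assert log.total_time_s - log.rounds[-1].duration_s < 300.0
    assert log.condition == "followup_dot"


def test_signal_log_pins_first_signal_and_never_updates():
    log = run_receiver_only_session(
        Receiver(), _bank(), signal_kind="dot", log_enabled=True,
        duration_s=600.0, seed=8,
    )
    panel = log.meta["panel_log"]
    log_refs = log.meta["log_referents"]
    assert len(log_refs) == 4
    assert set(panel) <= set(log_refs)
    for referent, entry in panel.items():
        first = next(r for r in log.rounds if r.target == referent)
        assert entry["round_index"] == first.round_index
        assert (entry["u"], entry["v"]) == (first.sent_point.u, first.sent_point.v)


def test_receiver_only_deterministic():
    a = run_receiver_only_session(Receiver(), _bank(), log_enabled=True, seed=4)
    b = run_receiver_only_session(Receiver(), _bank(), log_enabled=True, seed=4)
    assert a.rounds == b.rounds and a.meta == b.meta
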
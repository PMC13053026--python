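"""Log serialization, the deposited-data adapter, and config loading.

Two dialects are supported and round-trip losslessly:

* **JSONL** (canonical): per dyad, one header record
  (``kind="dyad"``: dyad_id, condition, won, total_time_s, meta) followed
  by one record per round (``kind="round"``: round_index, is_practice,
  target, sent_u, sent_v, guess, correct, duration_s).  Keys are sorted
  and floats written with full precision, so writing a just-read file
  reproduces it byte for byte.
* **CSV** (interchange): one flat row per round with columns
  dyad_id, condition, round_index, is_practice, target, sent_u, sent_v,
  guess, correct, duration_s, won.  Dyad-level ``meta`` is not carried.

Signal views are derived data (condition × pad point) and are
reconstructed on read rather than stored.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .engine import (
    GameLog,
    REFERENTS,
    ReliableLedger,
    RoundRecord,
    winning_condition_met,
)
from .signal_space import (
    BLANK_VIEW,
    CONDITIONS,
    DotSignal,
    PadPoint,
    SignalView,
    pad_to_lab,
    render_view,
)

__all__ = [
    "SchemaError",
    "ConfigError",
    "CSV_COLUMNS",
    "KNOWN_CONDITIONS",
    "read_logs",
    "write_logs",
    "adapt_deposited",
    "load_agent_config",
]


class SchemaError(ValueError):
    """A log file violates the round-level schema."""


class ConfigError(ValueError):
    """A mapping or parameter config is unusable."""


CSV_COLUMNS = [
    "dyad_id", "condition", "round_index", "is_practice", "target",
    "sent_u", "sent_v", "guess", "correct", "duration_s", "won",
]

FOLLOWUP_CONDITIONS = ("followup_color", "followup_dot")
KNOWN_CONDITIONS = CONDITIONS + FOLLOWUP_CONDITIONS


def _views_for(condition: str, p: Optional[PadPoint]):
    if condition in CONDITIONS:
        return render_view(condition, "sender", p), render_view(condition, "receiver", p)
    if p is None:
        return BLANK_VIEW, BLANK_VIEW
    if condition == "followup_color":
        return BLANK_VIEW, SignalView("color", pad_to_lab(p))
    if condition == "followup_dot":
        return BLANK_VIEW, SignalView("dot", DotSignal(p.u, p.v))
    raise SchemaError(f"unknown condition label {condition!r}")


def _build_round(condition: str, where: str, **f) -> RoundRecord:
    u, v = f.pop("sent_u"), f.pop("sent_v")
    if (u is None) != (v is None):
        raise SchemaError(f"{where}: sent_u/sent_v must both be present or both absent")
    try:
        point = None if u is None else PadPoint(float(u), float(v))
        sender_view, receiver_view = _views_for(condition, point)
        return RoundRecord(
            round_index=int(f["round_index"]),
            is_practice=bool(f["is_practice"]),
            target=f["target"],
            sent_point=point,
            sender_view=sender_view,
            receiver_view=receiver_view,
            guess=f["guess"],
            correct=bool(f["correct"]),
            duration_s=float(f["duration_s"]),
        )
    except ValueError as e:
        raise SchemaError(f"{where}: {e}") from e


def _finalize(dyad: dict, rounds: List[RoundRecord], where: str) -> GameLog:
    log = GameLog(
        dyad_id=dyad["dyad_id"],
        condition=dyad["condition"],
        rounds=rounds,
        won=bool(dyad["won"]),
        total_time_s=float(dyad["total_time_s"]),
        meta=dict(dyad.get("meta") or {}),
    )
    try:
        log.validate()
    except ValueError as e:
        raise SchemaError(f"{where}: {e}") from e
    return log


# ---------------------------------------------------------------- JSONL

def write_logs_jsonl(logs: Iterable[GameLog], path: Union[str, Path]) -> None:
    def dump(obj: dict) -> str:
        return json.dumps(obj, sort_keys=True, separators=(",", ":"))

    lines = []
    for log in logs:
        lines.append(dump({
            "kind": "dyad",
            "dyad_id": log.dyad_id,
            "condition": log.condition,
            "won": log.won,
            "total_time_s": log.total_time_s,
            "meta": log.meta,
        }))
        for r in log.rounds:
            lines.append(dump({
                "kind": "round",
                "round_index": r.round_index,
                "is_practice": r.is_practice,
                "target": r.target,
                "sent_u": None if r.sent_point is None else r.sent_point.u,
                "sent_v": None if r.sent_point is None else r.sent_point.v,
                "guess": r.guess,
                "correct": r.correct,
                "duration_s": r.duration_s,
            }))
    Path(path).write_text("\n".join(lines) + "\n")


_ROUND_KEYS = ("round_index", "is_practice", "target", "sent_u", "sent_v",
               "guess", "correct", "duration_s")


def read_logs_jsonl(path: Union[str, Path]) -> List[GameLog]:
    logs: List[GameLog] = []
    header: Optional[dict] = None
    header_line = 0
    rounds: List[RoundRecord] = []

    def close() -> None:
        if header is not None:
            logs.append(_finalize(header, rounds, f"{path}:{header_line}"))

    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        where = f"{path}:{lineno}"
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as e:
            raise SchemaError(f"{where}: invalid JSON ({e})") from e
        kind = obj.get("kind")
        if kind == "dyad":
            close()
            for key in ("dyad_id", "condition", "won", "total_time_s"):
                if key not in obj:
                    raise SchemaError(f"{where}: dyad record missing {key!r}")
            if obj["condition"] not in KNOWN_CONDITIONS:
                raise SchemaError(f"{where}: unknown condition {obj['condition']!r}")
            header, header_line, rounds = obj, lineno, []
        elif kind == "round":
            if header is None:
                raise SchemaError(f"{where}: round record before any dyad header")
            missing = [k for k in _ROUND_KEYS if k not in obj]
            if missing:
                raise SchemaError(f"{where}: round record missing {missing}")
            rounds.append(_build_round(header["condition"], where,
                                       **{k: obj[k] for k in _ROUND_KEYS}))
        else:
            raise SchemaError(f"{where}: unknown record kind {kind!r}")
    close()
    return logs


# ------------------------------------------------------------------ CSV

def write_logs_csv(logs: Iterable[GameLog], path: Union[str, Path]) -> None:
    rows = []
    for log in logs:
        for r in log.rounds:
            rows.append({
                "dyad_id": log.dyad_id,
                "condition": log.condition,
                "round_index": r.round_index,
                "is_practice": r.is_practice,
                "target": r.target,
                "sent_u": None if r.sent_point is None else r.sent_point.u,
                "sent_v": None if r.sent_point is None else r.sent_point.v,
                "guess": r.guess,
                "correct": r.correct,
                "duration_s": r.duration_s,
                "won": log.won,
            })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _logs_from_frame(df: pd.DataFrame, source: str) -> List[GameLog]:
    logs = []
    for dyad_id, group in df.groupby("dyad_id", sort=False):
        conditions = group["condition"].unique()
        if len(conditions) != 1:
            raise SchemaError(f"{source}: dyad {dyad_id} has multiple condition labels")
        condition = str(conditions[0])
        if condition not in KNOWN_CONDITIONS:
            raise SchemaError(
                f"{source}: unknown condition {condition!r} for dyad {dyad_id}"
            )
        rounds = []
        for _, row in group.iterrows():
            where = f"{source}:row {row.name + 2}"  # +2: header line and 0-base
            guess = row["guess"]
            guess = None if pd.isna(guess) else str(guess)
            u = None if pd.isna(row["sent_u"]) else float(row["sent_u"])
            v = None if pd.isna(row["sent_v"]) else float(row["sent_v"])
            rounds.append(_build_round(
                condition, where,
                round_index=row["round_index"],
                is_practice=row["is_practice"],
                target=str(row["target"]),
                sent_u=u, sent_v=v,
                guess=guess,
                correct=row["correct"],
                duration_s=row["duration_s"],
            ))
        total = sum(r.duration_s for r in rounds)
        logs.append(_finalize(
            {"dyad_id": str(dyad_id), "condition": condition,
             "won": bool(group["won"].iloc[0]), "total_time_s": total},
            rounds, f"{source}: dyad {dyad_id}"))
    return logs


def read_logs_csv(path: Union[str, Path]) -> List[GameLog]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return _logs_from_frame(df, str(path))


# ------------------------------------------------------------ dispatch

def read_logs(path: Union[str, Path], format: Optional[str] = None) -> List[GameLog]:
    """Read game logs from a JSONL or CSV file (format inferred by suffix)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        return read_logs_jsonl(path)
    if fmt == "csv":
        return read_logs_csv(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")


def write_logs(logs: Sequence[GameLog], path: Union[str, Path],
               format: Optional[str] = None) -> None:
    """Write game logs to a JSONL (canonical) or CSV (interchange) file."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        write_logs_jsonl(logs, path)
    elif fmt == "csv":
        write_logs_csv(logs, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")


# ------------------------------------------------------------- adapter

REQUIRED_FIELDS = ("dyad_id", "condition", "round_index", "target", "guess")
OPTIONAL_FIELDS = ("is_practice", "sent_u", "sent_v", "correct", "duration_s", "won")


def adapt_deposited(
    path: Union[str, Path],
    mapping_config: Union[str, Path, Mapping],
) -> List[GameLog]:
    """Ingest an externally deposited round-level CSV via a column mapping.

    ``mapping_config`` (dict or YAML path) must provide::

        columns:            # canonical field -> source column name
          dyad_id: ...
          condition: ...
          round_index: ...
          target: ...
          guess: ...
          # optional: is_practice, sent_u, sent_v, correct, duration_s, won
        condition_labels:   # optional source value -> {high, low, one_sided}
        n_practice: 8       # used when is_practice is unmapped
        send_select: last   # which send defines a multi-send round

    Derivations for unmapped optional fields: ``correct`` from
    guess == target; ``is_practice`` from the first ``n_practice`` rounds;
    ``won`` by re-checking the winning condition on the main rounds;
    ``duration_s`` falls back to 1 s per round (flagged in ``meta``, so
    time-based measures are not trusted).  Source columns that are not
    mapped are retained in each log's ``meta["extra_columns"]``.
    """
    if isinstance(mapping_config, (str, Path)):
        mapping_config = yaml.safe_load(Path(mapping_config).read_text())
    if not isinstance(mapping_config, Mapping):
        raise ConfigError("mapping config must be a mapping or a YAML file path")
    columns = dict(mapping_config.get("columns") or {})
    label_map = dict(mapping_config.get("condition_labels") or {})
    n_practice = int(mapping_config.get("n_practice", 8))
    send_select = str(mapping_config.get("send_select", "last"))
    if send_select not in ("last", "first"):
        raise ConfigError("send_select must be 'last' or 'first'")

    df = pd.read_csv(path, float_precision="round_trip")
    available = list(df.columns)
    for field in REQUIRED_FIELDS:
        if field not in columns:
            raise ConfigError(
                f"required field {field!r} is unmapped; candidate source columns: {available}"
            )
        if columns[field] not in df.columns:
            raise ConfigError(
                f"mapped source column {columns[field]!r} for {field!r} not found; "
                f"available: {available}"
            )
    for field in OPTIONAL_FIELDS:
        if field in columns and columns[field] not in df.columns:
            raise ConfigError(
                f"mapped source column {columns[field]!r} for {field!r} not found; "
                f"available: {available}"
            )

    mapped_sources = set(columns.values())
    extra_cols = [c for c in df.columns if c not in mapped_sources]

    out = pd.DataFrame()
    for field, src in columns.items():
        out[field] = df[src]
    if label_map:
        out["condition"] = out["condition"].map(lambda x: label_map.get(x, x))

    logs: List[GameLog] = []
    for dyad_id, group in out.groupby("dyad_id", sort=False):
        extras = df.loc[group.index, extra_cols]
        # a round may contain several sends (one row each); the last row
        # defines the round's guess and outcome, while send_select picks
        # which send counts as the round's signal
        ordered = group.sort_values("round_index", kind="stable")
        g = ordered.drop_duplicates("round_index", keep="last").reset_index(drop=True)
        if send_select == "first" and "sent_u" in group.columns:
            firsts = ordered.drop_duplicates("round_index", keep="first").reset_index(drop=True)
            g[["sent_u", "sent_v"]] = firsts[["sent_u", "sent_v"]]
        g["round_index"] = range(1, len(g) + 1)  # renumber 1..n after collapsing
        if "is_practice" not in g.columns:
            g["is_practice"] = [i < n_practice for i in range(len(g))]
        if "correct" not in g.columns:
            g["correct"] = g["guess"].notna() & (g["guess"] == g["target"])
        meta: Dict[str, object] = {}
        if "duration_s" not in g.columns:
            g["duration_s"] = 1.0
            meta["durations_missing"] = True
        if "sent_u" not in g.columns:
            g["sent_u"] = float("nan")
            g["sent_v"] = float("nan")
        condition = str(g["condition"].iloc[0])
        if condition not in KNOWN_CONDITIONS:
            raise SchemaError(
                f"{path}: unknown condition label {condition!r} for dyad {dyad_id} "
                f"(add it to condition_labels)"
            )
        rounds = []
        for _, row in g.iterrows():
            guess = row["guess"]
            guess = None if pd.isna(guess) else str(guess)
            u = None if pd.isna(row["sent_u"]) else float(row["sent_u"])
            v = None if pd.isna(row["sent_v"]) else float(row["sent_v"])
            rounds.append(_build_round(
                condition, f"{path}: dyad {dyad_id} round {row['round_index']}",
                round_index=row["round_index"], is_practice=row["is_practice"],
                target=str(row["target"]), sent_u=u, sent_v=v,
                guess=guess, correct=bool(row["correct"]),
                duration_s=row["duration_s"],
            ))
        if "won" in g.columns:
            won = bool(g["won"].iloc[0])
        else:
            ledger = ReliableLedger()
            for r in rounds:
                if not r.is_practice:
                    ledger.record(r.target, r.correct)
            main = [r for r in rounds if not r.is_practice]
            won = bool(main) and main[-1].correct and winning_condition_met(ledger)
            meta["won_inferred"] = True
        if extra_cols:
            meta["extra_columns"] = {c: extras[c].tolist() for c in extra_cols}
        total = sum(r.duration_s for r in rounds)
        logs.append(_finalize(
            {"dyad_id": str(dyad_id), "condition": condition, "won": won,
             "total_time_s": total, "meta": meta},
            rounds, f"{path}: dyad {dyad_id}"))
    return logs


# -------------------------------------------------------------- config

def load_agent_config(path: Union[str, Path, None]):
    """Load sender/receiver/game parameters from a YAML config.

    Recognized sections: ``sender`` (sigma_motor, sigma_drift, p_forget),
    ``receiver`` (memory_capacity, lambda_prior, epsilon_guess, tau_pad,
    tau_lab), ``anchors`` (referent → [u, v], applied to both agents) and
    ``game`` (any :class:`~signalgame.engine.GameConfig` field except
    ``condition``).  Returns ``(SenderParams, ReceiverParams, game_kwargs)``
    with defaults where the file is silent; ``path=None`` gives all
    defaults.
    """
    from .agents import ReceiverParams, SenderParams  # local: avoid cycle

    raw: Mapping = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a YAML mapping")
    anchors = None
    if raw.get("anchors"):
        try:
            anchors = {r: PadPoint(float(u), float(v))
                       for r, (u, v) in raw["anchors"].items()}
        except (TypeError, ValueError) as e:
            raise ConfigError(f"bad anchors section: {e}") from e
        if set(anchors) != set(REFERENTS):
            raise ConfigError("anchors must cover exactly the six referents")
    try:
        sender = SenderParams(**{**dict(raw.get("sender") or {}), "anchors": anchors})
        receiver = ReceiverParams(**{**dict(raw.get("receiver") or {}), "anchors": anchors})
    except (TypeError, ValueError) as e:
        raise ConfigError(f"bad agent parameters: {e}") from e
    game_kwargs = dict(raw.get("game") or {})
    if "condition" in game_kwargs:
        raise ConfigError("game.condition is set per dyad, not in the config")
    return sender, receiver, game_kwargs
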
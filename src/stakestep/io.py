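"""CSV/JSON round-tripping for sessions, truth tables and fit results."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .results import FitResult
from .task import (
    ACTIONS,
    GROUPS,
    KEYS,
    PLANETS,
    STAKES,
    STATES,
    Session,
    TaskConfig,
    TrialRecord,
)

SESSION_COLUMNS = (
    "subject_id", "group", "trial", "stake", "start_state", "action",
    "response_key", "planet", "base_reward", "delivered_reward",
)


class ParseError(ValueError):
    """Schema violation in an input file; the message names row and column."""


def write_sessions(sessions: Iterable[Session], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for sess in sessions:
            for tr in sess.trials:
                writer.writerow(
                    [
                        sess.subject_id, sess.group, tr.trial_index, tr.stake,
                        tr.start_state, tr.action, tr.response_key, tr.planet,
                        repr(float(tr.base_reward)), repr(float(tr.delivered_reward)),
                    ]
                )


def _parse_enum(value: str, allowed, row: int, column: str):
    if value not in allowed:
        raise ParseError(
            f"row {row}, column {column!r}: invalid value {value!r} "
            f"(allowed: {sorted(str(a) for a in allowed)})"
        )
    return value


def _parse_float(value: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"row {row}, column {column!r}: not a number: {value!r}") from None


def read_sessions(path, config: TaskConfig | None = None) -> list[Session]:
    """Read the tidy per-trial CSV back into Session objects.

    Strict: the header must contain exactly the documented columns, enums
    are case-sensitive and trial indices must count up from 0 within each
    subject.  ``config`` attaches a task configuration (per-session
    ``n_trials`` is set from the data); defaults are assumed otherwise.
    """
    base_cfg = config or TaskConfig()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("row 1: empty file, header required") from None
        if tuple(header) != SESSION_COLUMNS:
            missing = set(SESSION_COLUMNS) - set(header)
            extra = set(header) - set(SESSION_COLUMNS)
            raise ParseError(
                f"row 1: bad header (missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        per_subject: dict[str, dict] = {}
        order: list[str] = []
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(SESSION_COLUMNS):
                raise ParseError(f"row {rownum}: expected {len(SESSION_COLUMNS)} fields")
            rec = dict(zip(SESSION_COLUMNS, row))
            sid = rec["subject_id"]
            group = _parse_enum(rec["group"], GROUPS, rownum, "group")
            stake = _parse_enum(rec["stake"], STAKES, rownum, "stake")
            try:
                trial = int(rec["trial"])
                start_state = int(rec["start_state"])
            except ValueError:
                raise ParseError(
                    f"row {rownum}: trial and start_state must be integers"
                ) from None
            _parse_enum(start_state, STATES, rownum, "start_state")
            action = _parse_enum(rec["action"], ACTIONS, rownum, "action")
            key = _parse_enum(rec["response_key"], KEYS, rownum, "response_key")
            planet = _parse_enum(rec["planet"], PLANETS, rownum, "planet")
            base = _parse_float(rec["base_reward"], rownum, "base_reward")
            delivered = _parse_float(rec["delivered_reward"], rownum, "delivered_reward")
            if sid not in per_subject:
                per_subject[sid] = {"group": group, "trials": []}
                order.append(sid)
            expected = len(per_subject[sid]["trials"])
            if trial != expected:
                raise ParseError(
                    f"row {rownum}, column 'trial': non-monotone trial index "
                    f"{trial} for subject {sid!r} (expected {expected})"
                )
            per_subject[sid]["trials"].append(
                TrialRecord(
                    trial_index=trial, stake=stake, start_state=start_state,
                    action=action, response_key=key, planet=planet,
                    base_reward=base, delivered_reward=delivered,
                )
            )
    sessions = []
    for sid in order:
        entry = per_subject[sid]
        sessions.append(
            Session(
                subject_id=sid,
                group=entry["group"],
                config=base_cfg.replace(n_trials=len(entry["trials"])),
                trials=entry["trials"],
            )
        )
    return sessions


def write_truth(truth: Sequence[dict], path) -> None:
    pd.DataFrame(truth).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_results(
    results: Sequence[tuple[str, FitResult]],
    path,
    sidecar: dict | None = None,
) -> None:
    """One CSV row per (subject, model) with every estimated parameter, plus
    an optional JSON sidecar (priors, seeds, configuration)."""
    rows = []
    for subject_id, res in results:
        row = {
            "subject_id": subject_id,
            "model": res.model,
            **res.estimates,
            "log_likelihood": res.log_likelihood,
            "log_posterior": res.log_posterior,
            "n_restarts": res.n_restarts_run,
            "converged": res.converged,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_fit_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
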
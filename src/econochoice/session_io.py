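"""Data model and text-format readers/writers for choice sessions.

A behavioral session is one animal working through ~150-350 trials of a
two-alternative economic choice task.  On each trial two offers (so many
pellets of flavor *x* vs. so many of flavor *y*) are displayed and the animal
picks one side.  Sessions are stored one per file as a tab-separated trial
table preceded by a ``#key=value`` sidecar header carrying session metadata
(rat, pellet pair, fiber state, run, day).

Two further text layouts are supported:

* *source-data tables* - the per-replication 4-column condition tables
  (``B-off  B-on  P-off  P-on``: blocked/patent fiber crossed with laser
  off/on), one row per experimental replication, whitespace- or
  tab-delimited, columns identified by position;
* *progressive-ratio event logs* - TSV with columns ``event`` (press or
  pellet) and ``time_s``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import FormatError, PairingError, ValidationError

__all__ = [
    "CONDITIONS",
    "Offer",
    "TrialRecord",
    "Session",
    "SessionPairRecord",
    "PREventLog",
    "read_trial_log",
    "write_trial_log",
    "read_source_table",
    "write_source_table",
    "read_pr_log",
    "write_pr_log",
    "build_session_pairs",
]

#: Condition keys, in the fixed column order of the source-data tables:
#: blocked fiber laser-off/-on, then patent fiber laser-off/-on.
CONDITIONS = ("B-off", "B-on", "P-off", "P-on")

#: Maximum allowed reaction time under the task rule (seconds).
MAX_REACTION_TIME = 5.0


@dataclass(frozen=True)
class Offer:
    """One displayed offer: ``qty_x`` pellets of flavor x vs ``qty_y`` of y.

    Forced offers are exactly those with a zero on one side (1:0 or 0:1);
    they carry no trade-off and are excluded from psychometric fitting.
    """

    qty_x: int
    qty_y: int
    flavor_x: str = "x"
    flavor_y: str = "y"

    def __post_init__(self) -> None:
        if self.qty_x < 0 or self.qty_y < 0:
            raise ValidationError(f"negative pellet count in offer {self}")
        if self.qty_x + self.qty_y < 1:
            raise ValidationError("offer must contain at least one pellet")

    @property
    def forced(self) -> bool:
        return self.qty_x == 0 or self.qty_y == 0

    @property
    def log_ratio(self) -> float:
        """Natural log of qty_x / qty_y; undefined for forced offers."""
        if self.forced:
            raise ValueError("log ratio undefined for forced offers")
        return math.log(self.qty_x / self.qty_y)

    def flipped(self) -> "Offer":
        return Offer(self.qty_y, self.qty_x, self.flavor_y, self.flavor_x)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    offer: Offer
    laser_on: bool
    choice: str  # 'x' or 'y'
    reaction_time: float | None = None
    fiber_patent: bool | None = None  # session-level, duplicated for convenience

    def __post_init__(self) -> None:
        if self.choice not in ("x", "y"):
            raise ValidationError(f"choice must be 'x' or 'y', got {self.choice!r}")
        if self.reaction_time is not None and self.reaction_time < 0:
            raise ValidationError("reaction time must be >= 0")

    def flipped(self) -> "TrialRecord":
        return replace(
            self,
            offer=self.offer.flipped(),
            choice="y" if self.choice == "x" else "x",
        )


@dataclass
class Session:
    """One behavioral session: a rat, a pellet pair, a fiber state, trials."""

    rat_id: str
    run_index: int
    pellet_pair: tuple[str, str]
    fiber_state: str  # 'blocked' | 'patent'
    trials: list[TrialRecord] = field(default_factory=list)
    day_index: int | None = None
    warmup: bool = False
    true_log_ip: float | None = None  # set by the simulator, None for real data
    true_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.fiber_state not in ("blocked", "patent"):
            raise ValidationError(
                f"fiber_state must be 'blocked' or 'patent', got {self.fiber_state!r}"
            )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def laser_fraction(self) -> float:
        if not self.trials:
            return float("nan")
        return sum(t.laser_on for t in self.trials) / len(self.trials)

    def key(self) -> tuple[str, tuple[str, str], int]:
        return (self.rat_id, tuple(sorted(self.pellet_pair)), self.run_index)


@dataclass
class SessionPairRecord:
    """The four-condition tuple for one experimental replication.

    ``values`` maps each of the four conditions (``B-off``, ``B-on``,
    ``P-off``, ``P-on``) to a scalar (an indifference point or an inverse
    slope), mirroring one row of a source-data table.
    """

    block_id: int
    values: dict[str, float]
    measure: str = "ip"

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.values]
        if missing:
            raise ValidationError(f"record {self.block_id} missing conditions {missing}")
        if self.measure == "ip" and any(v <= 0 for v in self.values.values()):
            raise ValidationError(f"record {self.block_id}: IP values must be > 0")

    def as_row(self) -> list[float]:
        return [self.values[c] for c in CONDITIONS]


@dataclass
class PREventLog:
    """Press and pellet times (seconds from session start) for one PR session."""

    press_times: np.ndarray
    pellet_times: np.ndarray
    session_length: float

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)
        self.pellet_times = np.asarray(self.pellet_times, dtype=float)
        for name, t in (("press", self.press_times), ("pellet", self.pellet_times)):
            if t.size and np.any(np.diff(t) < 0):
                raise ValidationError(f"{name} times must be non-decreasing")


# ---------------------------------------------------------------------------
# trial logs
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ("trial", "qty_x", "qty_y", "laser", "choice", "rt")


def _open(source: str | Path | TextIO, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_trial_log(source: str | Path | TextIO) -> Session:
    """Parse a trial-log file (``#key=value`` header block + TSV table)."""
    stream, should_close = _open(source)
    try:
        meta: dict[str, str] = {}
        header: list[str] | None = None
        trials: list[TrialRecord] = []
        fiber_state = None
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FormatError(f"line {lineno}: malformed header line {line!r}")
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields_ = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields_]
                missing = [c for c in _TRIAL_COLUMNS if c not in header]
                if missing:
                    raise FormatError(
                        f"line {lineno}: missing required column(s) {missing}"
                    )
                idx = {c: header.index(c) for c in _TRIAL_COLUMNS}
                fiber_state = meta.get("fiber_state", "blocked")
                continue
            if len(fields_) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields_)}"
                )
            row = {c: fields_[idx[c]] for c in _TRIAL_COLUMNS}
            if row["laser"] not in ("0", "1"):
                raise ValidationError(
                    f"line {lineno}: laser must be 0 or 1, got {row['laser']!r}"
                )
            if row["choice"] not in ("x", "y"):
                raise ValidationError(
                    f"line {lineno}: choice must be x or y, got {row['choice']!r}"
                )
            try:
                trial_index = int(row["trial"])
                qty_x = int(row["qty_x"])
                qty_y = int(row["qty_y"])
                rt = float(row["rt"]) if row["rt"] not in ("", "NA") else None
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric value ({exc})") from None
            if rt is not None and rt > MAX_REACTION_TIME:
                warnings.warn(
                    f"line {lineno}: reaction time {rt} s exceeds the "
                    f"{MAX_REACTION_TIME} s task limit",
                    stacklevel=2,
                )
            trials.append(
                TrialRecord(
                    trial_index=trial_index,
                    offer=Offer(qty_x, qty_y),
                    laser_on=row["laser"] == "1",
                    choice=row["choice"],
                    reaction_time=rt,
                    fiber_patent=(fiber_state == "patent"),
                )
            )
        if header is None:
            raise FormatError("no header row found")
        pair = tuple(meta.get("pellet_pair", "x:y").split(":", 1))
        return Session(
            rat_id=meta.get("rat_id", "unknown"),
            run_index=int(meta.get("run", 1)),
            pellet_pair=(pair[0], pair[1] if len(pair) > 1 else "y"),
            fiber_state=meta.get("fiber_state", "blocked"),
            trials=trials,
            day_index=int(meta["day"]) if "day" in meta else None,
            warmup=meta.get("warmup", "0") == "1",
        )
    finally:
        if should_close:
            stream.close()


def write_trial_log(session: Session, target: str | Path | TextIO) -> None:
    stream, should_close = _open(target, "w")
    try:
        stream.write(f"#rat_id={session.rat_id}\n")
        stream.write(f"#pellet_pair={session.pellet_pair[0]}:{session.pellet_pair[1]}\n")
        stream.write(f"#fiber_state={session.fiber_state}\n")
        stream.write(f"#run={session.run_index}\n")
        if session.day_index is not None:
            stream.write(f"#day={session.day_index}\n")
        stream.write(f"#warmup={1 if session.warmup else 0}\n")
        stream.write("\t".join(_TRIAL_COLUMNS) + "\n")
        for t in session.trials:
            rt = "NA" if t.reaction_time is None else f"{t.reaction_time:.4f}"
            stream.write(
                f"{t.trial_index}\t{t.offer.qty_x}\t{t.offer.qty_y}\t"
                f"{1 if t.laser_on else 0}\t{t.choice}\t{rt}\n"
            )
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# source-data tables (4 numeric columns: B-off, B-on, P-off, P-on)
# ---------------------------------------------------------------------------

def read_source_table(
    source: str | Path | TextIO, measure: str = "ip"
) -> list[SessionPairRecord]:
    """Read a per-replication condition table (columns by position)."""
    stream, should_close = _open(source)
    try:
        records: list[SessionPairRecord] = []
        block = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"line {lineno}: expected 4 values, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric cell in {parts}") from None
            block += 1
            records.append(
                SessionPairRecord(
                    block_id=block,
                    values=dict(zip(CONDITIONS, vals)),
                    measure=measure,
                )
            )
        return records
    finally:
        if should_close:
            stream.close()


def write_source_table(
    records: Sequence[SessionPairRecord], target: str | Path | TextIO
) -> None:
    stream, should_close = _open(target, "w")
    try:
        for rec in records:
            stream.write("\t".join(f"{v:.6g}" for v in rec.as_row()) + "\n")
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# progressive-ratio event logs
# ---------------------------------------------------------------------------

def read_pr_log(source: str | Path | TextIO) -> PREventLog:
    stream, should_close = _open(source)
    try:
        presses: list[float] = []
        pellets: list[float] = []
        session_length = 0.0
        header_seen = False
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key.strip() == "session_length":
                    session_length = float(value)
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[:2] != ["event", "time_s"]:
                    raise FormatError(f"line {lineno}: expected header 'event\\ttime_s'")
                header_seen = True
                continue
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 fields, got {len(parts)}")
            event, t = parts
            try:
                t_val = float(t)
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric time {t!r}") from None
            if event == "press":
                presses.append(t_val)
            elif event == "pellet":
                pellets.append(t_val)
            else:
                raise ValidationError(f"line {lineno}: unknown event {event!r}")
        if not header_seen:
            raise FormatError("no header row found")
        if session_length == 0.0:
            session_length = max(presses + pellets, default=0.0)
        return PREventLog(np.array(presses), np.array(pellets), session_length)
    finally:
        if should_close:
            stream.close()


def write_pr_log(log: PREventLog, target: str | Path | TextIO) -> None:
    stream, should_close = _open(target, "w")
    try:
        stream.write(f"#session_length={log.session_length:.4f}\n")
        stream.write("event\ttime_s\n")
        events = [("press", t) for t in log.press_times] + [
            ("pellet", t) for t in log.pellet_times
        ]
        # stable sort keeps press-before-pellet order at equal times
        for name, t in sorted(events, key=lambda e: e[1]):
            stream.write(f"{name}\t{t:.4f}\n")
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def build_session_pairs(
    sessions: Iterable[Session],
) -> tuple[list[tuple[Session, Session]], list[Session]]:
    """Match blocked and patent test sessions on rat x pellet-pair x run.

    Warm-up (first-day) sessions are dropped.  Returns ``(pairs, unmatched)``
    where each pair is ``(blocked_session, patent_session)``.  Two sessions
    with the same fiber state in one cell raise :class:`PairingError`.
    """
    cells: dict[tuple, dict[str, Session]] = {}
    for s in sessions:
        if s.warmup:
            continue
        cell = cells.setdefault(s.key(), {})
        if s.fiber_state in cell:
            raise PairingError(
                f"two {s.fiber_state} sessions for rat={s.rat_id} "
                f"pair={s.pellet_pair} run={s.run_index}"
            )
        cell[s.fiber_state] = s
    pairs: list[tuple[Session, Session]] = []
    unmatched: list[Session] = []
    for cell in cells.values():
        if "blocked" in cell and "patent" in cell:
            pairs.append((cell["blocked"], cell["patent"]))
        else:
            unmatched.extend(cell.values())
    return pairs, unmatched
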
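"""Reading and validating screen-state event logs and questionnaire tables.

A screen-probe log is a delimited text file with one row per screen-state
transition: a participant identifier, a timestamp, and a binary state
(the phone entering or leaving an interactive state).  Loggers in the wild
disagree on every detail — epoch seconds vs milliseconds vs ISO strings,
``true/false`` vs ``1/0`` vs ``on/off`` — so the column names and state
encoding are carried in a :class:`Dialect` rather than hard-coded.

All timestamps are normalised to wall-clock time in a single configured
zone and stored timezone-naive; day and time-of-day logic downstream
operates on local clock time.  On a daylight-saving transition day the
wall clock covers 23 or 25 hours; sessions are never re-split to hide
this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DialectError,
    EmptyInputError,
    InputError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

STATE_ON = "ON"
STATE_OFF = "OFF"

#: Tokens accepted (case-insensitively) for each screen state.
DEFAULT_ON_TOKENS = frozenset({"true", "1", "on", "screen_on"})
DEFAULT_OFF_TOKENS = frozenset({"false", "0", "off", "screen_off"})


@dataclass(frozen=True)
class Dialect:
    """Column mapping and value encoding for a screen-probe file.

    Parameters
    ----------
    timestamp_col, state_col, participant_col
        Header names of the three relevant columns.  If
        ``participant_col`` is absent from the file every row is assigned
        ``default_participant`` (single-subject exports omit the column).
    on_tokens, off_tokens
        Lower-cased tokens decoded as screen-on / screen-off.
    epoch_ms_threshold
        Numeric timestamps whose magnitude exceeds this are interpreted
        as epoch milliseconds rather than seconds.  ``1e11`` seconds is
        year ~5138, so any sane epoch-second value sits far below it.
    delimiter
        ``None`` auto-detects comma vs tab from the header line.
    """

    timestamp_col: str = "timestamp"
    state_col: str = "state"
    participant_col: str = "participant_id"
    default_participant: str = "P01"
    on_tokens: frozenset[str] = field(default_factory=lambda: DEFAULT_ON_TOKENS)
    off_tokens: frozenset[str] = field(default_factory=lambda: DEFAULT_OFF_TOKENS)
    epoch_ms_threshold: float = 1e11
    delimiter: str | None = None


#: Dialect of the canonical event file written by :func:`write_events`.
CANONICAL_DIALECT = Dialect(timestamp_col="timestamp_iso8601")

EVENT_COLUMNS = ["participant_id", "timestamp", "state"]


@dataclass
class ParseReport:
    """Row accounting for one parsed log: valid + malformed = total."""

    n_rows: int
    n_valid: int
    n_malformed: int
    n_out_of_order: int


@dataclass
class ParseResult:
    events: pd.DataFrame
    report: ParseReport


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    sep = delimiter
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def _parse_timestamps(raw: pd.Series, tz: str, ms_threshold: float) -> pd.Series:
    """Decode a timestamp column to naive local wall-clock datetimes.

    Accepts epoch seconds, epoch milliseconds (auto-detected by
    magnitude), or ISO-8601 strings.  Unparseable entries become NaT.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().any():
        unit = "ms" if numeric.abs().max() > ms_threshold else "s"
        ts = pd.to_datetime(numeric, unit=unit, errors="coerce", utc=True)
        ts = ts.dt.tz_convert(tz).dt.tz_localize(None)
        return ts
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if ts.dt.tz is not None:
        ts = ts.dt.tz_convert(tz).dt.tz_localize(None)
    return ts


def read_screen_probe(
    path: str | Path,
    dialect: Dialect | None = None,
    tz: str = "UTC",
) -> ParseResult:
    """Read a screen-probe event log into a validated event table.

    Returns a :class:`ParseResult` whose ``events`` frame has columns
    ``participant_id`` (str), ``timestamp`` (naive local datetime64[ns])
    and ``state`` (``"ON"``/``"OFF"``), sorted ascending by participant
    then timestamp, with ON ordered before OFF at equal timestamps.
    Malformed rows (unparseable timestamp or unknown state token) are
    counted and logged, never silently dropped without trace.

    Raises
    ------
    InputError
        Missing file.
    DialectError
        Timestamp or state column absent.
    EmptyInputError
        No valid rows at all.
    """
    dialect = dialect or Dialect()
    df = _read_table(path, dialect.delimiter)

    for col in (dialect.timestamp_col, dialect.state_col):
        if col not in df.columns:
            raise DialectError(
                f"column {col!r} not found in {path}; available: {list(df.columns)}"
            )
    n_rows = len(df)

    if dialect.participant_col in df.columns:
        pid = df[dialect.participant_col].astype(str)
    else:
        pid = pd.Series(dialect.default_participant, index=df.index)

    ts = _parse_timestamps(df[dialect.timestamp_col], tz, dialect.epoch_ms_threshold)

    tokens = df[dialect.state_col].astype(str).str.strip().str.lower()
    state = pd.Series(pd.NA, index=df.index, dtype="object")
    state[tokens.isin(dialect.on_tokens)] = STATE_ON
    state[tokens.isin(dialect.off_tokens)] = STATE_OFF

    bad = ts.isna() | state.isna()
    n_malformed = int(bad.sum())
    if n_malformed:
        logger.warning("%d malformed rows dropped while parsing %s", n_malformed, path)

    events = pd.DataFrame(
        {"participant_id": pid[~bad], "timestamp": ts[~bad], "state": state[~bad]}
    )
    if events.empty:
        raise EmptyInputError(f"no valid events in {path}")

    # count chronology violations in original file order, per participant
    n_ooo = int(
        events.groupby("participant_id", sort=False)["timestamp"]
        .apply(lambda s: (s.diff() < pd.Timedelta(0)).sum())
        .sum()
    )
    if n_ooo:
        logger.warning("%d out-of-order rows detected in %s", n_ooo, path)

    events = sort_events(events)
    report = ParseReport(
        n_rows=n_rows,
        n_valid=len(events),
        n_malformed=n_malformed,
        n_out_of_order=n_ooo,
    )
    return ParseResult(events=events, report=report)


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Canonical stable ordering: participant, timestamp, ON before OFF."""
    key = events["state"].map({STATE_ON: 0, STATE_OFF: 1})
    return (
        events.assign(_k=key)
        .sort_values(["participant_id", "timestamp", "_k"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write events in the canonical dialect.

    Columns ``participant_id,timestamp_iso8601,state`` with stable
    ordering, so that re-reading reproduces the sequence bit-exactly.
    """
    out = sort_events(events)
    out = pd.DataFrame(
        {
            "participant_id": out["participant_id"],
            "timestamp_iso8601": out["timestamp"].map(pd.Timestamp.isoformat),
            "state": out["state"],
        }
    )
    out.to_csv(path, index=False)


def read_events(path: str | Path, tz: str = "UTC") -> ParseResult:
    """Read a canonical event file (convenience wrapper)."""
    return read_screen_probe(path, dialect=CANONICAL_DIALECT, tz=tz)


# ---------------------------------------------------------------------------
# self-report estimates


def read_self_reports(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read per-participant usage estimates.

    Expects columns ``participant_id``, ``estimated_daily_duration_h``
    (hours/day) and ``estimated_daily_uses`` (count/day).  Missing values
    stay NaN — distinguishable from zero — and set the ``incomplete``
    flag, mirroring the practice of excluding respondents who did not
    provide every estimate.

    Raises :class:`ValidationError` on duplicate participant ids or
    negative estimates.
    """
    df = _read_table(path, delimiter)
    required = ["participant_id", "estimated_daily_duration_h", "estimated_daily_uses"]
    for col in required:
        if col not in df.columns:
            raise DialectError(f"self-report file missing column {col!r}")
    if df.empty:
        logger.warning("self-report table %s is empty", path)
        return pd.DataFrame(columns=required + ["incomplete"])

    dup = df["participant_id"][df["participant_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate participant ids: {sorted(set(dup))}")

    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "estimated_daily_duration_h": pd.to_numeric(
                df["estimated_daily_duration_h"], errors="coerce"
            ),
            "estimated_daily_uses": pd.to_numeric(
                df["estimated_daily_uses"], errors="coerce"
            ),
        }
    )
    neg = (out[["estimated_daily_duration_h", "estimated_daily_uses"]] < 0).any(axis=1)
    if neg.any():
        raise ValidationError(
            f"negative estimates for participants {list(out['participant_id'][neg])}"
        )
    out["incomplete"] = (
        out[["estimated_daily_duration_h", "estimated_daily_uses"]].isna().any(axis=1)
    )
    return out


# ---------------------------------------------------------------------------
# problem-use questionnaire (27-item scale)

N_MPPUS_ITEMS = 27


def read_mppus(
    path: str | Path,
    scale_min: int = 1,
    scale_max: int = 10,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a 27-item problem-use questionnaire response table.

    The file must contain ``participant_id`` plus exactly 27 item
    columns; every response must be an integer in
    ``[scale_min, scale_max]``.

    Returns a frame with ``participant_id`` plus ``item_01`` ...
    ``item_27``.

    Raises
    ------
    SchemaError
        Wrong number of item columns.
    ValidationError
        Out-of-range or non-integer response (the message names the
        offending participant and item).
    """
    df = _read_table(path, delimiter)
    if "participant_id" not in df.columns:
        raise DialectError("questionnaire file missing column 'participant_id'")
    item_cols = [c for c in df.columns if c != "participant_id"]
    if len(item_cols) != N_MPPUS_ITEMS:
        raise SchemaError(
            f"expected {N_MPPUS_ITEMS} item columns, found {len(item_cols)}"
        )

    items = df[item_cols].apply(pd.to_numeric, errors="coerce")
    values = items.to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values != np.round(values))
    bad |= (values < scale_min) | (values > scale_max)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"invalid response for participant {df['participant_id'].iloc[r]!r} "
            f"item {item_cols[c]!r}: {df[item_cols[c]].iloc[r]!r} "
            f"(scale {scale_min}..{scale_max})"
        )

    out = pd.DataFrame(values.astype(int), columns=[f"item_{i + 1:02d}" for i in range(N_MPPUS_ITEMS)])
    out.insert(0, "participant_id", df["participant_id"].astype(str).to_numpy())
    return out
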
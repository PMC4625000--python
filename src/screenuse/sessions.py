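"""Pairing screen-state events into use sessions.

A *use session* runs from the phone entering an interactive state (ON)
to it leaving that state (OFF).  Real logs are imperfect: the logger can
miss an OFF when the handset powers down, producing a spuriously long
session (> 5 h) that really spans a period with the phone switched off —
overnight, this is almost always a power-off artifact.  Sessions are
flagged, never deleted: flagged sessions stay in every downstream metric
unless the caller explicitly filters them, and daily medians (rather
than means) keep the summaries robust to the long tail they create.

Each session is allocated to the calendar day and six-hour time-of-day
window in which it *originated* — a use starting 23:59 and ending 00:30
belongs entirely to its start date and the evening window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .events import STATE_OFF, STATE_ON

# anomaly flags
FLAG_SUSPECTED_POWER_OFF = "SUSPECTED_POWER_OFF"
FLAG_OVERNIGHT_POWER_OFF = "OVERNIGHT_POWER_OFF"
FLAG_UNTERMINATED = "UNTERMINATED"
FLAG_TRUNCATED_AT_BOUNDARY = "TRUNCATED_AT_BOUNDARY"
FLAG_MALFORMED_PAIRING = "MALFORMED_PAIRING"

#: Sessions longer than this many seconds are suspected power-off
#: artifacts (5 hours).
LONG_SESSION_THRESHOLD_S = 18_000.0

SESSION_COLUMNS = [
    "participant_id",
    "start",
    "end",
    "duration_s",
    "flags",
]


@dataclass(frozen=True)
class WindowSpec:
    """A partition of the 24-hour day into named half-open windows.

    Each entry is ``(name, start_hour, end_hour)`` with intervals
    ``[start, end)`` in local clock hours.  The default is the four
    six-hour windows night [00,06), morning [06,12), afternoon [12,18)
    and evening [18,24).  Half-open intervals make boundary membership
    unambiguous: 06:00:00 exactly is morning, not night.
    """

    windows: tuple[tuple[str, int, int], ...] = (
        ("night", 0, 6),
        ("morning", 6, 12),
        ("afternoon", 12, 18),
        ("evening", 18, 24),
    )

    def __post_init__(self) -> None:
        edges = sorted((lo, hi) for _, lo, hi in self.windows)
        cursor = 0
        for lo, hi in edges:
            if lo != cursor or hi <= lo:
                raise ConfigError(
                    f"windows must partition [0, 24) exactly; got {self.windows}"
                )
            cursor = hi
        if cursor != 24:
            raise ConfigError("windows must cover the full 24-hour day")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.windows]

    def window_of(self, ts: pd.Timestamp) -> str:
        hour = ts.hour + ts.minute / 60 + ts.second / 3600
        for name, lo, hi in self.windows:
            if lo <= hour < hi:
                return name
        raise AssertionError("unreachable: windows partition the day")

    def bounds(self, name: str) -> tuple[int, int]:
        for n, lo, hi in self.windows:
            if n == name:
                return lo, hi
        raise KeyError(name)


DEFAULT_WINDOWS = WindowSpec()


class PairingResult(NamedTuple):
    sessions: pd.DataFrame
    n_orphan_off: int


def _empty_sessions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "start": pd.Series(dtype="datetime64[ns]"),
            "end": pd.Series(dtype="datetime64[ns]"),
            "duration_s": pd.Series(dtype=float),
            "flags": pd.Series(dtype=str),
        }
    )


def pair_sessions(
    events: pd.DataFrame,
    observation_end: pd.Timestamp | dict[str, pd.Timestamp] | None = None,
) -> PairingResult:
    """Pair ON/OFF events into use sessions, per participant.

    Rules, applied to the time-sorted event stream of each participant:

    * an ON followed by an OFF closes a clean session;
    * an ON followed by another ON closes the first session at the second
      ON's timestamp, flagged ``MALFORMED_PAIRING`` (the true end was not
      observed);
    * a final ON with no subsequent OFF closes at ``observation_end``
      (default: the participant's last event timestamp), flagged
      ``UNTERMINATED``;
    * an OFF with no open session has no attested interaction start and
      is discarded — but counted, not silently swallowed.

    Every ON therefore opens exactly one session.

    Parameters
    ----------
    events
        Frame with ``participant_id``, ``timestamp``, ``state``, sorted
        ascending within participant.
    observation_end
        Either a single timestamp applied to all participants, or a
        mapping participant → timestamp.

    Returns
    -------
    PairingResult
        ``sessions`` (participant_id, start, end, duration_s, flags) in
        deterministic order, and the count of discarded orphan OFFs.
    """
    if events.empty:
        return PairingResult(_empty_sessions(), 0)

    rows: list[tuple] = []
    n_orphan = 0
    for pid, grp in events.groupby("participant_id", sort=True):
        ts = grp["timestamp"].to_numpy()
        states = grp["state"].to_numpy()
        if isinstance(observation_end, dict):
            obs_end = observation_end.get(pid, ts[-1])
        elif observation_end is not None:
            obs_end = observation_end
        else:
            obs_end = ts[-1]
        obs_end = np.datetime64(pd.Timestamp(obs_end), "ns")

        open_start = None
        for t, s in zip(ts, states):
            if s == STATE_ON:
                if open_start is not None:
                    rows.append((pid, open_start, t, FLAG_MALFORMED_PAIRING))
                open_start = t
            elif s == STATE_OFF:
                if open_start is None:
                    n_orphan += 1
                else:
                    rows.append((pid, open_start, t, ""))
                    open_start = None
        if open_start is not None:
            end = max(obs_end, open_start)
            rows.append((pid, open_start, end, FLAG_UNTERMINATED))

    if not rows:
        return PairingResult(_empty_sessions(), n_orphan)

    sessions = pd.DataFrame(rows, columns=["participant_id", "start", "end", "flags"])
    sessions["start"] = pd.to_datetime(sessions["start"])
    sessions["end"] = pd.to_datetime(sessions["end"])
    sessions["duration_s"] = (
        sessions["end"].astype("int64") - sessions["start"].astype("int64")
    ) / 1e9
    sessions = sessions[SESSION_COLUMNS]
    sessions = sessions.sort_values(
        ["participant_id", "start", "end"], kind="stable"
    ).reset_index(drop=True)
    return PairingResult(sessions, n_orphan)


def _add_flag(flags: pd.Series, mask: pd.Series, flag: str) -> pd.Series:
    joined = flags.where(~mask, flags.where(flags == "", flags + ";") + flag)
    return joined


def _intersects_night(
    start: pd.Timestamp, end: pd.Timestamp, night_lo: int, night_hi: int
) -> bool:
    """Does [start, end) overlap any daily night window [lo, hi) hours?"""
    day = start.normalize()
    last_day = end.normalize()
    while day <= last_day:
        n_lo = day + pd.Timedelta(hours=night_lo)
        n_hi = day + pd.Timedelta(hours=night_hi)
        if start < n_hi and end > n_lo:
            return True
        day += pd.Timedelta(days=1)
    return False


def flag_anomalies(
    sessions: pd.DataFrame,
    long_threshold_s: float = LONG_SESSION_THRESHOLD_S,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Flag suspected power-off artifacts; sessions are retained.

    A session strictly longer than ``long_threshold_s`` (default 5 h)
    gets ``SUSPECTED_POWER_OFF``: the logger misses the OFF when the
    handset shuts down and the ON at reboot, so a shutdown masquerades as
    one very long use.  A suspected session whose interval additionally
    intersects the night window gets ``OVERNIGHT_POWER_OFF`` — overnight
    occurrences are where the power-off explanation is established.

    Flagged sessions remain in all downstream analyses; exclusion is an
    explicit caller choice (see :func:`screenuse.metrics.daily_summaries`).
    """
    if long_threshold_s <= 0:
        raise ConfigError(f"long_threshold_s must be positive, got {long_threshold_s}")
    out = sessions.copy()
    if out.empty:
        return out
    long_mask = out["duration_s"] > long_threshold_s
    out["flags"] = _add_flag(out["flags"], long_mask, FLAG_SUSPECTED_POWER_OFF)

    night_lo, night_hi = windows.bounds("night")
    overnight = long_mask.copy()
    for i in out.index[long_mask]:
        overnight.loc[i] = _intersects_night(
            out.at[i, "start"], out.at[i, "end"], night_lo, night_hi
        )
    out["flags"] = _add_flag(out["flags"], overnight, FLAG_OVERNIGHT_POWER_OFF)
    return out


def assign_windows(
    sessions: pd.DataFrame, spec: WindowSpec = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Assign each session its origin day and time-of-day window.

    Both are functions of the *start* instant only: a use spanning
    midnight or a window boundary is allocated to the period in which it
    originated.  Adds ``origin_day`` (datetime.date) and
    ``origin_window`` columns.
    """
    out = sessions.copy()
    if out.empty:
        out["origin_day"] = pd.Series(dtype=object)
        out["origin_window"] = pd.Series(dtype=str)
        return out
    start = out["start"]
    out["origin_day"] = start.dt.date
    hours = start.dt.hour + start.dt.minute / 60 + start.dt.second / 3600
    window = pd.Series("", index=out.index, dtype=object)
    for name, lo, hi in spec.windows:
        window[(hours >= lo) & (hours < hi)] = name
    out["origin_window"] = window
    return out


def sessionize(
    events: pd.DataFrame,
    observation_end: pd.Timestamp | dict[str, pd.Timestamp] | None = None,
    long_threshold_s: float = LONG_SESSION_THRESHOLD_S,
    windows: WindowSpec = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Full pipeline: pair events, flag anomalies, assign day/window."""
    paired = pair_sessions(events, observation_end=observation_end)
    flagged = flag_anomalies(paired.sessions, long_threshold_s, windows)
    return assign_windows(flagged, windows)


def has_flag(sessions: pd.DataFrame, flag: str) -> pd.Series:
    """Boolean mask of sessions carrying ``flag``."""
    return sessions["flags"].str.split(";").map(lambda fs: flag in fs)


def write_sessions(sessions: pd.DataFrame, path) -> None:
    """Export the session table as delimited text, deterministic order."""
    out = sessions.sort_values(
        ["participant_id", "start", "end"], kind="stable"
    ).copy()
    out["start"] = out["start"].map(pd.Timestamp.isoformat)
    out["end"] = out["end"].map(pd.Timestamp.isoformat)
    out.to_csv(path, index=False)
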
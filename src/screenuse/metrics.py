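"""Descriptive usage metrics from the session table.

The summarisation runs in two stages.  Daily summaries give, for each
participant and calendar day, the number of uses, total duration, and
the *median* use length — the median, not the mean, because suspected
power-off artifacts inflate a day's mean unboundedly while moving its
median by at most one order statistic.  Participant summaries then
average the daily values, so a participant's "mean use length" is a mean
of daily medians.

*Checks* — brief habitual glances at the phone (time, notifications) —
are uses of at most 15 seconds; their sub-second structure is summarised
in a fixed-width histogram.  Only each participant's first 14 observed
calendar days enter the summaries, matching the two-week observation
design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, ValidationError
from .sessions import DEFAULT_WINDOWS, FLAG_SUSPECTED_POWER_OFF, WindowSpec, has_flag

#: A use of at most this many seconds (inclusive) counts as a check.
CHECK_THRESHOLD_S = 15.0

#: Default duration-category edges (seconds) for the skew summary:
#: 0-15 s, 15-30 s, 30-60 s, 1-5 min, 5-30 min, > 30 min.
DEFAULT_CATEGORY_EDGES = (15.0, 30.0, 60.0, 300.0, 1800.0)


def _filter_power_off(sessions: pd.DataFrame, include: bool) -> pd.DataFrame:
    if include or sessions.empty:
        return sessions
    return sessions[~has_flag(sessions, FLAG_SUSPECTED_POWER_OFF)]


def daily_summaries(
    sessions: pd.DataFrame,
    first_n_days: int = 14,
    windows: WindowSpec = DEFAULT_WINDOWS,
    include_power_off: bool = True,
    check_threshold_s: float = CHECK_THRESHOLD_S,
) -> pd.DataFrame:
    """Per-participant per-day usage summaries.

    For each participant, only sessions whose origin day falls among the
    first ``first_n_days`` distinct observed calendar dates are
    summarised.  Calendar days inside that span with zero sessions
    appear with ``n_uses = 0`` and an undefined (NaN) median, flagged by
    ``median_defined = False``.

    ``include_power_off=False`` drops suspected power-off sessions first
    (a sensitivity analysis; the default retains them).

    Returns one row per (participant, day) with columns ``n_uses``,
    ``total_duration_s``, ``median_use_length_s``, ``median_defined``,
    ``n_checks``, ``n_under_30s``, and per-window ``{w}_n_uses``,
    ``{w}_total_s``, ``{w}_median_s``.
    """
    if first_n_days < 1:
        raise ConfigError("first_n_days must be >= 1")
    sessions = _filter_power_off(sessions, include_power_off)
    if "origin_day" not in sessions.columns:
        raise ValidationError("sessions lack origin_day; run assign_windows first")

    rows = []
    for pid, grp in sessions.groupby("participant_id", sort=True):
        observed = sorted(grp["origin_day"].unique())
        eligible = observed[:first_n_days]
        if not eligible:
            continue
        span = pd.date_range(eligible[0], eligible[-1], freq="D").date
        grp = grp[grp["origin_day"].isin(set(eligible))]
        by_day = dict(tuple(grp.groupby("origin_day")))
        for day in span:
            g = by_day.get(day)
            row: dict = {"participant_id": pid, "day": day}
            if g is None or g.empty:
                row.update(
                    n_uses=0,
                    total_duration_s=0.0,
                    median_use_length_s=np.nan,
                    median_defined=False,
                    n_checks=0,
                    n_under_30s=0,
                )
                for w in windows.names:
                    row[f"{w}_n_uses"] = 0
                    row[f"{w}_total_s"] = 0.0
                    row[f"{w}_median_s"] = np.nan
            else:
                d = g["duration_s"]
                row.update(
                    n_uses=len(g),
                    total_duration_s=float(d.sum()),
                    median_use_length_s=float(d.median()),
                    median_defined=True,
                    n_checks=int((d <= check_threshold_s).sum()),
                    n_under_30s=int((d < 30.0).sum()),
                )
                for w in windows.names:
                    dw = d[g["origin_window"] == w]
                    row[f"{w}_n_uses"] = len(dw)
                    row[f"{w}_total_s"] = float(dw.sum())
                    row[f"{w}_median_s"] = float(dw.median()) if len(dw) else np.nan
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["participant_id", "day", "n_uses"])
    return pd.DataFrame(rows)


def participant_summary(
    dailies: pd.DataFrame, windows: WindowSpec = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Across-days summary per participant.

    Arithmetic means over the participant's days: ``mean_daily_uses``
    (uses/day; empty days contribute 0), ``mean_total_daily_duration_h``
    (hours/day), ``mean_of_daily_median_s`` (seconds; days with an
    undefined median are excluded — a median of nothing is undefined),
    ``checks_per_day``, and ``pct_under_30s`` — the percentage of *all*
    of the participant's uses shorter than 30 s.
    """
    if dailies.empty:
        raise EmptyInputError("no daily summaries to aggregate")
    rows = []
    for pid, g in dailies.groupby("participant_id", sort=True):
        n_uses_total = int(g["n_uses"].sum())
        rows.append(
            {
                "participant_id": pid,
                "n_days": len(g),
                "mean_daily_uses": float(g["n_uses"].mean()),
                "mean_total_daily_duration_h": float(
                    g["total_duration_s"].mean() / 3600.0
                ),
                "mean_of_daily_median_s": float(
                    g.loc[g["median_defined"], "median_use_length_s"].mean()
                ),
                "checks_per_day": float(g["n_checks"].mean()),
                "pct_under_30s": (
                    100.0 * g["n_under_30s"].sum() / n_uses_total
                    if n_uses_total
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CheckHistogram:
    """Counts of check durations in fixed half-open bins.

    ``counts[k]`` covers ``[k*bin_width, (k+1)*bin_width)``; the top
    edge of the last bin is inclusive so that a duration exactly equal
    to ``upper_limit`` (checks run *up to* 15 s) is counted.
    """

    bin_width: float
    upper_limit: float
    counts: np.ndarray

    @property
    def bin_edges(self) -> np.ndarray:
        n = len(self.counts)
        return np.linspace(0.0, self.upper_limit, n + 1)

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {"bin_lo_s": edges[:-1], "bin_hi_s": edges[1:], "count": self.counts}
        )


def check_histogram(
    sessions: pd.DataFrame,
    bin_width: float = 0.5,
    upper_limit: float = CHECK_THRESHOLD_S,
    include_power_off: bool = True,
) -> CheckHistogram:
    """Histogram of check durations pooled over the given sessions."""
    n_bins_f = upper_limit / bin_width
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ConfigError(
            f"bin_width {bin_width} does not divide upper_limit {upper_limit}"
        )
    n_bins = int(round(n_bins_f))
    sessions = _filter_power_off(sessions, include_power_off)
    d = sessions["duration_s"].to_numpy(dtype=float)
    d = d[d <= upper_limit]
    idx = np.minimum(np.floor(d / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return CheckHistogram(bin_width=bin_width, upper_limit=upper_limit, counts=counts)


def duration_category_distribution(
    sessions: pd.DataFrame,
    category_edges: tuple[float, ...] = DEFAULT_CATEGORY_EDGES,
    include_power_off: bool = True,
) -> pd.DataFrame:
    """Percentage of uses falling in each duration category.

    Categories are half-open ``[lo, hi)`` between consecutive edges,
    with an implicit first edge at 0 and an unbounded last category.
    Percentages sum to 100 up to rounding.
    """
    edges = list(category_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ConfigError("category_edges must be strictly increasing")
    sessions = _filter_power_off(sessions, include_power_off)
    d = sessions["duration_s"].to_numpy(dtype=float)
    if d.size == 0:
        raise EmptyInputError("no sessions to categorise")
    full = [0.0, *edges, math.inf]
    counts, _ = np.histogram(d, bins=full)
    labels = []
    for lo, hi in zip(full[:-1], full[1:]):
        labels.append(f"[{lo:g}s, {hi:g}s)" if math.isfinite(hi) else f">= {lo:g}s")
    return pd.DataFrame(
        {
            "category": labels,
            "lo_s": full[:-1],
            "hi_s": full[1:],
            "n": counts,
            "pct": 100.0 * counts / d.size,
        }
    )


def time_of_day_table(
    dailies: pd.DataFrame, windows: WindowSpec = DEFAULT_WINDOWS
) -> pd.DataFrame:
    """Participant × window means, shaped for repeated-measures analysis.

    For every participant and window: mean daily number of uses, mean
    daily total duration (seconds), and mean daily median use length
    (days without a median in that window excluded).  Participants with
    *no* session in some window over the whole observation get
    ``complete = False``; duration-length analyses drop them, as an
    all-empty window has no mean length.
    """
    if dailies.empty:
        raise EmptyInputError("no daily summaries")
    rows = []
    for pid, g in dailies.groupby("participant_id", sort=True):
        row: dict = {"participant_id": pid}
        complete = True
        for w in windows.names:
            n_uses = g[f"{w}_n_uses"]
            row[f"{w}_mean_n_uses"] = float(n_uses.mean())
            row[f"{w}_mean_total_s"] = float(g[f"{w}_total_s"].mean())
            med = g[f"{w}_median_s"].dropna()
            row[f"{w}_mean_median_s"] = float(med.mean()) if len(med) else np.nan
            if n_uses.sum() == 0:
                complete = False
        row["complete"] = complete
        rows.append(row)
    return pd.DataFrame(rows)


def window_matrix(
    tod: pd.DataFrame,
    metric: str,
    windows: WindowSpec = DEFAULT_WINDOWS,
    require_complete: bool = False,
) -> pd.DataFrame:
    """Extract a participants × windows matrix for one metric.

    ``metric`` is one of ``mean_n_uses``, ``mean_total_s``,
    ``mean_median_s``.  With ``require_complete`` (used for duration and
    length analyses) participants missing any window are removed first.
    """
    if require_complete:
        tod = tod[tod["complete"]]
    cols = [f"{w}_{metric}" for w in windows.names]
    mat = tod.set_index("participant_id")[cols]
    mat.columns = windows.names
    return mat.dropna()
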
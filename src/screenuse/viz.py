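"""Barcode and average-heatmap visualisations of phone use.

The barcode is a day-by-time binary raster: one row per calendar day,
one column per time bin (default 60 s), a cell dark iff the phone was in
use during *any part* of that bin.  Any-overlap occupancy keeps one-
second checks visible at minute resolution — the whole point of the plot
is that brief habitual uses show up as fine vertical stitching, while
weekday alarm times appear as a crisp vertical band.

The average heatmap folds the barcode over days — all days onto one row,
onto the seven days of the week (Monday first), or onto weekday vs
weekend — and averages the binary cells into occupancy probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ConfigError, EmptyInputError
from .sessions import FLAG_SUSPECTED_POWER_OFF, has_flag

SECONDS_PER_DAY = 86_400

HEATMAP_MODES = ("one_day", "seven_days", "weekday_weekend")


@dataclass
class BarcodeMatrix:
    """Binary day × time-bin occupancy raster for one participant."""

    values: np.ndarray  # shape (n_days, n_bins), dtype uint8
    days: list[date]
    bin_seconds: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a table (rows indexed by day) for text export."""
        return pd.DataFrame(self.values, index=pd.Index(self.days, name="day"))


@dataclass
class HeatmapMatrix:
    """Mean occupancy in [0, 1] per folded row; NaN rows had no days."""

    values: np.ndarray
    row_labels: list[str]
    bin_seconds: int
    mode: str


def barcode_matrix(
    sessions: pd.DataFrame,
    day_range: tuple[date, date] | None = None,
    bin_seconds: int = 60,
    include_power_off: bool = True,
) -> BarcodeMatrix:
    """Rasterise sessions into a binary day × time-bin matrix.

    A cell is 1 iff at least one session interval overlaps the bin
    interval; sessions spanning midnight paint bins in every row they
    touch.  ``day_range`` is inclusive on both ends and defaults to the
    span of the session starts.
    """
    if bin_seconds <= 0 or SECONDS_PER_DAY % bin_seconds != 0:
        raise ConfigError(f"bin_seconds must divide 24 h, got {bin_seconds}")
    if not include_power_off and not sessions.empty:
        sessions = sessions[~has_flag(sessions, FLAG_SUSPECTED_POWER_OFF)]
    if day_range is None:
        if sessions.empty:
            raise EmptyInputError("no sessions and no explicit day_range")
        first = sessions["start"].min().date()
        last = sessions["end"].max().date()
        day_range = (first, last)
    d0, d1 = day_range
    if d1 < d0:
        raise ConfigError(f"empty day range {day_range}")
    days = [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]
    n_bins = SECONDS_PER_DAY // bin_seconds
    values = np.zeros((len(days), n_bins), dtype=np.uint8)

    origin = pd.Timestamp(d0)
    start_s = (sessions["start"] - origin).dt.total_seconds().to_numpy()
    end_s = (sessions["end"] - origin).dt.total_seconds().to_numpy()
    total_s = len(days) * SECONDS_PER_DAY
    for s, e in zip(start_s, end_s):
        s = max(s, 0.0)
        e = min(e, float(total_s))
        if e < s:
            continue
        first_bin = int(s // bin_seconds)
        # any overlap: a session ending exactly on a bin edge does not
        # enter the next bin; a zero-length session marks its start bin
        last_bin = int(e // bin_seconds) if (e > s and e % bin_seconds == 0) else int(e // bin_seconds) + 1
        last_bin = min(last_bin, total_s // bin_seconds)
        if first_bin >= total_s // bin_seconds:
            continue
        flat = values.reshape(-1)
        flat[first_bin:max(last_bin, first_bin + 1)] = 1
    return BarcodeMatrix(values=values, days=days, bin_seconds=bin_seconds)


def average_heatmap(matrix: BarcodeMatrix, mode: str = "one_day") -> HeatmapMatrix:
    """Fold a barcode over days and average to occupancy probabilities.

    Modes: ``one_day`` (single row, mean over all days), ``seven_days``
    (Monday..Sunday), ``weekday_weekend``.  A fold group containing no
    days yields a NaN row rather than a fabricated zero.
    """
    if mode not in HEATMAP_MODES:
        raise ConfigError(f"mode must be one of {HEATMAP_MODES}, got {mode!r}")
    vals = matrix.values.astype(float)
    weekdays = np.array([d.weekday() for d in matrix.days])
    if mode == "one_day":
        groups = [("all days", np.ones(len(matrix.days), dtype=bool))]
    elif mode == "seven_days":
        names = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
        groups = [(names[i], weekdays == i) for i in range(7)]
    else:
        groups = [("weekday", weekdays < 5), ("weekend", weekdays >= 5)]
    rows, labels = [], []
    for label, mask in groups:
        labels.append(label)
        if mask.any():
            rows.append(vals[mask].mean(axis=0))
        else:
            rows.append(np.full(matrix.n_bins, np.nan))
    return HeatmapMatrix(
        values=np.vstack(rows),
        row_labels=labels,
        bin_seconds=matrix.bin_seconds,
        mode=mode,
    )


def _time_ticks(n_bins: int, bin_seconds: int):
    hours = range(0, 25, 6)
    pos = [h * 3600 / bin_seconds for h in hours]
    labels = [f"{h:02d}:00" for h in hours]
    return pos, labels


def render(
    matrix: BarcodeMatrix | HeatmapMatrix,
    out_path,
    weekend_marker: bool = True,
    title: str | None = None,
) -> None:
    """Render a barcode or heatmap to PNG/SVG (by file suffix).

    Black marks phone-in-use on a white background.  For a barcode with
    ``weekend_marker`` set, Saturday rows are underlined with a red
    dashed rule.  Output is deterministic: the same matrix produces
    byte-identical vector output (file metadata is pinned).
    """
    is_barcode = isinstance(matrix, BarcodeMatrix)
    vals = matrix.values.astype(float)
    n_rows, n_bins = vals.shape
    fig_h = max(1.5, 0.25 * n_rows + 1.2)
    fig, ax = plt.subplots(figsize=(10, fig_h))
    ax.imshow(
        vals,
        aspect="auto",
        cmap="gray_r",
        vmin=0.0,
        vmax=1.0,
        interpolation="nearest",
        extent=(0, n_bins, n_rows, 0),
    )
    pos, labels = _time_ticks(n_bins, matrix.bin_seconds)
    ax.set_xticks(pos)
    ax.set_xticklabels(labels)
    ax.set_xlabel("time of day")
    if is_barcode:
        ax.set_yticks(np.arange(n_rows) + 0.5)
        ax.set_yticklabels([d.isoformat() for d in matrix.days], fontsize=7)
        if weekend_marker:
            for i, d in enumerate(matrix.days):
                if d.weekday() == 5:  # Saturday
                    ax.axhline(i, color="red", linestyle="--", linewidth=0.8)
    else:
        ax.set_yticks(np.arange(n_rows) + 0.5)
        ax.set_yticklabels(matrix.row_labels)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path = str(out_path)
    metadata = {"Date": None} if out_path.endswith(".svg") else None
    try:
        # fixed hashsalt pins the generated SVG element ids, so identical
        # matrices produce byte-identical vector output
        with matplotlib.rc_context({"svg.hashsalt": "screenuse"}):
            fig.savefig(out_path, dpi=150, metadata=metadata)
    finally:
        plt.close(fig)
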
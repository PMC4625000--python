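"""Independent oracles used by the test suite.

These deliberately re-derive results from first principles (explicit
loops, stack-based pairing, definitional sums of squares) so that they
share no code path with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def stack_pair_oracle(events, observation_end):
    """Brute-force stack-based pairing of a single participant's stream.

    ``events``: list of (timestamp, state) sorted ascending.
    Returns list of (start, end, flag) and the orphan-OFF count.
    """
    out = []
    stack = []
    n_orphan = 0
    for t, s in events:
        if s == "ON":
            if stack:
                prev = stack.pop()
                out.append((prev, t, "MALFORMED_PAIRING"))
            stack.append(t)
        else:
            if stack:
                out.append((stack.pop(), t, ""))
            else:
                n_orphan += 1
    while stack:
        start = stack.pop()
        out.append((start, max(observation_end, start), "UNTERMINATED"))
    out.sort(key=lambda r: (r[0], r[1]))
    return out, n_orphan


def random_event_stream(rng: np.random.Generator, pid: str = "P01"):
    """A random, mostly alternating stream with injected anomalies."""
    n = int(rng.integers(0, 60))
    t = pd.Timestamp("2015-03-02") + pd.Timedelta(seconds=int(rng.integers(0, 3600)))
    rows = []
    state = "ON"
    for _ in range(n):
        rows.append((pid, t, state))
        # occasionally repeat a state (duplicate ON / orphan OFF)
        if rng.random() < 0.15:
            state = rng.choice(["ON", "OFF"])
        else:
            state = "OFF" if state == "ON" else "ON"
        t = t + pd.Timedelta(seconds=float(rng.uniform(0.5, 600)))
    return rows


def brute_force_daily(sessions: pd.DataFrame, first_n_days: int = 14):
    """Recompute per-day counts/totals/medians by explicit row scans."""
    out = {}
    for pid in sorted(sessions["participant_id"].unique()):
        g = sessions[sessions["participant_id"] == pid]
        days = sorted({ts.date() for ts in g["start"]})
        eligible = days[:first_n_days]
        for day in eligible:
            durs = sorted(
                row.duration_s
                for row in g.itertuples()
                if row.start.date() == day
            )
            n = len(durs)
            mid = n // 2
            median = durs[mid] if n % 2 else 0.5 * (durs[mid - 1] + durs[mid])
            out[(pid, day)] = (n, sum(durs), median)
    return out


def anova_ss_oracle(matrix: np.ndarray):
    """Definitional repeated-measures sums of squares via explicit loops."""
    n, k = matrix.shape
    grand = sum(matrix[i][j] for i in range(n) for j in range(k)) / (n * k)
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    row_means = [sum(matrix[i][j] for j in range(k)) / k for i in range(n)]
    ss_cond = n * sum((m - grand) ** 2 for m in col_means)
    ss_subj = k * sum((m - grand) ** 2 for m in row_means)
    ss_total = sum(
        (matrix[i][j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_total - ss_cond - ss_subj
    df_e, df_r = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df_e) / (ss_err / df_r)
    eta = ss_cond / (ss_cond + ss_err)
    return F, df_e, df_r, eta


def paired_t_oracle(x, y):
    """Textbook paired t: d-bar / (s_d / sqrt(n))."""
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n)


def pearson_oracle(x, y):
    """Covariance-formula correlation via explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def barcode_oracle(sessions: pd.DataFrame, d0, n_days: int, bin_seconds: int):
    """Per-bin interval-overlap test, one bin at a time."""
    n_bins = 86_400 // bin_seconds
    mat = np.zeros((n_days, n_bins), dtype=np.uint8)
    origin = pd.Timestamp(d0)
    intervals = [
        (
            (row.start - origin).total_seconds(),
            (row.end - origin).total_seconds(),
        )
        for row in sessions.itertuples()
    ]
    for day in range(n_days):
        for b in range(n_bins):
            lo = day * 86_400 + b * bin_seconds
            hi = lo + bin_seconds
            for s, e in intervals:
                if s < hi and e > lo:
                    mat[day, b] = 1
                    break
                if s == e and lo <= s < hi:
                    mat[day, b] = 1
                    break
    return mat
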
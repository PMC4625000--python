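"""Inferential layer: does self-reported use reflect logged use?

Paired t-tests and Pearson correlations compare each participant's
estimated daily use (duration in hours, number of uses) with the values
computed from their event log; a one-way repeated-measures ANOVA with
Fisher's LSD pairwise follow-ups tests time-of-day differences; the
27-item problem-use scale is scored against published norms and its
internal consistency summarised by standardised Cronbach's alpha.

Conventions: two-sided p-values throughout; pairwise-complete deletion
per analysis cell (each correlation or test uses every participant with
both values present, so degrees of freedom may differ between cells and
are always reported alongside).  No sphericity correction is applied to
the repeated-measures ANOVA; with four within-subject levels this is a
known limitation and the raw p-values should be read accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class PairedTestResult:
    """Classical paired-samples t-test on the differences x - y."""

    t: float
    df: int
    p: float
    mean_diff: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with df = n - 2."""

    r: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way repeated-measures ANOVA across within-subject levels.

    ``partial_eta_sq = SS_effect / (SS_effect + SS_error)``, equivalently
    ``df_effect*F / (df_effect*F + df_error)``.  ``pairwise`` holds
    Fisher's-LSD follow-ups: uncorrected paired t-tests per level pair.
    """

    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    pairwise: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def paired_t(x, y) -> PairedTestResult:
    """Paired-samples t-test of H0: mean(x - y) = 0.

    Pairs with a missing value are dropped first.  If the differences
    have zero variance the statistic is reported as 0 (p = 1) when the
    mean difference is zero and as signed infinity (p = 0) otherwise,
    rather than NaN.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 2:
        raise ValidationError(f"paired t-test needs >= 2 complete pairs, got {n}")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, n=n)
        t = math.inf if mean_d > 0 else -math.inf
        return PairedTestResult(t=t, df=df, p=0.0, mean_diff=mean_d, n=n)
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTestResult(t=float(t), df=df, p=float(p), mean_diff=mean_d, n=n)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation; p via t = r * sqrt(df / (1 - r^2)), df = n - 2."""
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValidationError(f"correlation needs >= 3 complete pairs, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("correlation undefined: zero variance in an input")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, df=df, p=float(p), n=n)


def rm_anova_one_way(data: pd.DataFrame | np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects × levels matrix.

    The total sum of squares is partitioned into between-subject,
    condition, and (subject × condition) error components:

        SS_cond  = n * sum_j (mean_j - grand)^2
        SS_subj  = k * sum_i (mean_i - grand)^2
        SS_error = SS_total - SS_cond - SS_subj

    with F = (SS_cond / (k-1)) / (SS_error / ((n-1)(k-1))).  The matrix
    must be complete — remove subjects with missing cells first.
    Fisher's-LSD pairwise comparisons (uncorrected paired t-tests) are
    attached for every level pair.
    """
    mat = pd.DataFrame(data)
    if mat.isna().any().any():
        raise ValidationError("repeated-measures matrix must be complete (no NaN)")
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >= 2 subjects and >= 2 levels, got {n} x {k}")
    values = mat.to_numpy(dtype=float)
    grand = values.mean()
    col_means = values.mean(axis=0)
    row_means = values.mean(axis=1)
    ss_total = float(((values - grand) ** 2).sum())
    ss_cond = float(n * ((col_means - grand) ** 2).sum())
    ss_subj = float(k * ((row_means - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    if ms_err <= 0.0:
        F = 0.0 if ss_cond == 0.0 else math.inf
        p = 1.0 if F == 0.0 else 0.0
    else:
        F = ms_cond / ms_err
        p = float(sps.f.sf(F, df_effect, df_error))
    denom = ss_cond + ss_err
    eta = ss_cond / denom if denom > 0 else 0.0

    pairwise = []
    levels = list(mat.columns)
    for a, b in combinations(levels, 2):
        res = paired_t(mat[a], mat[b])
        pairwise.append((str(a), str(b), res.p))
    return RmAnovaResult(
        F=float(F),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        partial_eta_sq=float(eta),
        pairwise=tuple(pairwise),
    )


def cronbach_alpha_standardized(items: pd.DataFrame | np.ndarray) -> float:
    """Standardised Cronbach's alpha from mean inter-item correlation.

    alpha_std = k * rbar / (1 + (k - 1) * rbar), where rbar is the mean
    of the k(k-1)/2 pairwise Pearson correlations between items.
    """
    mat = np.asarray(pd.DataFrame(items), dtype=float)
    n, k = mat.shape
    if k < 2 or n < 3:
        raise ValidationError(f"need >= 2 items and >= 3 respondents, got {n} x {k}")
    sd = mat.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(f"zero-variance item at column index {zero[0]}")
    corr = np.corrcoef(mat, rowvar=False)
    iu = np.triu_indices(k, 1)
    rbar = float(corr[iu].mean())
    return k * rbar / (1.0 + (k - 1) * rbar)


def mppus_score_and_flag(
    responses: pd.DataFrame, norm_mean: float, norm_sd: float
) -> pd.DataFrame:
    """Score the 27-item problem-use scale and flag probable problem use.

    The total is the sum of all item responses; a participant is flagged
    when the total is *strictly* greater than ``norm_mean + 2*norm_sd``
    (published norms must be supplied — they are sample statistics from
    the scale's normative study, not constants of this package).

    Returns a frame with ``participant_id``, ``total``, ``problem_flag``;
    the number flagged is ``df["problem_flag"].sum()``.
    """
    if norm_mean is None or norm_sd is None or norm_sd < 0:
        raise ConfigError(
            "MPPUS norms are required: pass the normative sample's mean and SD"
        )
    item_cols = [c for c in responses.columns if c.startswith("item_")]
    if not item_cols:
        raise ValidationError("responses frame has no item_* columns")
    totals = responses[item_cols].sum(axis=1)
    threshold = norm_mean + 2.0 * norm_sd
    return pd.DataFrame(
        {
            "participant_id": responses["participant_id"].astype(str),
            "total": totals.astype(int),
            "problem_flag": totals > threshold,
        }
    )


# ---------------------------------------------------------------------------
# estimated-vs-actual comparison table

COMPARISON_VARS = [
    "estimated_uses",
    "actual_uses",
    "estimated_duration",
    "actual_duration",
    "mppus",
]


@dataclass
class ComparisonTables:
    """Correlation matrix cells plus the two estimated-vs-actual t-tests."""

    correlations: pd.DataFrame
    paired_tests: dict[str, PairedTestResult]
    data: pd.DataFrame

    def correlation(self, a: str, b: str) -> CorrelationResult:
        c = self.correlations
        row = c[((c.var_a == a) & (c.var_b == b)) | ((c.var_a == b) & (c.var_b == a))]
        if row.empty:
            raise KeyError((a, b))
        r = row.iloc[0]
        return CorrelationResult(r=r["r"], df=int(r["df"]), p=r["p"], n=int(r["n"]))


def comparison_matrix(
    participant_summaries: pd.DataFrame,
    self_reports: pd.DataFrame,
    mppus_scores: pd.DataFrame | None = None,
) -> ComparisonTables:
    """Assemble the estimated/actual/problem-use comparison.

    Joins on ``participant_id`` (outer, so pairwise-complete n can
    differ per cell), computes the lower-triangular Pearson matrix over
    estimated uses, actual uses, estimated duration (h/day), actual
    duration (h/day) and the problem-use total, and runs paired t-tests
    for actual-vs-estimated uses and duration.  A cell with fewer than
    3 complete pairs is reported with NaN r rather than fabricated.
    """
    frame = participant_summaries[
        ["participant_id", "mean_daily_uses", "mean_total_daily_duration_h"]
    ].rename(
        columns={
            "mean_daily_uses": "actual_uses",
            "mean_total_daily_duration_h": "actual_duration",
        }
    )
    sr = self_reports[
        ["participant_id", "estimated_daily_uses", "estimated_daily_duration_h"]
    ].rename(
        columns={
            "estimated_daily_uses": "estimated_uses",
            "estimated_daily_duration_h": "estimated_duration",
        }
    )
    frame = frame.merge(sr, on="participant_id", how="outer")
    if mppus_scores is not None:
        mp = mppus_scores[["participant_id", "total"]].rename(columns={"total": "mppus"})
        frame = frame.merge(mp, on="participant_id", how="outer")
    else:
        frame["mppus"] = np.nan

    cells = []
    for i, a in enumerate(COMPARISON_VARS):
        for b in COMPARISON_VARS[:i]:
            x, y = _pairwise_complete(frame[b], frame[a])
            if len(x) < 3:
                cells.append(
                    {"var_a": a, "var_b": b, "r": np.nan, "df": len(x) - 2,
                     "p": np.nan, "n": len(x)}
                )
                continue
            res = pearson(x, y)
            cells.append(
                {"var_a": a, "var_b": b, "r": res.r, "df": res.df, "p": res.p,
                 "n": res.n}
            )
    correlations = pd.DataFrame(cells)

    paired = {}
    for name, actual, est in [
        ("uses", "actual_uses", "estimated_uses"),
        ("duration", "actual_duration", "estimated_duration"),
    ]:
        x, y = _pairwise_complete(frame[actual], frame[est])
        if len(x) >= 2:
            paired[name] = paired_t(x, y)
    return ComparisonTables(correlations=correlations, paired_tests=paired, data=frame)
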
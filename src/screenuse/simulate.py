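"""Synthetic smartphone-usage cohorts with planted ground truth.

The generator emulates the structure of real screen-state logs well
enough that every stage of the pipeline can be exercised — and checked
against known truth — at desk scale:

* session *starts* follow an inhomogeneous Poisson process with
  piecewise-constant rates over the four six-hour windows, ordered
  afternoon ≈ evening > morning > night, with lognormal per-participant
  rate multipliers (real cohorts show very large between-person spread);
* session *durations* come from a mixture dominated by brief checks,
  with modes at 1–3 s, 5–6 s and 10–11 s, calibrated so that 55 % of
  uses are under 30 s and daily totals land near 5 h;
* recurring weekday *alarm* sessions at a fixed clock time (optionally
  with a snooze repeat) reproduce the vertical alarm band visible in
  barcode plots;
* nightly *power-off artifacts* emulate the logger missing the OFF at
  shutdown and the ON at reboot: a > 5 h pseudo-session replaces
  whatever would have happened while the phone was off;
* *self-report estimates* are planted with an exact cohort-level sample
  correlation against true duration (default 0.5) and against true use
  counts (default 0.0) by construction — the empirical-correlation
  technique familiar from ``MASS::mvrnorm(empirical = TRUE)`` — so
  recovery tests are sharp rather than hostage to sampling noise;
* *questionnaire items* follow a one-factor model with exchangeable
  inter-item correlation, discretised to the response scale.

Everything derives from one seed: the same ``SimConfig`` regenerates
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SimulationError
from .events import STATE_OFF, STATE_ON, write_events
from .sessions import DEFAULT_WINDOWS, WindowSpec

NS = 1_000_000_000


@dataclass(frozen=True)
class MixtureComponent:
    """One duration-mixture component: weight plus a sampling recipe."""

    name: str
    weight: float
    kind: str  # "uniform" | "lognormal"
    lo: float  # uniform bounds, or truncation bounds for lognormal
    hi: float
    mu: float = 0.0  # lognormal parameters (of log-seconds)
    sigma: float = 1.0


#: Default duration mixture (seconds).  Checks (<= 15 s) carry 45 % of
#: the mass with the three characteristic modes; a further 10 % in
#: 15-30 s puts 55 % of uses under 30 s.  The remaining mass is split
#: between mid-length uses (30 s - 30 min, lognormal body) and long
#: uses (30-90 min), giving ordinary use a daily total near 4 h at the
#: default intensity; retained power-off artifacts lift the observed
#: daily total towards 5 h.  All components stay far below the 5 h
#: artifact threshold, so only injected artifacts trip the flag.
DEFAULT_MIXTURE = (
    MixtureComponent("check_1_3s", 0.12, "uniform", 1.0, 3.0),
    MixtureComponent("check_5_6s", 0.10, "uniform", 5.0, 6.0),
    MixtureComponent("check_10_11s", 0.10, "uniform", 10.0, 11.0),
    MixtureComponent("check_other", 0.13, "uniform", 0.5, 15.0),
    MixtureComponent("short", 0.10, "uniform", 15.0, 30.0),
    MixtureComponent("mid", 0.43, "lognormal", 30.0, 1800.0, mu=5.0, sigma=1.0),
    MixtureComponent("long", 0.02, "uniform", 1800.0, 5400.0),
)


@dataclass(frozen=True)
class AlarmConfig:
    """Recurring weekday alarm-clock session."""

    hour: int = 7
    minute: int = 0
    duration_lo_s: float = 2.0
    duration_hi_s: float = 8.0
    snooze_minutes: float = 9.0
    snooze_prob: float = 0.5


@dataclass(frozen=True)
class PowerOffConfig:
    """Nightly shutdown artifact: a spurious > 5 h session."""

    prob_per_night: float = 0.15
    duration_lo_s: float = 21_600.0  # 6 h
    duration_hi_s: float = 30_600.0  # 8.5 h
    start_hour_lo: float = 23.0  # start drawn in [23:00, 00:30]
    start_hour_hi: float = 24.5


@dataclass(frozen=True)
class SelfReportConfig:
    """Planted link between true usage and the evening estimates."""

    rho_duration: float = 0.5
    rho_uses: float = 0.0
    est_duration_mean_h: float = 4.12
    est_duration_sd_h: float = 1.5
    est_uses_mean: float = 37.2
    est_uses_sd: float = 15.0


@dataclass(frozen=True)
class MppusConfig:
    """One-factor item model for the 27-item problem-use scale."""

    n_items: int = 27
    scale_min: int = 1
    scale_max: int = 10
    #: latent inter-item correlation; 0.3 yields a standardized alpha
    #: near .89 after discretisation to the 10-point response scale
    rbar: float = 0.3
    item_mean: float = 5.5
    item_sd: float = 2.0
    norm_mean: float = 102.0
    norm_sd: float = 20.0


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic cohort.

    ``window_rates`` are mean session counts per window per day; the
    defaults sum to 85/day with the afternoon ≈ evening > morning >
    night ordering seen in time-of-day breakdowns of real cohorts.
    ``participant_sigma`` is the log-SD of the lognormal per-participant
    rate multiplier (mean 1).
    """

    n_participants: int = 23
    n_days: int = 14
    seed: int = 0
    start_date: str = "2015-03-02"  # a Monday
    window_rates: tuple[tuple[str, float], ...] = (
        ("night", 6.0),
        ("morning", 19.0),
        ("afternoon", 30.0),
        ("evening", 30.0),
    )
    participant_sigma: float = 0.45
    #: truncation range for the per-participant multiplier: untruncated
    #: lognormal tails occasionally demand more busy time than a day
    #: holds once counts and durations both scale with the draw
    participant_mult_range: tuple[float, float] = (0.3, 2.5)
    mixture: tuple[MixtureComponent, ...] = DEFAULT_MIXTURE
    alarm: AlarmConfig | None = field(default_factory=AlarmConfig)
    power_off: PowerOffConfig | None = field(default_factory=PowerOffConfig)
    self_report: SelfReportConfig = field(default_factory=SelfReportConfig)
    mppus: MppusConfig = field(default_factory=MppusConfig)
    min_gap_s: float = 1.0
    windows: WindowSpec = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        total_w = sum(c.weight for c in self.mixture)
        if abs(total_w - 1.0) > 1e-9:
            raise SimulationError(f"mixture weights must sum to 1, got {total_w}")
        if self.n_participants < 1 or self.n_days < 1:
            raise SimulationError("need at least one participant and one day")
        names = {n for n, _ in self.window_rates}
        if names != set(self.windows.names):
            raise SimulationError(
                f"window_rates names {names} do not match windows {self.windows.names}"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests.

    ``sessions`` is the definitive session list (one ON/OFF pair each);
    ``participants`` carries per-participant true metrics, planted
    estimates, questionnaire totals and problem-use flags;
    ``n_power_off`` is the number of injected shutdown artifacts;
    ``alarm_bin_of_day`` gives the alarm's column index at 60 s barcode
    resolution (None when alarms are disabled).
    """

    sessions: pd.DataFrame
    participants: pd.DataFrame
    n_power_off: int
    alarm_bin_of_day: int | None
    config: SimConfig


@dataclass
class Cohort:
    events: pd.DataFrame
    self_reports: pd.DataFrame
    mppus: pd.DataFrame
    truth: GroundTruth


def _sample_durations(rng: np.random.Generator, comps, n: int) -> np.ndarray:
    weights = np.array([c.weight for c in comps])
    choice = rng.choice(len(comps), size=n, p=weights)
    out = np.empty(n)
    for i, c in enumerate(comps):
        mask = choice == i
        m = int(mask.sum())
        if not m:
            continue
        if c.kind == "uniform":
            out[mask] = rng.uniform(c.lo, c.hi, size=m)
        elif c.kind == "lognormal":
            draws = rng.lognormal(c.mu, c.sigma, size=m)
            bad = (draws < c.lo) | (draws > c.hi)
            while bad.any():  # truncate by redraw
                draws[bad] = rng.lognormal(c.mu, c.sigma, size=int(bad.sum()))
                bad = (draws < c.lo) | (draws > c.hi)
            out[mask] = draws
        else:
            raise SimulationError(f"unknown mixture kind {c.kind!r}")
    return out


def _resolve_overlaps(
    starts_s: np.ndarray, durations_s: np.ndarray, gap_s: float, max_shift_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Serialise sessions in time: push each start past the previous end.

    Starts are sorted, then each session begins no earlier than the
    previous session's end plus ``gap_s``.  Durations are never altered,
    so the planted duration distribution survives intact.  If any start
    must move by more than ``max_shift_s`` the configuration is
    infeasible (the requested intensity cannot fit in the day) and an
    error is raised rather than silently distorting the process.
    """
    order = np.argsort(starts_s, kind="stable")
    s = starts_s[order]
    d = durations_s[order]
    adj = s.copy()
    cursor = -np.inf
    for i in range(len(s)):
        a = s[i] if s[i] > cursor else cursor
        if a - s[i] > max_shift_s:
            raise SimulationError(
                "session intensity too high: sessions cannot be scheduled "
                f"without shifting a start by more than {max_shift_s} s"
            )
        adj[i] = a
        cursor = a + d[i] + gap_s
    return adj, d


def _plant_correlated(
    rng: np.random.Generator,
    truth: np.ndarray,
    rho: float,
    mean: float,
    sd: float,
    floor: float,
) -> np.ndarray:
    """Construct estimates whose sample correlation with ``truth`` is rho.

    The noise vector is orthogonalised against the (standardised) truth
    in-sample, so corr(estimate, truth) equals the planted value exactly
    up to the clipping floor — the empirical-correlation construction.
    """
    n = len(truth)
    z = truth - truth.mean()
    z_norm = np.linalg.norm(z)
    if z_norm == 0:
        return np.clip(mean + sd * rng.standard_normal(n), floor, None)
    z = z / z_norm
    eps = rng.standard_normal(n)
    eps = eps - eps.mean()
    eps = eps - (eps @ z) * z  # orthogonal to truth, zero mean
    eps_norm = np.linalg.norm(eps)
    if eps_norm == 0:
        eps = np.zeros(n)
    else:
        eps = eps / eps_norm
    unit = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    scale = np.linalg.norm(unit)
    est_z = unit / scale if scale > 0 else unit
    return np.clip(mean + sd * np.sqrt(n - 1) * est_z, floor, None)


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate a cohort: event log, self-reports, questionnaire, truth.

    Events strictly alternate ON/OFF per participant, sessions never
    overlap, and (when enabled) each shutdown artifact appears as one
    session longer than 5 h replacing any use that would have fallen
    inside it.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    start_date = pd.Timestamp(config.start_date)
    rates = dict(config.window_rates)

    all_sessions: list[pd.DataFrame] = []
    n_power_off_total = 0
    pids = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    for pid in pids:
        m_lo, m_hi = config.participant_mult_range
        mult = rng.lognormal(
            -config.participant_sigma**2 / 2.0, config.participant_sigma
        )
        while not (m_lo <= mult <= m_hi):
            mult = rng.lognormal(
                -config.participant_sigma**2 / 2.0, config.participant_sigma
            )
        starts: list[np.ndarray] = []
        for day in range(config.n_days):
            day_off = day * 86_400.0
            for name, lo, hi in config.windows.windows:
                lam = rates[name] * mult
                k = rng.poisson(lam)
                if k:
                    starts.append(day_off + rng.uniform(lo * 3600, hi * 3600, size=k))
            if config.alarm is not None:
                weekday = (start_date + pd.Timedelta(days=day)).weekday()
                if weekday < 5:
                    a = config.alarm
                    t0 = day_off + a.hour * 3600 + a.minute * 60
                    alarm_starts = [t0]
                    if rng.uniform() < a.snooze_prob:
                        alarm_starts.append(t0 + a.snooze_minutes * 60)
                    starts.append(np.array(alarm_starts))
        starts_s = np.concatenate(starts) if starts else np.empty(0)
        durations = _sample_durations(rng, config.mixture, len(starts_s))
        if config.alarm is not None:
            # alarm sessions were appended per day; resample their durations
            # from the alarm range by matching the planted start times
            a = config.alarm
            base = a.hour * 3600 + a.minute * 60
            frac = np.mod(starts_s, 86_400.0)
            is_alarm = np.isclose(frac, base, rtol=0, atol=1e-6) | np.isclose(
                frac, base + a.snooze_minutes * 60, rtol=0, atol=1e-6
            )
            durations[is_alarm] = rng.uniform(
                a.duration_lo_s, a.duration_hi_s, size=int(is_alarm.sum())
            )

        # shutdown artifacts: fixed blocks that swallow overlapping use
        artifacts: list[tuple[float, float]] = []
        if config.power_off is not None and config.power_off.prob_per_night > 0:
            po = config.power_off
            for day in range(config.n_days):
                if rng.uniform() < po.prob_per_night:
                    t0 = day * 86_400.0 + rng.uniform(
                        po.start_hour_lo * 3600, po.start_hour_hi * 3600
                    )
                    artifacts.append(
                        (t0, rng.uniform(po.duration_lo_s, po.duration_hi_s))
                    )
        if artifacts:
            keep = np.ones(len(starts_s), dtype=bool)
            for t0, dur in artifacts:
                ends = starts_s + durations
                keep &= (ends <= t0) | (starts_s >= t0 + dur)
            starts_s, durations = starts_s[keep], durations[keep]
            art_starts = np.array([a[0] for a in artifacts])
            art_durs = np.array([a[1] for a in artifacts])
            starts_s = np.concatenate([starts_s, art_starts])
            durations = np.concatenate([durations, art_durs])
            n_power_off_total += len(artifacts)

        adj_starts, adj_durs = _resolve_overlaps(
            starts_s, durations, config.min_gap_s, max_shift_s=6 * 3600.0
        )
        start_ns = start_date.value + np.round(adj_starts * NS).astype(np.int64)
        dur_ns = np.round(adj_durs * NS).astype(np.int64)
        all_sessions.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "start": pd.to_datetime(start_ns),
                    "end": pd.to_datetime(start_ns + dur_ns),
                    "duration_s": dur_ns / 1e9,
                }
            )
        )

    sessions = pd.concat(all_sessions, ignore_index=True)

    # --- events -----------------------------------------------------------
    on = sessions[["participant_id", "start"]].rename(columns={"start": "timestamp"})
    on["state"] = STATE_ON
    off = sessions[["participant_id", "end"]].rename(columns={"end": "timestamp"})
    off["state"] = STATE_OFF
    events = pd.concat([on, off], ignore_index=True)
    key = events["state"].map({STATE_ON: 0, STATE_OFF: 1})
    events = (
        events.assign(_k=key)
        .sort_values(["participant_id", "timestamp", "_k"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )

    # --- true per-participant metrics ------------------------------------
    # restricted to each participant's first n_days observed origin dates,
    # the same day rule the metrics stage applies (a final-night artifact
    # can originate after midnight, outside the observation fortnight)
    per = []
    for pid, g in sessions.groupby("participant_id", sort=True):
        origin = g["start"].dt.date
        eligible = set(sorted(origin.unique())[: config.n_days])
        g = g[origin.isin(eligible)]
        per.append(
            {
                "participant_id": pid,
                "true_mean_daily_uses": float(len(g) / config.n_days),
                "true_mean_daily_duration_h": float(
                    g["duration_s"].sum() / 3600.0 / config.n_days
                ),
                "n_sessions": len(g),
            }
        )
    participants = pd.DataFrame(per)

    # --- planted self-reports --------------------------------------------
    sr = config.self_report
    est_dur = _plant_correlated(
        rng,
        participants["true_mean_daily_duration_h"].to_numpy(),
        sr.rho_duration,
        sr.est_duration_mean_h,
        sr.est_duration_sd_h,
        floor=0.1,
    )
    est_uses = _plant_correlated(
        rng,
        participants["true_mean_daily_uses"].to_numpy(),
        sr.rho_uses,
        sr.est_uses_mean,
        sr.est_uses_sd,
        floor=1.0,
    )
    self_reports = pd.DataFrame(
        {
            "participant_id": participants["participant_id"],
            "estimated_daily_duration_h": np.round(est_dur, 3),
            "estimated_daily_uses": np.round(est_uses, 1),
        }
    )
    participants["planted_est_duration_h"] = self_reports[
        "estimated_daily_duration_h"
    ].to_numpy()
    participants["planted_est_uses"] = self_reports["estimated_daily_uses"].to_numpy()

    # --- questionnaire ----------------------------------------------------
    mp = config.mppus
    f = rng.standard_normal(config.n_participants)
    e = rng.standard_normal((config.n_participants, mp.n_items))
    latent = np.sqrt(mp.rbar) * f[:, None] + np.sqrt(1.0 - mp.rbar) * e
    items = np.clip(
        np.round(mp.item_mean + mp.item_sd * latent), mp.scale_min, mp.scale_max
    ).astype(int)
    mppus = pd.DataFrame(
        items, columns=[f"item_{i + 1:02d}" for i in range(mp.n_items)]
    )
    mppus.insert(0, "participant_id", participants["participant_id"].to_numpy())
    totals = items.sum(axis=1)
    participants["mppus_total"] = totals
    participants["mppus_problem_flag"] = totals > mp.norm_mean + 2.0 * mp.norm_sd

    alarm_bin = (
        config.alarm.hour * 60 + config.alarm.minute if config.alarm else None
    )
    truth = GroundTruth(
        sessions=sessions,
        participants=participants,
        n_power_off=n_power_off_total,
        alarm_bin_of_day=alarm_bin,
        config=config,
    )
    return Cohort(
        events=events, self_reports=self_reports, mppus=mppus, truth=truth
    )


def _config_to_dict(config: SimConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [enc(v) for v in obj]
        return obj

    d = {
        k: enc(v)
        for k, v in dataclasses.asdict(config).items()
        if k != "windows"
    }
    return d


def write_fixture(output_dir: str | Path, config: SimConfig | None = None) -> Cohort:
    """Simulate a cohort and write every table to ``output_dir``.

    Emits the canonical event file plus self-report, questionnaire and
    ground-truth tables, and the configuration used (YAML), so a fixture
    can be regenerated or re-parsed end to end.
    """
    config = config or SimConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    write_events(cohort.events, out / "events.csv")
    cohort.self_reports.to_csv(out / "self_reports.csv", index=False)
    cohort.mppus.to_csv(out / "mppus.csv", index=False)
    t = cohort.truth.sessions.copy()
    t["start"] = t["start"].map(pd.Timestamp.isoformat)
    t["end"] = t["end"].map(pd.Timestamp.isoformat)
    t.to_csv(out / "truth_sessions.csv", index=False)
    cohort.truth.participants.to_csv(out / "truth_participants.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    return cohort
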
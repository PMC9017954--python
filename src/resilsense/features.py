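"""Hourly feature cleaning: mood interpolation, missing-data rules, outlier
filtering and participant eligibility.

The raw inputs are (a) an hourly table per participant with step count,
sleep/in-bed seconds and mean heart rate, and (b) daily mood EMA events on a
1-10 scale. Cleaning proceeds in the order the rules are stated:

1. the daily mood EMA is locally interpolated to an hourly mood value over
   the waking day it describes, with small uniform noise to make the
   discrete ratings continuous;
2. hours with classified sleep but no steps (or vice versa) are treated as
   non-randomly missing and zero-filled;
3. hours still missing any of the five features (no mood within 24 h, no
   heart-rate data) are dropped;
4. multivariate outliers among the pooled participant-hours are removed with
   an isolation forest (250 trees, full feature budget per tree);
5. participants with fewer than 100 cleaned baseline hours, fewer than 100
   cleaned internship hours, or zero variance on any hourly feature are
   excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

from .indicators import FEATURES

#: a sleep run qualifies as a full sleep cycle when its summed seconds
#: exceed two hours
_CYCLE_SECONDS = 7200.0
_FILL_CAP_HOURS = 24


@dataclass
class CleaningReport:
    """Counts accumulated across the cleaning stages."""

    n_hours_in: int = 0
    n_hours_out: int = 0
    n_outliers_removed: int = 0
    outliers_per_participant: dict = field(default_factory=dict)
    n_participants_in: int = 0
    n_participants_out: int = 0
    dropped_participants: dict = field(default_factory=dict)  # pid -> reason

    def to_dict(self) -> dict:
        return {
            "n_hours_in": self.n_hours_in,
            "n_hours_out": self.n_hours_out,
            "n_outliers_removed": self.n_outliers_removed,
            "outliers_per_participant": dict(self.outliers_per_participant),
            "n_participants_in": self.n_participants_in,
            "n_participants_out": self.n_participants_out,
            "dropped_participants": dict(self.dropped_participants),
        }


def _hour_index(ts: pd.Series) -> np.ndarray:
    """Hours since epoch, floored to the hourly grid."""
    return (ts.astype("int64") // 3_600_000_000_000).to_numpy()


def _sleep_runs(hours: np.ndarray, sleep_seconds: np.ndarray):
    """Contiguous runs of hours with sleep > 0, as (start, end_exclusive,
    total_seconds) with end_exclusive being the wake hour."""
    order = np.argsort(hours)
    hours = hours[order]
    sleep_seconds = sleep_seconds[order]
    mask = sleep_seconds > 0
    runs = []
    start = None
    total = 0.0
    prev = None
    for h, s, m in zip(hours, sleep_seconds, mask):
        if m:
            if start is not None and prev is not None and h == prev + 1:
                total += s
            else:
                if start is not None:
                    runs.append((start, prev + 1, total))
                start, total = h, s
            prev = h
        else:
            if start is not None:
                runs.append((start, prev + 1, total))
                start = None
    if start is not None:
        runs.append((start, prev + 1, total))
    return runs


def interpolate_mood(
    ema_events: pd.DataFrame,
    hourly: pd.DataFrame,
    noise_seed: int = 0,
    noise_per_hour: bool = True,
) -> pd.DataFrame:
    """Approximate an hourly mood value from daily EMA events.

    For each day with at least one EMA, the day's (averaged) EMA value fills
    every hour from the wake time ending the previous sleep cycle up to the
    wake time ending the next sleep cycle longer than two hours, never more
    than 24 hours past the EMA. Sleep-cycle anchors are contiguous runs of
    hours with positive sleep seconds; a run qualifies as a full cycle when
    its summed sleep exceeds 7200 s. If no prior wake anchor exists the fill
    starts at the EMA day's 00:00; if no following qualifying cycle exists
    it ends at EMA time + 24 h. Independent Uniform(0, 0.2) noise is added
    per filled hour (or one draw per EMA with ``noise_per_hour=False``).

    Returns a table (participant_id, hour_index, mood).
    """
    if ((ema_events["mood"] < 1) | (ema_events["mood"] > 10)).any():
        raise ValueError("EMA mood values must lie in [1, 10]")
    rng = np.random.default_rng(noise_seed)
    out_pid, out_hour, out_mood = [], [], []

    ema = ema_events.copy()
    ema["hour"] = _hour_index(ema["timestamp"])
    ema["day"] = ema["hour"] // 24
    hourly_by_pid = dict(tuple(hourly.groupby("participant_id", sort=True)))

    for pid, ev in ema.groupby("participant_id", sort=True):
        rec = hourly_by_pid.get(pid)
        if rec is None:
            continue
        hours = _hour_index(rec["hour_start"])
        runs = _sleep_runs(hours, rec["sleep_seconds"].to_numpy(dtype=float))
        wake_all = np.array([r[1] for r in runs], dtype=np.int64)
        wake_cycle = np.array(
            [r[1] for r in runs if r[2] > _CYCLE_SECONDS], dtype=np.int64
        )
        fill: dict[int, float] = {}
        daily = ev.groupby("day").agg(hour=("hour", "min"), mood=("mood", "mean"))
        for day, row in daily.iterrows():
            ema_hour = int(row["hour"])
            value = float(row["mood"])
            prev = wake_all[wake_all <= ema_hour]
            start = int(prev[-1]) if len(prev) else int(day) * 24
            nxt = wake_cycle[wake_cycle > ema_hour]
            end = int(nxt[0]) if len(nxt) else ema_hour + _FILL_CAP_HOURS
            end = min(end, ema_hour + _FILL_CAP_HOURS)
            if not noise_per_hour:
                noise = rng.uniform(0.0, 0.2)
            for h in range(start, end):
                fill[h] = value + (rng.uniform(0.0, 0.2) if noise_per_hour else noise)
        out_pid.extend([pid] * len(fill))
        out_hour.extend(fill.keys())
        out_mood.extend(fill.values())

    return pd.DataFrame(
        {"participant_id": out_pid, "hour_index": out_hour, "mood": out_mood}
    )


def fill_step_sleep_missing(records: pd.DataFrame) -> pd.DataFrame:
    """Zero-fill non-random step/sleep missingness, symmetrically.

    Hours with classified sleep but absent steps get step_count = 0 (the
    participant was asleep, not unmeasured); hours with steps but absent
    sleep get sleep_seconds = in_bed_seconds = 0 (awake).
    """
    out = records.copy()
    has_sleep = out["sleep_seconds"].notna() & (out["sleep_seconds"] > 0)
    out.loc[has_sleep & out["step_count"].isna(), "step_count"] = 0
    has_steps = out["step_count"].notna()
    awake = has_steps & out["sleep_seconds"].isna()
    out.loc[awake, ["sleep_seconds", "in_bed_seconds"]] = 0.0
    return out


def drop_incomplete_hours(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only hours where all five features are present."""
    return records.dropna(subset=list(FEATURES)).reset_index(drop=True)


def filter_outliers(
    records: pd.DataFrame,
    n_trees: int = 250,
    seed: int = 0,
    contamination: float | str = 0.03,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove multivariate hourly outliers with a pooled isolation forest.

    One forest (``n_trees`` trees, per-tree feature budget equal to the full
    five-feature dimension) is fitted over all participant-hours pooled and
    the ``contamination`` fraction of most-isolated rows is removed.
    The default keeps the flagged share in the few-percent regime typical of
    hourly wearable data; the library's automatic offset is available via
    ``contamination="auto"`` but over-flags heavily on zero-inflated
    features. Deterministic given ``seed``.
    """
    if len(records) < 10:
        raise ValueError("too few rows to fit the isolation forest")
    forest = IsolationForest(
        n_estimators=n_trees,
        max_features=len(FEATURES),
        contamination=contamination,
        random_state=seed,
    )
    flags = forest.fit_predict(records[list(FEATURES)].to_numpy(dtype=float)) == -1
    report = CleaningReport(
        n_hours_in=len(records),
        n_hours_out=int((~flags).sum()),
        n_outliers_removed=int(flags.sum()),
        outliers_per_participant=records.loc[flags, "participant_id"]
        .value_counts()
        .to_dict(),
    )
    # participants with zero flagged hours still appear in the burden counts
    for pid in records["participant_id"].unique():
        report.outliers_per_participant.setdefault(pid, 0)
    return records[~flags].reset_index(drop=True), report


def filter_participants(records: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the eligibility rules on cleaned hourly records.

    Retains participants with >= 100 cleaned baseline hours, >= 100 cleaned
    internship (Q1-Q4) hours, and nonzero variance on every hourly feature.
    """
    report = CleaningReport(
        n_hours_in=len(records),
        n_participants_in=records["participant_id"].nunique(),
    )
    keep_parts = []
    for pid, grp in records.groupby("participant_id", sort=True):
        n_bl = int((grp["period"] == "BL").sum())
        n_intern = int((grp["period"] != "BL").sum())
        if n_bl < 100:
            report.dropped_participants[pid] = "baseline hours"
            continue
        if n_intern < 100:
            report.dropped_participants[pid] = "internship hours"
            continue
        if any(grp[f].nunique() <= 1 for f in FEATURES):
            report.dropped_participants[pid] = "zero variance"
            continue
        keep_parts.append(pid)
    out = records[records["participant_id"].isin(keep_parts)].reset_index(drop=True)
    report.n_hours_out = len(out)
    report.n_participants_out = len(keep_parts)
    return out, report


def clean_pipeline(
    hourly: pd.DataFrame,
    ema: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 250,
    contamination: float | str = 0.03,
    noise_per_hour: bool = True,
    refit_outliers: bool = True,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning sequence on raw hourly + EMA tables.

    ``hourly`` needs participant_id, period, hour_start and the step /
    sleep / in-bed / heart-rate columns (mood, if present, is replaced by
    the interpolated value). Returns the cleaned table with all five
    features plus a merged :class:`CleaningReport`. ``refit_outliers=False``
    skips the isolation-forest stage (used to check idempotence).
    """
    work = hourly.copy()
    mood = interpolate_mood(ema, work, noise_seed=seed, noise_per_hour=noise_per_hour)
    work["hour_index"] = _hour_index(work["hour_start"])
    work = work.drop(columns=["mood"], errors="ignore").merge(
        mood, on=["participant_id", "hour_index"], how="left"
    )
    work = fill_step_sleep_missing(work)
    work = drop_incomplete_hours(work)
    n_in = len(hourly)
    if refit_outliers:
        work, forest_report = filter_outliers(
            work, n_trees=n_trees, seed=seed, contamination=contamination
        )
    else:
        forest_report = CleaningReport(n_hours_in=len(work), n_hours_out=len(work))
    work, part_report = filter_participants(work)
    report = CleaningReport(
        n_hours_in=n_in,
        n_hours_out=len(work),
        n_outliers_removed=forest_report.n_outliers_removed,
        outliers_per_participant=forest_report.outliers_per_participant,
        n_participants_in=hourly["participant_id"].nunique(),
        n_participants_out=part_report.n_participants_out,
        dropped_participants=part_report.dropped_participants,
    )
    return work.drop(columns=["hour_index"]), report
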
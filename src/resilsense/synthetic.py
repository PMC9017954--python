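"""Synthetic intern cohorts with the statistical structure the analysis assumes.

No raw wearable/EMA study data are publicly deposited, so every downstream
stage is exercised against generated cohorts that emulate the qualitative
shape of the real streams:

* hourly step counts follow a hurdle model — a circadian Bernoulli activity
  gate times negative-binomial counts — giving the right-skewed, zero-mode
  shape of real actigraphy;
* sleep / in-bed seconds are zero for most hours and filled by nightly sleep
  cycles; a cycle that crosses hour boundaries is occasionally booked
  entirely into its start hour, mimicking wearable APIs that log one long
  multi-hour cycle (so single hours can carry far more than 3600 s);
* mean heart rate is bounded to the device's [35, 204] BPM range and moves
  with sleep and activity;
* mood is a discrete 1-10 daily rating delivered at a fixed per-participant
  evening hour (17:00-22:00) with imperfect completion;
* each participant belongs to one of a small number of latent behaviour-shift
  clusters that change the generating parameters between the baseline and
  internship periods (emulating heterogeneous reactions to internship);
* quarterly PHQ-9 depression scores follow one of several latent quadratic
  trajectory classes (a majority minimal-change class plus sensitive
  classes), with a participant random intercept and residual noise;
* couplings between behaviour and symptom trajectory are planted by letting
  shift-cluster membership depend on the minimal-change ("resilient") class,
  and by drawing explicit planted indicator values whose logistic
  association with resilience has a configured log-odds slope;
* adherence decays: whole participant-quarters drop out with a per-quarter
  hazard and individual EMA days are thinned by a completion rate.

All randomness flows from ``CohortConfig.seed``; the same config yields
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PERIODS = ("BL", "Q1", "Q2", "Q3", "Q4")
QUARTERS = ("Q1", "Q2", "Q3", "Q4")

#: Intern specialty mix used for the grouping covariate (share, name).
SPECIALTIES = (
    ("Internal Medicine", 0.22),
    ("Surgery", 0.10),
    ("Ob/Gyn", 0.06),
    ("Pediatrics", 0.14),
    ("Psychiatry", 0.05),
    ("Emergency Medicine", 0.09),
    ("Med/Peds", 0.03),
    ("Family Practice", 0.09),
    ("Transitional", 0.04),
    ("Anesthesiology", 0.05),
    ("Neurology", 0.02),
    ("Otolaryngology", 0.01),
    ("Other", 0.10),
)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration field is invalid."""


@dataclass(frozen=True)
class TrajectoryClass:
    """Quadratic fixed effects (PHQ points over quarter index) and mixing weight."""

    gamma0: float
    gamma1: float
    gamma2: float
    weight: float

    def curve(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.gamma0 + self.gamma1 * t + self.gamma2 * t**2


@dataclass(frozen=True)
class ShiftCluster:
    """Between-period change in generating parameters for one latent cluster.

    ``mean_mult`` / ``sd_mult`` multiply the feature's generating location
    and scale parameters during the internship (keys: step_count,
    sleep_seconds, mean_heart_rate, mood; in-bed time follows sleep).
    """

    weight: float
    mean_mult: dict = field(default_factory=dict)
    sd_mult: dict = field(default_factory=dict)


def default_trajectory_classes() -> list[TrajectoryClass]:
    """Four ΔPHQ-9 classes: a 68% minimal-change majority plus three
    sensitive shapes (rise-and-recover, sustained worsening, improving)."""
    return [
        TrajectoryClass(0.0, 0.35, -0.07, 0.68),
        TrajectoryClass(0.0, 4.5, -0.90, 0.13),
        TrajectoryClass(0.0, 5.5, -0.70, 0.11),
        TrajectoryClass(0.0, -3.2, 0.35, 0.08),
    ]


def default_shift_clusters() -> list[ShiftCluster]:
    """Two behaviour-shift clusters: a mildly affected majority and a
    'disrupted' minority that sleeps much less and runs a higher heart rate,
    with only a small step-count contrast and none in mood."""
    return [
        ShiftCluster(
            weight=0.8,
            mean_mult={
                "step_count": 0.98,
                "sleep_seconds": 1.02,
                "mean_heart_rate": 1.015,
                "mood": 0.99,
            },
        ),
        ShiftCluster(
            weight=0.2,
            mean_mult={
                "step_count": 0.85,
                "sleep_seconds": 0.50,
                "mean_heart_rate": 1.07,
                "mood": 0.97,
            },
            sd_mult={"mean_heart_rate": 1.05},
        ),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for cohort simulation."""

    n_participants: int = 200
    baseline_weeks: int = 4
    internship_quarters: int = 4
    days_per_quarter: int = 10
    trajectory_classes: tuple = tuple(default_trajectory_classes())
    residual_sd: float = 2.0
    random_intercept_sd: float = 1.0
    shift_clusters: tuple = tuple(default_shift_clusters())
    #: (indicator name, log-odds slope on resilience) for planted values
    indicator_effects: tuple = (("planted_mood_ds", 0.5),)
    #: log-odds decrease in disrupted-cluster membership for resilient class
    cluster_resilience_log_odds: float = 1.0
    ema_completion_rate: float = 0.75
    dropout_hazard_per_quarter: float = 0.12
    wear_rate: float = 0.93
    #: probability a nightly sleep cycle is booked wholly into its start
    #: hour (the multi-hour cycle logging quirk); 0 gives anomaly-free data
    sleep_lump_prob: float = 0.15
    #: per-participant multiplicative jitter SD on the cluster shifts
    shift_jitter_sd: float = 0.05
    #: fraction of the sleep-shift heterogeneity explained by baseline sleep
    #: duration (long sleepers lose proportionally more during internship);
    #: the remainder is independent noise
    sleep_shift_coupling: float = 0.7
    #: regression-to-the-mean pull of internship means toward the population
    mood_pull: float = 0.12
    hr_pull: float = 0.05
    steps_pull: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ConfigurationError("n_participants must be positive")
        if self.baseline_weeks <= 0:
            raise ConfigurationError("baseline_weeks must be positive")
        if self.internship_quarters <= 0:
            raise ConfigurationError("internship_quarters must be positive")
        if self.days_per_quarter <= 0:
            raise ConfigurationError("days_per_quarter must be positive")
        if not self.trajectory_classes:
            raise ConfigurationError("trajectory_classes must be non-empty")
        w = sum(c.weight for c in self.trajectory_classes)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError("trajectory_classes weights must sum to 1")
        cw = sum(c.weight for c in self.shift_clusters)
        if not self.shift_clusters or abs(cw - 1.0) > 1e-9:
            raise ConfigurationError("shift_clusters weights must sum to 1")
        for name, p in (
            ("ema_completion_rate", self.ema_completion_rate),
            ("dropout_hazard_per_quarter", self.dropout_hazard_per_quarter),
            ("wear_rate", self.wear_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.residual_sd < 0 or self.random_intercept_sd < 0:
            raise ConfigurationError("residual_sd/random_intercept_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """Generated tables: hourly records, EMA events, PHQ series, covariates,
    and the ground truth (class, cluster, planted indicator values)."""

    hourly: pd.DataFrame  # participant_id, period, hour_start, 5 features
    ema: pd.DataFrame  # participant_id, timestamp, mood (integer 1-10)
    phq: pd.DataFrame  # participant_id, period, phq9, delta
    covariates: pd.DataFrame  # participant_id, sex, age, specialty
    truth: pd.DataFrame  # participant_id, class_id, cluster_id, resilient, planted_*
    config: CohortConfig


# --------------------------------------------------------------------------
# PHQ-9 trajectory simulation
# --------------------------------------------------------------------------

def resilient_class_index(classes) -> int:
    """Index of the minimal-change class: smallest max |curve| over Q1..Q4,
    ties broken toward the largest mixing weight."""
    t = np.arange(1, 5, dtype=float)
    peaks = [np.max(np.abs(c.curve(t))) for c in classes]
    order = sorted(range(len(classes)), key=lambda k: (peaks[k], -classes[k].weight))
    return order[0]


def simulate_phq_series(
    class_params,
    n_per_class,
    seed,
    residual_sd: float = 2.0,
    random_intercept_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate ΔPHQ-9 series on the (BL, Q1..Q4) grid.

    ``n_per_class`` is either an int applied to every class or a sequence.
    ΔPHQ at BL is exactly 0; at t in {1..4} it is the class quadratic plus a
    participant random intercept and residual noise. Returns a long table
    (participant_id, class_id, period, t, delta).
    """
    classes = list(class_params)
    if not classes:
        raise ConfigurationError("at least one trajectory class is required")
    if np.isscalar(n_per_class):
        counts = [int(n_per_class)] * len(classes)
    else:
        counts = [int(n) for n in n_per_class]
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    t_grid = np.arange(0, 5, dtype=float)
    for cid, (cls, n) in enumerate(zip(classes, counts)):
        curve = cls.curve(t_grid)
        for _ in range(n):
            b = rng.normal(0.0, random_intercept_sd)
            eps = rng.normal(0.0, residual_sd, size=5)
            delta = curve + b + eps
            delta[0] = 0.0  # ΔPHQ is defined against BL
            for t, d in zip(t_grid, delta):
                rows.append((f"P{pid:05d}", cid, PERIODS[int(t)], int(t), float(d)))
            pid += 1
    return pd.DataFrame(rows, columns=["participant_id", "class_id", "period", "t", "delta"])


# --------------------------------------------------------------------------
# Hourly feature simulation
# --------------------------------------------------------------------------

# circadian activity-gate probability by hour of day (0..23)
_ACTIVITY_GATE = np.array(
    [0.06, 0.04, 0.03, 0.03, 0.04, 0.10, 0.35, 0.60, 0.75, 0.75, 0.72, 0.72,
     0.75, 0.72, 0.70, 0.70, 0.72, 0.75, 0.70, 0.60, 0.50, 0.35, 0.20, 0.10]
)
# relative step intensity by hour of day
_STEP_INTENSITY = np.array(
    [0.2, 0.15, 0.1, 0.1, 0.15, 0.3, 0.8, 1.3, 1.2, 1.0, 1.0, 1.1,
     1.2, 1.0, 0.9, 0.9, 1.0, 1.2, 1.1, 0.9, 0.7, 0.5, 0.4, 0.3]
)


def _participant_params(rng: np.random.Generator, n: int) -> dict:
    """Draw stable per-participant baseline generating parameters."""
    return {
        "step_rate": rng.lognormal(np.log(330.0), 0.30, size=n),
        "step_dispersion": np.full(n, 1.2),
        "sleep_onset_hour": rng.normal(23.2, 0.7, size=n),  # local clock
        "sleep_duration_h": np.clip(rng.normal(6.8, 0.7, size=n), 4.0, 10.0),
        "gap_frac": np.clip(rng.normal(0.12, 0.04, size=n), 0.02, 0.3),
        "hr_mean": rng.normal(72.0, 6.0, size=n),
        "hr_noise_sd": np.full(n, 4.5),
        "mood_mean": np.clip(rng.normal(7.0, 1.2, size=n), 1.5, 9.5),
        "mood_day_sd": np.full(n, 1.0),
        "ema_hour": rng.integers(17, 23, size=n),  # fixed evening delivery hour
    }


def _simulate_period_hours(
    rng: np.random.Generator,
    params: dict,
    n_days: int,
    start: pd.Timestamp,
    lump_prob: float = 0.15,
) -> dict:
    """Simulate one period's hourly features for all participants at once.

    Returns dense arrays of shape (n_participants, n_hours); the wear mask is
    applied by the caller. ``params`` holds the (possibly shifted) generating
    parameters for this period.
    """
    n = len(params["step_rate"])
    n_hours = n_days * 24
    hod = np.arange(n_hours) % 24

    # --- sleep / in-bed: nightly cycles -----------------------------------
    sleep = np.zeros((n, n_hours))
    in_bed = np.zeros((n, n_hours))
    for day in range(n_days):
        onset = day * 24 + params["sleep_onset_hour"] + rng.normal(0, 0.8, size=n)
        dur = np.clip(
            params["sleep_duration_h"] + rng.normal(0, 0.9, size=n), 1.0, 12.0
        )
        end = onset + dur
        lump = rng.random(n) < lump_prob
        gap = params["gap_frac"]
        # booked wholly into the start hour (multi-hour cycle logging)
        h0 = np.clip(np.floor(onset).astype(int), 0, n_hours - 1)
        lump_idx = np.where(lump)[0]
        np.add.at(in_bed, (lump_idx, h0[lump_idx]), dur[lump_idx] * 3600.0)
        np.add.at(
            sleep, (lump_idx, h0[lump_idx]), dur[lump_idx] * (1 - gap[lump_idx]) * 3600.0
        )
        # spread across covered hours
        spread_idx = np.where(~lump)[0]
        if len(spread_idx):
            o = onset[spread_idx]
            e = end[spread_idx]
            g = gap[spread_idx]
            base = np.floor(o).astype(int)
            for k in range(14):  # cycles are <= 12 h
                h = base + k
                ok = (h < n_hours) & (h >= 0)
                overlap = np.clip(np.minimum(e, h + 1) - np.maximum(o, h), 0.0, 1.0)
                overlap = np.where(ok, overlap, 0.0)
                idx = spread_idx[ok]
                np.add.at(in_bed, (idx, np.clip(h, 0, n_hours - 1)[ok]), overlap[ok] * 3600.0)
                np.add.at(
                    sleep,
                    (idx, np.clip(h, 0, n_hours - 1)[ok]),
                    overlap[ok] * (1 - g[ok]) * 3600.0,
                )
    asleep_frac = np.clip(sleep / 3600.0, 0.0, 1.0)

    # --- steps: circadian hurdle x negative binomial ----------------------
    gate_p = _ACTIVITY_GATE[hod][None, :] * (1 - asleep_frac)
    active = rng.random((n, n_hours)) < gate_p
    mean_steps = params["step_rate"][:, None] * _STEP_INTENSITY[hod][None, :]
    k = params["step_dispersion"][:, None] * np.ones(n_hours)[None, :]
    p_nb = k / (k + np.maximum(mean_steps, 1e-9))
    counts = rng.negative_binomial(k, p_nb)
    steps = np.where(active, counts, 0).astype(float)

    # --- heart rate: person mean, sleep dip, activity surge ---------------
    hr = (
        params["hr_mean"][:, None]
        - 9.0 * asleep_frac
        + 12.0 * np.clip(steps / 800.0, 0.0, 1.5)
        + rng.normal(0.0, params["hr_noise_sd"][:, None], size=(n, n_hours))
    )
    hr = np.clip(hr, 35.0, 204.0)

    # --- mood: one discrete daily value spread over the day ---------------
    day_idx = np.arange(n_hours) // 24
    daily = np.clip(
        np.round(params["mood_mean"][:, None] + rng.normal(0, params["mood_day_sd"][:, None], size=(n, n_days))),
        1, 10,
    )
    mood_int = daily[:, day_idx]
    mood = mood_int + rng.uniform(0.0, 0.2, size=(n, n_hours))

    hour_start = start + pd.to_timedelta(np.arange(n_hours), unit="h")
    return {
        "steps": steps,
        "sleep": sleep,
        "in_bed": in_bed,
        "hr": hr,
        "mood": mood,
        "mood_daily": daily,
        "hour_start": hour_start,
    }


#: per-feature scale of the participant-level jitter on the shift multiplier.
#: Scales are set so the realized per-feature d_s spread across participants
#: approaches the interquartile ranges real intern cohorts show (sleep and
#: in-bed ~0.18, heart rate ~0.33, mood widest), while keeping the cluster
#: contrast the dominant axis of variation.
_JITTER_SCALE = {
    "step_count": 2.0,
    "sleep_seconds": 3.0,
    "mean_heart_rate": 0.4,
    "mood": 0.4,
}


def _shifted_params(base: dict, cluster_ids: np.ndarray, clusters, jitter: dict, pulls: dict) -> dict:
    """Apply cluster shift multipliers, per-participant jitter and
    regression-to-the-mean pulls to the baseline generating parameters."""
    p = {k: np.array(v, copy=True) for k, v in base.items()}

    def mult(feature: str, default: float = 1.0) -> np.ndarray:
        cluster_mult = np.array(
            [clusters[c].mean_mult.get(feature, default) for c in cluster_ids]
        )
        return cluster_mult + jitter[feature] * _JITTER_SCALE[feature]

    def smult(feature: str) -> np.ndarray:
        return np.array([clusters[c].sd_mult.get(feature, 1.0) for c in cluster_ids])

    p["step_rate"] = base["step_rate"] * mult("step_count")
    p["step_rate"] = p["step_rate"] + pulls["steps"] * (330.0 - p["step_rate"])
    p["sleep_duration_h"] = np.clip(
        base["sleep_duration_h"] * mult("sleep_seconds"), 1.0, 12.0
    )
    p["hr_mean"] = base["hr_mean"] * mult("mean_heart_rate")
    p["hr_mean"] = p["hr_mean"] + pulls["hr"] * (72.0 - base["hr_mean"])
    p["hr_noise_sd"] = base["hr_noise_sd"] * smult("mean_heart_rate")
    p["mood_mean"] = np.clip(
        base["mood_mean"] * mult("mood") + pulls["mood"] * (7.0 - base["mood_mean"]),
        1.0, 10.0,
    )
    p["mood_day_sd"] = base["mood_day_sd"] * smult("mood")
    return p


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

_BL_START = pd.Timestamp("2020-05-01")


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort (hourly, EMA, PHQ, covariates, truth).

    Deterministic given ``config.seed``. Dropout and EMA thinning are NOT
    applied here; see :func:`apply_missingness`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = np.array([f"P{i:05d}" for i in range(n)])

    # covariates
    spec_names = [s for s, _ in SPECIALTIES]
    spec_p = np.array([p for _, p in SPECIALTIES])
    spec_p = spec_p / spec_p.sum()
    covariates = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": rng.choice(["female", "male"], size=n, p=[0.55, 0.45]),
            "age": rng.integers(25, 33, size=n),
            "specialty": rng.choice(spec_names, size=n, p=spec_p),
        }
    )

    # latent trajectory class, then shift cluster conditioned on resilience
    classes = list(config.trajectory_classes)
    class_w = np.array([c.weight for c in classes])
    class_id = rng.choice(len(classes), size=n, p=class_w)
    res_idx = resilient_class_index(classes)
    resilient = class_id == res_idx

    clusters = list(config.shift_clusters)
    cluster_w = np.array([c.weight for c in clusters])
    if len(clusters) == 1:
        cluster_id = np.zeros(n, dtype=int)
    else:
        # log-odds of the last ("disrupted") cluster drop for resilient class
        logits = np.log(cluster_w / cluster_w.sum())
        probs = np.tile(logits, (n, 1))
        probs[resilient, -1] -= config.cluster_resilience_log_odds
        probs = np.exp(probs)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cluster_id = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    # planted indicator values: x | resilient ~ N(beta * resilient, 1), so a
    # logistic fit of resilience on x has slope beta
    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "class_id": class_id,
            "cluster_id": cluster_id,
            "resilient": resilient,
        }
    )
    for name, beta in config.indicator_effects:
        truth[name] = rng.normal(0.0, 1.0, size=n) + beta * resilient.astype(float)

    # PHQ-9 series per class
    t_grid = np.arange(0, 5, dtype=float)
    bl_phq = np.clip(np.round(rng.gamma(2.0, 1.6, size=n)), 0, 20)
    b_i = rng.normal(0.0, config.random_intercept_sd, size=n)
    phq_rows = []
    for i in range(n):
        curve = classes[class_id[i]].curve(t_grid)
        delta = curve + b_i[i] + rng.normal(0.0, config.residual_sd, size=5)
        delta[0] = 0.0
        for t in range(5):
            score = float(np.clip(np.round(bl_phq[i] + delta[t]), 0, 27))
            phq_rows.append((pids[i], PERIODS[t], score, float(delta[t])))
    phq = pd.DataFrame(phq_rows, columns=["participant_id", "period", "phq9", "delta"])

    # hourly features: baseline then internship quarters with shifted params
    base_params = _participant_params(rng, n)
    jitter = {
        feat: rng.normal(0.0, config.shift_jitter_sd, size=n)
        for feat in ("step_count", "sleep_seconds", "mean_heart_rate", "mood")
    }
    # part of the sleep reaction is regression to the mean: participants who
    # sleep longest at baseline shed the most sleep during internship
    dur = base_params["sleep_duration_h"]
    z_dur = (dur - dur.mean()) / max(dur.std(), 1e-9)
    rho = np.clip(config.sleep_shift_coupling, 0.0, 1.0)
    jitter["sleep_seconds"] = config.shift_jitter_sd * (
        -rho * z_dur
        + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    )
    pulls = {"mood": config.mood_pull, "hr": config.hr_pull, "steps": config.steps_pull}
    intern_params = _shifted_params(base_params, cluster_id, clusters, jitter, pulls)
    intern_params["ema_hour"] = base_params["ema_hour"]

    bl_days = config.baseline_weeks * 7
    q_days = config.days_per_quarter
    hourly_frames = []
    ema_frames = []

    def emit_period(params: dict, n_days: int, start: pd.Timestamp, day_labels) -> None:
        """Simulate one contiguous block; ``day_labels`` maps day -> period."""
        sim = _simulate_period_hours(rng, params, n_days, start, lump_prob=config.sleep_lump_prob)
        worn = rng.random(sim["steps"].shape) < config.wear_rate
        p_idx, h_idx = np.where(worn)
        hour_period = np.repeat(np.asarray(day_labels), 24)
        hourly_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pids[p_idx],
                    "period": hour_period[h_idx],
                    "hour_start": sim["hour_start"][h_idx],
                    "step_count": sim["steps"][p_idx, h_idx].astype(int),
                    "sleep_seconds": np.round(sim["sleep"][p_idx, h_idx], 0),
                    "in_bed_seconds": np.round(sim["in_bed"][p_idx, h_idx], 0),
                    "mean_heart_rate": np.round(sim["hr"][p_idx, h_idx], 1),
                    "mood": sim["mood"][p_idx, h_idx],
                }
            )
        )
        # one EMA event per participant-day at the fixed evening hour
        for day in range(n_days):
            ts = start + pd.to_timedelta(day * 24 + params["ema_hour"], unit="h")
            ema_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pids,
                        "timestamp": ts,
                        "mood": sim["mood_daily"][:, day].astype(int),
                    }
                )
            )

    emit_period(base_params, bl_days, _BL_START, ["BL"] * bl_days)
    # the internship is one continuous block labelled by quarter
    intern_start = _BL_START + pd.Timedelta(days=bl_days + 7)
    intern_labels = [
        QUARTERS[q] if q < 4 else f"Q{q + 1}"
        for q in range(config.internship_quarters)
        for _ in range(q_days)
    ]
    emit_period(intern_params, config.internship_quarters * q_days, intern_start, intern_labels)

    hourly = pd.concat(hourly_frames, ignore_index=True)
    ema = pd.concat(ema_frames, ignore_index=True).sort_values(
        ["participant_id", "timestamp"], kind="stable", ignore_index=True
    )
    return SyntheticCohort(
        hourly=hourly, ema=ema, phq=phq, covariates=covariates, truth=truth, config=config
    )


def apply_missingness(cohort: SyntheticCohort, config: CohortConfig | None = None) -> SyntheticCohort:
    """Thin a cohort: quarter-onset dropout plus per-day EMA completion.

    Each participant survives each internship quarter after Q1 independently
    with probability ``1 - dropout_hazard_per_quarter``; from the first
    failed quarter onward all hourly, EMA and PHQ records are removed. EMA
    days are kept with probability ``ema_completion_rate``. Deterministic
    given the cohort's seed.
    """
    config = config or cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    pids = cohort.truth["participant_id"].to_numpy()
    n = len(pids)
    hazard = config.dropout_hazard_per_quarter

    n_q = config.internship_quarters
    # dropout quarter index (2-based survival: hazard applies entering Q2..)
    survive = rng.random((n, max(n_q - 1, 0))) >= hazard
    # last quarter with data, per participant (1 = Q1 only)
    last_q = 1 + survive.cumprod(axis=1).sum(axis=1) if n_q > 1 else np.ones(n)
    last_q = pd.Series(np.asarray(last_q, dtype=int), index=pids)

    def quarter_num(period: pd.Series) -> pd.Series:
        return period.str.extract(r"Q(\d+)", expand=False).astype(float)

    def keep_rows(df: pd.DataFrame) -> pd.DataFrame:
        q = quarter_num(df["period"])
        limit = df["participant_id"].map(last_q).to_numpy()
        keep = q.isna().to_numpy() | (q.to_numpy() <= limit)
        return df[keep].reset_index(drop=True)

    hourly = keep_rows(cohort.hourly)
    phq = keep_rows(cohort.phq)

    # thin EMA days by completion, then remove dropped quarters by timestamp
    ema = cohort.ema[rng.random(len(cohort.ema)) < config.ema_completion_rate]
    bl_days = config.baseline_weeks * 7
    intern_start = _BL_START + pd.Timedelta(days=bl_days + 7)
    rel_days = ((ema["timestamp"] - intern_start) / pd.Timedelta(days=1)).to_numpy()
    ema_q = np.where(rel_days < 0, 0, np.floor(rel_days / config.days_per_quarter) + 1)
    limit = ema["participant_id"].map(last_q).to_numpy()
    ema = ema[ema_q <= limit].reset_index(drop=True)

    return SyntheticCohort(
        hourly=hourly,
        ema=ema,
        phq=phq,
        covariates=cohort.covariates,
        truth=cohort.truth,
        config=config,
    )


# --------------------------------------------------------------------------
# Analytic indicator-level cohort (for association screening)
# --------------------------------------------------------------------------

def simulate_indicator_cohort(
    n: int,
    effects: dict[str, float],
    n_null: int = 0,
    base_rate: float = 0.68,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard-normal indicator values with configured logistic effects.

    Labels are drawn as resilient ~ Bernoulli(logit^-1(alpha + sum beta_j
    x_j)) with alpha chosen so the marginal resilient rate is roughly
    ``base_rate``, so the true log-odds slope of each indicator is exactly
    its configured beta. ``n_null`` extra independent N(0,1) indicators named
    ``null_<k>`` are appended. Returns (indicator table, covariate table
    with resilient labels).
    """
    rng = np.random.default_rng(seed)
    names = list(effects)
    x = rng.normal(0.0, 1.0, size=(n, len(names)))
    beta = np.array([effects[k] for k in names])
    alpha = np.log(base_rate / (1 - base_rate))
    eta = alpha + x @ beta
    resilient = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    table = pd.DataFrame(x, columns=names)
    for k in range(n_null):
        table[f"null_{k}"] = rng.normal(0.0, 1.0, size=n)
    table.insert(0, "participant_id", [f"P{i:05d}" for i in range(n)])

    spec_names = [s for s, _ in SPECIALTIES]
    spec_p = np.array([p for _, p in SPECIALTIES])
    covars = pd.DataFrame(
        {
            "participant_id": table["participant_id"],
            "sex": rng.choice(["female", "male"], size=n, p=[0.55, 0.45]),
            "age": rng.integers(25, 33, size=n),
            "specialty": rng.choice(spec_names, size=n, p=spec_p / spec_p.sum()),
            "resilient": resilient,
        }
    )
    return table, covars


def small_config(**overrides) -> CohortConfig:
    """A quick desk-scale configuration used by tests and examples."""
    defaults = dict(
        n_participants=60,
        baseline_weeks=2,
        days_per_quarter=4,
        seed=0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)
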
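"""End-to-end orchestration: simulate → clean → indicators → trajectories →
GEE screen → split → cluster → train → predict → evaluate → contrast.

Every stage reads the artifacts of the previous stages from the run
directory and writes its own, so stages can be re-run in isolation from the
command line. All randomness is derived from one master seed through named
substreams; a ``manifest.json`` in the run directory records the config
hash and the seed every stage consumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features, gee, generative, indicators, synthetic, trajectories
from .evaluation import evaluate_predictions
from .indicators import FEATURES

logger = logging.getLogger(__name__)

#: canonical artifact files produced by a full run
ARTIFACTS = (
    "clean_hourly.parquet",
    "cleaning_report.json",
    "indicators.csv",
    "classes.csv",
    "fit.json",
    "gee_univariate.csv",
    "gee_multivariate.csv",
    "gee_contrasts.csv",
    "eval_report.json",
)

_STAGE_STREAMS = {
    "simulate": 1,
    "clean": 2,
    "trajectories": 3,
    "split": 4,
    "cluster": 5,
    "train": 6,
    "predict": 7,
    "evaluate": 8,
}


@dataclass
class RunConfig:
    """Run-level configuration (see the per-module defaults for the rest)."""

    outdir: str = "run"
    n_participants: int = 200
    train_fraction: float = 0.80
    family: str = "FP-CGAN"
    epochs: int = 100
    draws_per_point: int = 4
    k_range: tuple = (2, 3, 4, 5)
    n_restarts: int = 5
    collinearity_threshold: float = 0.7
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGE_STREAMS[stage]])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def _manifest(cfg: RunConfig, out: Path) -> dict:
    path = out / "manifest.json"
    if path.exists():
        return json.loads(path.read_text())
    return {"config_hash": cfg.config_hash(), "seeds": {}, "master_seed": cfg.seed}


def _record(cfg: RunConfig, out: Path, stage: str, artifacts: list[str]) -> None:
    man = _manifest(cfg, out)
    man["seeds"][stage] = cfg.stage_seed(stage)
    man.setdefault("artifacts", {})
    for a in artifacts:
        man["artifacts"][a] = {"stage": stage, "config_hash": man["config_hash"]}
    (out / "manifest.json").write_text(json.dumps(man, indent=2))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = synthetic.CohortConfig(
        n_participants=cfg.n_participants,
        seed=cfg.stage_seed("simulate"),
        **cfg.cohort,
    )
    cohort = synthetic.simulate_cohort(cohort_cfg)
    cohort = synthetic.apply_missingness(cohort)
    hourly = cohort.hourly.drop(columns=["mood"])  # mood arrives via EMA
    hourly.to_csv(out / "hourly.csv", index=False)
    cohort.ema.to_csv(out / "ema.csv", index=False)
    cohort.phq.drop(columns=["delta"]).to_csv(out / "phq.csv", index=False)
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    _record(cfg, out, "simulate", ["hourly.csv", "ema.csv", "phq.csv", "covariates.csv"])


def stage_clean(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    hourly = pd.read_csv(out / "hourly.csv", parse_dates=["hour_start"])
    ema = pd.read_csv(out / "ema.csv", parse_dates=["timestamp"])
    clean, report = features.clean_pipeline(hourly, ema, seed=cfg.stage_seed("clean"))
    clean.to_parquet(out / "clean_hourly.parquet", index=False)
    (out / "cleaning_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    _record(cfg, out, "clean", ["clean_hourly.parquet", "cleaning_report.json"])


def stage_indicators(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    clean = pd.read_parquet(out / "clean_hourly.parquet")
    table = indicators.indicator_table(clean)
    table.to_csv(out / "indicators.csv", index=False)
    _record(cfg, out, "clean", ["indicators.csv"])


def stage_trajectories(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    phq = pd.read_csv(out / "phq.csv")
    deltas = trajectories.deltas_from_phq(phq)
    fit = trajectories.select_class_count(
        deltas,
        K_range=cfg.k_range,
        n_restarts=cfg.n_restarts,
        seed=cfg.stage_seed("trajectories"),
    )
    labels = trajectories.label_resilience(fit)
    labels.to_csv(out / "classes.csv", index=False)
    (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    _record(cfg, out, "trajectories", ["classes.csv", "fit.json"])


def _analysis_frame(out: Path):
    """Indicators joined with labels and covariates (analysis cohort)."""
    table = pd.read_csv(out / "indicators.csv")
    labels = pd.read_csv(out / "classes.csv")
    covars = pd.read_csv(out / "covariates.csv")
    merged = table.merge(
        labels[["participant_id", "resilient"]], on="participant_id"
    ).merge(covars, on="participant_id")
    ind_cols = [c for c in indicators.indicator_columns() if c in merged.columns]
    std = gee.standardize_indicators(merged[["participant_id"] + ind_cols])
    return std, merged["resilient"].astype(float), merged[["sex", "age", "specialty"]]


def stage_gee(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    std, labels, covars = _analysis_frame(out)
    uni = gee.screen_univariate(std, labels, covars)
    uni.to_csv(out / "gee_univariate.csv", index=False)
    retained = gee.prune_collinear(std, uni, threshold=cfg.collinearity_threshold)
    if retained:
        multi = gee.fit_multivariate_gee(std, retained, labels, covars)
    else:
        logger.warning("no significant indicators; multivariate GEE skipped")
        multi = pd.DataFrame(
            columns=["indicator", "beta", "ci_lo", "ci_hi", "p", "model", "converged"]
        )
    multi.to_csv(out / "gee_multivariate.csv", index=False)
    _record(cfg, out, "clean", ["gee_univariate.csv", "gee_multivariate.csv"])


def split_participants(
    pids, class_ids, train_fraction: float, seed: int
) -> tuple[list, list]:
    """Participant-level (leave-subject-out) split stratified by trajectory
    class; test size per class by largest-remainder rounding."""
    rng = np.random.default_rng(seed)
    pids = np.asarray(pids)
    class_ids = np.asarray(class_ids)
    n_test_total = round((1.0 - train_fraction) * len(pids))
    test: list = []
    classes, counts = np.unique(class_ids, return_counts=True)
    exact = counts * (1.0 - train_fraction)
    base = np.floor(exact).astype(int)
    rem = exact - base
    extra = n_test_total - base.sum()
    order = np.argsort(-rem)
    take = base.copy()
    take[order[: max(extra, 0)]] += 1
    for cls, k in zip(classes, take):
        members = pids[class_ids == cls]
        test.extend(rng.choice(members, size=min(k, len(members)), replace=False))
    test_set = set(test)
    train = [p for p in pids if p not in test_set]
    return train, sorted(test_set)


def stage_model(cfg: RunConfig) -> None:
    """Split, cluster, train the configured family, predict, evaluate,
    and compare actual vs predicted indicator associations."""
    out = Path(cfg.outdir)
    clean = pd.read_parquet(out / "clean_hourly.parquet")
    labels = pd.read_csv(out / "classes.csv")

    train_ids, test_ids = split_participants(
        labels["participant_id"],
        labels["class_id"],
        cfg.train_fraction,
        cfg.stage_seed("split"),
    )
    pd.DataFrame(
        {
            "participant_id": train_ids + test_ids,
            "split": ["train"] * len(train_ids) + ["test"] * len(test_ids),
        }
    ).to_csv(out / "split.csv", index=False)

    train_h = clean[clean["participant_id"].isin(train_ids)]
    test_h = clean[clean["participant_id"].isin(test_ids)]

    ads_train = generative.actual_ds_table(train_h)
    ads_test = generative.actual_ds_table(test_h)
    cluster_model = generative.cluster_participants(
        ads_train, seed=cfg.stage_seed("cluster")
    )

    spec = generative.GeneratorSpec(
        family=cfg.family, epochs=cfg.epochs, seed=cfg.stage_seed("train")
    )
    gen = generative.train_generator(
        spec, train_h, cluster_model if spec.uses_clusters else None
    )
    gen.save(out / "model.json", out / "model_params.npz")

    # evaluation on held-out participants (Q1 may be used for matching)
    predict_seed = cfg.stage_seed("predict")
    pred_ds = generative.predict_ds_table(
        gen, test_h, noise_seed=predict_seed, draws_per_point=cfg.draws_per_point
    )
    train_mean_ds = ads_train[list(FEATURES)].mean()
    merged = ads_test.merge(pred_ds, on="participant_id", suffixes=("_a", "_p"))
    report = evaluate_predictions(
        merged[["participant_id"] + [f + "_a" for f in FEATURES]].rename(
            columns={f + "_a": f for f in FEATURES}
        ),
        merged[["participant_id"] + [f + "_p" for f in FEATURES]].rename(
            columns={f + "_p": f for f in FEATURES}
        ),
        train_mean_ds,
        model=cfg.family,
    )
    (out / "eval_report.json").write_text(json.dumps(report.to_dict(), indent=2))

    # predicted indicators for the whole cohort (train + test)
    predicted = generative.predict_indicators(
        gen, clean, noise_seed=predict_seed, draws_per_point=cfg.draws_per_point
    )
    predicted.to_csv(out / "predicted_indicators.csv", index=False)
    _record(cfg, out, "split", ["split.csv"])
    _record(cfg, out, "cluster", [])
    _record(cfg, out, "predict", ["predicted_indicators.csv"])
    _record(cfg, out, "train", ["model.json", "eval_report.json"])


def stage_contrast(cfg: RunConfig) -> None:
    """GEE on predicted indicators and actual-vs-predicted contrasts."""
    out = Path(cfg.outdir)
    std, labels, covars = _analysis_frame(out)
    predicted = pd.read_csv(out / "predicted_indicators.csv")
    common = std["participant_id"].isin(predicted["participant_id"])
    std = std[common].reset_index(drop=True)
    labels = labels[common.to_numpy()].reset_index(drop=True)
    covars = covars[common.to_numpy()].reset_index(drop=True)
    predicted = predicted.set_index("participant_id").loc[
        std["participant_id"]
    ].reset_index()
    pred_cols = [c for c in predicted.columns if c != "participant_id"]
    pred_std = gee.standardize_indicators(predicted[["participant_id"] + pred_cols])

    # univariate screen on predicted indicators
    uni_pred = gee.screen_univariate(pred_std, labels, covars)
    uni_pred.to_csv(out / "gee_predicted_univariate.csv", index=False)

    # BL-exclusive entries are observed (copied from actual A), so only
    # internship-side and difference indicators are contrasted
    shared = [
        c
        for c in std.columns
        if c not in ("participant_id", "const")
        and c in pred_std.columns
        and ("__INTERN" in c or "__DIFF" in c)
        and not c.startswith("hours__")
    ]
    contrasts = gee.compare_actual_vs_predicted(
        std[["participant_id"] + shared],
        pred_std[["participant_id"] + shared],
        labels,
        covars,
    )
    pd.DataFrame(
        [
            {
                "indicator": c.indicator,
                "beta_actual": c.beta_actual,
                "beta_predicted": c.beta_predicted,
                "interaction_beta": c.interaction_beta,
                "interaction_p": c.interaction_p,
                "significantly_different": c.significantly_different,
            }
            for c in contrasts
        ]
    ).to_csv(out / "gee_contrasts.csv", index=False)
    _record(cfg, out, "evaluate", ["gee_contrasts.csv", "gee_predicted_univariate.csv"])


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns {artifact name: path}."""
    out = Path(cfg.outdir)
    if cfg.simulate:
        stage_simulate(cfg)
    stage_clean(cfg)
    stage_indicators(cfg)
    stage_trajectories(cfg)
    stage_gee(cfg)
    stage_model(cfg)
    stage_contrast(cfg)
    return {name: out / name for name in ARTIFACTS}


# --------------------------------------------------------------------------
# input validation
# --------------------------------------------------------------------------

_HOURLY_COLS = {
    "participant_id",
    "hour_start",
    "step_count",
    "sleep_seconds",
    "in_bed_seconds",
    "mean_heart_rate",
}


def validate_inputs(hourly_path, ema_path=None, phq_path=None) -> list[dict]:
    """Schema checks on the raw input tables; returns machine-readable
    violations (empty list = well-formed)."""
    violations = []

    def add(file, kind, detail):
        violations.append({"file": str(file), "kind": kind, "detail": detail})

    hourly = pd.read_csv(hourly_path)
    missing = _HOURLY_COLS - set(hourly.columns)
    if missing:
        add(hourly_path, "missing_columns", sorted(missing))
    else:
        ts = pd.to_datetime(hourly["hour_start"], errors="coerce")
        if ts.isna().any():
            add(hourly_path, "bad_timestamp", int(ts.isna().sum()))
        elif not (ts.dt.minute.eq(0) & ts.dt.second.eq(0)).all():
            add(hourly_path, "off_hour_grid", "timestamps must be on the hour")
        dup = hourly.duplicated(subset=["participant_id", "hour_start"])
        if dup.any():
            add(hourly_path, "duplicate_participant_hour", int(dup.sum()))
        for col in ("step_count", "sleep_seconds", "in_bed_seconds"):
            bad = hourly[col].dropna() < 0
            if bad.any():
                add(hourly_path, "negative_value", {col: int(bad.sum())})
        hr = hourly["mean_heart_rate"].dropna()
        if ((hr < 20) | (hr > 250)).any():
            add(hourly_path, "heart_rate_range", int(((hr < 20) | (hr > 250)).sum()))

    if ema_path is not None:
        ema = pd.read_csv(ema_path)
        if not {"participant_id", "timestamp", "mood"} <= set(ema.columns):
            add(ema_path, "missing_columns", "participant_id/timestamp/mood")
        else:
            bad = (ema["mood"] < 1) | (ema["mood"] > 10)
            if bad.any():
                add(ema_path, "mood_range", [int(i) for i in ema.index[bad][:10]])

    if phq_path is not None:
        phq = pd.read_csv(phq_path)
        if not {"participant_id", "period", "phq9"} <= set(phq.columns):
            add(phq_path, "missing_columns", "participant_id/period/phq9")
        else:
            bad = (phq["phq9"] < 0) | (phq["phq9"] > 27)
            if bad.any():
                add(phq_path, "phq9_range", [int(i) for i in phq.index[bad][:10]])
            unknown = ~phq["period"].isin(synthetic.PERIODS)
            if unknown.any():
                add(phq_path, "unknown_period", sorted(phq.loc[unknown, "period"].unique()))

    return violations
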
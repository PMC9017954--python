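"""Per-participant summary indicators of hourly feature distributions.

Each eligible participant contributes two multivariate hourly distributions:
``A`` (baseline, label ``BL``) and ``B`` (internship, label ``INTERN``), each
an ``n x m`` table over the m = 5 hourly features. The indicator vector
summarises these with, per feature, the mean, standard deviation and Pearson
skew of each period plus the between-period Cohen's d_s, and adds the two
hour counts ``n_A`` / ``n_B`` as a measure of data availability:
5 features x (3 statistics x 2 periods + 1 d_s) + 2 counts = 37 indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Fixed feature order of the multivariate hourly distributions.
FEATURES = (
    "step_count",
    "sleep_seconds",
    "in_bed_seconds",
    "mean_heart_rate",
    "mood",
)

#: Number of hourly features (m).
N_FEATURES = len(FEATURES)

#: Total indicators per participant: 5 x (3 x 2 + 1) + 2 hour counts.
N_INDICATORS = N_FEATURES * 7 + 2

_METRICS = ("mean", "sd", "skew")
_PERIODS = ("BL", "INTERN")


class DegenerateSampleError(ValueError):
    """A statistic is undefined because the sample has zero variance."""


def indicator_columns() -> list[str]:
    """Canonical ``<feature>__<metric>__<period>`` column order (37 names)."""
    cols = []
    for feat in FEATURES:
        for period in _PERIODS:
            for metric in _METRICS:
                cols.append(f"{feat}__{metric}__{period}")
        cols.append(f"{feat}__cohens_ds__DIFF")
    cols.append("hours__count__BL")
    cols.append("hours__count__INTERN")
    return cols


def pearson_skew(sample) -> float:
    """Pearson's skew coefficient 3*(mean - median)/SD.

    Uses the sample (n-1) standard deviation and the mid-rank median.
    Raises :class:`DegenerateSampleError` when the SD is zero.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise DegenerateSampleError("pearson_skew needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("pearson_skew undefined for zero-variance sample")
    return float(3.0 * (x.mean() - np.median(x)) / sd)


def cohens_ds(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Standardised mean difference (B - A) with the pooled (n-1)-weighted SD.

    d_s = (mean_B - mean_A) / sqrt(((n_A-1) SD_A^2 + (n_B-1) SD_B^2)
                                   / (n_A + n_B - 2))
    """
    if n_a < 2 or n_b < 2:
        raise DegenerateSampleError("cohens_ds needs n >= 2 in both periods")
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if pooled_var <= 0:
        raise DegenerateSampleError("cohens_ds undefined for zero pooled variance")
    return float((mean_b - mean_a) / np.sqrt(pooled_var))


@dataclass(frozen=True)
class PeriodDistribution:
    """One participant-period block of hourly feature vectors."""

    participant_id: str
    label: str  # "A" (baseline) or "B" (internship)
    points: pd.DataFrame  # n x 5, columns FEATURES

    def __post_init__(self):
        missing = [c for c in FEATURES if c not in self.points.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")

    @property
    def n(self) -> int:
        return len(self.points)


def build_indicator_vector(dist_a: PeriodDistribution, dist_b: PeriodDistribution) -> dict:
    """Compute the 37 named indicators from a participant's A and B blocks.

    Degenerate (zero-variance) features raise with the feature named so the
    caller can drop the participant or the indicator.
    """
    if dist_a.participant_id != dist_b.participant_id:
        raise ValueError("A and B belong to different participants")
    out: dict[str, float] = {}
    for feat in FEATURES:
        stats = {}
        for period, dist in (("BL", dist_a), ("INTERN", dist_b)):
            x = np.asarray(dist.points[feat], dtype=float)
            mean = float(x.mean())
            sd = float(x.std(ddof=1))
            try:
                skew = pearson_skew(x)
            except DegenerateSampleError as err:
                raise DegenerateSampleError(f"{feat} ({period}): {err}") from err
            out[f"{feat}__mean__{period}"] = mean
            out[f"{feat}__sd__{period}"] = sd
            out[f"{feat}__skew__{period}"] = skew
            stats[period] = (mean, sd, len(x))
        (ma, sa, na), (mb, sb, nb) = stats["BL"], stats["INTERN"]
        try:
            out[f"{feat}__cohens_ds__DIFF"] = cohens_ds(ma, sa, na, mb, sb, nb)
        except DegenerateSampleError as err:
            raise DegenerateSampleError(f"{feat}: {err}") from err
    out["hours__count__BL"] = int(dist_a.n)
    out["hours__count__INTERN"] = int(dist_b.n)
    assert len(out) == N_INDICATORS
    return out


def cohens_ds_from_samples(a, b) -> float:
    """Cohen's d_s computed directly from the two raw samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return cohens_ds(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))


def indicator_table(clean_hourly: pd.DataFrame) -> pd.DataFrame:
    """One indicator row per participant from a cleaned hourly table.

    ``clean_hourly`` must carry ``participant_id``, ``period`` (BL or Q1..Q4)
    and the five feature columns. Participants whose blocks are degenerate on
    any feature are skipped (mirroring the zero-variance eligibility rule).
    """
    rows = []
    for pid, grp in clean_hourly.groupby("participant_id", sort=True):
        bl = grp[grp["period"] == "BL"]
        intern = grp[grp["period"] != "BL"]
        if len(bl) < 2 or len(intern) < 2:
            continue
        dist_a = PeriodDistribution(str(pid), "A", bl[list(FEATURES)])
        dist_b = PeriodDistribution(str(pid), "B", intern[list(FEATURES)])
        try:
            vec = build_indicator_vector(dist_a, dist_b)
        except DegenerateSampleError:
            continue
        vec["participant_id"] = pid
        rows.append(vec)
    cols = ["participant_id"] + indicator_columns()
    return pd.DataFrame(rows, columns=cols)


def ds_table(indicators: pd.DataFrame) -> pd.DataFrame:
    """Extract the 5-column Cohen's d_s block (one row per participant)."""
    cols = [f"{feat}__cohens_ds__DIFF" for feat in FEATURES]
    out = indicators[["participant_id"] + cols].copy()
    out.columns = ["participant_id"] + list(FEATURES)
    return out
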
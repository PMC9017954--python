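"""Robust evaluation statistics.

Prediction quality for the generative models is measured with the skipped
correlation between actual and predicted per-participant Cohen's d_s, which
removes bivariate outliers before correlating, and with one-sided Wilcoxon
signed-rank comparisons of per-participant squared errors against the
mean-assignment baseline (predicting every test participant with the
training-set average d_s). Two-sample contrasts elsewhere in the pipeline are
gated on Shapiro-Wilk normality: a t-test when both samples look normal,
Mann-Whitney U otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet


@dataclass
class SkippedCorrelation:
    r: float
    p: float
    n_used: int
    flags: np.ndarray  # True where the pair was removed as a bivariate outlier

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _ideal_fourths(x: np.ndarray) -> tuple[float, float]:
    """Ideal-fourths (interpolated quartile) estimates of q1 and q2."""
    x = np.sort(x)
    n = len(x)
    j = int(np.floor(n / 4 + 5 / 12))
    h = n / 4 + 5 / 12 - j
    q1 = (1 - h) * x[j - 1] + h * x[j]
    k = n - j + 1
    q2 = (1 - h) * x[k - 1] + h * x[k - 2]
    return float(q1), float(q2)


def skipped_correlation(x, y, random_state: int = 0) -> SkippedCorrelation:
    """Skipped Pearson correlation with MCD-centred projection outlier removal.

    The robust bivariate centre is the minimum-covariance-determinant
    location. Each data point defines a projection direction from that
    centre; along every direction, points whose projection falls outside the
    ideal-fourths boxplot bound (median +/- sqrt(chi2_{0.975,2}) * (q2 - q1))
    are flagged. Pearson's r is then computed on the unflagged pairs with a
    t-based p-value on the reduced n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 10:
        raise ValueError("skipped correlation needs n >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) input")

    pts = np.column_stack([x, y])
    mcd = MinCovDet(random_state=random_state).fit(pts)
    centred = pts - mcd.location_

    cutoff = np.sqrt(stats.chi2.ppf(0.975, df=2))
    flags = np.zeros(n, dtype=bool)
    norms = np.linalg.norm(centred, axis=1)
    for i in range(n):
        if norms[i] == 0:
            continue
        d = centred[i] / norms[i]
        proj = centred @ d
        med = np.median(proj)
        q1, q2 = _ideal_fourths(proj)
        span = cutoff * (q2 - q1)
        flags |= (proj > med + span) | (proj < med - span)

    keep = ~flags
    n_used = int(keep.sum())
    if n_used < 3 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
        raise ValueError("too few non-outlying pairs for correlation")
    r, _ = stats.pearsonr(x[keep], y[keep])
    # t approximation on the post-removal sample size
    t = r * np.sqrt((n_used - 2) / max(1e-300, 1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df=n_used - 2))
    return SkippedCorrelation(r=float(r), p=p, n_used=n_used, flags=flags)


def compare_to_mean_baseline(predicted_ds, actual_ds, training_mean_ds):
    """One-sided Wilcoxon signed-rank: model squared error < baseline error.

    The baseline error is the squared deviation of each actual d_s from the
    training-set mean d_s for the feature. Returns ``(W, p)``; if every
    paired difference is zero the test is undefined and ``(nan, nan)`` is
    returned.
    """
    predicted = np.asarray(predicted_ds, dtype=float)
    actual = np.asarray(actual_ds, dtype=float)
    model_err = (predicted - actual) ** 2
    base_err = (actual - float(training_mean_ds)) ** 2
    diff = model_err - base_err
    if np.all(diff == 0):
        return float("nan"), float("nan")
    w, p = stats.wilcoxon(model_err, base_err, alternative="less", zero_method="wilcox")
    return float(w), float(p)


def gated_two_sample_test(sample_a, sample_b, alpha: float = 0.05):
    """Two-sample location test gated by Shapiro-Wilk normality checks.

    If either sample rejects normality at ``alpha``, a two-sided
    Mann-Whitney U test is used; otherwise an independent two-sample t-test.
    Returns ``(test_name, statistic, p)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    normal = (stats.shapiro(a).pvalue >= alpha) and (stats.shapiro(b).pvalue >= alpha)
    if normal:
        res = stats.ttest_ind(a, b)
        return "t", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mannwhitney", float(res.statistic), float(res.pvalue)


def outlier_burden_test(outlier_counts, resilient_labels):
    """One-sided Mann-Whitney U: do sensitive participants shed more outliers?

    Tests whether the per-participant outlier counts of stress-sensitive
    participants are stochastically greater than those of stress-resilient
    participants. Returns ``(U, p)``.
    """
    counts = np.asarray(outlier_counts, dtype=float)
    labels = np.asarray(resilient_labels, dtype=bool)
    sensitive = counts[~labels]
    resilient = counts[labels]
    if len(sensitive) == 0 or len(resilient) == 0:
        raise ValueError("both label groups must be non-empty")
    u, p = stats.mannwhitneyu(sensitive, resilient, alternative="greater")
    return float(u), float(p)


@dataclass
class EvalReport:
    """Per-model evaluation: skipped correlations and baseline comparisons."""

    model: str
    skipped: dict[str, SkippedCorrelation] = field(default_factory=dict)
    wilcoxon: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "skipped_correlation": {
                f: {"r": s.r, "p": s.p, "n_used": s.n_used, "n_flagged": s.n_flagged}
                for f, s in self.skipped.items()
            },
            "wilcoxon_vs_mean_baseline": {
                f: {"W": w, "p": p} for f, (w, p) in self.wilcoxon.items()
            },
        }


def evaluate_predictions(actual_ds, predicted_ds, training_mean_ds, model: str) -> EvalReport:
    """Build an :class:`EvalReport` from per-participant d_s tables.

    All three inputs are keyed by feature: ``actual_ds`` / ``predicted_ds``
    are DataFrames with one row per test participant, ``training_mean_ds``
    maps feature name to the training-set mean d_s.
    """
    report = EvalReport(model=model)
    for feat in actual_ds.columns:
        if feat == "participant_id":
            continue
        a = np.asarray(actual_ds[feat], dtype=float)
        p = np.asarray(predicted_ds[feat], dtype=float)
        report.skipped[feat] = skipped_correlation(a, p)
        report.wilcoxon[feat] = compare_to_mean_baseline(p, a, training_mean_ds[feat])
    return report
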
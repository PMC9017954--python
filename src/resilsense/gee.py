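"""GEE association screening of indicators against stress-resilience.

Each indicator is standardised and tested one at a time in a binomial
logit-link generalized estimating equation of the resilient/sensitive label,
controlling for sex and age, clustered by internship specialty with an
exchangeable working correlation (marginal, cluster-robust inference).
Significant indicators are pruned for collinearity and refitted jointly in a
multivariate GEE. The same machinery compares actual against predicted
indicator tables through a source-flag interaction term: a significant
interaction coefficient means the predicted indicator carries a different
association with resilience than the actual one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by an indicator."""


@dataclass
class GEEFit:
    indicator: str
    beta: float
    ci_lo: float
    ci_hi: float
    p: float
    model: str  # univariate | multivariate | interaction
    converged: bool = True

    def to_row(self) -> dict:
        return {
            "indicator": self.indicator,
            "beta": self.beta,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "p": self.p,
            "model": self.model,
            "converged": self.converged,
        }


@dataclass
class InteractionContrast:
    indicator: str
    beta_actual: float
    beta_predicted: float
    interaction_beta: float
    interaction_p: float

    @property
    def significantly_different(self) -> bool:
        return self.interaction_p < ALPHA


def standardize_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every numeric indicator column (sample SD) and append a
    constant intercept column of 1. Zero-SD columns are dropped with a
    warning; non-numeric columns (ids) pass through untouched."""
    out = {}
    for col in table.columns:
        x = table[col]
        if not pd.api.types.is_numeric_dtype(x) or col == "participant_id":
            out[col] = x
            continue
        sd = float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            logger.warning("dropping zero-variance indicator column %r", col)
            continue
        out[col] = (x - x.mean()) / sd
    frame = pd.DataFrame(out)
    frame["const"] = 1.0
    return frame


def _control_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Sex as binary, age continuous (unstandardised)."""
    sex = covariates["sex"]
    if not pd.api.types.is_numeric_dtype(sex):
        sex = (sex.astype(str).str.lower() == "female").astype(float)
    return pd.DataFrame(
        {"sex": sex.to_numpy(dtype=float), "age": covariates["age"].to_numpy(dtype=float)}
    )


def _fit_gee(
    y,
    exog: pd.DataFrame,
    groups,
    focus: str,
    model_name: str,
    cov_type: str = "bias_reduced",
) -> GEEFit:
    y = np.asarray(y, dtype=float)
    x_focus = exog[focus].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError(f"outcome is constant when fitting {focus!r}")
    # complete separation: the focus indicator splits the outcome perfectly
    if x_focus.std() > 0:
        lo, hi = x_focus[y == 0], x_focus[y == 1]
        if len(lo) and len(hi) and (lo.max() < hi.min() or hi.max() < lo.min()):
            raise SeparationError(f"complete separation on indicator {focus!r}")
    converged = True
    groups = np.asarray(groups)
    focus_ix = list(exog.columns).index(focus)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        # the bias-reduced (Mancl-DeRouen) sandwich corrects the
        # anti-conservative robust covariance at a small cluster count; with
        # a near-zero within-cluster correlation the exchangeable iteration
        # can oscillate or diverge, so the independence structure (estimates
        # stay consistent under any working structure) and the plain robust
        # sandwich serve as fallbacks
        attempts = [
            (sm.cov_struct.Exchangeable(), cov_type),
            (sm.cov_struct.Independence(), cov_type),
            (sm.cov_struct.Exchangeable(), "robust"),
            (sm.cov_struct.Independence(), "robust"),
        ]
        last_err = None
        for struct, ct in attempts:
            model = sm.GEE(
                y,
                exog.to_numpy(dtype=float),
                groups=groups,
                family=sm.families.Binomial(),
                cov_struct=struct,
            )
            try:
                candidate = model.fit(maxiter=100, cov_type=ct)
            except Exception as err:
                last_err = err
                converged = False
                continue
            ok = np.isfinite(candidate.params[focus_ix]) and np.isfinite(
                candidate.bse[focus_ix]
            )
            if ok and getattr(candidate, "converged", True):
                res = candidate
                break
            converged = False
        if res is None:
            logger.warning("GEE failed for %s: %s", focus, last_err)
            raise SeparationError(
                f"GEE produced non-finite estimates for {focus!r}"
            )
    params = pd.Series(res.params, index=exog.columns)
    bse = pd.Series(res.bse, index=exog.columns)
    # t reference with G-2 df: robust inference at a small cluster count
    df = max(len(np.unique(groups)) - 2, 1)
    crit = stats.t.ppf(1 - ALPHA / 2, df)
    beta = float(params[focus])
    se = float(bse[focus])
    if se > 0:
        p = float(2 * stats.t.sf(abs(beta) / se, df))
    else:  # a degenerate column (e.g. identical stacked copies): no evidence
        p = 1.0 if beta == 0 else 0.0
    return GEEFit(
        indicator=focus,
        beta=beta,
        ci_lo=beta - crit * se,
        ci_hi=beta + crit * se,
        p=p,
        model=model_name,
        converged=converged,
    )


def fit_univariate_gee(
    indicator: pd.Series | np.ndarray,
    labels,
    covariates: pd.DataFrame,
    name: str = "indicator",
) -> GEEFit:
    """GEE of resilient on {indicator, sex, age, const}, specialty-clustered.

    ``indicator`` should already be standardised; ``covariates`` carries
    sex, age and specialty.
    """
    exog = _control_matrix(covariates)
    exog.insert(0, name, np.asarray(indicator, dtype=float))
    exog["const"] = 1.0
    return _fit_gee(labels, exog, covariates["specialty"], name, "univariate")


def screen_univariate(
    indicator_table: pd.DataFrame, labels, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Univariate GEE per standardised indicator column; one row per fit.

    Indicator columns are everything numeric except the intercept. Fits
    that fail (separation, non-convergence) are recorded with NaN beta.
    """
    rows = []
    for col in indicator_table.columns:
        if col in ("participant_id", "const"):
            continue
        try:
            fit = fit_univariate_gee(indicator_table[col], labels, covariates, name=col)
            rows.append(fit.to_row())
        except SeparationError as err:
            logger.warning("skipping %s: %s", col, err)
            rows.append(
                {
                    "indicator": col,
                    "beta": np.nan,
                    "ci_lo": np.nan,
                    "ci_hi": np.nan,
                    "p": np.nan,
                    "model": "univariate",
                    "converged": False,
                }
            )
    return pd.DataFrame(rows)


def prune_collinear(
    indicator_table: pd.DataFrame,
    univariate: pd.DataFrame,
    threshold: float = 0.7,
) -> list[str]:
    """Greedy collinearity pruning of the significant indicator set.

    Among any pair with |Spearman rho| > ``threshold`` the indicator with
    the larger univariate p is dropped. Candidates are visited in
    deterministic order (ascending p, then name); each survivor knocks out
    every remaining candidate too correlated with it.
    """
    sig = univariate[(univariate["p"] < ALPHA) & univariate["beta"].notna()]
    ordered = sig.sort_values(["p", "indicator"], kind="stable")["indicator"].tolist()
    kept: list[str] = []
    for cand in ordered:
        ok = True
        for surv in kept:
            rho = spearmanr(indicator_table[cand], indicator_table[surv]).statistic
            if abs(rho) > threshold:
                ok = False
                break
        if ok:
            kept.append(cand)
    return kept


def fit_multivariate_gee(
    indicator_table: pd.DataFrame,
    retained: list[str],
    labels,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """One GEE with all retained indicators plus controls; per-indicator rows."""
    if not retained:
        raise ValueError("no indicators retained for the multivariate GEE")
    exog = indicator_table[retained].copy()
    controls = _control_matrix(covariates)
    exog["sex"] = controls["sex"].to_numpy()
    exog["age"] = controls["age"].to_numpy()
    exog["const"] = 1.0
    rows = []
    for name in retained:
        fit = _fit_gee(labels, exog, covariates["specialty"], name, "multivariate")
        rows.append(fit.to_row())
    return pd.DataFrame(rows)


def benjamini_hochberg(univariate: pd.DataFrame) -> pd.DataFrame:
    """Optional FDR adjustment of the univariate screen (off by default in
    the pipeline, matching unadjusted per-indicator reporting)."""
    out = univariate.copy()
    ok = out["p"].notna()
    out.loc[ok, "p_adjusted"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def compare_actual_vs_predicted(
    actual: pd.DataFrame,
    predicted: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    indicators: list[str] | None = None,
) -> list[InteractionContrast]:
    """Interaction-term comparison of actual vs predicted indicator effects.

    Rows from both tables are concatenated with a binary source flag
    (1 = predicted) and a source × indicator interaction; the GEE then has
    exog {indicator, source, interaction, sex, age, const} with the usual
    specialty clustering. The interaction beta estimates the change in the
    indicator's association when computed from predicted data.
    """
    a_ids = set(actual["participant_id"])
    if a_ids != set(predicted["participant_id"]):
        raise ValueError("actual and predicted tables cover different participants")
    if indicators is None:
        indicators = [
            c
            for c in actual.columns
            if c not in ("participant_id", "const") and c in predicted.columns
        ]
    actual = actual.set_index("participant_id")
    predicted = predicted.set_index("participant_id").reindex(actual.index)
    labels = pd.Series(np.asarray(labels, dtype=float), index=actual.index)
    cov = covariates.set_index(actual.index)

    contrasts = []
    for name in indicators:
        frames = []
        for source_flag, table in ((0.0, actual), (1.0, predicted)):
            x = table[name].to_numpy(dtype=float)
            frames.append(
                pd.DataFrame(
                    {
                        name: x,
                        "source": source_flag,
                        "interaction": source_flag * x,
                        "sex": _control_matrix(cov)["sex"].to_numpy(),
                        "age": cov["age"].to_numpy(dtype=float),
                        "const": 1.0,
                        "_y": labels.to_numpy(),
                        "_g": cov["specialty"].to_numpy(),
                    }
                )
            )
        stacked = pd.concat(frames, ignore_index=True)
        exog = stacked[[name, "source", "interaction", "sex", "age", "const"]]
        try:
            fit_main = _fit_gee(stacked["_y"], exog, stacked["_g"], name, "interaction")
            fit_inter = _fit_gee(
                stacked["_y"], exog, stacked["_g"], "interaction", "interaction"
            )
        except SeparationError as err:
            logger.warning("contrast GEE failed for %s: %s", name, err)
            continue
        contrasts.append(
            InteractionContrast(
                indicator=name,
                beta_actual=fit_main.beta,
                beta_predicted=fit_main.beta + fit_inter.beta,
                interaction_beta=fit_inter.beta,
                interaction_p=fit_inter.p,
            )
        )
    return contrasts
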
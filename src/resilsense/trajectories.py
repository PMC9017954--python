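"""Quadratic growth mixture modelling of depression-symptom trajectories.

ΔPHQ-9 (change from the pre-internship baseline) is observed on the quarter
grid t in {1..4}. A K-class growth mixture model puts a quadratic mean curve
gamma0_k + gamma1_k t + gamma2_k t^2 on each latent class, a shared
participant random intercept (variance tau^2) and shared residual variance
sigma^2, so within a class the observed vector y_i over the participant's
available quarters is multivariate normal with covariance
sigma^2 I + tau^2 J. Parameters and posterior class responsibilities are
estimated by EM (random intercept and class jointly latent), missing
quarters are handled by the marginal likelihood over observed timepoints,
and the class count is selected across K by information criteria. The class
whose fitted curve stays closest to zero — the minimal-change majority — is
labelled stress-resilient; all other classes are pooled as stress-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_T_GRID = np.arange(1, 5, dtype=float)


@dataclass
class TrajectoryMixtureFit:
    K: int
    gamma: np.ndarray  # (K, 3) quadratic fixed effects
    pi: np.ndarray  # (K,) mixing proportions
    tau2: float  # random-intercept variance
    sigma2: float  # residual variance
    responsibilities: np.ndarray  # (n, K)
    participant_ids: list
    loglik: float
    loglik_path: np.ndarray = field(repr=False, default=None)
    converged: bool = True

    @property
    def n_params(self) -> int:
        # K quadratics (3K) + K-1 free proportions + sigma^2 + tau^2
        return 3 * self.K + (self.K - 1) + 2

    @property
    def n(self) -> int:
        return len(self.participant_ids)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n) - 2 * self.loglik

    def fitted_curves(self, t=_T_GRID) -> np.ndarray:
        x = _design(np.asarray(t, dtype=float))
        return self.gamma @ x.T

    def hard_assignments(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "gamma": self.gamma.tolist(),
            "pi": self.pi.tolist(),
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
        }


def _design(t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, t**2])


def deltas_from_phq(phq: pd.DataFrame) -> pd.DataFrame:
    """Convert a (participant_id, period, phq9) table to ΔPHQ-9 long format.

    Periods are BL and Q1..Q4; the delta at quarter q is phq9(q) - phq9(BL).
    Participants without a BL score are dropped.
    """
    wide = phq.pivot_table(index="participant_id", columns="period", values="phq9")
    if "BL" not in wide.columns:
        raise ValueError("no BL period in PHQ table")
    wide = wide.dropna(subset=["BL"])
    rows = []
    for q, t in zip(("Q1", "Q2", "Q3", "Q4"), (1, 2, 3, 4)):
        if q not in wide.columns:
            continue
        sub = wide[[q, "BL"]].dropna()
        for pid, (v, bl) in sub.iterrows():
            rows.append((pid, t, float(v - bl)))
    return pd.DataFrame(rows, columns=["participant_id", "t", "delta"])


def _prepare(series: pd.DataFrame):
    """Group the long delta table into per-participant (t, y) arrays.

    Only post-baseline timepoints (t >= 1) are informative; participants
    with fewer than two of them are excluded from fitting.
    """
    post = series[series["t"] >= 1]
    ids, ys, ts = [], [], []
    for pid, grp in post.groupby("participant_id", sort=True):
        if len(grp) < 2:
            continue
        ids.append(pid)
        ts.append(grp["t"].to_numpy(dtype=float))
        ys.append(grp["delta"].to_numpy(dtype=float))
    return ids, ts, ys


def _pattern_groups(ts):
    """Index participants by identical observed-timepoint patterns so the
    E-step runs vectorised per pattern."""
    groups: dict[tuple, list[int]] = {}
    for i, t in enumerate(ts):
        groups.setdefault(tuple(t), []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def _class_loglik(Y, X, gamma_k, sigma2, tau2):
    """Marginal log N(y; X gamma, sigma^2 I + tau^2 J), vectorised over rows
    of Y sharing the design X."""
    n_t = X.shape[0]
    resid = Y - X @ gamma_k
    ssq = (resid**2).sum(axis=1)
    srow = resid.sum(axis=1)
    denom = sigma2 + n_t * tau2
    quad = (ssq - (tau2 / denom) * srow**2) / sigma2
    logdet = (n_t - 1) * np.log(sigma2) + np.log(denom)
    return -0.5 * (n_t * np.log(2 * np.pi) + logdet + quad)


def fit_quadratic_gmm(
    series: pd.DataFrame,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> TrajectoryMixtureFit:
    """Fit the K-class quadratic growth mixture by EM; best of restarts.

    ``series`` is a long table (participant_id, t, delta) with t in 0..4;
    the baseline point (t=0, delta=0 by construction) is uninformative and
    excluded. Each restart initialises from k-means on the mean-imputed
    delta vectors. Returns the restart with the highest final
    log-likelihood.
    """
    ids, ts, ys = _prepare(series)
    n = len(ids)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} available series")
    groups = _pattern_groups(ts)
    # imputed wide matrix for k-means initialisation only
    wide = np.full((n, 4), np.nan)
    for i, (t, y) in enumerate(zip(ts, ys)):
        wide[i, (t - 1).astype(int)] = y
    col_mean = np.nanmean(wide, axis=0)
    imputed = np.where(np.isnan(wide), col_mean, wide)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(n_restarts, 1)):
        km_seed = int(rng.integers(2**31 - 1))
        if K == 1:
            labels = np.zeros(n, dtype=int)
        else:
            labels = KMeans(n_clusters=K, n_init=2, random_state=km_seed).fit_predict(
                imputed
            )
        fit = _em(ids, ts, ys, groups, labels, K, max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em(ids, ts, ys, groups, init_labels, K, max_iter, tol) -> TrajectoryMixtureFit:
    n = len(ids)
    X_full = _design(_T_GRID)

    # initial parameters from the k-means partition
    gamma = np.zeros((K, 3))
    pi = np.full(K, 1.0 / K)
    resid_acc = []
    for k in range(K):
        members = np.where(init_labels == k)[0]
        if len(members) == 0:
            members = np.arange(n)
        Xs = np.vstack([_design(ts[i]) for i in members])
        Ys = np.concatenate([ys[i] for i in members])
        gamma[k], *_ = np.linalg.lstsq(Xs, Ys, rcond=None)
        resid_acc.append(Ys - Xs @ gamma[k])
        pi[k] = max(len(members), 1) / n
    pi = pi / pi.sum()
    sigma2 = max(float(np.concatenate(resid_acc).var()), 1e-3)
    tau2 = max(sigma2 * 0.25, 1e-3)

    loglik_path = []
    converged = False
    resp = np.full((n, K), 1.0 / K)
    for it in range(max_iter):
        # E-step: responsibilities and random-intercept posterior moments
        log_r = np.zeros((n, K))
        m = np.zeros((n, K))  # posterior mean of b_i given class k
        v = np.zeros(n)  # posterior variance (class-free)
        for t_pat, idx in groups.items():
            t_arr = np.array(t_pat)
            X = _design(t_arr)
            n_t = len(t_arr)
            Y = np.vstack([ys[i] for i in idx])
            v_pat = 1.0 / (1.0 / tau2 + n_t / sigma2)
            v[idx] = v_pat
            for k in range(K):
                log_r[idx, k] = _class_loglik(Y, X, gamma[k], sigma2, tau2)
                srow = (Y - X @ gamma[k]).sum(axis=1)
                m[idx, k] = v_pat / sigma2 * srow
        log_r = log_r + np.log(pi)[None, :]
        norm = logsumexp(log_r, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_r - norm[:, None])
        loglik_path.append(loglik)
        if it > 0 and abs(loglik_path[-1] - loglik_path[-2]) < tol * (1 + abs(loglik)):
            converged = True
            break

        # M-step (coordinate updates of the same Q function)
        pi = resp.mean(axis=0).clip(1e-12)
        pi = pi / pi.sum()
        for k in range(K):
            A = np.zeros((3, 3))
            bvec = np.zeros(3)
            for t_pat, idx in groups.items():
                X = _design(np.array(t_pat))
                Y = np.vstack([ys[i] for i in idx])
                w = resp[idx, k]
                A += (X.T @ X) * w.sum()
                target = Y - m[idx, k][:, None]
                bvec += X.T @ (w[:, None] * target).sum(axis=0)
            gamma[k] = np.linalg.solve(A + 1e-12 * np.eye(3), bvec)
        tau2 = float((resp * (m**2 + v[:, None])).sum() / n)
        tau2 = max(tau2, 1e-8)
        num = 0.0
        den = 0.0
        for t_pat, idx in groups.items():
            t_arr = np.array(t_pat)
            X = _design(t_arr)
            n_t = len(t_arr)
            Y = np.vstack([ys[i] for i in idx])
            for k in range(K):
                resid = Y - X @ gamma[k] - m[idx, k][:, None]
                num += (resp[idx, k] * ((resid**2).sum(axis=1) + n_t * v[idx])).sum()
            den += n_t * len(idx)
        sigma2 = max(float(num / den), 1e-8)

    if not converged:
        logger.warning("EM did not converge in %d iterations (K=%d)", max_iter, K)
    return TrajectoryMixtureFit(
        K=K,
        gamma=gamma.copy(),
        pi=pi.copy(),
        tau2=tau2,
        sigma2=sigma2,
        responsibilities=resp,
        participant_ids=list(ids),
        loglik=loglik_path[-1],
        loglik_path=np.array(loglik_path),
        converged=converged,
    )


def select_class_count(
    series: pd.DataFrame,
    K_range=range(2, 6),
    n_restarts: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> TrajectoryMixtureFit:
    """Fit every K in ``K_range`` and select by information criteria.

    The AIC-minimising fit is selected; when AIC and BIC disagree on the
    class count, BIC wins and a warning is logged.
    """
    ks = list(K_range)
    if not ks:
        raise ValueError("K_range must be non-empty")
    fits = {
        k: fit_quadratic_gmm(series, k, n_restarts=n_restarts, seed=seed + 101 * k, **fit_kwargs)
        for k in ks
    }
    k_aic = min(ks, key=lambda k: fits[k].aic)
    k_bic = min(ks, key=lambda k: fits[k].bic)
    if k_aic != k_bic:
        logger.warning(
            "AIC selects K=%d but BIC selects K=%d; using BIC", k_aic, k_bic
        )
        return fits[k_bic]
    return fits[k_aic]


def label_resilience(fit: TrajectoryMixtureFit) -> pd.DataFrame:
    """Hard-assign classes and mark the minimal-change class as resilient.

    The resilient class minimises max_t |fitted ΔPHQ-9(t)| over the quarter
    grid, ties broken toward the largest mixing proportion. Returns a table
    (participant_id, class_id, resilient, max_responsibility).
    """
    curves = fit.fitted_curves()
    peaks = np.abs(curves).max(axis=1)
    order = sorted(range(fit.K), key=lambda k: (peaks[k], -fit.pi[k]))
    resilient_class = order[0]
    hard = fit.hard_assignments()
    return pd.DataFrame(
        {
            "participant_id": fit.participant_ids,
            "class_id": hard,
            "resilient": hard == resilient_class,
            "max_responsibility": fit.responsibilities.max(axis=1),
        }
    )
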
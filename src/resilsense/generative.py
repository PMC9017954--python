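"""Baseline-to-internship generative models of hourly feature distributions.

The prediction target is a participant's multivariate internship hourly
distribution B, generated from their baseline distribution A one hourly
point at a time. Eight model families are provided:

* ``MLP`` / ``P-MLP`` — multilayer-perceptron regression of the 5-vector of
  per-feature Cohen's d_s from the 5 baseline feature means (no generated
  distribution, d_s is predicted directly);
* ``GEN`` / ``P-GEN`` — a feedforward map from a baseline hourly point to an
  internship hourly point, trained with squared error on randomly paired
  within-participant (baseline, internship) hours;
* ``CGAN`` / ``F-CGAN`` / ``P-CGAN`` / ``FP-CGAN`` — conditional GANs whose
  generator maps (baseline point, noise) to an internship point and whose
  discriminator scores (baseline point, internship point) pairs, trained
  with the non-saturating adversarial loss on within-participant pairs
  re-sampled each epoch.

The multitask variants share a trunk network and split the output stage:
``F`` puts one head per feature, ``P`` routes each participant through the
head of their behaviour-shift cluster (clusters of the training
participants' d_s profiles, configuration chosen by silhouette score), and
``FP`` does both. At test time a participant's cluster is unknown; it is
matched by generating an internship distribution under each cluster head
and choosing the cluster whose predicted d_s best matches the d_s computed
against the participant's actual first-quarter data.

Networks are small fully-connected stacks (ReLU, Adam) implemented directly
on numpy arrays, which keeps the package dependency-light and the training
loops deterministic under a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .indicators import FEATURES, cohens_ds_from_samples

logger = logging.getLogger(__name__)

FAMILIES = ("MLP", "P-MLP", "GEN", "P-GEN", "CGAN", "F-CGAN", "P-CGAN", "FP-CGAN")


# --------------------------------------------------------------------------
# numpy neural-network primitives
# --------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


class _Seq:
    """Fully-connected stack with ReLU hidden activations, linear output."""

    def __init__(self, rng: np.random.Generator, sizes: list[int]):
        self.W = []
        self.b = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    @property
    def params(self):
        return self.W + self.b

    def forward(self, x: np.ndarray, relu_out: bool = False):
        acts = [x]
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ W + b
            if i < last or relu_out:
                z = _relu(z)
            acts.append(z)
        return acts

    def backward(self, acts, d_out, relu_out: bool = False):
        """Returns (d_input, grads aligned with .params)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        d = d_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last or relu_out:
                d = d * (acts[i + 1] > 0)
            gW[i] = acts[i].T @ d
            gb[i] = d.sum(axis=0)
            d = d @ self.W[i].T
        return d, gW + gb


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _MultiHeadNet:
    """Shared trunk + per-task output heads.

    ``cluster_keys`` routes rows (participant multitasking); ``per_feature``
    gives every head a single output column (feature multitasking). With
    neither, a single head emits the full output vector.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        d_in: int,
        d_out: int,
        trunk: tuple[int, ...],
        head_width: int,
        cluster_keys: tuple,
        per_feature: bool,
    ):
        self.d_out = d_out
        self.per_feature = per_feature
        self.cluster_keys = tuple(cluster_keys)
        self.trunk = _Seq(rng, [d_in, *trunk])
        self.heads: dict = {}
        for c in self.cluster_keys:
            if per_feature:
                for j in range(d_out):
                    self.heads[(c, j)] = _Seq(rng, [trunk[-1], head_width, 1])
            else:
                self.heads[(c, None)] = _Seq(rng, [trunk[-1], head_width, d_out])

    @property
    def params(self):
        ps = list(self.trunk.params)
        for key in sorted(self.heads, key=str):
            ps.extend(self.heads[key].params)
        return ps

    def forward(self, x: np.ndarray, clusters: np.ndarray | None):
        """Returns (output, cache). ``clusters`` is a per-row key array (or
        None when there is a single cluster key)."""
        t_acts = self.trunk.forward(x, relu_out=True)
        h = t_acts[-1]
        out = np.zeros((len(x), self.d_out))
        head_caches = {}
        if clusters is None:
            groups = {self.cluster_keys[0]: np.arange(len(x))}
        else:
            groups = {c: np.where(clusters == c)[0] for c in self.cluster_keys}
        for c, idx in groups.items():
            if len(idx) == 0:
                continue
            if self.per_feature:
                for j in range(self.d_out):
                    acts = self.heads[(c, j)].forward(h[idx])
                    out[idx, j] = acts[-1][:, 0]
                    head_caches[(c, j)] = (idx, acts)
            else:
                acts = self.heads[(c, None)].forward(h[idx])
                out[idx] = acts[-1]
                head_caches[(c, None)] = (idx, acts)
        return out, (t_acts, head_caches)

    def backward(self, cache, d_out):
        t_acts, head_caches = cache
        h = t_acts[-1]
        d_h = np.zeros_like(h)
        head_grads = {}
        for key, (idx, acts) in head_caches.items():
            if self.per_feature:
                d_local = d_out[idx, key[1]][:, None]
            else:
                d_local = d_out[idx]
            d_in, grads = self.heads[key].backward(acts, d_local)
            d_h[idx] += d_in
            head_grads[key] = grads
        d_x, trunk_grads = self.trunk.backward(t_acts, d_h, relu_out=True)
        all_grads = list(trunk_grads)
        for key in sorted(self.heads, key=str):
            all_grads.extend(head_grads.get(key) or [np.zeros_like(p) for p in self.heads[key].params])
        return d_x, all_grads


# --------------------------------------------------------------------------
# participant clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterModel:
    method: str
    n_pca_components: int | None
    k: int
    silhouette: float
    labels: pd.Series  # participant_id -> cluster label
    profile: pd.DataFrame  # per-cluster mean d_s by feature

    @property
    def cluster_sizes(self) -> dict:
        return self.labels.value_counts().to_dict()


def cluster_participants(
    ds_table: pd.DataFrame,
    k_range=range(2, 6),
    methods=("agglomerative", "kmeans"),
    seed: int = 0,
) -> ClusterModel:
    """Cluster training participants on their 5-dim Cohen's d_s profiles.

    The d_s columns are standardised first (features carry very different
    estimation noise — the daily-granularity mood d_s in particular — and
    PCA/k-means are scale-sensitive). The sweep covers dimensionality
    reduction (1..5 principal components and none) x clustering method
    (Ward-linkage agglomerative, k-means) x k, and keeps the configuration
    with the highest silhouette score computed on the representation used
    for clustering.
    """
    x = ds_table[list(FEATURES)].to_numpy(dtype=float)
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("identical d_s profiles: nothing to cluster")
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    pids = ds_table["participant_id"].to_numpy()
    best = None
    for n_pca in (None, 1, 2, 3, 4, 5):
        if n_pca is not None and n_pca > min(xs.shape):
            continue
        rep = xs if n_pca is None else PCA(n_components=n_pca, random_state=seed).fit_transform(xs)
        for method in methods:
            for k in k_range:
                if k >= len(rep):
                    continue
                if method == "agglomerative":
                    labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(rep)
                elif method == "kmeans":
                    labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(rep)
                else:
                    raise ValueError(f"unknown clustering method {method!r}")
                if len(np.unique(labels)) < 2:
                    continue
                score = silhouette_score(rep, labels)
                if best is None or score > best[0]:
                    best = (score, method, n_pca, k, labels)
    if best is None:
        raise ValueError("no clustering configuration produced >= 2 clusters")
    score, method, n_pca, k, labels = best
    # canonical label order: cluster 0 is the largest
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    profile = (
        pd.DataFrame(x, columns=FEATURES).assign(cluster=labels).groupby("cluster").mean()
    )
    return ClusterModel(
        method=method,
        n_pca_components=n_pca,
        k=k,
        silhouette=float(score),
        labels=pd.Series(labels, index=pids, name="cluster"),
        profile=profile,
    )


# --------------------------------------------------------------------------
# model specification and training
# --------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    family: str = "FP-CGAN"
    trunk: tuple[int, ...] = (64, 64)
    head_width: int = 32
    noise_dim: int = 8
    epochs: int = 90
    batch_size: int = 512
    lr_g: float = 5e-4
    lr_d: float = 4e-4
    lr_mlp: float = 1e-3
    pairs_per_participant: int = 44
    conditional_disc: bool = True
    identity_skip: bool = True
    #: weight of the per-cluster batch moment-matching stabiliser added to
    #: the generator objective (guards against variance collapse, which
    #: would directly corrupt generated-d_s scale)
    moment_weight: float = 200.0
    #: weight of the paired-sample reconstruction (squared error) term in
    #: the generator objective; anchors the conditional mean the way
    #: image-translation GANs pair an L1 term with the adversarial loss
    recon_weight: float = 20.0
    #: exponential-moving-average decay for the generator weights used at
    #: sampling time (0 disables); smooths adversarial oscillation
    ema_decay: float = 0.998
    #: adversarial restarts; the restart whose predicted d_s best fits the
    #: training participants (known clusters) is kept
    n_restarts: int = 4
    #: per-restart multipliers on (recon_weight, moment_weight): restarts
    #: explore different stabiliser regimes, and each feature keeps the
    #: regime that fits its training d_s best (features differ in which
    #: regime suits them — spiky zero-heavy durations want strong moment
    #: anchoring, smooth near-Gaussian features a light touch)
    restart_profiles: tuple = ((1.0, 1.0), (1.0, 0.1), (0.1, 0.1), (1.0, 0.3))
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")

    @property
    def uses_clusters(self) -> bool:
        return self.family.startswith(("P", "FP"))

    @property
    def per_feature(self) -> bool:
        return self.family.startswith(("F", "FP"))

    @property
    def is_gan(self) -> bool:
        return self.family.endswith("CGAN")

    @property
    def is_regressor(self) -> bool:
        return self.family.endswith("MLP")


@dataclass
class TrainedGenerator:
    spec: GeneratorSpec
    net: _MultiHeadNet = field(repr=False)
    norm_mu: np.ndarray
    norm_sd: np.ndarray
    ranges: np.ndarray  # (2, 5) raw-unit min/max seen in training
    cluster_sizes: dict
    training_log: pd.DataFrame = field(repr=False)
    train_mean_ds: pd.Series | None = None
    #: adversarial restarts kept for per-feature selection (GAN families);
    #: feature j is generated by members[feature_member[j]]
    members: list = field(default_factory=list, repr=False)
    feature_member: np.ndarray | None = None

    def save(self, json_path, blob_path) -> None:
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "spec": asdict(self.spec),
                    "cluster_sizes": {str(k): v for k, v in self.cluster_sizes.items()},
                },
                fh,
                indent=2,
            )
        np.savez(
            blob_path,
            norm_mu=self.norm_mu,
            norm_sd=self.norm_sd,
            ranges=self.ranges,
            **{f"param_{i}": p for i, p in enumerate(self.net.params)},
        )


def _split_blocks(hourly: pd.DataFrame) -> dict:
    """pid -> dict(A=baseline points, B=internship points) as float arrays."""
    blocks = {}
    for pid, grp in hourly.groupby("participant_id", sort=True):
        a = grp.loc[grp["period"] == "BL", list(FEATURES)].to_numpy(dtype=float)
        b = grp.loc[grp["period"] != "BL", list(FEATURES)].to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2:
            blocks[pid] = {"A": a, "B": b}
    return blocks


def actual_ds_table(hourly: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-feature Cohen's d_s (baseline vs internship)."""
    rows = []
    for pid, blk in _split_blocks(hourly).items():
        row = {"participant_id": pid}
        for j, feat in enumerate(FEATURES):
            row[feat] = cohens_ds_from_samples(blk["A"][:, j], blk["B"][:, j])
        rows.append(row)
    return pd.DataFrame(rows)


def _bce_with_logits_grad(logits: np.ndarray, target: float):
    """Mean binary cross-entropy on logits; returns (loss, d_logits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = -np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps))
    grad = (p - target) / len(logits)
    return float(loss), grad


def train_generator(
    spec: GeneratorSpec,
    hourly: pd.DataFrame,
    clusters: ClusterModel | None = None,
) -> TrainedGenerator:
    """Train one model family on the training participants' hourly data.

    ``hourly`` carries participant_id, period and the five features for the
    training split only. P-families require ``clusters`` covering every
    training participant. Returns the trained model with its per-epoch loss
    log; fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = _split_blocks(hourly)
    pids = sorted(blocks)
    if not pids:
        raise ValueError("no training participants with both periods")

    if spec.uses_clusters:
        if clusters is None:
            raise ValueError(f"{spec.family} requires a ClusterModel")
        missing = [p for p in pids if p not in clusters.labels.index]
        if missing:
            raise ValueError(f"no cluster for participants {missing[:5]}")
        pid_cluster = {p: int(clusters.labels[p]) for p in pids}
        cluster_keys = tuple(sorted(set(pid_cluster.values())))
        cluster_sizes = pd.Series(pid_cluster).value_counts().to_dict()
    else:
        pid_cluster = {p: 0 for p in pids}
        cluster_keys = (0,)
        cluster_sizes = {0: len(pids)}

    # normalisation statistics from pooled training hours
    pooled = np.vstack([np.vstack([b["A"], b["B"]]) for b in blocks.values()])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd[sd == 0] = 1.0
    ranges = np.vstack([pooled.min(axis=0), pooled.max(axis=0)])

    m = len(FEATURES)
    if spec.is_regressor:
        net = _MultiHeadNet(
            rng, d_in=m, d_out=m, trunk=spec.trunk, head_width=spec.head_width,
            cluster_keys=cluster_keys, per_feature=spec.per_feature,
        )
        gen = TrainedGenerator(
            spec=spec, net=net, norm_mu=mu, norm_sd=sd, ranges=ranges,
            cluster_sizes=cluster_sizes, training_log=None,
        )
        gen.training_log = _train_mlp(spec, gen, blocks, pid_cluster, rng)
        return gen

    d_in = m + (spec.noise_dim if spec.is_gan else 0)

    def build_and_train(restart_rng, train_spec=None):
        train_spec = train_spec or spec
        net = _MultiHeadNet(
            restart_rng, d_in=d_in, d_out=m, trunk=train_spec.trunk,
            head_width=train_spec.head_width, cluster_keys=cluster_keys,
            per_feature=train_spec.per_feature,
        )
        g = TrainedGenerator(
            spec=train_spec, net=net, norm_mu=mu, norm_sd=sd, ranges=ranges,
            cluster_sizes=cluster_sizes, training_log=None,
        )
        if train_spec.is_gan:
            g.training_log = _train_cgan(
                train_spec, g, blocks, pid_cluster, cluster_keys, restart_rng
            )
        else:
            g.training_log = _train_gen(train_spec, g, blocks, pid_cluster, restart_rng)
        return g

    if not spec.is_gan or spec.n_restarts <= 1:
        return build_and_train(rng)

    # adversarial training is restart-sensitive, and individual output heads
    # can converge poorly in an otherwise good restart. Train n_restarts
    # models — each under its profile's stabiliser regime — and keep, per
    # feature, the two restarts whose training d_s fit is best.
    import dataclasses as _dc

    gens = []
    scores = []
    for restart in range(spec.n_restarts):
        rw_mult, mw_mult = spec.restart_profiles[restart % len(spec.restart_profiles)]
        sub = _dc.replace(
            spec,
            recon_weight=spec.recon_weight * rw_mult,
            moment_weight=spec.moment_weight * mw_mult,
        )
        g = build_and_train(np.random.default_rng([spec.seed, restart]), sub)
        g.spec = spec  # the nominal spec identifies the model family
        score = _train_ds_error(g, blocks, pid_cluster)
        logger.info(
            "%s restart %d: per-feature training d_s score %s",
            spec.family, restart, np.round(score, 3),
        )
        gens.append(g)
        scores.append(score)
    scores = np.asarray(scores)  # (n_restarts, n_features)
    main = gens[int(scores.mean(axis=1).argmin())]
    main.members = [g.net for g in gens]
    # per feature, sample only from the two best-fitting restarts; every
    # downstream indicator is a per-feature marginal, so feature columns may
    # be drawn from different restarts
    main.feature_member = np.argsort(scores, axis=0)[:2, :]
    return main


def _train_ds_error(
    gen: "TrainedGenerator", blocks: dict, pid_cluster: dict, max_participants: int = 150
) -> float:
    """Mean squared error between predicted and actual d_s over (a subsample
    of) the training participants, using their known cluster labels."""
    pids = sorted(blocks)
    if len(pids) > max_participants:
        step = len(pids) / max_participants
        pids = [pids[int(i * step)] for i in range(max_participants)]
    actuals, preds = [], []
    for pid in pids:
        blk = blocks[pid]
        actuals.append(
            [
                cohens_ds_from_samples(blk["A"][:, j], blk["B"][:, j])
                for j in range(len(FEATURES))
            ]
        )
        preds.append(
            predicted_ds(
                gen, blk["A"], draws_per_point=2, noise_seed=1234,
                cluster_id=pid_cluster[pid] if gen.spec.uses_clusters else None,
            )
        )
    actual = np.asarray(actuals)
    pred = np.asarray(preds)
    # per-feature score: variance-normalised MSE (calibration) minus the
    # training skipped correlation (agreement after robust outlier removal,
    # which plain MSE cannot see); lower is better
    from .evaluation import skipped_correlation

    var = actual.var(axis=0)
    var[var == 0] = 1.0
    nmse = ((pred - actual) ** 2).mean(axis=0) / var
    score = np.array(nmse, dtype=float)
    for j in range(actual.shape[1]):
        try:
            score[j] -= skipped_correlation(actual[:, j], pred[:, j]).r
        except ValueError:
            score[j] += 1.0  # degenerate predictions are penalised
    return score


def _epoch_pairs(spec, blocks, pid_cluster, rng, balance: bool = False):
    """Random within-participant (baseline, internship) hour pairs,
    re-sampled every epoch.

    With ``balance`` (multitask cluster routing), minority-cluster
    participants contribute proportionally more pairs so every cluster head
    receives a comparable gradient budget per epoch."""
    weights = {}
    if balance:
        sizes = pd.Series(pid_cluster).value_counts()
        target = sizes.max()
        weights = {c: min(target / n, 4.0) for c, n in sizes.items()}
    xs, ys, cs = [], [], []
    for pid, blk in blocks.items():
        mult = weights.get(pid_cluster[pid], 1.0)
        n_pairs = min(
            int(round(spec.pairs_per_participant * mult)), len(blk["A"]), len(blk["B"])
        )
        ia = rng.integers(0, len(blk["A"]), size=n_pairs)
        ib = rng.integers(0, len(blk["B"]), size=n_pairs)
        xs.append(blk["A"][ia])
        ys.append(blk["B"][ib])
        cs.append(np.full(n_pairs, pid_cluster[pid]))
    x = np.vstack(xs)
    y = np.vstack(ys)
    c = np.concatenate(cs)
    perm = rng.permutation(len(x))
    return x[perm], y[perm], c[perm]


def _train_gen(spec, gen, blocks, pid_cluster, rng) -> pd.DataFrame:
    """Direct feedforward map (no adversary): MSE on random pairs."""
    opt = _Adam(gen.net.params, lr=2e-3)  # plain regression trains faster
    log = []
    for epoch in range(spec.epochs):
        x, y, c = _epoch_pairs(spec, blocks, pid_cluster, rng, balance=spec.uses_clusters)
        xn = (x - gen.norm_mu) / gen.norm_sd
        yn = (y - gen.norm_mu) / gen.norm_sd
        total = 0.0
        for lo in range(0, len(xn), spec.batch_size):
            xb = xn[lo : lo + spec.batch_size]
            yb = yn[lo : lo + spec.batch_size]
            cb = c[lo : lo + spec.batch_size]
            out, cache = gen.net.forward(xb, cb if spec.uses_clusters else None)
            if spec.identity_skip:
                out = out + xb
            diff = out - yb
            loss = float((diff**2).mean())
            _, grads = gen.net.backward(cache, 2 * diff / diff.size)
            opt.step(grads)
            total += loss * len(xb)
        log.append({"epoch": epoch, "loss": total / len(xn)})
    return pd.DataFrame(log)


def _train_mlp(spec, gen, blocks, pid_cluster, rng) -> pd.DataFrame:
    """Regress per-feature d_s on the baseline feature means."""
    pids = sorted(blocks)
    x = np.array([blocks[p]["A"].mean(axis=0) for p in pids])
    y = np.array(
        [
            [
                cohens_ds_from_samples(blocks[p]["A"][:, j], blocks[p]["B"][:, j])
                for j in range(len(FEATURES))
            ]
            for p in pids
        ]
    )
    c = np.array([pid_cluster[p] for p in pids])
    xn = (x - gen.norm_mu) / gen.norm_sd
    opt = _Adam(gen.net.params, lr=spec.lr_mlp)
    log = []
    epochs = max(spec.epochs, 300)  # tiny data, cheap epochs
    for epoch in range(epochs):
        perm = rng.permutation(len(xn))
        total = 0.0
        for lo in range(0, len(xn), spec.batch_size):
            idx = perm[lo : lo + spec.batch_size]
            out, cache = gen.net.forward(xn[idx], c[idx] if spec.uses_clusters else None)
            diff = out - y[idx]
            loss = float((diff**2).mean())
            _, grads = gen.net.backward(cache, 2 * diff / diff.size)
            opt.step(grads)
            total += loss * len(idx)
        log.append({"epoch": epoch, "loss": total / len(xn)})
    return pd.DataFrame(log)


def _train_cgan(spec, gen, blocks, pid_cluster, cluster_keys, rng) -> pd.DataFrame:
    """Non-saturating conditional GAN on within-participant hour pairs."""
    m = len(FEATURES)
    n_c = len(cluster_keys)
    d_in = (m if spec.conditional_disc else 0) + m + (n_c if n_c > 1 else 0)
    disc = _Seq(rng, [d_in, *spec.trunk, 1])
    opt_g = _Adam(gen.net.params, lr=spec.lr_g)
    opt_d = _Adam(disc.params, lr=spec.lr_d)
    onehot = np.eye(n_c)
    ema = [p.copy() for p in gen.net.params] if spec.ema_decay > 0 else None

    def disc_input(xb, yb, cb):
        parts = []
        if spec.conditional_disc:
            parts.append(xb)
        parts.append(yb)
        if n_c > 1:
            parts.append(onehot[cb])
        return np.concatenate(parts, axis=1)

    log = []
    for epoch in range(spec.epochs):
        x, y, c = _epoch_pairs(spec, blocks, pid_cluster, rng, balance=spec.uses_clusters)
        xn = (x - gen.norm_mu) / gen.norm_sd
        yn = (y - gen.norm_mu) / gen.norm_sd
        # stable epoch-level real moment targets per cluster
        moment_targets = {
            ck: (yn[c == ck].mean(axis=0), yn[c == ck].std(axis=0))
            for ck in np.unique(c)
        }
        d_loss_tot = g_loss_tot = 0.0
        gen_sd_acc = real_sd_acc = None
        for lo in range(0, len(xn), spec.batch_size):
            xb = xn[lo : lo + spec.batch_size]
            yb = yn[lo : lo + spec.batch_size]
            cb = c[lo : lo + spec.batch_size]
            nb = len(xb)
            z = rng.normal(size=(nb, spec.noise_dim))
            g_in = np.concatenate([xb, z], axis=1)
            fake, g_cache = gen.net.forward(g_in, cb if spec.uses_clusters else None)
            if spec.identity_skip:
                fake = fake + xb

            # --- discriminator step ---
            real_acts = disc.forward(disc_input(xb, yb, cb))
            loss_r, grad_r = _bce_with_logits_grad(real_acts[-1][:, 0], 1.0)
            _, g_real = disc.backward(real_acts, grad_r[:, None])
            fake_acts = disc.forward(disc_input(xb, fake, cb))
            loss_f, grad_f = _bce_with_logits_grad(fake_acts[-1][:, 0], 0.0)
            _, g_fake = disc.backward(fake_acts, grad_f[:, None])
            opt_d.step([a + b for a, b in zip(g_real, g_fake)])
            d_loss_tot += (loss_r + loss_f) * nb

            # --- generator step (non-saturating) ---
            z = rng.normal(size=(nb, spec.noise_dim))
            g_in = np.concatenate([xb, z], axis=1)
            fake, g_cache = gen.net.forward(g_in, cb if spec.uses_clusters else None)
            if spec.identity_skip:
                fake = fake + xb
            fake_acts = disc.forward(disc_input(xb, fake, cb))
            loss_g, grad_g = _bce_with_logits_grad(fake_acts[-1][:, 0], 1.0)
            d_disc_in, _ = disc.backward(fake_acts, grad_g[:, None])
            off = m if spec.conditional_disc else 0
            d_fake = d_disc_in[:, off : off + m]
            if spec.recon_weight > 0:
                d_fake = d_fake + spec.recon_weight * 2 * (fake - yb) / fake.size
            if spec.moment_weight > 0:
                # per-cluster batch moment matching (first + second moment of
                # the generated marginal against the real one)
                for ck in np.unique(cb):
                    idx = np.where(cb == ck)[0]
                    if len(idx) < 4:
                        continue
                    fk = fake[idx]
                    mr, sr = moment_targets[ck]
                    mf, sf = fk.mean(axis=0), fk.std(axis=0)
                    k_n = len(idx)
                    d_mm = 2 * (mf - mr) / (m * k_n)
                    sf_safe = np.maximum(sf, 1e-8)
                    d_sd = (2 * (sf - sr) / m)[None, :] * (fk - mf) / (k_n * sf_safe)
                    d_fake[idx] += spec.moment_weight * (d_mm[None, :] + d_sd)
            _, grads_g = gen.net.backward(g_cache, d_fake)
            opt_g.step(grads_g)
            if ema is not None:
                d = spec.ema_decay
                for e, p in zip(ema, gen.net.params):
                    e *= d
                    e += (1 - d) * p
            g_loss_tot += loss_g * nb

            gs = fake.std(axis=0)
            rs = yb.std(axis=0)
            gen_sd_acc = gs if gen_sd_acc is None else gen_sd_acc + gs
            real_sd_acc = rs if real_sd_acc is None else real_sd_acc + rs

        n_batches = int(np.ceil(len(xn) / spec.batch_size))
        sd_ratio = gen_sd_acc / np.maximum(real_sd_acc, 1e-9)
        if np.any(sd_ratio < 0.5):
            logger.warning(
                "epoch %d: generated/actual SD ratio below 0.5 for %s "
                "(possible mode collapse)",
                epoch,
                [f for f, r in zip(FEATURES, sd_ratio) if r < 0.5],
            )
        log.append(
            {
                "epoch": epoch,
                "d_loss": d_loss_tot / (2 * len(xn)),
                "g_loss": g_loss_tot / len(xn),
                "min_sd_ratio": float(sd_ratio.min()),
            }
        )
    if ema is not None:
        for p, e in zip(gen.net.params, ema):
            p[...] = e
    return pd.DataFrame(log)


# --------------------------------------------------------------------------
# generation, cluster matching, indicator prediction
# --------------------------------------------------------------------------

def generate_internship(
    gen: TrainedGenerator,
    baseline_points: np.ndarray,
    draws_per_point: int = 1,
    noise_seed: int = 0,
    cluster_id: int | None = None,
    member: int | None = None,
) -> np.ndarray:
    """Generate an internship distribution B' from raw baseline points.

    Emits ``draws_per_point`` generated points per baseline point,
    de-normalised to raw units and clipped to the feature ranges observed in
    training. P-families require ``cluster_id``. When the model kept several
    adversarial restarts, the default output pools draws from each feature's
    selected restarts; ``member`` restricts generation to one restart.
    """
    if gen.spec.is_regressor:
        raise ValueError("MLP families predict d_s directly, not distributions")
    x = np.asarray(baseline_points, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(FEATURES):
        raise ValueError("baseline points must be (n, 5) in the canonical feature order")
    if gen.spec.uses_clusters and cluster_id is None:
        raise ValueError(f"{gen.spec.family} needs a cluster_id")
    rng = np.random.default_rng(noise_seed)
    xn = (x - gen.norm_mu) / gen.norm_sd
    xn = np.repeat(xn, draws_per_point, axis=0)
    if gen.spec.is_gan:
        z = rng.normal(size=(len(xn), gen.spec.noise_dim))
        net_in = np.concatenate([xn, z], axis=1)
    else:
        net_in = xn
    routing = (
        np.full(len(xn), int(cluster_id)) if gen.spec.uses_clusters else None
    )
    if gen.members and member is not None:
        out, _ = gen.members[int(member)].forward(net_in, routing)
    elif gen.members:
        # restart mixture: kept restarts contribute draws, so the generated
        # distribution (and hence d_s) averages over restarts; per feature,
        # only its selected restarts contribute (all downstream indicator
        # statistics are per-feature marginals)
        outs = []
        for i, net in enumerate(gen.members):
            if gen.spec.is_gan:
                z = rng.normal(size=(len(xn), gen.spec.noise_dim))
                net_in = np.concatenate([xn, z], axis=1)
            m_out, _ = net.forward(net_in, routing)
            outs.append(m_out)
        if gen.feature_member is not None:
            k = gen.feature_member.shape[0]
            out = np.zeros((k * len(xn), len(FEATURES)))
            for j in range(len(FEATURES)):
                for slot in range(k):
                    midx = int(gen.feature_member[slot, j])
                    out[slot * len(xn) : (slot + 1) * len(xn), j] = outs[midx][:, j]
            xn = np.tile(xn, (k, 1))
        else:
            out = np.vstack(outs)
            xn = np.tile(xn, (len(gen.members), 1))
    else:
        out, _ = gen.net.forward(net_in, routing)
    if gen.spec.identity_skip:
        out = out + xn
    raw = out * gen.norm_sd + gen.norm_mu
    return np.clip(raw, gen.ranges[0], gen.ranges[1])


def predicted_ds(
    gen: TrainedGenerator,
    baseline_points: np.ndarray,
    draws_per_point: int = 1,
    noise_seed: int = 0,
    cluster_id: int | None = None,
) -> np.ndarray:
    """Per-feature Cohen's d_s between actual A and generated B'.

    With several kept restarts, each feature's d_s is the average of the
    d_s computed under that feature's selected restarts (a restart-ensemble
    estimate that does not inflate the pooled SD the way pooling draws
    across restarts would)."""
    x = np.asarray(baseline_points, dtype=float)

    def ds_of(b_prime):
        return np.array(
            [cohens_ds_from_samples(x[:, j], b_prime[:, j]) for j in range(len(FEATURES))]
        )

    if not gen.members:
        return ds_of(
            generate_internship(gen, x, draws_per_point, noise_seed, cluster_id)
        )
    member_ids = (
        np.unique(gen.feature_member)
        if gen.feature_member is not None
        else np.arange(len(gen.members))
    )
    member_ds = {
        int(i): ds_of(
            generate_internship(
                gen, x, draws_per_point, noise_seed + 31 * int(i), cluster_id, member=int(i)
            )
        )
        for i in member_ids
    }
    if gen.feature_member is None:
        return np.mean([member_ds[int(i)] for i in member_ids], axis=0)
    out = np.zeros(len(FEATURES))
    for j in range(len(FEATURES)):
        picks = [member_ds[int(m)][j] for m in gen.feature_member[:, j]]
        out[j] = float(np.mean(picks))
    return out


def match_cluster(
    gen: TrainedGenerator,
    baseline_points: np.ndarray,
    q1_points: np.ndarray,
    noise_seed: int = 0,
) -> int:
    """Pick the cluster head whose generated d_s best matches actual Q1 d_s.

    The error for a cluster is the mean over features of
    |d_s(A, B'_cluster) - d_s(A, Q1)|; ties break toward the larger
    training cluster. Raises when no Q1 data is available (callers should
    fall back to the largest training cluster).
    """
    q1 = np.asarray(q1_points, dtype=float)
    if q1.ndim != 2 or len(q1) < 2:
        raise ValueError("no Q1 data: fall back to the larger training cluster")
    x = np.asarray(baseline_points, dtype=float)
    target = np.array(
        [cohens_ds_from_samples(x[:, j], q1[:, j]) for j in range(len(FEATURES))]
    )
    errors = {}
    for c in sorted(gen.cluster_sizes):
        ds_c = predicted_ds(gen, x, noise_seed=noise_seed, cluster_id=c)
        errors[c] = float(np.mean(np.abs(ds_c - target)))
    # ties go to the larger training cluster
    return min(errors, key=lambda c: (errors[c], -gen.cluster_sizes[c]))


def largest_cluster(gen: TrainedGenerator) -> int:
    return max(gen.cluster_sizes, key=lambda c: (gen.cluster_sizes[c], -c))


def assign_clusters(
    gen: TrainedGenerator, hourly_test: pd.DataFrame, noise_seed: int = 0
) -> dict:
    """Q1-matched cluster per test participant (largest cluster when Q1 is
    missing). Non-P families map everyone to the single head."""
    out = {}
    for pid, grp in hourly_test.groupby("participant_id", sort=True):
        if not gen.spec.uses_clusters:
            out[pid] = None
            continue
        a = grp.loc[grp["period"] == "BL", list(FEATURES)].to_numpy(dtype=float)
        q1 = grp.loc[grp["period"] == "Q1", list(FEATURES)].to_numpy(dtype=float)
        try:
            out[pid] = match_cluster(gen, a, q1, noise_seed=noise_seed)
        except ValueError:
            out[pid] = largest_cluster(gen)
    return out


def predict_ds_table(
    gen: TrainedGenerator,
    hourly_test: pd.DataFrame,
    noise_seed: int = 0,
    draws_per_point: int = 1,
    cluster_assignment: dict | None = None,
) -> pd.DataFrame:
    """Predicted per-participant d_s for each feature (one row per
    participant). Uses Q1 cluster matching for P-families unless an explicit
    assignment is provided."""
    if cluster_assignment is None:
        cluster_assignment = assign_clusters(gen, hourly_test, noise_seed)
    rows = []
    for pid, grp in hourly_test.groupby("participant_id", sort=True):
        a = grp.loc[grp["period"] == "BL", list(FEATURES)].to_numpy(dtype=float)
        if len(a) < 2:
            continue
        row = {"participant_id": pid}
        if gen.spec.is_regressor:
            xn = (a.mean(axis=0) - gen.norm_mu) / gen.norm_sd
            routing = (
                np.array([cluster_assignment[pid]]) if gen.spec.uses_clusters else None
            )
            out, _ = gen.net.forward(xn[None, :], routing)
            vals = out[0]
        else:
            vals = predicted_ds(
                gen, a, draws_per_point, noise_seed, cluster_assignment[pid]
            )
        for feat, v in zip(FEATURES, vals):
            row[feat] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def predict_indicators(
    gen: TrainedGenerator,
    hourly: pd.DataFrame,
    noise_seed: int = 0,
    draws_per_point: int = 1,
    cluster_assignment: dict | None = None,
) -> pd.DataFrame:
    """Predicted indicator table: INTERN-side entries from generated B',
    BL-side entries from actual A (those are observed, not predictions).
    Schema matches :func:`resilsense.indicators.indicator_table`."""
    from .indicators import PeriodDistribution, build_indicator_vector, indicator_columns

    if gen.spec.is_regressor:
        raise ValueError("MLP families do not generate distributions")
    if cluster_assignment is None:
        cluster_assignment = assign_clusters(gen, hourly, noise_seed)
    rows = []
    for pid, grp in hourly.groupby("participant_id", sort=True):
        a = grp.loc[grp["period"] == "BL", list(FEATURES)]
        if len(a) < 2:
            continue
        b_prime = generate_internship(
            gen, a.to_numpy(dtype=float), draws_per_point, noise_seed,
            cluster_assignment[pid],
        )
        vec = build_indicator_vector(
            PeriodDistribution(str(pid), "A", a),
            PeriodDistribution(str(pid), "B", pd.DataFrame(b_prime, columns=FEATURES)),
        )
        vec["participant_id"] = pid
        rows.append(vec)
    return pd.DataFrame(rows, columns=["participant_id"] + indicator_columns())
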
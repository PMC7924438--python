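"""Cluster-based undersampling combined with SMOTE (the CluSMOTE method).

The procedure balances a two-class dataset in five steps:

1. separate the positive (minority) and negative (majority) classes;
2. cluster the majority class with HDBSCAN, which extracts flat clusters
   by density stability and may leave points unassigned (noise);
3. allocate to each cluster Ci a sampling quota proportional to its size,

       Size_Ci = r * MI * M_ci / MA

   where MI is the minority count, MA the majority count, M_ci the size
   of cluster Ci and r the desired majority-to-minority ratio after
   undersampling (r = 2 retains twice as many negatives as positives);
4. draw each cluster's quota uniformly at random without replacement and
   recombine with the minority class;
5. oversample the minority class with SMOTE until the classes balance.

With r = 1 only clustering and undersampling apply — no synthetic points
are created.  Quotas are integerized by largest-remainder (Hamilton)
rounding so they sum exactly to min(round(r*MI), MA); a quota can never
exceed its cluster, with any excess redistributed proportionally among
clusters that still have headroom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import HDBSCAN
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .dataset import SYNTHETIC, LabeledDataset

logger = logging.getLogger(__name__)

NOISE = -1  # cluster id reserved for points HDBSCAN leaves unassigned

STRATEGIES = ("none", "smote_only", "cluster_only", "clusmote")


@dataclass(frozen=True)
class ResamplerConfig:
    r: float = 2.0
    min_cluster_size: int = 5
    smote_k: int = 5
    include_noise: bool = True
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclass
class ClusterModel:
    """Majority-class cluster assignment; ``NOISE`` is a reserved id."""

    labels: np.ndarray  # per-majority-row integer cluster id
    cluster_sizes: dict[int, int]
    n_clusters: int  # non-noise clusters

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "ClusterModel":
        labels = np.asarray(labels, dtype=int)
        ids, counts = np.unique(labels, return_counts=True)
        sizes = dict(zip(ids.tolist(), counts.tolist()))
        return cls(labels=labels, cluster_sizes=sizes,
                   n_clusters=sum(1 for i in sizes if i != NOISE))


@dataclass
class SamplingPlan:
    """Integer per-cluster quotas summing exactly to ``target_total``.

    ``raw_quotas`` keeps the pre-rounding proportional values
    r * MI * M_ci / MA for bookkeeping.
    """

    r: float
    quotas: dict[int, int]
    target_total: int
    raw_quotas: dict[int, float] | None = None


def split_by_class(ds: LabeledDataset) -> tuple[LabeledDataset, LabeledDataset]:
    """Separate the positive and negative classes.

    Returns (minority, majority).  If the labeled-positive class is in
    fact the larger one, the roles are swapped with a warning so that
    the first element is always the minority.
    """
    pos_idx = np.flatnonzero(ds.y == 1)
    neg_idx = np.flatnonzero(ds.y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    if len(pos_idx) > len(neg_idx):
        logger.warning(
            "positive class (%d) outnumbers negative (%d); swapping "
            "minority/majority roles", len(pos_idx), len(neg_idx))
        pos_idx, neg_idx = neg_idx, pos_idx
    return ds.subset(pos_idx), ds.subset(neg_idx)


def cluster_majority(majority: LabeledDataset,
                     cfg: ResamplerConfig) -> ClusterModel:
    """Density-cluster the majority class (HDBSCAN, stability-based).

    Deterministic given data and config.  Points may be labeled noise.
    If the class is smaller than ``min_cluster_size`` the whole class is
    returned as a single cluster.
    """
    cfg.validate()
    X = majority.X
    if len(X) < cfg.min_cluster_size:
        logger.warning("majority class (%d rows) smaller than "
                       "min_cluster_size; using a single cluster", len(X))
        return ClusterModel.from_labels(np.zeros(len(X), dtype=int))
    if cfg.standardize:
        scale = X.std(axis=0)
        if np.all(scale == 0):  # all points identical
            return ClusterModel.from_labels(np.zeros(len(X), dtype=int))
        X = StandardScaler().fit_transform(X)
    labels = HDBSCAN(min_cluster_size=cfg.min_cluster_size,
                     copy=True).fit_predict(X)
    if (labels == NOISE).all():
        logger.warning("density clustering found no structure (all noise); "
                       "falling back to one cluster = simple random "
                       "undersampling")
        labels = np.zeros(len(X), dtype=int)
    return ClusterModel.from_labels(labels)


def allocate_quotas(model: ClusterModel, MI: int, MA: int,
                    r: float) -> SamplingPlan:
    """Proportional per-cluster quotas with exact total conservation.

    Raw quota r*MI*M_ci/MA per cluster, scaled so totals hit
    target_total = min(round(r*MI), MA); quotas capped at cluster size
    with excess redistributed proportionally (water-filling); then
    largest-remainder rounding, ties broken by ascending cluster id.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    if MI < 1 or MA < 1:
        raise ValueError("MI and MA must be >= 1")
    target = int(round(r * MI))
    if target > MA:
        logger.warning("r*MI = %d exceeds majority size %d; clamping",
                       target, MA)
        target = MA
    ids = sorted(model.cluster_sizes)
    sizes = np.array([model.cluster_sizes[i] for i in ids], dtype=float)
    capacity = int(sizes.sum())
    if target > capacity:  # e.g. noise excluded from the model
        logger.warning("target %d exceeds cluster capacity %d; clamping",
                       target, capacity)
        target = capacity

    # water-filling: proportional shares capped at cluster size
    alloc = np.zeros(len(ids))
    active = np.ones(len(ids), dtype=bool)
    remaining = float(target)
    while remaining > 1e-9 and active.any():
        share = remaining * sizes[active] / sizes[active].sum()
        alloc_active = alloc[active] + share
        over = alloc_active > sizes[active]
        alloc[active] = np.minimum(alloc_active, sizes[active])
        remaining = float(np.maximum(alloc_active - sizes[active], 0).sum())
        if not over.any():
            break
        newly_capped = np.flatnonzero(active)[over]
        active[newly_capped] = False

    # largest-remainder integerization under the same caps
    floors = np.floor(alloc + 1e-9).astype(int)
    leftover = target - int(floors.sum())
    frac = alloc - floors
    # ties broken by ascending cluster id: stable sort on -frac
    order = np.argsort(-frac, kind="stable")
    quotas = floors.copy()
    for j in order:
        if leftover == 0:
            break
        if quotas[j] < sizes[j]:
            quotas[j] += 1
            leftover -= 1
    if leftover > 0:  # remaining headroom anywhere
        for j in range(len(ids)):
            while leftover > 0 and quotas[j] < sizes[j]:
                quotas[j] += 1
                leftover -= 1
    raw = {i: r * MI * model.cluster_sizes[i] / MA for i in ids}
    return SamplingPlan(r=r, quotas=dict(zip(ids, quotas.tolist())),
                        target_total=target, raw_quotas=raw)


def draw_cluster_samples(majority: LabeledDataset, model: ClusterModel,
                         plan: SamplingPlan, seed: int) -> LabeledDataset:
    """Draw each cluster's quota uniformly without replacement."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for cid in sorted(plan.quotas):
        quota = plan.quotas[cid]
        members = np.flatnonzero(model.labels == cid)
        if quota > len(members):
            raise RuntimeError(
                f"quota {quota} exceeds cluster {cid} size {len(members)}")
        if quota:
            chosen.append(rng.choice(members, size=quota, replace=False))
    idx = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return majority.subset(idx)


def smote(minority_X: np.ndarray, n_synthetic: int, k: int,
          seed: int) -> np.ndarray:
    """Synthetic minority oversampling by nearest-neighbor interpolation.

    Each synthetic point is x + u * (x_nn - x) with x a minority row,
    x_nn one of its k Euclidean nearest minority neighbors, and
    u ~ Uniform(0, 1).
    """
    minority_X = np.asarray(minority_X, dtype=float)
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if n_synthetic == 0:
        return np.empty((0, minority_X.shape[1]))
    n = len(minority_X)
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority_X)
    neighbors = nn.kneighbors(minority_X, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n, size=n_synthetic)
    pick = rng.integers(0, k, size=n_synthetic)
    u = rng.uniform(size=n_synthetic)
    x = minority_X[base]
    x_nn = minority_X[neighbors[base, pick]]
    return x + u[:, None] * (x_nn - x)


def clusmote(ds: LabeledDataset, cfg: ResamplerConfig) -> LabeledDataset:
    """Full hybrid resampling: cluster-undersample negatives, SMOTE positives.

    The output holds all MI original minority rows, target_total =
    min(round(r*MI), MA) sampled majority rows, and target_total - MI
    synthetic minority rows, so the classes balance exactly (for r >= 1).
    Synthetic rows carry the ``synthetic`` provenance tag.
    """
    cfg.validate()
    minority, majority = split_by_class(ds)
    MI, MA = len(minority), len(majority)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2) % (2 ** 31)

    model = cluster_majority(majority, cfg)
    if not cfg.include_noise and model.n_clusters > 0:
        keep = {i: s for i, s in model.cluster_sizes.items() if i != NOISE}
        model = ClusterModel(labels=model.labels, cluster_sizes=keep,
                             n_clusters=model.n_clusters)
    plan = allocate_quotas(model, MI, MA, cfg.r)
    sampled_maj = draw_cluster_samples(majority, model, plan, int(seeds[0]))

    n_syn = max(0, plan.target_total - MI)
    X_syn = smote(minority.X, n_syn, cfg.smote_k, int(seeds[1])) \
        if n_syn else np.empty((0, ds.n_features))

    X = np.vstack([minority.X, X_syn, sampled_maj.X])
    y = np.concatenate([np.ones(MI + n_syn, dtype=int),
                        np.zeros(len(sampled_maj), dtype=int)])
    prov = np.concatenate([minority.provenance,
                           np.full(n_syn, SYNTHETIC, dtype=object),
                           sampled_maj.provenance])
    group = None
    if ds.group is not None:
        # synthetic rows inherit no group; tag with the mode of minority groups
        fill = minority.group[0]
        group = np.concatenate([minority.group,
                                np.full(n_syn, fill, dtype=minority.group.dtype),
                                sampled_maj.group])
    return LabeledDataset(X=X, y=y, group=group, provenance=prov,
                          feature_names=list(ds.feature_names))


def resample(ds: LabeledDataset, strategy: str,
             cfg: ResamplerConfig) -> LabeledDataset:
    """Dispatch over the four study strategies.

    ``none`` is the identity; ``smote_only`` oversamples the minority up
    to the majority count; ``cluster_only`` is clusmote with r = 1 (pure
    cluster-based undersampling); ``clusmote`` is the full hybrid.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "none":
        return ds
    if strategy == "cluster_only":
        return clusmote(ds, ResamplerConfig(
            r=1.0, min_cluster_size=cfg.min_cluster_size,
            smote_k=cfg.smote_k, include_noise=cfg.include_noise,
            standardize=cfg.standardize, seed=cfg.seed))
    if strategy == "clusmote":
        return clusmote(ds, cfg)
    # smote_only
    cfg.validate()
    minority, majority = split_by_class(ds)
    n_syn = len(majority) - len(minority)
    X_syn = smote(minority.X, n_syn, cfg.smote_k, cfg.seed)
    X = np.vstack([minority.X, X_syn, majority.X])
    y = np.concatenate([np.ones(len(minority) + n_syn, dtype=int),
                        np.zeros(len(majority), dtype=int)])
    prov = np.concatenate([minority.provenance,
                           np.full(n_syn, SYNTHETIC, dtype=object),
                           majority.provenance])
    group = None
    if ds.group is not None:
        fill = minority.group[0]
        group = np.concatenate([minority.group,
                                np.full(n_syn, fill, dtype=minority.group.dtype),
                                majority.group])
    return LabeledDataset(X=X, y=y, group=group, provenance=prov,
                          feature_names=list(ds.feature_names))
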
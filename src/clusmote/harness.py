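"""Experimental protocol: grouped leave-one-out CV and the strategy x r sweep.

Evaluation mimics complex-based leave-one-out cross-validation: each
fold's test set is every row of one group (one antigen–antibody
complex), the training set is everything else.  Resampling is applied
to the training fold only — test folds retain their natural imbalance —
and is refit independently inside every fold, so no test row ever
reaches the clustering or the SMOTE interpolation.

Classifiers sit behind a small spec: a decision tree pruned on a
held-out fraction of the training fold, and a linear SVM trained by
stochastic (sub)gradient descent on the hinge loss with the recorded
defaults (5 epochs, regularization 1e-4, batch size 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import LeaveOneGroupOut, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .dataset import LabeledDataset
from .metrics import MetricReport, aggregate, fold_report
from .resampler import STRATEGIES, ResamplerConfig, resample


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "decision_tree"  # decision_tree | linear_svm
    dt_prune_fraction: float = 0.1
    svm_epochs: int = 5
    svm_regularization: float = 1e-4
    svm_batch_size: int = 1

    def validate(self) -> None:
        if self.kind not in ("decision_tree", "linear_svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass(frozen=True)
class ExperimentGrid:
    strategies: tuple[str, ...] = ("none", "smote_only", "cluster_only",
                                   "clusmote")
    r_values: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    classifiers: tuple[ClassifierSpec, ...] = (ClassifierSpec(),)
    seeds: tuple[int, ...] = (0,)

    def validate(self) -> None:
        if not (self.strategies and self.r_values and self.classifiers
                and self.seeds):
            raise ValueError("grid lists must be non-empty")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        for c in self.classifiers:
            c.validate()


def logo_folds(groups) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-group-out folds: one fold per distinct group id."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("leave-one-group-out needs at least 2 groups")
    logo = LeaveOneGroupOut()
    return [(tr, te) for tr, te in
            logo.split(np.zeros((len(groups), 1)), groups=groups)]


def _build_dt(spec: ClassifierSpec, X, y, seed: int) -> DecisionTreeClassifier:
    """Decision tree with cost-complexity pruning selected on a holdout.

    The pruning strength is chosen to maximize accuracy on a held-out
    ``dt_prune_fraction`` of the training data, echoing error-based
    pruning on a reserved pruning set.
    """
    base = DecisionTreeClassifier(random_state=seed)
    if spec.dt_prune_fraction <= 0 or len(np.unique(y)) < 2:
        return base.fit(X, y)
    try:
        X_fit, X_prune, y_fit, y_prune = train_test_split(
            X, y, test_size=spec.dt_prune_fraction, random_state=seed,
            stratify=y)
    except ValueError:  # class too small to stratify the holdout
        return base.fit(X, y)
    if len(np.unique(y_fit)) < 2:
        return base.fit(X, y)
    path = base.cost_complexity_pruning_path(X_fit, y_fit)
    alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))
    if len(alphas) > 20:  # keep the search cheap on big folds
        alphas = alphas[np.linspace(0, len(alphas) - 1, 20).astype(int)]
    best_alpha, best_acc = 0.0, -1.0
    for a in alphas:
        m = DecisionTreeClassifier(random_state=seed, ccp_alpha=a)
        m.fit(X_fit, y_fit)
        acc = m.score(X_prune, y_prune)
        if acc > best_acc:
            best_alpha, best_acc = a, acc
    return DecisionTreeClassifier(random_state=seed,
                                  ccp_alpha=best_alpha).fit(X, y)


def fit_predict(clf: ClassifierSpec, train: LabeledDataset,
                test: LabeledDataset, seed: int = 0,
                standardize: bool = True):
    """Fit the specified classifier on train; return (labels, scores) on test.

    Scores are the signed margin for the linear SVM and the positive-
    class leaf proportion for the decision tree.  Features are
    standardized on the training fold by default.
    """
    clf.validate()
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    X_tr, X_te = train.X, test.X
    if standardize:
        scaler = StandardScaler().fit(X_tr)
        if np.any(scaler.scale_ == 0):  # constant features: leave as-is
            scaler.scale_ = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)

    if clf.kind == "decision_tree":
        model = _build_dt(clf, X_tr, train.y, seed)
        scores = model.predict_proba(X_te)[:, list(model.classes_).index(1)]
        labels = model.predict(X_te)
    else:
        model = SGDClassifier(
            loss="hinge", penalty="l2", alpha=clf.svm_regularization,
            max_iter=clf.svm_epochs, tol=None, random_state=seed,
            learning_rate="optimal")
        model.fit(X_tr, train.y)
        scores = model.decision_function(X_te)
        labels = model.predict(X_te)
    return np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)


def _cell_seed(master: int, strategy: str, r: float, kind: str,
               fold: int, seed: int) -> int:
    ss = np.random.SeedSequence(
        (master, hash(strategy) % (2 ** 31), int(r * 1000),
         hash(kind) % (2 ** 31), fold, seed))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def evaluate_cell(ds: LabeledDataset, strategy: str, r: float,
                  clf: ClassifierSpec, seed: int,
                  resampler_cfg: ResamplerConfig | None = None,
                  master_seed: int = 0) -> MetricReport:
    """One grid cell: LOGO CV with in-fold resampling, macro-aggregated."""
    if ds.group is None:
        raise ValueError("grouped dataset required")
    base_cfg = resampler_cfg or ResamplerConfig()
    # r only parameterizes the full hybrid; keep cells of r-independent
    # strategies identical across the r sweep
    r_eff = r if strategy == "clusmote" else 0.0
    reports = []
    for fold_i, (tr_idx, te_idx) in enumerate(logo_folds(ds.group)):
        cell = _cell_seed(master_seed, strategy, r_eff, clf.kind, fold_i, seed)
        cfg = replace(base_cfg, r=r, seed=cell)
        train = resample(ds.subset(tr_idx), strategy, cfg)
        test = ds.subset(te_idx)
        if len(np.unique(test.y)) < 2:
            continue  # a fold without both classes yields no AUC
        labels, scores = fit_predict(clf, train, test, seed=cell)
        reports.append(fold_report(test.y, labels, scores))
    if not reports:
        raise ValueError("no evaluable folds (each needs both classes)")
    return aggregate(reports)


def run_grid(ds: LabeledDataset, grid: ExperimentGrid,
             resampler_cfg: ResamplerConfig | None = None,
             master_seed: int = 0) -> pd.DataFrame:
    """Full sweep: one row per (strategy, r, classifier, seed).

    r parameterizes only the full hybrid; rows for the other strategies
    repeat identically across the r sweep (their cells ignore r).
    """
    grid.validate()
    if ds.group is None:
        raise ValueError("grouped dataset required")
    rows = []
    cache: dict = {}
    for strategy, r, clf, seed in itertools.product(
            grid.strategies, grid.r_values, grid.classifiers, grid.seeds):
        key = (strategy, r if strategy == "clusmote" else None, clf, seed)
        if key not in cache:
            cache[key] = evaluate_cell(ds, strategy, r, clf, seed,
                                       resampler_cfg, master_seed)
        row = {"strategy": strategy, "r": r,
               "classifier": clf.kind, "seed": seed}
        row.update(cache[key].to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
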
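"""The repeated-split evaluation protocol and train/test overlap inspection.

The protocol mirrors standard practice for reporting multi-label epitope
classifiers: the dataset is divided into five different 80:20 random splits
using five seeds; each 80% training split yields a 5-fold cross-validation
estimate, the model is then refitted on the full 80% and scored on the held
out 20%; finally the five CV and the five test reports are averaged
arithmetically.  Splits are plain random (not label-stratified) by default,
with a stratified option.

A 2-component PCA projection, fitted on a training split and applied to
both sides, supports visual inspection of train/test overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold, StratifiedKFold

from . import multilabel
from .features import PseAACConfig, encode_dataset
from .io import Dataset
from .metrics import MetricsReport, evaluate, mean_report
from .multilabel import BaseLearnerConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    """Five seeded 80:20 splits with 5-fold CV inside each training split."""

    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    train_fraction: float = 0.8
    cv_folds: int = 5
    stratified: bool = False

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class EvaluationSummary:
    """Per-split CV and test reports plus their arithmetic means."""

    cv_per_split: list[MetricsReport] = field(default_factory=list)
    test_per_split: list[MetricsReport] = field(default_factory=list)
    cv_averaged: MetricsReport | None = None
    test_averaged: MetricsReport | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (cv, te) in enumerate(zip(self.cv_per_split, self.test_per_split)):
            rows.append({"split": i, "phase": "cv", **cv.to_dict()})
            rows.append({"split": i, "phase": "test", **te.to_dict()})
        rows.append({"split": "mean", "phase": "cv", **self.cv_averaged.to_dict()})
        rows.append({"split": "mean", "phase": "test", **self.test_averaged.to_dict()})
        return pd.DataFrame(rows)


def _n_train(n: int, fraction: float) -> int:
    # round-half-even, so 0.8 * 10744 = 8595.2 -> 8595
    return int(round(fraction * n))


def make_splits(ds: Dataset, plan: SplitPlan | None = None
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (train_indices, test_indices) pairs, one per seed."""
    plan = plan or SplitPlan()
    n = len(ds)
    if n < 2 * plan.cv_folds:
        raise ValueError(f"dataset of {n} records is too small for "
                         f"{plan.cv_folds}-fold CV inside a split")
    n_train = _n_train(n, plan.train_fraction)
    splits = []
    for seed in plan.seeds:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def label_marginal_baseline(train_labels: np.ndarray,
                            test_labels: np.ndarray) -> MetricsReport:
    """Score the trivial predictor emitting each label's training majority bit."""
    majority = (train_labels.mean(axis=0) >= 0.5).astype(int)
    pred = np.tile(majority, (test_labels.shape[0], 1))
    return evaluate(test_labels, pred)


def _fit_eval(fm: pd.DataFrame, ds: Dataset, train_idx, eval_idx,
              strategy: str, base: BaseLearnerConfig, encoder: str,
              pseaac: PseAACConfig) -> MetricsReport:
    model = multilabel.fit(fm.iloc[train_idx], ds.subset(train_idx),
                           strategy=strategy, base=base, encoder=encoder,
                           pseaac=pseaac)
    bits, _ = multilabel.predict(model, fm.iloc[eval_idx])
    return evaluate(ds.subset(eval_idx).label_matrix(), bits)


def cross_validate(fm: pd.DataFrame, ds: Dataset, train_idx: np.ndarray,
                   strategy: str, base: BaseLearnerConfig,
                   encoder: str = "dc", pseaac: PseAACConfig | None = None,
                   cv_folds: int = 5, seed: int = 0,
                   stratified: bool = False) -> MetricsReport:
    """Mean of the held-out-fold reports of a k-fold CV on one training split."""
    pseaac = pseaac or PseAACConfig()
    train_idx = np.asarray(train_idx)
    labels = ds.label_matrix()[train_idx]
    if stratified:
        _, strata = np.unique(labels, axis=0, return_inverse=True)
        folds = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                random_state=seed).split(train_idx, strata)
    else:
        folds = KFold(n_splits=cv_folds, shuffle=True,
                      random_state=seed).split(train_idx)
    reports = []
    for fold_train, fold_test in folds:
        held = labels[fold_train]
        lost = [j for j in range(held.shape[1]) if len(np.unique(held[:, j])) < 2]
        if lost:
            logger.warning("fold lost all variation for label index(es) %s; "
                           "proceeding", lost)
        reports.append(_fit_eval(fm, ds, train_idx[fold_train],
                                 train_idx[fold_test], strategy, base,
                                 encoder=encoder, pseaac=pseaac))
    return mean_report(reports)


def run_protocol(ds: Dataset, encoder: str = "dc",
                 pseaac: PseAACConfig | None = None,
                 strategy: str = "binary_relevance",
                 base: BaseLearnerConfig | None = None,
                 plan: SplitPlan | None = None) -> EvaluationSummary:
    """Run the full five-split protocol for one encoder/strategy/base combo.

    For each seeded 80:20 split: 5-fold CV on the training 80%, then a fit
    on the full 80% scored on the held-out 20%.  Per-split reports and their
    arithmetic means are returned.  Deterministic given the plan's seeds and
    ``base.seed``.
    """
    pseaac = pseaac or PseAACConfig()
    base = base or BaseLearnerConfig()
    plan = plan or SplitPlan()
    logger.info("protocol: encoder=%s strategy=%s base=%s seeds=%s",
                encoder, strategy, base.kind, plan.seeds)
    fm = encode_dataset(ds, encoder, pseaac)
    summary = EvaluationSummary()
    for offset, (train_idx, test_idx) in enumerate(make_splits(ds, plan)):
        cv = cross_validate(fm, ds, train_idx, strategy, base,
                            encoder=encoder, pseaac=pseaac,
                            cv_folds=plan.cv_folds,
                            seed=plan.seeds[offset] + 1000,
                            stratified=plan.stratified)
        test = _fit_eval(fm, ds, train_idx, test_idx, strategy, base,
                         encoder=encoder, pseaac=pseaac)
        summary.cv_per_split.append(cv)
        summary.test_per_split.append(test)
    summary.cv_averaged = mean_report(summary.cv_per_split)
    summary.test_averaged = mean_report(summary.test_per_split)
    return summary


def projection_2d(train_fm: pd.DataFrame, test_fm: pd.DataFrame
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Project train and test feature rows onto the top-2 PCA axes of train.

    Returns a coordinate frame (columns pc1, pc2, set in {train, test}) and
    the explained-variance fractions of the two axes.
    """
    if len(train_fm) < 3 or train_fm.shape[1] < 2:
        raise ValueError("projection needs >= 3 training records and >= 2 features")
    if train_fm.to_numpy().std(axis=0).max() == 0.0:
        raise ValueError("training features are constant; projection undefined")
    pca = PCA(n_components=2)
    train_xy = pca.fit_transform(train_fm.to_numpy(dtype=float))
    test_xy = pca.transform(test_fm.to_numpy(dtype=float))
    frames = [
        pd.DataFrame({"id": train_fm.index, "pc1": train_xy[:, 0],
                      "pc2": train_xy[:, 1], "set": "train"}),
        pd.DataFrame({"id": test_fm.index, "pc1": test_xy[:, 0],
                      "pc2": test_xy[:, 1], "set": "test"}),
    ]
    return pd.concat(frames, ignore_index=True), pca.explained_variance_ratio_
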
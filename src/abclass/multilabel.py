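"""Binary Relevance and Label Powerset models over Random Forest bases.

Two problem transformations map the 4-label task (IgG, IgE, IgA, IgM) onto
trainable single-label problems:

* **Binary Relevance (BR)** — four independent one-vs-rest binary
  classifiers, one per antibody class; a test peptide is pushed through all
  four and a class bit is set when that member's positive score reaches the
  0.5 threshold.  The all-zero call is allowed.
* **Label Powerset (LP)** — every label combination observed in training
  becomes one multiclass category; a single multiclass model is fitted and
  its prediction decoded back to a 4-bit vector through the codebook.  LP
  can never emit a combination absent from training.

The base learner is a Random Forest, optionally boosted with AdaBoost
(stagewise multiclass exponential loss, i.e. the SAMME update, which for
two classes is classic binary AdaBoost).  Boosting a forest is unusual but
deliberate here: a large forest can drive its weighted training error to
zero, at which point boosting stops early with a single member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier

from .features import PseAACConfig
from .io import LABEL_NAMES, Dataset

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

LabelVector = tuple[int, int, int, int]


@dataclass(frozen=True)
class BaseLearnerConfig:
    """Base-learner settings shared by BR members and the LP model.

    kind
        ``"rf"`` for a plain Random Forest, ``"rf_adaboost"`` for AdaBoost
        over Random Forest base estimators.
    n_trees
        Trees per forest (per boosting round for ``rf_adaboost``).
    n_boost_rounds
        Maximum AdaBoost rounds T (``rf_adaboost`` only).
    """

    kind: str = "rf"
    n_trees: int = 100
    n_boost_rounds: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rf", "rf_adaboost"):
            raise ValueError(f"unknown base learner kind {self.kind!r}")
        if self.n_trees < 1 or self.n_boost_rounds < 1:
            raise ValueError("n_trees and n_boost_rounds must be >= 1")


def make_base_estimator(cfg: BaseLearnerConfig, seed: int):
    """Instantiate one (unfitted) base learner from its config."""
    rf = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
    if cfg.kind == "rf":
        return rf
    return AdaBoostClassifier(estimator=rf, n_estimators=cfg.n_boost_rounds,
                              random_state=seed)


def fit_adaboost(X, y, cfg: BaseLearnerConfig, seed: int | None = None):
    """Fit one AdaBoost-over-Random-Forest ensemble on a single-label target.

    Each round fits one forest on the current example-weight distribution,
    derives the learner weight from its weighted error, and reweights the
    examples towards the mistakes; boosting stops early when a round is
    perfect (single-learner ensemble) or no longer better than chance.
    """
    cfg = replace(cfg, kind="rf_adaboost")
    est = make_base_estimator(cfg, cfg.seed if seed is None else seed)
    est.fit(X, y)
    return est


@dataclass
class MultiLabelModel:
    """A fitted BR or LP ensemble plus the config needed to reuse it."""

    strategy: str  # binary_relevance | label_powerset
    base: BaseLearnerConfig
    encoder: str
    pseaac: PseAACConfig
    feature_names: tuple[str, ...]
    members: list = field(default_factory=list)       # BR: 4 fitted models
    codebook: tuple[LabelVector, ...] = ()            # LP: class idx -> bits
    label_names: tuple[str, ...] = LABEL_NAMES


def _fit_binary_member(X: np.ndarray, y: np.ndarray, cfg: BaseLearnerConfig,
                       seed: int, label: str):
    if len(np.unique(y)) < 2:
        only = int(y[0]) if len(y) else 0
        logger.warning("label %s has a single class (%d) in training; "
                       "member predicts that constant", label, only)
        m = DummyClassifier(strategy="constant", constant=only)
        m.fit(X, y)
        return m
    m = make_base_estimator(cfg, seed)
    m.fit(X, y)
    return m


def fit(fm: pd.DataFrame, ds: Dataset, strategy: str = "binary_relevance",
        base: BaseLearnerConfig | None = None, encoder: str = "dc",
        pseaac: PseAACConfig | None = None) -> MultiLabelModel:
    """Train a multi-label model on an encoded, labelled dataset.

    ``fm`` rows must align with ``ds`` records.  Deterministic given
    ``base.seed``.
    """
    base = base or BaseLearnerConfig()
    pseaac = pseaac or PseAACConfig()
    if len(fm) != len(ds):
        raise ValueError("feature matrix rows must align with dataset records")
    from .features import feature_names
    if list(fm.columns) != feature_names(encoder, pseaac):
        raise ValueError(
            f"feature matrix columns do not come from encoder {encoder!r} "
            "with the given PseAAC settings")
    X = fm.to_numpy(dtype=float)
    Y = ds.label_matrix()
    model = MultiLabelModel(strategy=strategy, base=base, encoder=encoder,
                            pseaac=pseaac, feature_names=tuple(fm.columns))
    if strategy == "binary_relevance":
        for j, label in enumerate(LABEL_NAMES):
            model.members.append(
                _fit_binary_member(X, Y[:, j], base, base.seed + j, label))
    elif strategy == "label_powerset":
        combos = sorted({tuple(int(b) for b in row) for row in Y})
        codebook = tuple(combos)
        code_of = {c: i for i, c in enumerate(codebook)}
        y = np.array([code_of[tuple(int(b) for b in row)] for row in Y])
        counts = np.bincount(y, minlength=len(codebook))
        for c, n in zip(codebook, counts):
            if n == 1:
                logger.warning("label combination %s has a single training "
                               "example; trained as-is", c)
        logger.info("label-powerset codebook: %d observed combination(s)", len(codebook))
        if len(codebook) == 1:
            member = DummyClassifier(strategy="constant", constant=0)
            member.fit(X, y)
        else:
            member = make_base_estimator(base, base.seed)
            member.fit(X, y)
        model.members = [member]
        model.codebook = codebook
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return model


def _positive_score(member, X: np.ndarray) -> np.ndarray:
    proba = member.predict_proba(X)
    classes = list(member.classes_)
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(len(X))


def predict(model: MultiLabelModel, fm: pd.DataFrame
            ) -> tuple[np.ndarray, np.ndarray]:
    """Predict 4-bit label vectors and per-class scores for encoded records.

    Returns ``(bits, scores)``, each of shape (n, 4).  BR sets a bit when
    the member's positive score is >= 0.5; LP decodes the argmax class
    through the codebook, and its per-class score is the total probability
    of the combinations containing that class.
    """
    if tuple(fm.columns) != model.feature_names:
        raise ValueError("feature columns do not match the model's encoder spec")
    X = fm.to_numpy(dtype=float)
    n = X.shape[0]
    if model.strategy == "binary_relevance":
        scores = np.column_stack([_positive_score(m, X) for m in model.members])
        bits = (scores >= 0.5).astype(int)
        return bits, scores
    member = model.members[0]
    proba = member.predict_proba(X)
    # map member class order onto codebook positions
    full = np.zeros((n, len(model.codebook)))
    for col, cls in enumerate(member.classes_):
        full[:, int(cls)] = proba[:, col]
    book = np.asarray(model.codebook, dtype=int)   # (C, 4)
    scores = full @ book
    bits = book[np.argmax(full, axis=1)]
    return bits.astype(int), scores


def predict_dataset(model: MultiLabelModel, ds: Dataset
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Encode raw sequences with the model's own encoder spec, then predict."""
    from .features import encode_dataset

    fm = encode_dataset(ds, model.encoder, model.pseaac)
    return predict(model, fm)


def save_model(model: MultiLabelModel, path) -> None:
    """Serialize a fitted model (strategy, configs, codebook, members)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> MultiLabelModel:
    """Load a model saved by :func:`save_model`; round-trips predictions."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an abclass model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})")
    return payload["model"]
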
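"""Biometric identification from blink features.

Implements the β-mean bootstrap (each constructed blink is the arithmetic
mean of β randomly chosen trials of one subject; averaging suppresses
intra-subject noise while preserving the subject's signature), classifier
evaluation under stratified 10-fold or leave-one-out cross-validation with
the correct identification rate (CIR) as the figure of merit, and greedy
sequential forward feature selection with selection-rate profiling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .data import FeatureDataset
from .errors import InfeasibleUniquenessError, InvalidParameterError

__all__ = [
    "BetaMeanConfig",
    "ClassificationReport",
    "SelectionProfile",
    "build_beta_mean_set",
    "evaluate_classifier",
    "forward_select",
    "selection_rates",
    "CLASSIFIERS",
]

log = logging.getLogger(__name__)

CLASSIFIERS = ("lda", "qda", "knn", "ct")


@dataclass
class BetaMeanConfig:
    """Bootstrap-averaging configuration.

    ``beta`` trials are averaged per constructed blink (the study uses
    β in {3, 5, 10, 25}); ``n_boot`` constructed blinks per subject (100);
    ``mode`` selects whether feature vectors or raw cropped waveforms are
    averaged (feature averaging is the default; waveform averaging re-runs
    feature extraction on the mean window).
    """

    beta: int
    n_boot: int = 100
    seed: int = 0
    mode: str = "average-of-features"

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise InvalidParameterError(f"beta must be >= 1, got {self.beta}")
        if self.mode not in ("average-of-features", "average-of-waveforms"):
            raise InvalidParameterError(f"unknown beta-mean mode '{self.mode}'")


def _unique_subsets(rng: np.random.Generator, b: int, beta: int, n_boot: int):
    """Draw n_boot distinct sorted beta-subsets of range(b), uniformly."""
    total = math.comb(b, beta)
    if n_boot > total:
        raise InfeasibleUniquenessError(
            f"cannot draw {n_boot} unique {beta}-subsets of {b} trials "
            f"(only {total} exist)"
        )
    seen = set()
    out = []
    while len(out) < n_boot:
        subset = tuple(sorted(rng.choice(b, size=beta, replace=False).tolist()))
        if subset not in seen:
            seen.add(subset)
            out.append(subset)
    return out


def build_beta_mean_set(
    ds: FeatureDataset,
    cfg: BetaMeanConfig,
    segments_by_subject: dict | None = None,
    extract_fn=None,
) -> FeatureDataset:
    """Construct a β-mean bootstrap dataset: per subject, ``cfg.n_boot``
    unique β-subsets of trials, each averaged into one constructed blink.

    In ``average-of-features`` mode the subject's feature rows are averaged.
    In ``average-of-waveforms`` mode the subject's cropped intensity windows
    (``segments_by_subject[subject]``, a list of :class:`BlinkSegment` in the
    dataset's trial order) are averaged sample-wise and re-run through
    ``extract_fn`` (default :func:`blinkkin.features.extract_features`).
    """
    if cfg.beta > ds.b:
        raise InvalidParameterError(
            f"beta={cfg.beta} exceeds trials per subject b={ds.b}"
        )
    rng = np.random.default_rng(cfg.seed)
    rows, subjects, trials = [], [], []
    for subj in ds.subject_labels:
        idx = ds.rows_of(subj)
        subsets = _unique_subsets(rng, len(idx), cfg.beta, cfg.n_boot)
        for k, subset in enumerate(subsets):
            if cfg.mode == "average-of-features":
                rows.append(ds.X[idx[list(subset)]].mean(axis=0))
            else:
                from .features import extract_features
                from .segmentation import BlinkSegment

                segs = segments_by_subject[subj]
                chosen = [segs[i] for i in subset]
                I_mean = np.mean([s.I_win for s in chosen], axis=0)
                proto = chosen[0]
                mean_seg = BlinkSegment(
                    subject_id=str(subj),
                    trial_id=f"beta{cfg.beta}-{k}",
                    I_win=I_mean,
                    t_win=proto.t_win.copy(),
                    peak_offset=int(np.argmax(I_mean)),
                    T=proto.T,
                )
                fn = extract_fn or extract_features
                rows.append(fn(mean_seg).values)
            subjects.append(subj)
            trials.append(f"beta{cfg.beta}-{k}")
    return FeatureDataset(
        X=np.vstack(rows),
        subjects=np.array(subjects),
        trials=np.array(trials),
        feature_names=list(ds.feature_names),
    )


@dataclass
class ClassificationReport:
    """Cross-validated identification result for one classifier and scheme."""

    classifier: str
    scheme: str
    cir: float  # correct identification rate, percent
    confusion: np.ndarray = field(repr=False)
    fold_assignment: np.ndarray = field(repr=False)
    seed: int = 0
    classes: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "scheme": self.scheme,
            "cir_percent": self.cir,
            "seed": self.seed,
            "classes": [str(c) for c in (self.classes if self.classes is not None else [])],
            "confusion": self.confusion.astype(int).tolist(),
        }


def _make_classifier(name: str, seed: int, knn_k: int = 5):
    name = name.lower()
    if name == "lda":
        # SVD solver never inverts the pooled covariance, so singular
        # within-class scatter is handled without an explicit ridge.
        return LinearDiscriminantAnalysis(solver="svd")
    if name == "qda":
        return QuadraticDiscriminantAnalysis()
    if name == "knn":
        # Distance-based, so z-score on training-fold statistics only.
        return make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=knn_k)
        )
    if name == "ct":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    raise InvalidParameterError(
        f"unknown classifier '{name}'; choose one of {CLASSIFIERS}"
    )


def _fit_predict(clf, Xtr, ytr, Xte):
    try:
        clf.fit(Xtr, ytr)
    except np.linalg.LinAlgError:
        if isinstance(clf, QuadraticDiscriminantAnalysis):
            log.warning("QDA covariance singular; refitting with ridge reg_param")
            clf = QuadraticDiscriminantAnalysis(reg_param=1e-6)
            clf.fit(Xtr, ytr)
        else:
            raise
    return clf.predict(Xte)


def evaluate_classifier(
    ds: FeatureDataset,
    classifier: str = "lda",
    scheme: str = "kfold",
    n_folds: int = 10,
    seed: int = 0,
    knn_k: int = 5,
) -> ClassificationReport:
    """Cross-validated correct identification rate for one classifier.

    ``scheme='kfold'`` uses subject-stratified folds (each subject
    proportionally represented in every fold, within one row); ``'loo'``
    leaves one blink out per round.  The result is deterministic given the
    dataset, classifier, scheme and seed.
    """
    if ds.n < 2:
        raise InvalidParameterError("need at least 2 subjects to classify")
    X, y = ds.X, ds.subjects.astype(str)
    fold_assignment = np.full(ds.B, -1, dtype=int)
    y_pred = np.empty(ds.B, dtype=object)

    if scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    elif scheme == "loo":
        splits = LeaveOneOut().split(X, y)
    else:
        raise InvalidParameterError(f"unknown scheme '{scheme}' (kfold|loo)")

    for fold, (train, test) in enumerate(splits):
        clf = _make_classifier(classifier, seed=seed, knn_k=knn_k)
        y_pred[test] = _fit_predict(clf, X[train], y[train], X[test])
        fold_assignment[test] = fold

    classes = np.unique(y)
    conf = confusion_matrix(y, y_pred.astype(str), labels=classes)
    cir = 100.0 * np.trace(conf) / conf.sum()
    return ClassificationReport(
        classifier=classifier,
        scheme=scheme if scheme == "loo" else f"kfold({n_folds})",
        cir=float(cir),
        confusion=conf,
        fold_assignment=fold_assignment,
        seed=seed,
        classes=classes,
    )


def _misclassified(X, y, feature_idx, classifier, splits, seed, knn_k):
    loss = 0
    for train, test in splits:
        clf = _make_classifier(classifier, seed=seed, knn_k=knn_k)
        pred = _fit_predict(clf, X[np.ix_(train, feature_idx)], y[train],
                            X[np.ix_(test, feature_idx)])
        loss += int(np.sum(pred != y[test]))
    return loss


def forward_select(
    ds: FeatureDataset,
    classifier: str = "lda",
    seed: int = 0,
    n_folds: int = 10,
    knn_k: int = 5,
    max_features: int | None = None,
) -> list:
    """Greedy sequential forward feature selection.

    Starting from the empty set, each step adds the candidate feature that
    minimizes the 10-fold cross-validated misclassification count (ties break
    to the lowest canonical index) and stops when no candidate strictly
    decreases the loss.  Returns the selected features as 0-based column
    indices of ``ds`` in selection order.
    """
    X, y = ds.X, ds.subjects.astype(str)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))  # fixed folds for the whole run
    selected: list = []
    best_loss = math.inf
    limit = max_features if max_features is not None else ds.F
    while len(selected) < limit:
        candidates = [f for f in range(ds.F) if f not in selected]
        if not candidates:
            break
        losses = [
            _misclassified(X, y, selected + [f], classifier, splits, seed, knn_k)
            for f in candidates
        ]
        best = int(np.argmin(losses))  # argmin takes the first (lowest index) tie
        if losses[best] >= best_loss:
            break
        best_loss = losses[best]
        selected.append(candidates[best])
    return selected


@dataclass
class SelectionProfile:
    """Per-feature selection counts and rates over repeated selection runs."""

    counts: np.ndarray
    repeats: int
    feature_names: list = field(default_factory=list)

    @property
    def rate(self) -> np.ndarray:
        return 100.0 * self.counts / self.repeats

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "counts": self.counts.astype(int).tolist(),
            "rate_percent": self.rate.tolist(),
            "features": list(self.feature_names),
        }


def selection_rates(runs, n_features: int, feature_names=None) -> SelectionProfile:
    """Percentage of selection runs in which each feature appears."""
    if not runs:
        raise InvalidParameterError("no selection runs supplied")
    counts = np.zeros(n_features, dtype=int)
    for run in runs:
        for f in set(run):
            counts[f] += 1
    return SelectionProfile(
        counts=counts,
        repeats=len(runs),
        feature_names=list(feature_names) if feature_names else [],
    )
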
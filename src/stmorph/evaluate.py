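"""Episode-level classification protocol.

Each annotated episode (per lead) becomes one instance: the mean of the
normalized transform coefficients over a 20 s window centered on the
episode extremum, restricted to a coefficient subset (1-3, 1-5 or 1-8).
Instances are classified ischaemic vs non-ischaemic by a roster of five
classifier families under stratified 10-fold cross-validation repeated 10
times, reporting sensitivity, specificity and classification accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from stmorph.delineate import FeatureSeries
from stmorph.synth import Episode, ISCHAEMIC

__all__ = [
    "EpisodeFeature",
    "EvalResult",
    "SUBSETS",
    "CLASSIFIERS",
    "episode_feature",
    "metrics",
    "make_classifier",
    "crossvalidate",
]

logger = logging.getLogger(__name__)

SUBSETS = {"1-3": 3, "1-5": 5, "1-8": 8}
CLASSIFIERS = ("3nn", "4nn", "5nn", "ct", "qda", "svm", "nbc")

EPISODE_WINDOW_S = 20.0  # mean taken over extremum +/- 10 s, clipped to the episode


@dataclass
class EpisodeFeature:
    episode: Episode
    transform: str  # KLT | LPT
    subset: str  # key of SUBSETS
    vector: npt.NDArray[np.float64]
    label: str  # "ischaemic" | "non_ischaemic"


class UndefinedMetricError(ValueError):
    pass


class StratificationError(ValueError):
    pass


@dataclass
class EvalResult:
    classifier: str
    transform: str
    subset: str
    se: float  # %
    sp: float  # %
    ca: float  # %
    confusion_per_repetition: list[tuple[int, int, int, int]] = field(default_factory=list)


def episode_feature(
    series: FeatureSeries,
    episode: Episode,
    transform: str,
    subset: str = "1-8",
) -> EpisodeFeature | None:
    """Mean normalized coefficient vector around the episode extremum.

    The window is extremum +/- 10 s clipped to [onset, offset]; beats of the
    episode's lead inside it are averaged unweighted.  Returns None (with a
    warning) if no beat falls in the window.
    """
    n = SUBSETS[subset]
    lo = max(episode.extremum_s - EPISODE_WINDOW_S / 2, episode.onset_s)
    hi = min(episode.extremum_s + EPISODE_WINDOW_S / 2, episode.offset_s)
    mask = (series.lead == episode.lead) & (series.time_s >= lo) & (series.time_s <= hi)
    if not np.any(mask):
        logger.warning("episode at %.1f s has no beats in its window; skipped", episode.extremum_s)
        return None
    coeffs = series.norm_coeffs(transform)[mask, :n]
    label = "ischaemic" if episode.label == ISCHAEMIC else "non_ischaemic"
    return EpisodeFeature(
        episode=episode,
        transform=transform.upper(),
        subset=subset,
        vector=coeffs.mean(axis=0),
        label=label,
    )


def metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Sensitivity, specificity and classification accuracy, in percent.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), CA = (TP+TN)/(TP+FN+TN+FP).
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("a class has no instances; Se/Sp undefined")
    se = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    ca = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    return se, sp, ca


class KDENaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature Gaussian kernel density estimates."""

    def __init__(self, bw_method: str | float = "scott"):
        self.bw_method = bw_method

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._kdes = {}
        self._priors = {}
        for cls in self.classes_:
            rows = X[y == cls]
            self._priors[cls] = len(rows) / len(y)
            kdes = []
            for j in range(X.shape[1]):
                col = rows[:, j]
                if np.std(col) < 1e-12:
                    col = col + 1e-6 * np.random.default_rng(0).standard_normal(len(col))
                kdes.append(gaussian_kde(col, bw_method=self.bw_method))
            self._kdes[cls] = kdes
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((len(X), len(self.classes_)))
        for c_idx, cls in enumerate(self.classes_):
            log_lik = np.full(len(X), np.log(self._priors[cls]))
            for j, kde in enumerate(self._kdes[cls]):
                dens = np.maximum(kde(X[:, j]), 1e-300)
                log_lik += np.log(dens)
            scores[:, c_idx] = log_lik
        return self.classes_[np.argmax(scores, axis=1)]


def make_classifier(spec: str):
    """Instantiate one of the roster classifiers by id."""
    spec = spec.lower()
    if spec.endswith("nn") and spec[:-2].isdigit():
        return KNeighborsClassifier(n_neighbors=int(spec[:-2]))
    if spec == "ct":
        return DecisionTreeClassifier(random_state=0)
    if spec == "qda":
        return QuadraticDiscriminantAnalysis()
    if spec == "svm":
        # inhomogeneous (x.y + 1)^2 kernel; the homogeneous form cannot
        # represent affine boundaries
        return SVC(kernel="poly", degree=2, coef0=1.0, C=1.0)
    if spec == "nbc":
        return KDENaiveBayes()
    raise ValueError(f"unknown classifier {spec!r}; choose from {CLASSIFIERS}")


def crossvalidate(
    features: list[EpisodeFeature],
    classifier: str,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> EvalResult:
    """Stratified k-fold cross-validation repeated with reshuffling.

    Confusion counts are pooled over the held-out folds within each
    repetition; Se/Sp/CA are averaged across repetitions.  Instances are
    put into a canonical order before shuffling so results do not depend on
    input ordering.  Positive class = ischaemic.
    """
    X = np.asarray([f.vector for f in features], dtype=float)
    y = np.asarray([1 if f.label == "ischaemic" else 0 for f in features])
    order = np.lexsort(np.vstack([X.T, y]))
    X, y = X[order], y[order]

    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"need at least {folds} instances per class for {folds}-fold "
            f"stratification, got {counts.tolist()}; reduce folds or add episodes"
        )

    per_rep = []
    ses, sps, cas = [], [], []
    for rep in range(repetitions):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        tp = fn = tn = fp = 0
        for train_idx, test_idx in skf.split(X, y):
            clf = make_classifier(classifier)
            clf.fit(X[train_idx], y[train_idx])
            pred = np.asarray(clf.predict(X[test_idx]))
            truth = y[test_idx]
            tp += int(np.sum((pred == 1) & (truth == 1)))
            fn += int(np.sum((pred == 0) & (truth == 1)))
            tn += int(np.sum((pred == 0) & (truth == 0)))
            fp += int(np.sum((pred == 1) & (truth == 0)))
        se, sp, ca = metrics(tp, fn, tn, fp)
        per_rep.append((tp, fn, tn, fp))
        ses.append(se)
        sps.append(sp)
        cas.append(ca)

    return EvalResult(
        classifier=classifier,
        transform=features[0].transform if features else "",
        subset=features[0].subset if features else "",
        se=float(np.mean(ses)),
        sp=float(np.mean(sps)),
        ca=float(np.mean(cas)),
        confusion_per_repetition=per_rep,
    )
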
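"""Per-searchlight decoding with leave-one-run-out cross-validation.

Every downsampled vertex hosts a classifier working on the flattened,
circularly-masked searchlight image of each trial.  Each run serves once as
the test set while the remaining runs train the classifier; the per-fold
accuracies are averaged into the vertex's value of the subject accuracy
map.  Chance level is 1/k for a k-class contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from .io import TrialSet
from .searchlight import SearchlightLayout, circular_mask


@dataclass
class AccuracyMap:
    """Per-vertex mean cross-validated accuracy for one subject."""

    accuracy: np.ndarray
    subject_id: str
    contrast: tuple
    chance: float


def loro_folds(runs) -> list:
    """Leave-one-run-out folds: (train run ids, test run id) per distinct run."""
    unique = list(dict.fromkeys(runs))  # first-appearance order
    if len(unique) < 2:
        raise ValueError(f"leave-one-run-out needs >= 2 runs, got {len(unique)}")
    return [([r for r in unique if r != test], test) for test in unique]


def apply_contrast(labels: np.ndarray, contrast) -> tuple:
    """Map condition codes onto superclass indices.

    ``contrast`` is a sequence of disjoint code sets; trials whose code is
    in superclass k get label k, others are dropped.  Returns (kept trial
    indices, superclass labels).
    """
    groups = [frozenset(g) for g in contrast]
    keep, y = [], []
    for t, code in enumerate(labels):
        for k, g in enumerate(groups):
            if int(code) in g:
                keep.append(t)
                y.append(k)
                break
    return np.asarray(keep, dtype=np.int64), np.asarray(y, dtype=np.int64)


def svm_decode(train_X, train_y, test_X, C: float = 1.0) -> np.ndarray:
    """Linear-kernel SVM: fit on the training fold, predict the test fold.

    One-vs-one for more than two classes; deterministic for fixed inputs.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(train_X), train_y)
    return clf.predict(np.asarray(test_X))


class SearchlightDecoder(BaseEstimator):
    """Searchlight decoding of trial patterns on the sphere.

    Parameters
    ----------
    layout : SearchlightLayout
        Grid-searchlight layout for the template pair in use.
    contrast : sequence of sets of condition codes, optional
        Superclasses to decode (e.g. ``[{1}, {4}]``).  By default every
        observed non-baseline code is its own class.
    classifier : {"svm", "cnn"}
        Decoder applied per searchlight: linear SVM on the flattened masked
        image, or the small convolutional network on the image itself.
    C : float
        SVM regularisation constant.
    cnn_params : dict, optional
        Overrides forwarded to :class:`~surflight.cnn.ConvNetClassifier`.
    n_jobs : int
        Vertex-level parallelism; results are identical for any value.
    random_state : int
        Seed for the CNN stream (the SVM stream is deterministic).

    Attributes
    ----------
    accuracy_map_ : (V_low,) array
        Mean leave-one-run-out accuracy per downsampled vertex.
    chance_ : float
        1 / number of superclasses.
    classes_ : tuple of frozensets
        The decoded superclasses.
    """

    def __init__(self, layout: SearchlightLayout, contrast=None,
                 classifier: str = "svm", C: float = 1.0, cnn_params=None,
                 n_jobs: int = 1, random_state: int = 0):
        self.layout = layout
        self.contrast = contrast
        self.classifier = classifier
        self.C = C
        self.cnn_params = cnn_params
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y, runs):
        """Compute the per-vertex accuracy map.

        Parameters
        ----------
        X : (trials, V_high) array of trial patterns.
        y : (trials,) condition codes.
        runs : (trials,) run identifier per trial.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        runs = np.asarray(runs)
        if self.classifier not in ("svm", "cnn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.contrast is None:
            contrast = [frozenset([int(c)]) for c in sorted(set(y.tolist()))
                        if int(c) != 0]
        else:
            contrast = [frozenset(int(c) for c in g) for g in self.contrast]
        if len(contrast) < 2:
            raise ValueError("a contrast needs at least 2 classes")
        observed = set(int(c) for c in y.tolist())
        missing = sorted(set().union(*contrast) - observed)
        if missing:
            raise ValueError(f"contrast codes absent from the data: {missing}")

        keep, labels = apply_contrast(y, contrast)
        X, runs = X[keep], runs[keep]
        folds = loro_folds(runs.tolist())
        mask = circular_mask(self.layout.spec.n1)

        accs = Parallel(n_jobs=self.n_jobs)(
            delayed(self._vertex_accuracy)(X, labels, runs, folds, v, mask)
            for v in range(self.layout.n_records))
        self.accuracy_map_ = np.asarray(accs)
        self.classes_ = tuple(contrast)
        self.chance_ = 1.0 / len(contrast)
        self.n_folds_ = len(folds)
        return self

    def _vertex_accuracy(self, X, labels, runs, folds, vertex, mask) -> float:
        op = self.layout.cell_operator(vertex, mask)
        feats = np.asarray(X @ op.T)
        fold_accs = []
        for train_runs, test_run in folds:
            tr = np.flatnonzero(np.isin(runs, train_runs))
            te = runs == test_run
            # canonical content-based training order so the map is invariant
            # to trial permutations within runs (the fit itself can be
            # order-sensitive in degenerate problems)
            key = np.column_stack([labels[tr], feats[tr]])
            tr = tr[np.lexsort(key.T[::-1])]
            if self.classifier == "svm":
                pred = svm_decode(feats[tr], labels[tr], feats[te], C=self.C)
            else:
                from .cnn import cnn_decode
                n1 = self.layout.spec.n1
                imgs = feats.reshape(-1, n1, n1)
                pred = cnn_decode(imgs[tr], labels[tr], imgs[te],
                                  random_state=self.random_state,
                                  **(self.cnn_params or {}))
            fold_accs.append(np.mean(pred == labels[te]))
        return float(np.mean(fold_accs))

    def accuracy_map(self, subject_id: str = "") -> AccuracyMap:
        """Package the fitted map with its contrast and chance level."""
        if not hasattr(self, "accuracy_map_"):
            raise RuntimeError("call fit() first")
        return AccuracyMap(accuracy=self.accuracy_map_, subject_id=subject_id,
                           contrast=self.classes_, chance=self.chance_)


def subject_accuracy_map(trialsets, layout: SearchlightLayout, contrast=None,
                         classifier: str = "svm", subject_id: str = "",
                         n_jobs: int = 1, random_state: int = 0,
                         **kwargs) -> AccuracyMap:
    """Decode one subject's runs into a per-vertex accuracy map.

    ``trialsets`` is a list of per-run :class:`TrialSet` objects (or one
    combined set carrying run identifiers).
    """
    if isinstance(trialsets, TrialSet):
        combined = trialsets
    else:
        from .io import concat_trialsets
        combined = concat_trialsets(trialsets)
    dec = SearchlightDecoder(layout, contrast=contrast, classifier=classifier,
                             n_jobs=n_jobs, random_state=random_state, **kwargs)
    dec.fit(combined.patterns, combined.labels, combined.runs)
    return dec.accuracy_map(subject_id)
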
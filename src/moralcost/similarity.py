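"""Multivariate similarity analyses on subject x voxel contrast matrices.

Three procedures, each with permutation inference:

* IS-RSA: Spearman rank correlation between the lower triangles of a
  behavioral RDM (pairwise Euclidean distance of subjects in the
  (theta, omega) moral-cost plane) and a neural RDM (1 - Pearson r between
  subjects' voxel patterns), with a Mantel-style permutation test that
  jointly permutes rows and columns of one RDM.
* Pattern similarity: per-subject Pearson correlation between two
  condition maps, Fisher z-transformed, with a sign-flip permutation test
  of the group mean against zero.
* LOSO decoding: a linear SVM (C = 1) trained on all-but-one subject's two
  condition maps (labels +1 / -1); the held-out subject is scored by
  two-choice forced alternative (correct iff the decision value of their
  first-condition map exceeds that of the second). Significance by
  within-subject label-flip permutations; ROC/AUC from the pooled
  cross-validated decision values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .synth import PatternMatrix

__all__ = [
    "RDM",
    "parameter_rdm",
    "neural_rdm",
    "isrsa",
    "pattern_similarity",
    "loso_decode",
    "LosoPatternDecoder",
]


@dataclass(frozen=True)
class RDM:
    """Symmetric subject x subject dissimilarity matrix, zero diagonal."""

    subject_ids: tuple[str, ...]
    matrix: np.ndarray
    metric_label: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        n = len(self.subject_ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} subjects")
        if not np.allclose(m, m.T):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("RDM diagonal must be zero")
        object.__setattr__(self, "matrix", m)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n_subjects, k=-1)
        return self.matrix[i, j]


def _default_ids(n: int) -> tuple[str, ...]:
    return tuple(f"sub{i + 1:03d}" for i in range(n))


def parameter_rdm(
    theta,
    omega,
    standardize: bool = True,
    subject_ids=None,
) -> RDM:
    """Pairwise Euclidean distance between subjects in the (theta, omega)
    moral-cost plane.

    With ``standardize`` (the default) each parameter is z-scored first;
    theta's spread is several times omega's, so raw distances would be
    theta-dominated. The choice is recorded in ``metric_label``.
    """
    theta = np.asarray(theta, float)
    omega = np.asarray(omega, float)
    if theta.shape != omega.shape or theta.ndim != 1:
        raise ValueError("theta and omega must be 1-d and equally long")
    if theta.size < 3:
        raise ValueError("need at least 3 subjects for an RDM analysis")
    pts = np.column_stack([theta, omega])
    if standardize:
        sd = pts.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("zero variance in theta or omega with standardize on")
        pts = (pts - pts.mean(axis=0)) / sd
    mat = squareform(pdist(pts, metric="euclidean"))
    ids = tuple(subject_ids) if subject_ids is not None else _default_ids(theta.size)
    label = "euclidean(z-scored theta, omega)" if standardize else "euclidean(theta, omega)"
    return RDM(ids, mat, metric_label=label)


def neural_rdm(patterns: PatternMatrix) -> RDM:
    """Correlation-distance RDM: entry (i, j) = 1 - Pearson r of the two
    subjects' voxel vectors."""
    v = patterns.values
    sd = v.std(axis=1)
    bad = [patterns.subject_ids[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise ValueError(f"constant voxel vector (correlation undefined) for {bad}")
    mat = squareform(pdist(v, metric="correlation"))
    np.fill_diagonal(mat, 0.0)
    mat = (mat + mat.T) / 2.0
    return RDM(tuple(patterns.subject_ids), mat, metric_label="1 - pearson r")


def _perm_p(null: np.ndarray, observed: float, tail: str) -> float:
    """Permutation p with the +1 correction, p = (b + 1) / (n + 1)."""
    if tail == "greater":
        b = int(np.sum(null >= observed))
    elif tail == "two-sided":
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (b + 1) / (len(null) + 1)


def isrsa(
    rdm_a: RDM,
    rdm_b: RDM,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "greater",
) -> dict:
    """Spearman correlation between two RDMs with a Mantel permutation test.

    The statistic is the Spearman rho of the strictly-lower-triangle
    vectors; the null is built by jointly permuting rows and columns of
    the second RDM ``n_perm`` times. The default tail is one-sided for a
    positive brain-behavior association.
    """
    if rdm_a.subject_ids != rdm_b.subject_ids:
        raise ValueError("RDMs must share the same subject ordering")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for permutation inference", stacklevel=2)
    va = rdm_a.lower_triangle()
    rho = float(spearmanr(va, rdm_b.lower_triangle()).statistic)

    rng = np.random.default_rng(seed)
    n = rdm_a.n_subjects
    i, j = np.tril_indices(n, k=-1)
    m = rdm_b.matrix
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = spearmanr(va, m[np.ix_(perm, perm)][i, j]).statistic
    return {"rho": rho, "p": _perm_p(null, rho, tail), "n_perm": n_perm, "tail": tail}


def pattern_similarity(
    patterns_a: PatternMatrix,
    patterns_b: PatternMatrix,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Cross-condition pattern similarity with a sign-flip permutation test.

    Per subject: Pearson r between the two condition maps, Fisher
    z-transformed (|r| = 1 is clipped before the transform and flagged).
    Group inference: two-sided sign-flip permutation test of mean z vs 0.
    """
    if patterns_a.subject_ids != patterns_b.subject_ids:
        raise ValueError("pattern matrices must share subjects")
    if patterns_a.values.shape != patterns_b.values.shape:
        raise ValueError("pattern matrices must share voxel count")
    if patterns_a.values.shape[1] < 3:
        warnings.warn("fewer than 3 voxels: correlations are nearly degenerate", stacklevel=2)
    a = patterns_a.values
    b = patterns_b.values
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    r = (az * bz).sum(1) / np.sqrt((az**2).sum(1) * (bz**2).sum(1))
    clipped = np.abs(r) >= 1.0
    if clipped.any():
        warnings.warn(
            f"|r| = 1 for subjects {np.flatnonzero(clipped).tolist()}; "
            "clipping before the Fisher z transform",
            stacklevel=2,
        )
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, z.size))
    null = (flips * z).mean(axis=1)
    mean_z = float(z.mean())
    return {
        "per_subject_r": r,
        "per_subject_z": z,
        "mean_z": mean_z,
        "mean_r": float(np.tanh(mean_z)),
        "p": _perm_p(null, mean_z, "two-sided"),
        "n_perm": n_perm,
    }


def _loso_accuracy(a: np.ndarray, b: np.ndarray, c_value: float):
    """LOSO forced-choice accuracy and cross-validated decision values."""
    n = a.shape[0]
    correct = np.empty(n, bool)
    dv_a = np.empty(n)
    dv_b = np.empty(n)
    idx = np.arange(n)
    for s in range(n):
        tr = idx != s
        Xtr = np.vstack([a[tr], b[tr]])
        ytr = np.concatenate([np.ones(n - 1), -np.ones(n - 1)])
        clf = SVC(kernel="linear", C=c_value)
        clf.fit(Xtr, ytr)
        da, db = clf.decision_function(np.vstack([a[s], b[s]]))
        dv_a[s], dv_b[s] = da, db
        correct[s] = da > db
    return float(correct.mean()), dv_a, dv_b


def loso_decode(
    patterns_a: PatternMatrix,
    patterns_b: PatternMatrix,
    c_value: float = 1.0,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Leave-one-subject-out linear-SVM forced-choice decoding.

    Condition a is labelled +1 and condition b -1. The held-out subject
    counts as correct iff the decision value of their condition-a map
    exceeds that of their condition-b map. The permutation null relabels
    the two maps within random subsets of subjects.
    """
    if patterns_a.subject_ids != patterns_b.subject_ids:
        raise ValueError("pattern matrices must share subjects")
    n = len(patterns_a.subject_ids)
    if n < 3:
        raise ValueError("LOSO decoding needs at least 3 subjects")
    if c_value <= 0:
        raise ValueError("c_value must be positive")
    a, b = patterns_a.values, patterns_b.values
    accuracy, dv_a, dv_b = _loso_accuracy(a, b, c_value)

    dv = np.concatenate([dv_a, dv_b])
    labels = np.concatenate([np.ones(n), np.zeros(n)])
    fpr, tpr, _ = roc_curve(labels, dv)
    auc = float(roc_auc_score(labels, dv))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        flip = rng.random(n) < 0.5
        pa = np.where(flip[:, None], b, a)
        pb = np.where(flip[:, None], a, b)
        null[t], _, _ = _loso_accuracy(pa, pb, c_value)
    return {
        "forced_choice_accuracy": accuracy,
        "decision_values_a": dv_a,
        "decision_values_b": dv_b,
        "roc_points": np.column_stack([fpr, tpr]),
        "auc": auc,
        "p": _perm_p(null, accuracy, "greater"),
        "n_perm": n_perm,
    }


class LosoPatternDecoder(BaseEstimator):
    """sklearn-style wrapper around :func:`loso_decode`.

    Parameters: ``C`` (SVM slack), ``n_perm``, ``seed``. Fitted attributes:
    ``accuracy_``, ``auc_``, ``p_value_``, ``roc_points_``, ``result_``.
    """

    def __init__(self, C: float = 1.0, n_perm: int = 5000, seed: int = 0):
        self.C = C
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, patterns_a: PatternMatrix, patterns_b: PatternMatrix):
        self.result_ = loso_decode(
            patterns_a, patterns_b, c_value=self.C, n_perm=self.n_perm, seed=self.seed
        )
        self.accuracy_ = self.result_["forced_choice_accuracy"]
        self.auc_ = self.result_["auc"]
        self.p_value_ = self.result_["p"]
        self.roc_points_ = self.result_["roc_points"]
        return self
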
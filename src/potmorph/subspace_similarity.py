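"""Cross-projection similarity between per-trial morphogenetic subspaces.

Each trial's sequence of 60-D coefficient vectors is analyzed by its own PCA;
V1 is the variance captured by the trial's top-3 axes.  Projecting trial A's
(own-mean-centered) data onto trial B's top-3 axes captures variance V2, and
the ratio V2/V1 measures how well B's subspace accounts for A's path.  The
symmetrized average of the two directions is the subspace similarity S, and
D = 1 - S the dissimilarity used for permutation tests and dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dissimilarity import DissimilarityMatrix
from .efa import CoefficientVector
from .errors import DegenerateInputError, InsufficientRankError, ValidationError

__all__ = [
    "TrialSubspace",
    "trial_subspace",
    "cross_projection",
    "similarity",
    "dissimilarity_matrix",
]

MIN_OUTLINES = 4  # below this a 3-D trial subspace is rank-deficient


@dataclass
class TrialSubspace:
    """Top-k orthonormal axes of one trial's own coefficient sequence."""

    label: object
    basis: np.ndarray        # (k, 60), rows orthonormal
    own_mean: np.ndarray     # (60,)
    v1: float                # variance captured by the trial's own top-k axes
    total_variance: float


def _data_matrix(data) -> np.ndarray:
    if isinstance(data, np.ndarray):
        X = np.asarray(data, float)
    else:
        X = np.vstack([v.values if isinstance(v, CoefficientVector) else np.asarray(v, float)
                       for v in data])
    if X.ndim != 2:
        raise ValidationError("trial data must be a 2-D (outlines x coefficients) array")
    return X


def trial_subspace(data, label=None, k: int = 3) -> TrialSubspace:
    """PCA of one trial's outline sequence; V1 = sum of the top-k eigenvalues
    (population variance convention, divide by n)."""
    X = _data_matrix(data)
    n = len(X)
    if n < MIN_OUTLINES:
        raise InsufficientRankError(
            f"trial {label!r} has {n} outlines; >= {MIN_OUTLINES} required "
            "for a 3-D morphogenetic subspace"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / n
    total = float(var.sum())
    v1 = float(var[:k].sum())
    return TrialSubspace(label=label, basis=Vt[:k], own_mean=mean, v1=v1,
                         total_variance=total)


def cross_projection(data_a, sub_a: TrialSubspace, sub_b: TrialSubspace) -> float:
    """V2/V1 for trial A projected onto trial B's axes.

    A's data are centered by A's own mean (B contributes directions only), so
    the ratio compares orientations of scatter, not locations.  By PCA
    optimality of A's own basis, the ratio lies in [0, 1].
    """
    if sub_a.v1 <= 0:
        raise DegenerateInputError(f"trial {sub_a.label!r} has zero variance")
    if sub_a.basis.shape != sub_b.basis.shape:
        raise ValidationError("subspace dimensionalities do not match")
    X = _data_matrix(data_a)
    Xc = X - sub_a.own_mean
    scores = Xc @ sub_b.basis.T
    v2 = float(np.sum(scores**2) / len(X))
    ratio = v2 / sub_a.v1
    # numerical guard: V2 <= V1 analytically
    return min(ratio, 1.0)


def similarity(data_a, sub_a: TrialSubspace, data_b, sub_b: TrialSubspace) -> float:
    """Symmetrized cross-projection index S in [0, 1]."""
    r_ab = cross_projection(data_a, sub_a, sub_b)
    r_ba = cross_projection(data_b, sub_b, sub_a)
    return (r_ab + r_ba) / 2.0


def dissimilarity_matrix(trial_data: dict, k: int = 3) -> DissimilarityMatrix:
    """Pairwise D = 1 - S over all trials.

    ``trial_data`` maps a hashable trial label to that trial's (n_outlines x
    60) coefficient matrix.  Trials with fewer than 4 outlines are excluded
    with a warning naming them.
    """
    usable, excluded = {}, []
    for label, data in trial_data.items():
        X = _data_matrix(data)
        if len(X) < MIN_OUTLINES:
            excluded.append(label)
        else:
            usable[label] = X
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} trial(s) with < {MIN_OUTLINES} outlines "
            f"from the subspace analysis: {excluded}",
            UserWarning, stacklevel=2,
        )
    if len(usable) < 2:
        raise ValidationError("need at least 2 usable trials")

    labels = list(usable)
    subs = {lab: trial_subspace(usable[lab], label=lab, k=k) for lab in labels}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = similarity(usable[labels[i]], subs[labels[i]],
                           usable[labels[j]], subs[labels[j]])
            D[i, j] = D[j, i] = 1.0 - s
    return DissimilarityMatrix(labels=labels, values=D)
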
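"""Pooled PCA shape space, morphogenetic trajectories, and stage snapshots.

All size-normalized coefficient vectors (every outline of every trial, pooled)
define one covariance-based PCA; each outline is then a point in that space
and each trial an ordered trajectory from preform to final form.  Separate
per-stage PCAs (preform / middle / final) support stage-specific shape maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .efa import CoefficientVector
from .errors import PotmorphError, ValidationError
from .profile_io import TrialRecord, percent_time

__all__ = [
    "ShapeSpace",
    "Trajectory",
    "fit_shape_space",
    "project",
    "make_trajectory",
    "stage_index",
    "stage_extract",
    "fit_stage_space",
    "STAGES",
]

STAGES = ("preform", "middle", "final")


class LowRankWarning(UserWarning):
    pass


@dataclass
class ShapeSpace:
    """Centered orthonormal axes of the pooled coefficient data.

    ``loadings`` has one axis per row, ordered by decreasing variance;
    ``explained_variance`` is the per-axis fraction of total variance
    (summing to 1 over all axes)."""

    mean_vector: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    n_samples: int

    @property
    def n_axes(self) -> int:
        return len(self.loadings)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mean_vector": self.mean_vector.tolist(),
                "loadings": self.loadings.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "n_samples": self.n_samples,
            }, fh)

    @classmethod
    def from_json(cls, path) -> "ShapeSpace":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean_vector=np.array(d["mean_vector"]),
                   loadings=np.array(d["loadings"]),
                   explained_variance=np.array(d["explained_variance"]),
                   n_samples=int(d["n_samples"]))


@dataclass
class Trajectory:
    """Time-ordered shape-space points of one trial."""

    community: str
    potter_id: str
    vessel_type: str
    clay_mass_kg: float
    trial_number: int
    points: np.ndarray
    percent_times: np.ndarray

    @property
    def key(self) -> tuple:
        return (self.community, self.potter_id, self.vessel_type,
                self.clay_mass_kg, self.trial_number)


def _as_matrix(vectors) -> np.ndarray:
    rows = [v.values if isinstance(v, CoefficientVector) else np.asarray(v, float)
            for v in vectors]
    X = np.vstack(rows)
    if np.isnan(X).any():
        raise ValidationError("coefficient data contain missing values")
    return X


def fit_shape_space(vectors) -> ShapeSpace:
    """Covariance PCA of the pooled 60-D coefficient data.

    Axes carry a deterministic sign convention (the largest-magnitude loading
    element of each axis is positive) so trajectories are reproducible across
    runs and platforms.
    """
    X = _as_matrix(vectors)
    n = len(X)
    if n < 4:
        raise ValidationError(f"need >= 4 vectors to fit a shape space, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / n  # population convention
    # variances at numerical-noise level (relative to the data magnitude)
    # count as exactly zero so degenerate inputs report zero variance
    tol = (np.finfo(float).eps * max(1.0, float(np.abs(X).max())) * n) ** 2
    var = np.where(var > tol, var, 0.0)
    total = var.sum()
    if total <= 0:
        frac = np.zeros_like(var)
    else:
        frac = var / total
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) and s[0] > 0 else 0
    if rank < 3:
        warnings.warn(f"pooled data have rank {rank} < 3", LowRankWarning,
                      stacklevel=2)
    # deterministic sign: largest |loading| entry positive per axis
    for i in range(len(Vt)):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    return ShapeSpace(mean_vector=mean, loadings=Vt, explained_variance=frac,
                      n_samples=n)


def project(space: ShapeSpace, vector, k: int = 3) -> np.ndarray:
    """Coordinates of a coefficient vector on the first k axes."""
    if k > space.n_axes:
        raise ValidationError(f"k={k} exceeds {space.n_axes} available axes")
    v = vector.values if isinstance(vector, CoefficientVector) else np.asarray(vector, float)
    if v.shape != space.mean_vector.shape:
        raise ValidationError("vector dimension does not match the shape space")
    return space.loadings[:k] @ (v - space.mean_vector)


def transform(space: ShapeSpace, vectors, k: int = 3) -> np.ndarray:
    X = _as_matrix(vectors)
    return (X - space.mean_vector) @ space.loadings[:k].T


def make_trajectory(trial: TrialRecord, coeffs, space: ShapeSpace,
                    k: int = 3) -> Trajectory:
    """Project one trial's per-outline coefficient vectors into shape space."""
    if len(coeffs) != trial.n_outlines:
        raise PotmorphError(
            f"trial {trial.key}: {len(coeffs)} coefficient vectors for "
            f"{trial.n_outlines} outlines"
        )
    pts = transform(space, coeffs, k=k)
    return Trajectory(community=trial.community, potter_id=trial.potter_id,
                      vessel_type=trial.vessel_type,
                      clay_mass_kg=trial.clay_mass_kg,
                      trial_number=trial.trial_number,
                      points=pts, percent_times=percent_time(trial))


def stage_index(n_outlines: int, stage: str) -> int:
    """Outline index for a stage: preform = 0, final = last, middle = the
    gesture-count midpoint round((n-1)/2) with the half-up rule."""
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if stage == "preform":
        return 0
    if stage == "final":
        return n_outlines - 1
    if n_outlines == 2:
        warnings.warn("middle stage of a 2-outline trial is degenerate",
                      UserWarning, stacklevel=2)
    return int(np.floor((n_outlines - 1) / 2.0 + 0.5))


def stage_extract(trial: TrialRecord, coeffs, stage: str) -> CoefficientVector:
    """The coefficient vector of one trial at one stage."""
    idx = stage_index(trial.n_outlines, stage)
    v = coeffs[idx]
    return v if isinstance(v, CoefficientVector) else CoefficientVector(values=np.asarray(v))


def fit_stage_space(snapshots) -> ShapeSpace:
    """Independent PCA of one stage's snapshot vectors (used 2-D)."""
    return fit_shape_space(snapshots)


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for p, t in zip(tr.points, tr.percent_times):
            row = {"community": tr.community, "potter_id": tr.potter_id,
                   "vessel_type": tr.vessel_type,
                   "clay_mass_kg": tr.clay_mass_kg,
                   "trial": tr.trial_number, "percent_time": t}
            for i, val in enumerate(p, start=1):
                row[f"pc{i}"] = val
            rows.append(row)
    return pd.DataFrame(rows)
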
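"""Reading, calibrating, resampling, smoothing and mirroring digitized half-profiles.

A wheel-thrown vessel is axisymmetric, so its cross-section is fully described
by the right half-profile: an ordered sequence of (x, y) points with x >= 0,
traced from the rim down to the base (or vice versa).  This module turns such
half-profiles into closed, bilaterally symmetric outlines suitable for
elliptical Fourier analysis, and computes simple per-vessel quantities
(height, maximum diameter, percent time within a trial).

Units: raw profiles are in pixels; calibrated profiles and outlines in cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import interp1d

from .errors import DegenerateInputError, DomainError, ValidationError

__all__ = [
    "RawProfile",
    "CalibratedProfile",
    "Outline",
    "TrialRecord",
    "calibrate",
    "resample_profile",
    "smooth_profile",
    "close_outline",
    "vessel_dimensions",
    "percent_time",
    "read_trials",
    "write_trials",
]

#: Canonical community codes and vessel-type names used by the study design.
COMMUNITIES = ("PR", "MK", "FR")
VESSEL_TYPES = ("cylinder", "bowl", "sphere", "vase")

CSV_COLUMNS = [
    "potter_id",
    "community",
    "vessel_type",
    "clay_mass_kg",
    "trial",
    "gesture_index",
    "elapsed_time_s",
    "point_index",
    "x",
    "y",
]

_AXIS_TOL = 1e-7  # cm; a point with |x| below this sits on the symmetry axis


@dataclass
class RawProfile:
    """Digitized right half-profile in pixel coordinates.

    ``gesture_index`` 0 denotes the preform (the profile right after the
    centering-and-opening phase); ``elapsed_time`` is seconds from the onset
    of the forming phase.
    """

    points: np.ndarray
    gesture_index: int
    elapsed_time: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("profile points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValidationError("a profile needs at least 3 points")
        if np.any(self.points[:, 0] < 0):
            raise ValidationError("right half-profile must have x >= 0")
        if self.gesture_index < 0:
            raise ValidationError("gesture_index must be >= 0")


@dataclass
class CalibratedProfile:
    """Half-profile in cm.  ``parameterization`` records how the points are
    spaced: ``"y"`` for a regular grid along the vertical axis (x single-valued
    in y) or ``"arclength"`` for profiles that overhang and were resampled
    along normalized arc length instead."""

    points: np.ndarray
    parameterization: str = "y"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("profile points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValidationError("a calibrated profile needs at least 2 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class Outline:
    """Closed, bilaterally symmetric contour of a vessel at one gesture.

    ``points`` traverses the right edge from the on-axis rim point downward,
    then the mirrored left edge back up; the last point repeats the first.
    ``half`` keeps the generating half-profile so outlines can be written
    back to the long-format table losslessly.
    """

    points: np.ndarray
    start_index: int = 0
    orientation: str = "clockwise"
    gesture_index: int = 0
    elapsed_time: float = 0.0
    half: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not np.allclose(self.points[0], self.points[-1], atol=1e-12):
            raise ValidationError("outline must be closed (first point == last point)")

    @property
    def n_distinct(self) -> int:
        return len(self.points) - 1


@dataclass
class TrialRecord:
    """One throwing trial: an ordered sequence of outlines from preform to
    final form, with the design keys identifying it."""

    potter_id: str
    community: str
    vessel_type: str
    clay_mass_kg: float
    trial_number: int
    outlines: list[Outline]

    def __post_init__(self) -> None:
        if len(self.outlines) < 2:
            raise ValidationError(
                f"trial {self.key} needs at least 2 outlines (preform and final)"
            )
        times = self.elapsed_times
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"elapsed times must be strictly increasing in trial {self.key}"
            )

    @property
    def key(self) -> tuple:
        return (
            self.community,
            self.potter_id,
            self.vessel_type,
            self.clay_mass_kg,
            self.trial_number,
        )

    @property
    def elapsed_times(self) -> np.ndarray:
        return np.array([o.elapsed_time for o in self.outlines], dtype=float)

    @property
    def duration(self) -> float:
        return float(self.outlines[-1].elapsed_time)

    @property
    def n_outlines(self) -> int:
        return len(self.outlines)


def calibrate(profile: RawProfile, factor: float) -> CalibratedProfile:
    """Convert a pixel-space profile to cm with a cm-per-pixel factor."""
    if factor <= 0:
        raise DomainError(f"calibration factor must be > 0, got {factor}")
    return CalibratedProfile(points=profile.points * factor)


def resample_profile(profile: CalibratedProfile, n: int = 256) -> CalibratedProfile:
    """Resample to ``n`` points at regular intervals along the vertical axis.

    If the profile overhangs (x is multivalued in y, e.g. a necked vase) it is
    instead resampled at regular intervals of normalized arc length and the
    result flagged with ``parameterization="arclength"``.
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    pts = profile.points
    y = pts[:, 1]
    if np.ptp(y) <= 0:
        raise DegenerateInputError("profile has zero height; cannot resample")

    dy = np.diff(y)
    if np.all(dy > 0) or np.all(dy < 0):
        if np.all(dy < 0):
            pts = pts[::-1]
            y = pts[:, 1]
        grid = np.linspace(y[0], y[-1], n)
        x_new = interp1d(y, pts[:, 0], kind="linear")(grid)
        return CalibratedProfile(points=np.column_stack([x_new, grid]),
                                 parameterization="y")

    # overhanging profile: arc-length parameterization
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise DegenerateInputError("profile has zero length")
    grid = np.linspace(0.0, s[-1], n)
    x_new = interp1d(s, pts[:, 0])(grid)
    y_new = interp1d(s, pts[:, 1])(grid)
    return CalibratedProfile(points=np.column_stack([x_new, y_new]),
                             parameterization="arclength")


def smooth_profile(profile: CalibratedProfile, cutoff: float = 0.1) -> CalibratedProfile:
    """Zero-phase second-order low-pass filter of the x series.

    ``cutoff`` is a fraction of the point-index sampling rate (0 < cutoff < 0.5).
    The filter is applied forward and backward (no phase shift) with reflective
    padding so the endpoints are preserved; the y grid is untouched.
    """
    if not 0 < cutoff < 0.5:
        raise DomainError(f"cutoff must be in (0, 0.5), got {cutoff}")
    b, a = signal.butter(2, cutoff / 0.5)
    x = signal.filtfilt(b, a, profile.points[:, 0], padtype="even")
    return CalibratedProfile(points=np.column_stack([x, profile.points[:, 1]]),
                             parameterization=profile.parameterization)


def close_outline(
    profile: CalibratedProfile,
    gesture_index: int = 0,
    elapsed_time: float = 0.0,
    axis_tol: float = _AXIS_TOL,
) -> Outline:
    """Mirror a half-profile about x = 0 into a closed outline.

    The contour starts at the on-axis rim point and traverses the right edge
    downward (clockwise), then the mirrored left edge upward.  On-axis
    endpoint duplicates are merged, so a half-profile with both endpoints on
    the axis and n points yields 2n - 2 distinct contour points plus the
    closing repeat of the start point.
    """
    pts = profile.points
    if np.any(pts[:, 0] < -axis_tol):
        raise ValidationError("half-profile has x < 0; not a right half")
    pts = pts.copy()
    pts[np.abs(pts[:, 0]) <= axis_tol, 0] = 0.0
    if pts[0, 1] < pts[-1, 1]:  # orient rim (max y) first
        pts = pts[::-1]

    left = pts[::-1] * np.array([-1.0, 1.0])
    # merge duplicated on-axis endpoints: drop left copies of shared points
    if pts[-1, 0] == 0.0:
        left = left[1:]
    if pts[0, 0] == 0.0:
        left = left[:-1]
    contour = np.vstack([pts, left, pts[:1]])
    return Outline(points=contour, start_index=0, orientation="clockwise",
                   gesture_index=gesture_index, elapsed_time=elapsed_time,
                   half=pts)


def vessel_dimensions(profile: CalibratedProfile) -> tuple[float, float]:
    """(height, max_diameter) in cm: height = y range, diameter = 2 * max x."""
    y = profile.points[:, 1]
    x = profile.points[:, 0]
    return float(y.max() - y.min()), float(2.0 * x.max())


def percent_time(trial: TrialRecord) -> np.ndarray:
    """Map elapsed times linearly onto [0, 100] percent of the shaping phase."""
    t = trial.elapsed_times
    span = t[-1] - t[0]
    if span <= 0:
        raise DegenerateInputError(f"trial {trial.key} has zero duration")
    return (t - t[0]) / span * 100.0


# ---------------------------------------------------------------------------
# long-format file I/O


def _trial_from_group(keys: tuple, grp: pd.DataFrame,
                      resample_n: int | None, smooth_cutoff: float | None) -> TrialRecord:
    community, potter, vtype, mass, trial_no = keys
    outlines = []
    gestures = grp.sort_values(["gesture_index", "point_index"])
    times = gestures.groupby("gesture_index")["elapsed_time_s"].first()
    if np.any(np.diff(times.values) <= 0):
        raise ValidationError(
            f"elapsed_time_s not strictly increasing for trial "
            f"{community}/{potter}/{vtype}/{mass}/{trial_no}"
        )
    for gi, g in gestures.groupby("gesture_index"):
        prof = CalibratedProfile(points=g[["x", "y"]].to_numpy(dtype=float))
        if resample_n is not None:
            prof = resample_profile(prof, resample_n)
        if smooth_cutoff is not None:
            prof = smooth_profile(prof, smooth_cutoff)
        outlines.append(close_outline(prof, gesture_index=int(gi),
                                      elapsed_time=float(g["elapsed_time_s"].iloc[0])))
    return TrialRecord(potter_id=str(potter), community=str(community),
                       vessel_type=str(vtype), clay_mass_kg=float(mass),
                       trial_number=int(trial_no), outlines=outlines)


def read_trials(
    path,
    format: str | None = None,
    resample_n: int | None = 256,
    smooth_cutoff: float | None = None,
) -> list[TrialRecord]:
    """Read trials from a long-format CSV (one row per profile point) or the
    equivalent nested JSON.

    Half-profiles are resampled to ``resample_n`` points and closed into
    outlines.  Smoothing is opt-in here (``smooth_cutoff=None``) so that a
    write/read round-trip is exact; the pipeline ingest stage applies the
    documented default cutoff.
    """
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "csv"
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        rows = []
        for tr in payload["trials"]:
            for g in tr["gestures"]:
                for i, (x, y) in enumerate(g["points"]):
                    rows.append(
                        (tr["potter_id"], tr["community"], tr["vessel_type"],
                         tr["clay_mass_kg"], tr["trial"], g["gesture_index"],
                         g["elapsed_time_s"], i, x, y))
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    elif format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surfaced with context
            raise ValidationError(f"could not parse {path}: {exc}") from exc
    else:
        raise DomainError(f"unknown format {format!r}")

    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path} is missing required columns: {missing}")
    bad = df[CSV_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise ValidationError(
            f"{path}: rows with missing values at index {df.index[bad][:5].tolist()}"
        )

    trials = []
    for keys, grp in df.groupby(
        ["community", "potter_id", "vessel_type", "clay_mass_kg", "trial"], sort=True
    ):
        trials.append(_trial_from_group(keys, grp, resample_n, smooth_cutoff))
    return trials


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Long-format table of the half-profiles of every outline."""
    frames = []
    for tr in trials:
        for out in tr.outlines:
            half = out.half
            if half is None:
                # recover the right edge from the closed contour
                n_half = (len(out.points) + 1) // 2
                half = out.points[:n_half]
            frames.append(pd.DataFrame({
                "potter_id": tr.potter_id,
                "community": tr.community,
                "vessel_type": tr.vessel_type,
                "clay_mass_kg": tr.clay_mass_kg,
                "trial": tr.trial_number,
                "gesture_index": out.gesture_index,
                "elapsed_time_s": out.elapsed_time,
                "point_index": np.arange(len(half)),
                "x": half[:, 0],
                "y": half[:, 1],
            }))
    return pd.concat(frames, ignore_index=True)


def write_trials(trials: list[TrialRecord], path, format: str | None = None) -> None:
    """Write trials in the long-format schema consumed by :func:`read_trials`."""
    path = str(path)
    if format is None:
        format = "json" if path.endswith(".json") else "csv"
    df = trials_to_frame(trials)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        payload = {"trials": []}
        for keys, grp in df.groupby(
            ["community", "potter_id", "vessel_type", "clay_mass_kg", "trial"], sort=True
        ):
            community, potter, vtype, mass, trial_no = keys
            gestures = []
            for gi, g in grp.groupby("gesture_index"):
                gestures.append({
                    "gesture_index": int(gi),
                    "elapsed_time_s": float(g["elapsed_time_s"].iloc[0]),
                    "points": g.sort_values("point_index")[["x", "y"]].to_numpy().tolist(),
                })
            payload["trials"].append({
                "potter_id": str(potter), "community": str(community),
                "vessel_type": str(vtype), "clay_mass_kg": float(mass),
                "trial": int(trial_no), "gestures": gestures,
            })
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        raise DomainError(f"unknown format {format!r}")


def dimensions_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """Final-form height / maximum diameter and duration per trial (the
    descriptive summary of the study design table)."""
    rows = []
    for tr in trials:
        half = tr.outlines[-1].half
        prof = CalibratedProfile(points=half)
        h, md = vessel_dimensions(prof)
        rows.append({
            "community": tr.community, "potter_id": tr.potter_id,
            "vessel_type": tr.vessel_type, "clay_mass_kg": tr.clay_mass_kg,
            "trial": tr.trial_number, "height_cm": h, "max_diameter_cm": md,
            "duration_s": tr.duration, "n_outlines": tr.n_outlines,
        })
    return pd.DataFrame(rows)
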
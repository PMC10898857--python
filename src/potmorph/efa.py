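"""Elliptical Fourier analysis of closed vessel outlines.

A closed contour (x(t), y(t)), parameterized by cumulative chord length t over
one traversal of total length T, is decomposed into harmonic ellipses

    x(t) = A0 + sum_n [ a_n cos(2*pi*n*t/T) + b_n sin(2*pi*n*t/T) ]
    y(t) = C0 + sum_n [ c_n cos(2*pi*n*t/T) + d_n sin(2*pi*n*t/T) ]

with the Kuhl-Giardina closed-form coefficients for a piecewise-linear
contour.  For a bilaterally symmetric outline whose traversal starts at the
on-axis rim point (x odd in t, y even in t), the a_n and d_n vanish, leaving
30 coefficient pairs (b_n, c_n) per outline.  Dividing the 60 retained values
by the magnitude of the first pair removes size, so pure shape remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DomainError, ValidationError
from .profile_io import Outline

__all__ = [
    "EFACoefficients",
    "CoefficientVector",
    "elliptic_fourier",
    "symmetry_reduce",
    "size_normalize",
    "coefficient_vector",
    "reconstruct",
    "SymmetryWarning",
]

DEFAULT_HARMONICS = 30


class SymmetryWarning(UserWarning):
    """Raised when the symmetry-suppressed coefficients are not negligible."""


@dataclass
class EFACoefficients:
    """Full Kuhl-Giardina coefficients: ``harmonics[n-1] = (a_n, b_n, c_n, d_n)``
    plus the centroid terms ``dc_terms = (A0, C0)``."""

    harmonics: np.ndarray
    dc_terms: tuple[float, float]

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def ellipse_magnitudes(self) -> np.ndarray:
        """Semi-major axis length of each harmonic ellipse (largest singular
        value of the per-harmonic 2x2 coefficient matrix)."""
        h = self.harmonics
        # singular values of [[a, b], [c, d]]
        a, b, c, d = h[:, 0], h[:, 1], h[:, 2], h[:, 3]
        q = a * a + b * b + c * c + d * d
        det = a * d - b * c
        disc = np.sqrt(np.maximum(q * q - 4 * det * det, 0.0))
        return np.sqrt(np.maximum((q + disc) / 2.0, 0.0))


@dataclass
class ReducedCoefficients:
    """The 30 symmetry-retained pairs (b_n, c_n) and a QC measure: the largest
    suppressed-coefficient magnitude relative to the first-harmonic magnitude."""

    pairs: np.ndarray
    qc_asymmetry: float


@dataclass
class CoefficientVector:
    """60-D size-normalized shape descriptor: 30 pairs flattened as
    (b_1, c_1, b_2, c_2, ...)."""

    values: np.ndarray
    convention: str = "pair_norm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_pairs(self) -> int:
        return len(self.values) // 2


def elliptic_fourier(outline: Outline, n_harmonics: int = DEFAULT_HARMONICS,
                     parameterization: str = "chord") -> EFACoefficients:
    """Kuhl-Giardina elliptical Fourier coefficients of a closed outline.

    ``parameterization="chord"`` (default) uses cumulative chord length as
    the traversal parameter, the standard closed-contour convention;
    ``"uniform"`` assigns equal parameter increments to every segment, under
    which a conic sampled at equal angles is exactly single-harmonic.
    """
    pts = outline.points
    if not np.allclose(pts[0], pts[-1], atol=1e-12):
        raise ValidationError("outline must be closed")
    if len(pts) - 1 < 2 * n_harmonics + 1:
        raise ValidationError(
            f"outline with {len(pts) - 1} distinct points undersamples "
            f"{n_harmonics} harmonics (need >= {2 * n_harmonics + 1})"
        )
    d = np.diff(pts, axis=0)
    chord = np.hypot(d[:, 0], d[:, 1])
    keep = chord > 0
    if parameterization == "chord":
        dt = chord[keep]
    elif parameterization == "uniform":
        dt = np.ones(int(keep.sum()))
    else:
        raise DomainError(f"unknown parameterization {parameterization!r}")
    d = d[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise DegenerateInputError("outline has zero perimeter")

    n = np.arange(1, n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :] / T
    cos, sin = np.cos(phi), np.sin(phi)
    dcos = cos[:, 1:] - cos[:, :-1]
    dsin = sin[:, 1:] - sin[:, :-1]
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    const = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)

    # centroid terms: exact integrals of the piecewise-linear contour
    mid = (pts[:-1][keep] + pts[1:][keep]) / 2.0
    A0 = float(np.sum(mid[:, 0] * dt) / T)
    C0 = float(np.sum(mid[:, 1] * dt) / T)
    return EFACoefficients(harmonics=np.column_stack([a, b, c, dd]),
                           dc_terms=(A0, C0))


def symmetry_reduce(coeffs: EFACoefficients, warn_ratio: float = 1e-3) -> ReducedCoefficients:
    """Retain the (b_n, c_n) pairs of a bilaterally symmetric outline.

    With the fixed on-axis start point, x(t) is odd and y(t) even in the
    traversal parameter, so the a_n and d_n must vanish; their largest
    magnitude relative to the first-harmonic magnitude is recorded as a QC
    metric and a :class:`SymmetryWarning` is raised if it exceeds
    ``warn_ratio``.
    """
    h = coeffs.harmonics
    pairs = h[:, [1, 2]]  # (b_n, c_n)
    ref = float(np.hypot(*pairs[0]))
    if ref <= 0:
        raise DegenerateInputError("first-harmonic magnitude is zero")
    suppressed = float(np.max(np.abs(h[:, [0, 3]])))
    qc = suppressed / ref
    if qc > warn_ratio:
        warnings.warn(
            f"outline deviates from bilateral symmetry: suppressed-coefficient "
            f"ratio {qc:.2e} exceeds {warn_ratio:.0e}",
            SymmetryWarning, stacklevel=2,
        )
    return ReducedCoefficients(pairs=pairs, qc_asymmetry=qc)


def size_normalize(reduced: ReducedCoefficients | np.ndarray,
                   convention: str = "pair_norm") -> CoefficientVector:
    """Divide all retained coefficients by a first-harmonic size measure.

    ``convention="pair_norm"`` (default) divides by the Euclidean norm of the
    first retained pair, making the normalized first pair a unit vector;
    ``"semi_major"`` divides by the first harmonic's semi-major axis length.
    Either way the result is invariant to uniform scaling of the outline.
    """
    pairs = reduced.pairs if isinstance(reduced, ReducedCoefficients) else np.asarray(reduced)
    if convention == "pair_norm":
        scale = float(np.hypot(*pairs[0]))
    elif convention == "semi_major":
        b1, c1 = pairs[0]
        # symmetric outline first-harmonic matrix [[0, b1], [c1, 0]]
        scale = float(max(abs(b1), abs(c1)))
    else:
        raise DomainError(f"unknown normalization convention {convention!r}")
    if scale <= 0:
        raise DegenerateInputError("degenerate shape: zero first harmonic")
    return CoefficientVector(values=(pairs / scale).ravel(), convention=convention)


def coefficient_vector(outline: Outline, n_harmonics: int = DEFAULT_HARMONICS,
                       convention: str = "pair_norm") -> CoefficientVector:
    """Outline -> size-normalized 60-D descriptor in one call."""
    return size_normalize(symmetry_reduce(elliptic_fourier(outline, n_harmonics)),
                          convention=convention)


def reconstruct(coeffs: EFACoefficients, n_points: int = 256) -> Outline:
    """Sample the harmonic series at ``n_points`` equal parameter steps."""
    if n_points < 8:
        raise DomainError("n_points must be >= 8")
    t = np.linspace(0.0, 1.0, n_points + 1)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phi), np.sin(phi)
    h = coeffs.harmonics
    x = coeffs.dc_terms[0] + h[:, 0] @ cos + h[:, 1] @ sin
    y = coeffs.dc_terms[1] + h[:, 2] @ cos + h[:, 3] @ sin
    x[-1], y[-1] = x[0], y[0]
    return Outline(points=np.column_stack([x, y]))
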
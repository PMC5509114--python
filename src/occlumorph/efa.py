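"""Elliptical Fourier analysis (EFA) of closed outlines.

A closed planar outline is represented by the parametric model

    x(t) = A0 + sum_j  a_j cos(j t) + b_j sin(j t)
    y(t) = C0 + sum_j  c_j cos(j t) + d_j sin(j t),      t in [0, 2*pi)

where ``H`` harmonics are retained and ``(a_j, b_j, c_j, d_j)`` are the
amplitudes of harmonic ``j``.  The coefficients are estimated with the
classical closed-form expressions for a chord-length-parameterized
piecewise-linear contour, which are exact for polygonal input.

After estimation, outlines produced by different tracings of the same
tooth differ in their start vertex and orientation.  :func:`normalize`
removes both with the standard first-harmonic normalization so that
landmarks regenerated with :func:`efa_inverse` start at a canonical
location and are homologous across tracings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EFADecomposition",
    "LandmarkSet",
    "FeatureVector",
    "efa_forward",
    "normalize",
    "efa_inverse",
    "features",
    "harmonic_power",
    "cumulative_power",
]

START_CONVENTION = "first-harmonic-semi-major-axis"


@dataclass(frozen=True)
class EFADecomposition:
    """EFA coefficients of one closed outline.

    Attributes
    ----------
    A0, C0 : float
        Constant (centroid) terms of the x(t) and y(t) series.
    coeffs : ndarray of shape (H, 4)
        Rows are the per-harmonic quadruples ``(a_j, b_j, c_j, d_j)``.
    normalized : bool
        Whether the first-harmonic start-point/orientation
        normalization has been applied.
    """

    A0: float
    C0: float
    coeffs: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.ndim != 2 or coeffs.shape[1] != 4 or coeffs.shape[0] < 1:
            raise ValueError("coeffs must have shape (H, 4) with H >= 1")
        if not (np.isfinite(coeffs).all() and np.isfinite([self.A0, self.C0]).all()):
            raise ValueError("EFA coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def H(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class LandmarkSet:
    """K ordered (x, y) landmarks regenerated from an EFA fit.

    Point ``K`` connects back to point ``1``; when produced from a
    normalized decomposition, point ``1`` sits at the canonical start so
    that the k-th landmark is homologous across tracings of one tooth.
    """

    points: np.ndarray
    start_convention: str = START_CONVENTION

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("points must have shape (K, 2) with K >= 3")
        if not np.isfinite(pts).all():
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """Flattened harmonic amplitudes used as classifier input."""

    values: np.ndarray
    label: str | None = None
    specimen_id: str | None = None


def _closed_edges(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge vectors and chord lengths of the closed polyline, with
    duplicate consecutive vertices (zero-length edges) removed."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour points must have shape (N, 2)")
    if len(pts) >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    if keep.sum() < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct vertices")
    pts = pts[keep]
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    return pts, dt


def efa_forward(points: np.ndarray | "object", H: int,
                parameterization: str = "chord") -> EFADecomposition:
    """Fit ``H`` harmonics to a closed contour.

    Parameters
    ----------
    points : (N, 2) array or object with a ``.points`` attribute
        Vertices of the closed contour (the closing edge from the last
        vertex back to the first is implicit).
    H : int
        Number of harmonics (``>= 1``; capped at ``floor(N / 2)`` for
        the uniform parameterization).
    parameterization : {"chord", "uniform"}
        ``"chord"`` (default) parameterizes the contour by cumulative
        chord length — the classical elliptic-Fourier-descriptor
        estimator, exact for polygonal input and independent of how
        densely each stretch of the outline was sampled.  ``"uniform"``
        assigns equal parameter increments per vertex; it recovers the
        generating coefficients exactly when the vertices are samples
        of the parametric model at uniform ``t``.

    Notes
    -----
    ``A0``/``C0`` are the exact parameterization centroid of the
    piecewise-linear curve; the harmonic quadruples are the closed-form
    Fourier coefficients of that curve.  The initial vertex of the
    listing only shifts the phase of the coefficients, so per-harmonic
    power is unaffected and :func:`normalize` removes the shift
    entirely.
    """
    if hasattr(points, "points"):
        points = points.points
    pts, dt = _closed_edges(np.asarray(points, dtype=float))
    n = len(pts)
    H = int(H)
    if H < 1:
        raise ValueError(f"H must be >= 1, got {H}")
    if parameterization == "uniform":
        # vertices are treated as uniform samples of the model, so
        # harmonics beyond the Nyquist index are not identifiable
        if H > n // 2:
            raise ValueError(f"uniform parameterization requires "
                             f"H <= floor(n/2) = {n // 2}, got {H}")
        dt = np.full(n, 2.0 * np.pi / n)
    elif parameterization != "chord":
        raise ValueError("parameterization must be 'chord' or 'uniform'")

    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T                      # (n+1,)
    dxy = np.diff(np.vstack([pts, pts[:1]]), axis=0)  # (n, 2)
    slope = dxy / dt[:, None]                      # dx/dt, dy/dt per edge

    j = np.arange(1, H + 1)[:, None]               # (H, 1)
    dcos = np.cos(j * phi[1:]) - np.cos(j * phi[:-1])  # (H, n)
    dsin = np.sin(j * phi[1:]) - np.sin(j * phi[:-1])
    scale = T / (2.0 * np.pi**2 * j[:, 0] ** 2)    # (H,)

    a = scale * (dcos @ slope[:, 0])
    b = scale * (dsin @ slope[:, 0])
    c = scale * (dcos @ slope[:, 1])
    d = scale * (dsin @ slope[:, 1])

    # DC terms: exact mean of the piecewise-linear curve over arc length.
    nxt = np.vstack([pts[1:], pts[:1]])
    mids = (pts + nxt) / 2.0
    A0, C0 = (dt @ mids) / T

    return EFADecomposition(A0=float(A0), C0=float(C0),
                            coeffs=np.column_stack([a, b, c, d]))


def _phase_shift(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the curve's start parameter by ``theta`` (t -> t + theta)."""
    H = coeffs.shape[0]
    out = np.empty_like(coeffs)
    for idx in range(H):
        j = idx + 1
        cj, sj = np.cos(j * theta), np.sin(j * theta)
        rot = np.array([[cj, -sj], [sj, cj]])
        m = coeffs[idx].reshape(2, 2) @ rot
        out[idx] = m.ravel()
    return out


def _frame_rotation(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the coordinate frame by ``-psi`` (shape rotates by -psi)."""
    cpsi, spsi = np.cos(psi), np.sin(psi)
    rot = np.array([[cpsi, spsi], [-spsi, cpsi]])
    return np.stack([(rot @ m.reshape(2, 2)).ravel() for m in coeffs])


def normalize(decomp: EFADecomposition) -> EFADecomposition:
    """Apply the standard first-harmonic normalization.

    The start parameter is shifted so that ``t = 0`` lands on the first
    harmonic ellipse's semi-major axis, and the coordinate frame is
    rotated so that this axis defines phase zero.  Afterwards
    ``b1 = c1 = 0`` and ``a1 > 0``.  Shape, as seen through regenerated
    landmarks and the Riemannian distance, is unchanged (the distance is
    rotation invariant); reflection is deliberately *not* normalized
    because mirrored outlines (left vs right teeth) are distinct shapes.
    """
    if decomp.normalized:
        return decomp
    a1, b1, c1, d1 = decomp.coeffs[0]
    if a1**2 + b1**2 + c1**2 + d1**2 <= 0.0:
        raise ValueError("degenerate first harmonic: cannot normalize")

    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1**2 - b1**2 + c1**2 - d1**2)
    coeffs = _phase_shift(decomp.coeffs, theta)
    # theta lands t=0 on one of the two conjugate semi-axes; pick the major.
    a1, b1, c1, d1 = coeffs[0]
    if a1**2 + c1**2 < b1**2 + d1**2:
        theta += np.pi / 2.0
        coeffs = _phase_shift(decomp.coeffs, theta)
        a1, b1, c1, d1 = coeffs[0]
    psi = np.arctan2(c1, a1)
    coeffs = _frame_rotation(coeffs, psi)
    if coeffs[0, 0] < 0:  # two-fold start ambiguity along the major axis
        theta += np.pi
        coeffs = _frame_rotation(_phase_shift(decomp.coeffs, theta), psi)
    # rotate the DC point into the same frame
    cpsi, spsi = np.cos(psi), np.sin(psi)
    A0 = cpsi * decomp.A0 + spsi * decomp.C0
    C0 = -spsi * decomp.A0 + cpsi * decomp.C0
    if coeffs[0, 0] < 0:
        raise AssertionError("normalization failed to achieve a1 > 0")
    return EFADecomposition(A0=float(A0), C0=float(C0), coeffs=coeffs,
                            normalized=True)


def efa_inverse(decomp: EFADecomposition, K: int = 150) -> LandmarkSet:
    """Regenerate ``K`` landmarks by evaluating the parametric model at
    ``t = 2*pi*k/K`` for ``k = 0..K-1``.

    With a normalized decomposition, point 0 is the canonical start, so
    landmark ``k`` is comparable across tracings.
    """
    K = int(K)
    if K < 3:
        raise ValueError("K must be >= 3")
    if not decomp.normalized:
        warnings.warn("regenerating landmarks from an unnormalized decomposition; "
                      "start point will be listing-dependent", stacklevel=2)
    t = 2.0 * np.pi * np.arange(K) / K
    j = np.arange(1, decomp.H + 1)[:, None]
    cos_jt = np.cos(j * t)                         # (H, K)
    sin_jt = np.sin(j * t)
    a, b, c, d = decomp.coeffs.T
    x = decomp.A0 + a @ cos_jt + b @ sin_jt
    y = decomp.C0 + c @ cos_jt + d @ sin_jt
    convention = START_CONVENTION if decomp.normalized else "listing-dependent"
    return LandmarkSet(points=np.column_stack([x, y]),
                       start_convention=convention)


def features(decomp: EFADecomposition,
             drop_normalized_entries: bool = False,
             label: str | None = None,
             specimen_id: str | None = None) -> FeatureVector:
    """Flatten the harmonic amplitudes into a classifier feature vector.

    With ``drop_normalized_entries=False`` the vector is
    ``(a_1, b_1, c_1, d_1, ..., a_H, ..., d_H)`` of length ``4H``; size
    information (teeth are pre-scaled to each other, so size carries
    signal) is retained.  With the flag set, all coefficients are
    divided by ``a_1`` and the normalization-pinned entries
    ``a_1 = 1, b_1 = 0, c_1 = 0`` are dropped, giving a size-invariant
    vector of length ``4H - 3``.
    """
    if not decomp.normalized:
        raise ValueError("features require a normalized decomposition")
    flat = decomp.coeffs.ravel().copy()
    if drop_normalized_entries:
        flat = flat / decomp.coeffs[0, 0]
        flat = flat[3:]
    return FeatureVector(values=flat, label=label, specimen_id=specimen_id)


def canonicalize(points: np.ndarray | "object", H: int = 10,
                 K: int = 150) -> LandmarkSet:
    """Fit, normalize and regenerate canonical-start landmarks.

    This is the homology-establishing step applied to every tracing
    before landmark-based comparison: the raw outline (whose listing
    start is arbitrary) is summarized by ``H`` harmonics and re-emitted
    as ``K`` landmarks beginning at the canonical start, so landmark
    ``k`` corresponds across tracings of the same tooth.
    """
    return efa_inverse(normalize(efa_forward(points, H=H)), K=K)


def harmonic_power(decomp: EFADecomposition) -> np.ndarray:
    """Per-harmonic power ``(a^2 + b^2 + c^2 + d^2) / 2``.

    Power is invariant to the contour's start vertex even before
    normalization, which makes it a convenient listing-independent
    summary of harmonic content.
    """
    return 0.5 * np.sum(decomp.coeffs**2, axis=1)


def cumulative_power(decomp: EFADecomposition) -> np.ndarray:
    """Cumulative fraction of total harmonic power, for choosing H.

    ``cumulative_power(d)[j-1] >= 0.99`` indicates that the first ``j``
    harmonics capture at least 99% of the outline's harmonic power.
    """
    p = harmonic_power(decomp)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total harmonic power")
    return np.cumsum(p) / total
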
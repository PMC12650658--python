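"""Least-squares fitting of a general quadric ellipsoid to 3-D points.

The nine coefficients of ``Ax² + By² + Cz² + Dxy + Exz + Fyz + Gx + Hy +
Iz = 1`` are obtained by linear least squares on the point coordinates;
center, semi-axes and rotation follow from the eigen-decomposition of the
centered quadric.  A spheroid summary reduces the three radii to a polar
radius plus the mean of the two most similar radii (equatorial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EllipsoidError(ValueError):
    """Degenerate input or a non-elliptic fitted quadric."""


@dataclass(frozen=True)
class EllipsoidFit:
    """Quadric coefficients plus the derived center/radii/rotation."""

    coefficients: np.ndarray  # (A, B, C, D, E, F, G, H, I)
    center: np.ndarray
    radii: np.ndarray  # sorted ascending
    rotation: np.ndarray  # columns are the axis directions, det = +1
    rss: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise EllipsoidError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise EllipsoidError("rotation must have determinant +1")
        if not np.all(np.asarray(self.radii) > 0):
            raise EllipsoidError("all radii must be positive")


@dataclass(frozen=True)
class SpheroidSummary:
    r_polar: float
    r_equatorial: float
    shape_class: str  # prolate | oblate | sphere
    axis_direction: np.ndarray


def fit_ellipsoid(points: np.ndarray) -> EllipsoidFit:
    """Fit the 9-coefficient general ellipsoid to a point cloud.

    Coefficients minimize ``Σ (Ax²+...+Iz - 1)²``.  Noiseless surface
    points of a true ellipsoid are recovered exactly.  Coplanar input or a
    fit whose quadric is not elliptic (mixed eigenvalue signs) raises
    :class:`EllipsoidError`.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n < 9:
        raise EllipsoidError(f"need at least 9 points, got {n}")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    design = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, float(np.abs(design).max()))) < 9:
        raise EllipsoidError("degenerate point set (coplanar or quadric-deficient)")
    ones = np.ones(n)
    coeffs, residuals, _, _ = np.linalg.lstsq(design, ones, rcond=None)
    rss = float(residuals[0]) if residuals.size else float(
        np.sum((design @ coeffs - ones) ** 2)
    )

    A, B, C, D, E, F, G, H, I = coeffs
    M = np.array([[A, D / 2, E / 2], [D / 2, B, F / 2], [E / 2, F / 2, C]])
    g = np.array([G, H, I])
    try:
        center = -0.5 * np.linalg.solve(M, g)
    except np.linalg.LinAlgError as exc:
        raise EllipsoidError("singular quadric matrix; cannot locate center") from exc
    # After translating to the center the quadric reads  y^T M y = s.
    s = 1.0 + center @ M @ center
    eigvals, eigvecs = np.linalg.eigh(M)
    if s <= 0 or np.any(eigvals <= 0):
        raise EllipsoidError(
            "fitted quadric is not an ellipsoid "
            f"(eigenvalue signs {np.sign(eigvals).astype(int).tolist()}, scale {s:.3g})"
        )
    radii = np.sqrt(s / eigvals)
    # eigh returns ascending eigenvalues -> radii descending; sort ascending.
    order = np.argsort(radii)
    radii = radii[order]
    rotation = eigvecs[:, order]
    if np.linalg.det(rotation) < 0:
        rotation = rotation.copy()
        rotation[:, 2] *= -1
    return EllipsoidFit(
        coefficients=coeffs,
        center=center,
        radii=radii,
        rotation=rotation,
        rss=rss,
    )


def spheroid_summary(fit: EllipsoidFit, sphere_tolerance: float = 0.02) -> SpheroidSummary:
    """Reduce three radii to polar/equatorial by averaging the two most
    similar radii; the remaining radius is polar.

    Ties are broken toward the pair with the smaller indices after the
    ascending sort.  ``shape_class`` is ``sphere`` when polar and
    equatorial agree within ``sphere_tolerance`` (relative).
    """
    r = np.asarray(fit.radii, float)
    pairs = [(0, 1), (0, 2), (1, 2)]
    diffs = [abs(r[i] - r[j]) for i, j in pairs]
    i, j = pairs[int(np.argmin(diffs))]
    k = ({0, 1, 2} - {i, j}).pop()
    r_eq = 0.5 * (r[i] + r[j])
    r_pol = float(r[k])
    axis = fit.rotation[:, k].copy()
    if abs(r_pol - r_eq) / r_eq < sphere_tolerance:
        shape = "sphere"
    elif r_pol > r_eq:
        shape = "prolate"
    else:
        shape = "oblate"
    return SpheroidSummary(
        r_polar=r_pol, r_equatorial=float(r_eq), shape_class=shape, axis_direction=axis
    )


def covariance_extent_radii(points: np.ndarray) -> np.ndarray:
    """Semi-axis estimates for a *filled* uniform cloud, sorted ascending.

    A uniform solid ellipsoid has per-axis variance a²/5, so extents are
    √5 times the principal standard deviations.  (The direct quadric fit
    to a filled cloud lands on an interior mean shell instead; use this
    estimator when the cloud is a volume, not a surface.)
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    cov = np.cov(pts.T)
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals <= 0):
        raise EllipsoidError("degenerate covariance; points are not 3-dimensional")
    return np.sqrt(5.0 * eigvals)


def summarize_radii(radii, sphere_tolerance: float = 0.02) -> SpheroidSummary:
    """Spheroid summary straight from three radii (no fit required)."""
    r = np.sort(np.asarray(radii, dtype=float))
    fit = EllipsoidFit(
        coefficients=np.zeros(9),
        center=np.zeros(3),
        radii=r,
        rotation=np.eye(3),
        rss=0.0,
    )
    return spheroid_summary(fit, sphere_tolerance=sphere_tolerance)
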
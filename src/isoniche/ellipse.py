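"""Standard ellipse geometry and maximum-likelihood fits.

The standard ellipse of a bivariate sample is the 1-standard-deviation
contour of the fitted bivariate normal; its area

    SEA = π √det(Σ)

contains 1 − e^(−1/2) ≈ 39.35% of the probability mass.  SEAc applies the
small-sample correction (n−1)/(n−2), unbiased for the population area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientSampleError


@dataclass(frozen=True)
class EllipseFit:
    """Point estimates for one (group, year) unit."""

    group: str
    year: int
    n: int
    mean: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2), sample covariance (n−1 denominator)
    sea: float
    seac: float


def standard_ellipse_area(cov: np.ndarray) -> float:
    """SEA = π √det(cov); raises on non-positive-definite covariance."""
    cov = np.asarray(cov, dtype=float)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.all(np.isfinite(cov)):
        raise DegenerateGeometryError(
            f"covariance is singular or indefinite (det={det!r})"
        )
    return float(np.pi * np.sqrt(det))


def seac_correction(sea: float, n: int) -> float:
    """Small-sample corrected area sea·(n−1)/(n−2); requires n ≥ 3."""
    if n < 3:
        raise InsufficientSampleError(f"SEAc needs n >= 3, got n={n}")
    return sea * (n - 1) / (n - 2)


def fit_ml_ellipse(points, group: str = "", year: int = 0) -> EllipseFit:
    """Fit mean, covariance, SEA and SEAc to an (n, 2) point cloud.

    The covariance uses the n−1 denominator.  Collinear points (singular
    covariance) and n < 3 are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DegenerateGeometryError(f"expected (n, 2) points, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 3:
        raise InsufficientSampleError(f"ellipse fit needs n >= 3, got n={n}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    sea = standard_ellipse_area(cov)
    return EllipseFit(
        group=group,
        year=int(year),
        n=n,
        mean=mean,
        cov=cov,
        sea=sea,
        seac=seac_correction(sea, n),
    )


def ellipse_boundary(
    mean, cov, scale: float = 1.0, n_points: int = 200
) -> np.ndarray:
    """Ordered boundary points of the scale-σ ellipse.

    Parametrized as mean + scale · L (cos t, sin t) with L the Cholesky
    root of cov; at scale 1 the enclosed region is the standard ellipse.
    """
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"covariance not positive-definite: {cov!r}") from exc
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    circle = np.stack([np.cos(t), np.sin(t)])
    return mean + scale * (L @ circle).T
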
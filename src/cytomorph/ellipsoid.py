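"""Geometric dimension of the dot cloud: the covariance error ellipsoid.

For a gated, log-transformed cloud the 90% covariance error ellipsoid is the
set of points whose Mahalanobis quadratic form w.r.t. the sample mean and
covariance is at most the chi-square(3 df) critical value (6.251 at the 90%
confidence level).  Its axis lengths along the instrument channels are

    W = 2 sqrt(chi2 * lambda_SSC)   (width,  SSC axis)
    H = 2 sqrt(chi2 * lambda_FL1)   (height, FL1 axis)
    L = 2 sqrt(chi2 * lambda_FSC)   (length, FSC axis)

where the lambdas are covariance eigenvalues attributed to channel axes.
Volume is the ellipsoid volume V = (4/3) pi a b c with semi-axes a,b,c =
W/2, H/2, L/2, and eccentricity e = sqrt(1 - b^2/a^2) is computed in the
FL1-SSC plane from W and H.

Eigenvalues are attributed to channels by dominant loading: each eigenvalue,
taken in descending order, is assigned to the (still unused) channel axis on
which its eigenvector loads most heavily.  This reduces to the per-channel
variances whenever the covariance is (near-)diagonal; a ``mode="diagonal"``
switch skips the eigen step entirely and uses the raw diagonal variances,
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateCloudError
from .io import EventCloud

_EIG_TOL = 1e-12

#: column order of the geometric metrics in output tables
GEOMETRIC_COLUMNS = (
    "centroid_SSC",
    "centroid_FL1",
    "centroid_FSC",
    "W",
    "H",
    "L",
    "V",
    "eccentricity",
)


def chi2_quantile(p: float, df: int) -> float:
    """Chi-square quantile (inverse CDF); chi2_quantile(0.90, 3) = 6.251..."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must be in (0, 1), got {p}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.chi2.ppf(p, df))


def covariance_eigen(cloud: EventCloud) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the 3x3 sample covariance (n-1 denominator).

    Returns eigenvalues (descending, clipped to 0 below ``1e-12``) and the
    matching orthonormal eigenvectors as columns.
    """
    if cloud.n_events < 4:
        raise DegenerateCloudError(
            f"need at least 4 events for a stable covariance, "
            f"got {cloud.n_events}"
        )
    cov = np.cov(cloud.values, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.where(np.abs(evals) < _EIG_TOL, 0.0, evals)
    if np.any(evals < 0):
        # eigh of a symmetric PSD matrix can only go negative by roundoff
        evals = np.clip(evals, 0.0, None)
    if np.all(evals == 0):
        raise DegenerateCloudError("all events identical: rank-0 covariance")
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def assign_eigenvalues_to_axes(
    eigenvalues: np.ndarray, eigenvectors: np.ndarray
) -> tuple[float, float, float]:
    """Bijectively attribute eigenvalues to the SSC, FL1, FSC axes.

    Greedy in descending eigenvalue order: each eigenvalue claims the unused
    axis where its eigenvector has the largest absolute loading; loading
    ties break by channel order (SSC, FL1, FSC).
    """
    order = np.argsort(np.asarray(eigenvalues))[::-1]
    lam = {}
    used: set[int] = set()
    for i in order:
        load = np.abs(eigenvectors[:, i])
        free = [ax for ax in range(3) if ax not in used]
        best = max(free, key=lambda ax: (load[ax], -ax))
        lam[best] = float(eigenvalues[i])
        used.add(best)
    return lam[0], lam[1], lam[2]


def axis_lengths(
    lam_ssc: float, lam_fl1: float, lam_fsc: float, chi2_critical: float
) -> tuple[float, float, float]:
    """Full axis lengths (W, H, L) = 2 sqrt(chi2 * lambda) per channel."""
    lams = np.array([lam_ssc, lam_fl1, lam_fsc], dtype=float)
    if np.any(lams < -_EIG_TOL):
        raise ValueError(f"negative eigenvalue beyond tolerance: {lams}")
    if chi2_critical <= 0:
        raise ValueError("chi-square critical value must be > 0")
    w, h, l = 2.0 * np.sqrt(chi2_critical * np.clip(lams, 0.0, None))
    return float(w), float(h), float(l)


def ellipsoid_volume(W: float, H: float, L: float) -> float:
    """V = (4/3) pi a b c with semi-axes a,b,c = W/2, H/2, L/2 = pi W H L / 6."""
    return float(np.pi * W * H * L / 6.0)


def eccentricity(W: float, H: float) -> tuple[float, bool]:
    """Ellipse eccentricity in the FL1-SSC plane from axis lengths W and H.

    e = sqrt(1 - b^2/a^2) with a = max(W, H)/2, b = min(W, H)/2.  Returns
    ``(e, degenerate)``: a fully collapsed minor axis yields (1.0, True)
    instead of erroring so pipelines can continue.
    """
    if W < 0 or H < 0:
        raise ValueError("axis lengths must be non-negative")
    a, b = max(W, H) / 2.0, min(W, H) / 2.0
    if a == 0.0:
        raise DegenerateCloudError("both axes zero: eccentricity undefined")
    if b == 0.0:
        return 1.0, True
    return float(np.sqrt(1.0 - (b * b) / (a * a))), False


@dataclass
class EllipsoidMetrics:
    """Centroid, axis lengths, volume and eccentricity of one cloud."""

    centroid_SSC: float
    centroid_FL1: float
    centroid_FSC: float
    W: float
    H: float
    L: float
    V: float
    eccentricity: float
    eccentricity_degenerate: bool
    lam_SSC: float
    lam_FL1: float
    lam_FSC: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    covariance: np.ndarray
    confidence: float
    chi2_critical: float
    mode: str

    def as_dict(self) -> dict[str, float]:
        return {
            "centroid_SSC": self.centroid_SSC,
            "centroid_FL1": self.centroid_FL1,
            "centroid_FSC": self.centroid_FSC,
            "W": self.W,
            "H": self.H,
            "L": self.L,
            "V": self.V,
            "eccentricity": self.eccentricity,
        }


def compute_ellipsoid(
    cloud: EventCloud,
    confidence: float = 0.90,
    mode: str = "eigen",
) -> EllipsoidMetrics:
    """Compute the geometric metrics of a cloud's covariance error ellipsoid.

    ``mode="eigen"`` (default) attributes covariance eigenvalues to channel
    axes by dominant loading; ``mode="diagonal"`` uses the raw per-channel
    variances without an eigen step.
    """
    if mode not in ("eigen", "diagonal"):
        raise ValueError(f"unknown mode {mode!r}")
    crit = chi2_quantile(confidence, 3)
    centroid = cloud.values.mean(axis=0)
    evals, evecs = covariance_eigen(cloud)
    cov = np.cov(cloud.values, rowvar=False, ddof=1)
    if mode == "diagonal":
        lam_ssc, lam_fl1, lam_fsc = (float(cov[i, i]) for i in range(3))
    else:
        lam_ssc, lam_fl1, lam_fsc = assign_eigenvalues_to_axes(evals, evecs)
    w, h, l = axis_lengths(lam_ssc, lam_fl1, lam_fsc, crit)
    v = ellipsoid_volume(w, h, l)
    ecc, degen = eccentricity(w, h)
    return EllipsoidMetrics(
        centroid_SSC=float(centroid[0]),
        centroid_FL1=float(centroid[1]),
        centroid_FSC=float(centroid[2]),
        W=w,
        H=h,
        L=l,
        V=v,
        eccentricity=ecc,
        eccentricity_degenerate=degen,
        lam_SSC=lam_ssc,
        lam_FL1=lam_fl1,
        lam_FSC=lam_fsc,
        eigenvalues=evals,
        eigenvectors=evecs,
        covariance=cov,
        confidence=confidence,
        chi2_critical=crit,
        mode=mode,
    )


def mahalanobis_sq(points: np.ndarray, metrics: EllipsoidMetrics) -> np.ndarray:
    """Quadratic form (x-mu)' Sigma^-1 (x-mu) for each point."""
    mu = np.array(
        [metrics.centroid_SSC, metrics.centroid_FL1, metrics.centroid_FSC]
    )
    diff = np.asarray(points, dtype=float) - mu
    sol = np.linalg.solve(metrics.covariance, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def containment_fraction(points: np.ndarray, metrics: EllipsoidMetrics) -> float:
    """Fraction of points inside the ellipsoid (quadratic form <= chi2)."""
    return float(np.mean(mahalanobis_sq(points, metrics) <= metrics.chi2_critical))
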
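"""Topographic dimension: plane slopes and cytometric population count.

The orientation of the dot cloud is summarized by Type II (major-axis)
regression slopes in the FL1-SSC, FL1-FSC and SSC-FSC planes.  Major-axis
regression minimizes summed squared *perpendicular* distances to the line —
appropriate when both channels carry measurement error — giving

    beta = (s_yy - s_xx + sqrt((s_yy - s_xx)^2 + 4 s_xy^2)) / (2 s_xy)

for covariance s_xy != 0; the sign of beta matches the sign of s_xy.

Internal heterogeneity is the number of cytometric populations: density
peaks of the cloud in the FL1-SSC plane.  The detector over-segments with
seeded k-means, estimates a smoothed (binned Gaussian KDE) density on a
regular grid, then merges cluster pairs whose connecting segment shows no
density valley, and finally discards populations below a minimal mass
fraction.  All parameters live in :class:`PeakParams` and are deterministic
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .errors import DegenerateCloudError
from .io import EventCloud

#: slope columns in output tables
SLOPE_COLUMNS = ("slope_FL1_SSC", "slope_FL1_FSC", "slope_SSC_FSC")


@dataclass
class SlopeResult:
    """A signed major-axis slope plus a degeneracy flag.

    flag is one of ``ok``, ``isotropic`` (undefined: no preferred axis),
    ``zero`` (zero covariance, variance concentrated in x) or ``vertical``
    (zero covariance, variance concentrated in y).
    """

    slope: float
    flag: str = "ok"

    @property
    def defined(self) -> bool:
        return self.flag in ("ok", "zero")


def major_axis_slope(x, y) -> SlopeResult:
    """Type II (major-axis) regression slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    s_xx = float(np.var(x, ddof=1))
    s_yy = float(np.var(y, ddof=1))
    s_xy = float(np.cov(x, y, ddof=1)[0, 1])
    if s_xx == 0.0 and s_yy == 0.0:
        raise DegenerateCloudError("zero variance in both coordinates")
    if s_xy == 0.0:
        if s_xx == s_yy:
            return SlopeResult(float("nan"), "isotropic")
        if s_xx > s_yy:
            return SlopeResult(0.0, "zero")
        return SlopeResult(float("nan"), "vertical")
    d = s_yy - s_xx
    disc = math.sqrt(d * d + 4.0 * s_xy * s_xy)
    if d >= 0.0:
        beta = (d + disc) / (2.0 * s_xy)
    else:
        # rationalized form, numerically stable when s_xx > s_yy
        beta = 2.0 * s_xy / (disc - d)
    return SlopeResult(float(beta), "ok")


def plane_slopes(cloud: EventCloud) -> dict[str, SlopeResult]:
    """Major-axis slopes in the FL1-SSC, FL1-FSC and SSC-FSC planes."""
    return {
        "slope_FL1_SSC": major_axis_slope(cloud.ssc, cloud.fl1),
        "slope_FL1_FSC": major_axis_slope(cloud.fsc, cloud.fl1),
        "slope_SSC_FSC": major_axis_slope(cloud.fsc, cloud.ssc),
    }


@dataclass
class PeakParams:
    """Tuning knobs of the population detector (all deterministic)."""

    events_per_cluster: int = 50  # drives the over-segmentation K0
    k_max: int = 15
    grid_size: int = 128
    pad_fraction: float = 0.05
    merge_ratio: float = 0.7
    min_mass: float = 0.01
    seed: int = 0
    n_init: int = 10
    n_profile: int = 25  # density samples along a centroid-pair segment


@dataclass
class PopulationResult:
    """Detected cytometric populations in the FL1-SSC plane."""

    centroids: np.ndarray  # (k, 2): columns (SSC, FL1), log10 units
    n_populations: int
    mass_fractions: np.ndarray  # (k,), sums to 1
    labels: np.ndarray  # per-event population index


@dataclass
class TopographyMetrics:
    slopes: dict[str, SlopeResult]
    populations: PopulationResult

    def as_dict(self) -> dict[str, float]:
        out = {name: res.slope for name, res in self.slopes.items()}
        out["n_populations"] = float(self.populations.n_populations)
        return out


def _binned_kde(xy: np.ndarray, params: PeakParams):
    """Smoothed density on a regular grid (histogram + Gaussian filter).

    Bandwidth per axis follows Silverman's rule for d=2:
    h_i = sigma_i * n^(-1/6).
    """
    n = len(xy)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo = lo - params.pad_fraction * span
    hi = hi + params.pad_fraction * span
    g = params.grid_size
    hist, xedges, yedges = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=g, range=[(lo[0], hi[0]), (lo[1], hi[1])]
    )
    widths = (hi - lo) / g
    sigma = np.std(xy, axis=0, ddof=1) * n ** (-1.0 / 6.0)
    sigma_bins = np.maximum(sigma / widths, 1e-6)
    density = gaussian_filter(hist, sigma=sigma_bins, mode="constant")
    centers_x = 0.5 * (xedges[:-1] + xedges[1:])
    centers_y = 0.5 * (yedges[:-1] + yedges[1:])
    interp = RegularGridInterpolator(
        (centers_x, centers_y), density, bounds_error=False, fill_value=0.0
    )
    return density, (centers_x, centers_y), interp


def _merge_pass(xy, labels, active, interp, params) -> bool:
    """Merge the closest valley-free centroid pair; True if a merge happened."""
    cents = {c: xy[labels == c].mean(axis=0) for c in active}
    dens = {c: float(interp(cents[c])[0]) for c in active}
    pairs = sorted(
        (
            (float(np.linalg.norm(cents[a] - cents[b])), a, b)
            for i, a in enumerate(active)
            for b in active[i + 1 :]
        ),
    )
    for _, a, b in pairs:
        seg = np.linspace(cents[a], cents[b], params.n_profile)
        profile = interp(seg)
        valley = float(np.min(profile))
        if valley >= params.merge_ratio * min(dens[a], dens[b]):
            labels[labels == b] = a
            return True
    return False


def detect_populations(
    cloud: EventCloud, params: PeakParams | None = None
) -> PopulationResult:
    """Count density peaks (cytometric populations) in the FL1-SSC plane."""
    params = params or PeakParams()
    xy = cloud.values[:, [0, 1]]  # (SSC, FL1)
    n = len(xy)
    if n < 4:
        raise DegenerateCloudError("too few events for population detection")

    k0 = max(1, min(math.ceil(math.sqrt(n / params.events_per_cluster)), params.k_max))
    if k0 == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(
            n_clusters=k0,
            init="k-means++",
            n_init=params.n_init,
            random_state=params.seed,
        ).fit(xy)
        labels = km.labels_.astype(int).copy()

    _, _, interp = _binned_kde(xy, params)

    while True:
        active = sorted(set(labels.tolist()))
        if len(active) <= 1 or not _merge_pass(xy, labels, active, interp, params):
            break

    # prune low-mass populations, reassigning events to the nearest survivor
    while True:
        active = sorted(set(labels.tolist()))
        masses = {c: np.mean(labels == c) for c in active}
        if len(active) <= 1:
            break
        smallest = min(active, key=lambda c: (masses[c], c))
        if masses[smallest] >= params.min_mass:
            break
        cents = {
            c: xy[labels == c].mean(axis=0) for c in active if c != smallest
        }
        others = sorted(cents)
        dists = np.stack(
            [np.linalg.norm(xy - cents[c], axis=1) for c in others], axis=1
        )
        nearest = np.array(others)[np.argmin(dists, axis=1)]
        labels[labels == smallest] = nearest[labels == smallest]

    active = sorted(set(labels.tolist()))
    relabel = {c: i for i, c in enumerate(active)}
    labels = np.array([relabel[c] for c in labels], dtype=int)
    centroids = np.stack([xy[labels == i].mean(axis=0) for i in range(len(active))])
    masses = np.array([np.mean(labels == i) for i in range(len(active))])
    return PopulationResult(
        centroids=centroids,
        n_populations=len(active),
        mass_fractions=masses,
        labels=labels,
    )


def compute_topography(
    cloud: EventCloud, params: PeakParams | None = None
) -> TopographyMetrics:
    """Slopes and population structure of one cloud."""
    return TopographyMetrics(
        slopes=plane_slopes(cloud),
        populations=detect_populations(cloud, params),
    )
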
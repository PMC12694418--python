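"""Categorical labels for the fingerprint and its environmental context.

Shape: the dot cloud is *prolate* when the ellipsoid is taller than wide in
the FL1-SSC plane (H > W) and *oblate* when wider than tall (W > H); exact
ties get an explicit ``spherical-tie`` label.  Volume bins are small (< 2.5),
medium (2.5-3.5) and large (> 3.5); internal heterogeneity is *simple* with
one cytometric population and *complex* with two or more.  Optional
environmental bins: degree of evaporation from deuterium excess (d-excess
> 0 low, 0 to -10 intermediate, < -10 high) and trophic status from total
phosphorus (< 10 oligotrophic, 10-35 mesotrophic, > 35 ug/L eutrophic).
All interval boundaries are inclusive to the middle bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: default eccentricity breakpoints for the elongation classes; the source
#: study used elongation only qualitatively, so these are configurable
#: placeholders, not established cutoffs.
DEFAULT_ELONGATION_BREAKS = (0.3, 0.6, 0.9)

_TIE_TOL = 1e-9


def classify_shape(H: float, W: float) -> str:
    """prolate (H > W), oblate (W > H), or spherical-tie at H == W."""
    if abs(H - W) <= _TIE_TOL:
        return "spherical-tie"
    return "prolate" if H > W else "oblate"


def classify_volume(V: float, small: float = 2.5, large: float = 3.5) -> str:
    """small (< 2.5), medium (2.5-3.5, boundaries inclusive), large (> 3.5)."""
    if V < small:
        return "small"
    if V <= large:
        return "medium"
    return "large"


def classify_heterogeneity(n_populations: int) -> str:
    """simple with one cytometric population, complex with two or more."""
    if n_populations < 1:
        raise ValueError("population count must be >= 1")
    return "simple" if n_populations == 1 else "complex"


def classify_elongation(
    e: float, breaks: tuple[float, ...] = DEFAULT_ELONGATION_BREAKS
) -> str:
    """Qualitative elongation class from eccentricity (0 circular .. 1)."""
    names = ("low", "moderate", "high", "extreme")
    for name, cut in zip(names, breaks):
        if e <= cut:
            return name
    return names[len(breaks)]


def bin_evaporation(d_excess: float | None) -> str | None:
    """low (> 0), intermediate (0 to -10 inclusive), high (< -10)."""
    if d_excess is None or (isinstance(d_excess, float) and math.isnan(d_excess)):
        return None
    if d_excess > 0:
        return "low"
    if d_excess >= -10:
        return "intermediate"
    return "high"


def bin_trophic(tp: float | None) -> str | None:
    """oligotrophic (< 10), mesotrophic (10-35 inclusive), eutrophic (> 35)."""
    if tp is None or (isinstance(tp, float) and math.isnan(tp)):
        return None
    if tp < 10:
        return "oligotrophic"
    if tp <= 35:
        return "mesotrophic"
    return "eutrophic"


def bin_environment(
    d_excess: float | None, tp: float | None
) -> tuple[str | None, str | None]:
    """(evaporation class, trophic class); missing values give None labels."""
    return bin_evaporation(d_excess), bin_trophic(tp)


@dataclass
class CategoryLabels:
    shape: str
    elongation: str
    volume: str
    heterogeneity: str
    evaporation: str | None = None
    trophic: str | None = None

    def as_row(self) -> dict[str, str]:
        out = {
            "shape": self.shape,
            "elongation": self.elongation,
            "volume": self.volume,
            "heterogeneity": self.heterogeneity,
        }
        if self.evaporation is not None:
            out["evaporation"] = self.evaporation
        if self.trophic is not None:
            out["trophic"] = self.trophic
        return out


def classify_record(
    metrics: dict[str, float],
    n_populations_int: int,
    d_excess: float | None = None,
    tp: float | None = None,
    elongation_breaks: tuple[float, ...] = DEFAULT_ELONGATION_BREAKS,
) -> CategoryLabels:
    """All categorical labels for one averaged fingerprint record."""
    evap, troph = bin_environment(d_excess, tp)
    return CategoryLabels(
        shape=classify_shape(metrics["H"], metrics["W"]),
        elongation=classify_elongation(metrics["eccentricity"], elongation_breaks),
        volume=classify_volume(metrics["V"]),
        heterogeneity=classify_heterogeneity(n_populations_int),
        evaporation=evap,
        trophic=troph,
    )
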
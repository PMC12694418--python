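"""Reading per-event cytometry data and applying the common gate.

Input is either an FCS 3.0/3.1 file or a delimited text table with one row
per event (the usual cytometry-software export).  A channel map ties the
canonical channel names used throughout the package — ``SSC`` (side scatter),
``FL1`` (green fluorescence), ``FSC`` (forward scatter), optionally ``FL2`` /
``FL3`` (orange/red fluorescence) — to the column labels of the file; whether
those are height (-H) or area (-A) parameters is the user's call.

Gating reproduces the acquisition workflow: an instrument threshold on raw
FL1 (default 500) removes the background-noise floor, events that are
non-positive on any of SSC/FL1/FSC are dropped before the log10 transform,
a single common polygon gate in the log10(SSC)-log10(FL1) plane retains the
bacterial cloud, and optional exclusion polygons in log10(FL1)-log10(FL2/FL3)
planes remove photosynthetic picoplankton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml

from ._fcs import read_fcs, sniff_fcs
from .errors import GateError, MissingChannelError, TooFewEventsError

#: canonical channel order used everywhere downstream
CHANNELS = ("SSC", "FL1", "FSC")

DEFAULT_CHANNEL_MAP = {"SSC": "SSC-H", "FL1": "FL1-H", "FSC": "FSC-H"}

#: default minimum number of events surviving the gate; covariance and
#: density estimates are unstable below this.
DEFAULT_MIN_EVENTS = 100


@dataclass
class RawEvents:
    """Per-event channel values in linear instrument units."""

    data: pd.DataFrame  # columns are canonical channel names
    sample_id: str = ""
    replicate_id: str = ""
    n_dropped_nonfinite: int = 0

    @property
    def n_events(self) -> int:
        return len(self.data)


@dataclass
class GateCounts:
    """Per-stage bookkeeping of events removed by :func:`apply_gate`."""

    n_raw: int = 0
    n_below_threshold: int = 0
    n_nonpositive: int = 0
    n_outside_gate: int = 0
    n_excluded: int = 0
    n_retained: int = 0

    def check(self) -> bool:
        return self.n_raw == (
            self.n_below_threshold
            + self.n_nonpositive
            + self.n_outside_gate
            + self.n_excluded
            + self.n_retained
        )


@dataclass
class EventCloud:
    """Gated, log10-transformed events: an n x 3 matrix (SSC, FL1, FSC)."""

    values: np.ndarray  # shape (n, 3), columns in CHANNELS order
    sample_id: str = ""
    replicate_id: str = ""
    gate_counts: GateCounts | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("EventCloud values must be an (n, 3) array")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def ssc(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def fl1(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def fsc(self) -> np.ndarray:
        return self.values[:, 2]


def _as_polygon(vertices) -> shapely.Polygon:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise GateError("polygon needs at least 3 (x, y) vertices")
    poly = shapely.Polygon(arr)
    if not poly.is_valid or poly.area == 0:
        raise GateError("polygon must be simple (non-self-intersecting)")
    return poly


@dataclass
class GateSpec:
    """The single common gate applied to every sample.

    ``polygon`` lives in the log10(SSC)-log10(FL1) plane; ``exclusions`` are
    (channel, polygon) pairs in the log10(FL1)-log10(channel) plane used to
    cut out photosynthetic picoplankton signatures.
    """

    polygon: np.ndarray
    fl1_threshold: float = 500.0
    exclusions: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        _as_polygon(self.polygon)
        if not self.fl1_threshold > 0:
            raise GateError("FL1 acquisition threshold must be > 0")
        self.exclusions = [
            (str(ch), np.asarray(p, dtype=float)) for ch, p in self.exclusions
        ]
        for _, p in self.exclusions:
            _as_polygon(p)

    @classmethod
    def default(cls, fl1_threshold: float = 500.0) -> "GateSpec":
        """Rectangle spanning the full log decades (all-pass main gate)."""
        rect = [(-2.0, -2.0), (8.0, -2.0), (8.0, 8.0), (-2.0, 8.0)]
        return cls(polygon=rect, fl1_threshold=fl1_threshold)

    @classmethod
    def from_yaml(cls, path) -> "GateSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            polygon=doc["polygon"],
            fl1_threshold=float(doc.get("fl1_threshold", 500.0)),
            exclusions=[
                (e["channel"], e["polygon"]) for e in doc.get("exclusions", [])
            ],
        )

    def to_yaml(self, path) -> None:
        doc = {
            "polygon": [list(map(float, v)) for v in self.polygon],
            "fl1_threshold": float(self.fl1_threshold),
            "exclusions": [
                {"channel": ch, "polygon": [list(map(float, v)) for v in p]}
                for ch, p in self.exclusions
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def point_in_polygon(point, polygon) -> bool:
    """Boundary-inclusive membership of a 2-point in a simple polygon."""
    poly = _as_polygon(polygon)
    return bool(shapely.covers(poly, shapely.Point(point)))


def _points_in_polygon(xy: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    poly = _as_polygon(polygon)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    return shapely.covers(poly, pts)


def read_events(
    path,
    channel_map: dict[str, str] | None = None,
    sample_id: str = "",
    replicate_id: str = "",
) -> RawEvents:
    """Read per-event data from FCS or delimited text.

    ``channel_map`` maps canonical names (SSC, FL1, FSC, optionally FL2/FL3)
    to the column labels of the file.  Event order is preserved; rows that
    are non-finite on a required channel are dropped (counted on the result).
    """
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    for req in CHANNELS:
        if req not in channel_map:
            raise MissingChannelError(req, path)

    if sniff_fcs(path):
        table = read_fcs(path)
    else:
        table = pd.read_csv(path, sep=None, engine="python")

    cols = {}
    for canonical, label in channel_map.items():
        if label not in table.columns:
            raise MissingChannelError(canonical, path)
        cols[canonical] = pd.to_numeric(table[label], errors="coerce")
    data = pd.DataFrame(cols)

    finite = np.isfinite(data[list(CHANNELS)]).all(axis=1)
    n_dropped = int((~finite).sum())
    data = data.loc[finite].reset_index(drop=True)
    if len(data) == 0:
        raise IOError(f"{path}: no events")
    return RawEvents(
        data=data,
        sample_id=sample_id,
        replicate_id=replicate_id,
        n_dropped_nonfinite=n_dropped,
    )


def apply_gate(
    raw: RawEvents,
    gate: GateSpec,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> EventCloud:
    """Threshold, log-transform and gate raw events into an EventCloud.

    Stages, in order: (1) drop events with raw FL1 below the acquisition
    threshold; (2) drop events non-positive on any of SSC/FL1/FSC; (3) log10
    transform; (4) drop events outside the common polygon (log SSC vs log
    FL1, boundary-inclusive); (5) drop events inside any exclusion polygon.
    Raises :class:`TooFewEventsError` if fewer than ``min_events`` survive.
    """
    counts = GateCounts(n_raw=raw.n_events)
    data = raw.data

    keep = data["FL1"].to_numpy() >= gate.fl1_threshold
    counts.n_below_threshold = int((~keep).sum())
    data = data.loc[keep]

    pos = (data[list(CHANNELS)].to_numpy() > 0).all(axis=1)
    counts.n_nonpositive = int((~pos).sum())
    data = data.loc[pos]

    logged = np.log10(data[list(CHANNELS)].to_numpy())
    log_extra = {
        ch: np.log10(np.maximum(data[ch].to_numpy(), np.finfo(float).tiny))
        for ch in data.columns
        if ch not in CHANNELS
    }

    inside = _points_in_polygon(logged[:, [0, 1]], gate.polygon)
    counts.n_outside_gate = int((~inside).sum())
    logged = logged[inside]
    log_extra = {ch: v[inside] for ch, v in log_extra.items()}

    excluded = np.zeros(len(logged), dtype=bool)
    for ch, poly in gate.exclusions:
        if ch not in log_extra:
            raise MissingChannelError(ch)
        xy = np.column_stack([logged[:, 1], log_extra[ch]])
        excluded |= _points_in_polygon(xy, poly)
    counts.n_excluded = int(excluded.sum())
    logged = logged[~excluded]

    counts.n_retained = len(logged)
    assert counts.check()
    if counts.n_retained < min_events:
        raise TooFewEventsError(raw.sample_id, counts.n_retained, min_events)
    return EventCloud(
        values=logged,
        sample_id=raw.sample_id,
        replicate_id=raw.replicate_id,
        gate_counts=counts,
    )
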
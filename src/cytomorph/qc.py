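"""Replicate QC (variance-ratio F-test) and duplicate averaging.

Each sample is acquired in duplicate.  Homogeneity between the duplicates is
checked with a two-sided F-test on the variance of log10 FL1 — the channel
carrying the acquisition threshold and the dominant biological signal —
and pairs rejected at alpha = 0.05 are removed from further analysis.
Surviving duplicates are averaged metric-by-metric into one record per
sample: the 12-metric fingerprint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import EventCloud

#: the 12 metrics of the fingerprint, in canonical output order
METRIC_NAMES = (
    "centroid_SSC",
    "centroid_FL1",
    "centroid_FSC",
    "H",
    "W",
    "L",
    "V",
    "eccentricity",
    "slope_FL1_SSC",
    "slope_FL1_FSC",
    "slope_SSC_FSC",
    "n_populations",
)

QC_PASS = "pass"
QC_FAILED = "failed_ftest"
QC_SINGLETON = "singleton"


def f_test_variance_ratio(a, b) -> tuple[float, float]:
    """Two-sided F-test of variance homogeneity between two samples.

    The statistic is the larger-over-smaller variance ratio (F >= 1) with
    the matching degrees of freedom; p = min(1, 2 * P(F >= f)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need length >= 2")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero variance: F-test undefined")
    if va >= vb:
        f, df1, df2 = va / vb, len(a) - 1, len(b) - 1
    else:
        f, df1, df2 = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, df1, df2)))
    return f, p


@dataclass
class QCResult:
    sample_id: str
    status: str
    f_statistic: float = float("nan")
    p_value: float = float("nan")
    channels: tuple[str, ...] = ("FL1",)
    replicate_ids: tuple[str, ...] = ()


def qc_pair(
    rep1: EventCloud,
    rep2: EventCloud,
    alpha: float = 0.05,
    channels: tuple[str, ...] = ("FL1",),
) -> QCResult:
    """F-test replicate homogeneity on the given channels (default FL1 only).

    With multiple channels the pair fails if any channel rejects at alpha;
    the reported F/p are those of the most significant channel.
    """
    if rep1.sample_id != rep2.sample_id:
        raise ValueError(
            f"replicates from different samples: "
            f"{rep1.sample_id!r} vs {rep2.sample_id!r}"
        )
    idx = {"SSC": 0, "FL1": 1, "FSC": 2}
    best_f, best_p = float("nan"), float("inf")
    for ch in channels:
        f, p = f_test_variance_ratio(
            rep1.values[:, idx[ch]], rep2.values[:, idx[ch]]
        )
        if p < best_p:
            best_f, best_p = f, p
    status = QC_FAILED if best_p < alpha else QC_PASS
    return QCResult(
        sample_id=rep1.sample_id,
        status=status,
        f_statistic=best_f,
        p_value=best_p,
        channels=tuple(channels),
        replicate_ids=(rep1.replicate_id, rep2.replicate_id),
    )


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding (1.5 -> 2, 2.5 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass
class BMSRecord:
    """The averaged 12-metric fingerprint of one sample."""

    sample_id: str
    metrics: dict[str, float]
    qc_status: str
    n_replicates_used: int
    n_populations_int: int = field(default=0)

    def __post_init__(self):
        missing = set(METRIC_NAMES) - set(self.metrics)
        extra = set(self.metrics) - set(METRIC_NAMES)
        if missing or extra:
            raise ValueError(
                f"BMSRecord requires exactly the 12 metrics; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        if not self.n_populations_int:
            self.n_populations_int = round_half_up(self.metrics["n_populations"])

    def as_row(self) -> dict[str, float]:
        row = {"sample_id": self.sample_id}
        row.update({k: self.metrics[k] for k in METRIC_NAMES})
        row["n_populations_int"] = self.n_populations_int
        row["qc_status"] = self.qc_status
        row["n_replicates_used"] = self.n_replicates_used
        return row


def average_duplicates(
    sample_id: str,
    replicate_metrics: list[dict[str, float]],
    qc_status: str = QC_PASS,
) -> BMSRecord:
    """Arithmetic mean of each metric across replicate records.

    The population count is averaged as a real number (possibly fractional);
    a companion integer field (half-up rounding) serves categorical use.
    """
    if not replicate_metrics:
        raise ValueError("no replicate records to average")
    for rec in replicate_metrics:
        missing = set(METRIC_NAMES) - set(rec)
        if missing:
            raise ValueError(
                f"replicate record lacks the 12 metrics: missing {sorted(missing)}"
            )
    means = {
        name: float(np.mean([r[name] for r in replicate_metrics]))
        for name in METRIC_NAMES
    }
    return BMSRecord(
        sample_id=sample_id,
        metrics=means,
        qc_status=qc_status,
        n_replicates_used=len(replicate_metrics),
    )
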
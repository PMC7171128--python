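"""Specific growth rates from paired scans and binned dispersion statistics.

Each patient contributes one record ``(V1, dt, V2)``: tumor volume at a first
MRI scan, the inter-scan interval in days, and the volume at the second scan.
The specific growth rate ``SGR = (ln V2 - ln V1) / dt`` is the per-day
relative growth between scans.  To characterise how growth-rate scatter
varies with tumor size, first-scan volumes are partitioned into bins and the
sample SD of a chosen statistic (SGR by default) is computed per bin; the
resulting (volume, SD) pairs feed the noise-strength fit in
:mod:`gbmgrowth.model_fit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "SGRPoint",
    "VolumeBin",
    "specific_growth_rate",
    "cohort_sgr",
    "bin_by_volume",
    "bin_dispersion",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS = ["patient_id", "v1_ml", "dt_days", "v2_ml"]


@dataclass(frozen=True)
class PatientRecord:
    """One paired-scan observation: first volume, interval, second volume."""

    patient_id: str
    v1: float
    dt: float
    v2: float

    def __post_init__(self) -> None:
        if not (self.v1 > 0 and self.v2 > 0 and self.dt > 0):
            raise ValueError("v1, v2 and dt must all be positive")
        if not all(math.isfinite(x) for x in (self.v1, self.dt, self.v2)):
            raise ValueError("record fields must be finite")


@dataclass(frozen=True)
class SGRPoint:
    """A (first-scan volume, specific growth rate) pair."""

    v: float
    sgr: float

    def __post_init__(self) -> None:
        if self.v <= 0 or not math.isfinite(self.v) or not math.isfinite(self.sgr):
            raise ValueError("v must be positive and both fields finite")


def _ref_volume(item) -> float:
    """First-scan volume of a record or the x-coordinate of an SGR point."""
    if isinstance(item, PatientRecord):
        return item.v1
    if isinstance(item, SGRPoint):
        return item.v
    raise TypeError(f"cannot bin object of type {type(item).__name__}")


def _statistic_value(item, statistic: str) -> float:
    if statistic == "sgr":
        if isinstance(item, SGRPoint):
            return item.sgr
        return specific_growth_rate(item)
    if statistic == "v1":
        return _ref_volume(item)
    raise ValueError(f"unknown statistic {statistic!r}; expected 'sgr' or 'v1'")


@dataclass
class VolumeBin:
    """Records whose first-scan volume falls in ``(lower, upper]``.

    The first bin is closed below at 0 and the overflow bin is open-ended
    (``upper = inf``).  ``representative`` is the mean of the members'
    first-scan volumes by default; ``midpoint`` of the bounds is available for
    finite bins.
    """

    index: int
    lower: float
    upper: float
    members: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def is_overflow(self) -> bool:
        return math.isinf(self.upper)

    def representative(self, mode: str = "mean") -> float:
        if mode == "mean":
            if not self.members:
                raise ValueError("empty bin has no representative volume")
            return float(np.mean([_ref_volume(m) for m in self.members]))
        if mode == "midpoint":
            if self.is_overflow:
                raise ValueError("overflow bin has no midpoint")
            return 0.5 * (self.lower + self.upper)
        raise ValueError(f"unknown representative mode {mode!r}")

    def statistic_values(self, statistic: str = "sgr") -> np.ndarray:
        return np.array([_statistic_value(m, statistic) for m in self.members])


def specific_growth_rate(record: PatientRecord) -> float:
    """``(ln V2 - ln V1) / dt`` in 1/day (natural log)."""
    return (math.log(record.v2) - math.log(record.v1)) / record.dt


def cohort_sgr(records: Sequence[PatientRecord]) -> list[SGRPoint]:
    """One SGR point per record, paired with its first-scan volume, order kept."""
    if not records:
        raise ValueError("cohort is empty")
    return [SGRPoint(v=r.v1, sgr=specific_growth_rate(r)) for r in records]


def bin_by_volume(items: Sequence, edges: Sequence[float]) -> list[VolumeBin]:
    """Partition records/points by first-scan volume at the given separators.

    With edges ``e1 < e2 < ... < eK`` the bins are ``(0, e1]``,
    ``(e1, e2]``, ..., plus an open-ended overflow bin ``(eK, inf)``.  Every
    item lands in exactly one bin.
    """
    edges = list(edges)
    if not edges or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be non-empty and strictly increasing")
    bounds = [0.0] + edges + [math.inf]
    bins = [
        VolumeBin(index=j + 1, lower=bounds[j], upper=bounds[j + 1])
        for j in range(len(bounds) - 1)
    ]
    upper = np.array(edges)
    for item in items:
        v = _ref_volume(item)
        j = int(np.searchsorted(upper, v, side="left"))  # (e_{j-1}, e_j]
        bins[j].members.append(item)
    return bins


def bin_dispersion(
    bins: Sequence[VolumeBin],
    statistic: str = "sgr",
    drop_overflow: bool = True,
    min_count: int = 2,
    representative: str = "mean",
) -> list[tuple[float, float]]:
    """Per-bin (representative volume, sample SD of the statistic) pairs.

    The overflow bin is dropped by default (mirroring the exclusion of the
    sparse largest-volume group from the noise fit) and any bin with fewer
    than ``min_count`` members is skipped — a sample SD needs n >= 2.
    """
    pairs: list[tuple[float, float]] = []
    for b in bins:
        if drop_overflow and b.is_overflow:
            continue
        if b.count < max(min_count, 2):
            continue
        vals = b.statistic_values(statistic)
        pairs.append((b.representative(representative), float(np.std(vals, ddof=1))))
    if not pairs:
        raise ValueError("no bin satisfied the count requirement")
    return pairs


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    """Write the standard cohort CSV (patient_id, v1_ml, dt_days, v2_ml)."""
    df = pd.DataFrame(
        [(r.patient_id, r.v1, r.dt, r.v2) for r in records], columns=COHORT_COLUMNS
    )
    # %.17g keeps the CSV exactly round-trippable for float64 volumes
    df.to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    return [
        PatientRecord(
            patient_id=str(row.patient_id),
            v1=float(row.v1_ml),
            dt=float(row.dt_days),
            v2=float(row.v2_ml),
        )
        for row in df.itertuples()
    ]
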
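"""Read-recruitment detection metric and coverage summaries.

Detection of a genome in a metagenome is the fraction of its nucleotide
positions covered by at least one mapped short read. It is a robust
presence proxy because conserved regions recruit reads from non-target
populations, which inflates mean coverage but not breadth. Detection values
across samples are typically bimodal (present vs. absent), and a genome is
called detected at a detection value of at least 0.25 (inclusive).

The ``q2q3_mean`` summary is the mean coverage over the central half of
positions (2nd and 3rd quartiles after sorting), an outlier-robust coverage
estimate used e.g. for donor-stool dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DetectionThresholds",
    "DetectionTable",
    "detection_value",
    "is_detected",
    "q2q3_mean",
    "prevalence",
]


@dataclass(frozen=True)
class DetectionThresholds:
    """Inclusive thresholds for presence calls.

    detection_min: minimum detection (breadth of coverage) to call a genome
        present in a sample.
    scg_coverage_min: minimum single-copy-core-gene coverage for strain-level
        (subpopulation) evidence to be considered reliable.
    """

    detection_min: float = 0.25
    scg_coverage_min: float = 10.0

    def __post_init__(self):
        if not 0.0 <= self.detection_min <= 1.0:
            raise ValidationError("detection_min must be in [0,1]")
        if self.scg_coverage_min < 0:
            raise ValidationError("scg_coverage_min must be >= 0")


DEFAULT_THRESHOLDS = DetectionThresholds()


@dataclass
class DetectionTable:
    """Genome x sample detection values plus optional coverage summaries.

    ``detection`` is a DataFrame indexed by genome id with sample-id columns;
    the optional frames share that layout.
    """

    detection: pd.DataFrame
    q2q3_mean_coverage: Optional[pd.DataFrame] = None
    scg_nonoutlier_coverage: Optional[pd.DataFrame] = None

    def __post_init__(self):
        values = self.detection.to_numpy(dtype=float)
        if values.size and ((values < 0) | (values > 1)).any():
            raise ValidationError("detection values must be in [0,1]")


def detection_value(per_nucleotide_coverage: Sequence[int]) -> float:
    """Fraction of positions covered by >= 1 read."""
    cov = np.asarray(per_nucleotide_coverage)
    if cov.size == 0:
        raise ValidationError("empty coverage vector")
    if (cov < 0).any():
        raise ValidationError("coverage values must be >= 0")
    return float(np.count_nonzero(cov >= 1) / cov.size)


def is_detected(
    detection: float, thresholds: DetectionThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """True iff detection >= detection_min (the threshold is inclusive)."""
    if not 0.0 <= detection <= 1.0:
        raise ValidationError(f"detection {detection} outside [0,1]")
    return detection >= thresholds.detection_min


def q2q3_mean(values: Sequence[float]) -> float:
    """Mean of the central half of the sorted values.

    Drops the floor(n/4) lowest and floor(n/4) highest values, a
    deterministic count-based reading of "mean coverage in the 2nd and 3rd
    quartiles" that is exact when n is divisible by 4.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 4:
        raise ValidationError("q2q3_mean needs at least 4 values")
    k = n // 4
    return float(arr[k : n - k].mean())


def prevalence(
    genome_id: str,
    sample_ids: Iterable[str],
    detection: pd.DataFrame,
    thresholds: DetectionThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Fraction of the given samples in which the genome is detected."""
    samples = list(sample_ids)
    if not samples:
        raise ValidationError("empty sample group")
    missing = [s for s in samples if s not in detection.columns]
    if missing:
        raise ValidationError(f"samples not in detection table: {missing}")
    if genome_id not in detection.index:
        raise ValidationError(f"genome {genome_id} not in detection table")
    vals = detection.loc[genome_id, samples].to_numpy(dtype=float)
    return float((vals >= thresholds.detection_min).mean())
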
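"""Stress-reporter fluorescence normalisation.

A chromosomally integrated stress-responsive GFP reporter is read out by
flow cytometry; the per-sample statistic is the median event intensity.
Two normalisations are supported: log2 fold change versus a reference
strain at the matched timepoint/condition, and the stress-induction
ratio of a strain against its own unstressed culture at the same
timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FluorescenceMeasurement",
    "median_fluorescence",
    "log2_fold_change",
    "induction_ratio",
]


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """Median reporter intensity for one strain/timepoint/condition."""

    strain_label: str
    timepoint: str
    condition: str
    median_intensity: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not (self.median_intensity > 0) or not math.isfinite(self.median_intensity):
            raise ValueError("median_intensity must be finite and > 0 (required for log ratios)")


def median_fluorescence(event_intensities: Sequence[float]) -> float:
    """Sample median of a list of event intensities.

    Even-length lists use the midpoint of the two central order
    statistics.
    """
    arr = np.asarray(event_intensities, dtype=float)
    if arr.size == 0:
        raise ValueError("no events; median undefined")
    return float(np.median(arr))


def _group_means(
    measurements: Iterable[FluorescenceMeasurement],
) -> dict[tuple[str, str], float]:
    groups: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        groups.setdefault((m.timepoint, m.condition), []).append(m.median_intensity)
    return {k: float(np.mean(v)) for k, v in groups.items()}


def log2_fold_change(
    strain: Iterable[FluorescenceMeasurement],
    reference: Iterable[FluorescenceMeasurement],
    *,
    per_replicate: bool = False,
) -> dict[tuple[str, str], float]:
    """log2 fold change of a strain's signal over a reference strain.

    Measurements are matched on (timepoint, condition).  By default
    replicate medians are averaged per group before the ratio is formed;
    ``per_replicate=True`` instead pairs replicates in order, computes a
    log2 FC per pair, and averages the log values.

    Returns a mapping (timepoint, condition) -> log2 FC, one entry per
    matched group.  Strain groups with no reference counterpart raise.
    """
    strain = list(strain)
    reference = list(reference)
    if per_replicate:
        s_groups: dict[tuple[str, str], list[float]] = {}
        r_groups: dict[tuple[str, str], list[float]] = {}
        for m in strain:
            s_groups.setdefault((m.timepoint, m.condition), []).append(m.median_intensity)
        for m in reference:
            r_groups.setdefault((m.timepoint, m.condition), []).append(m.median_intensity)
        missing = sorted(set(s_groups) - set(r_groups))
        if missing:
            raise ValueError(f"no reference measurements for timepoint/condition pairs: {missing}")
        out = {}
        for key, svals in s_groups.items():
            rvals = r_groups[key]
            if len(svals) != len(rvals):
                raise ValueError(f"replicate counts differ for {key}: {len(svals)} vs {len(rvals)}")
            out[key] = float(np.mean([math.log2(s / r) for s, r in zip(svals, rvals)]))
        return out
    s_means = _group_means(strain)
    r_means = _group_means(reference)
    missing = sorted(set(s_means) - set(r_means))
    if missing:
        raise ValueError(f"no reference measurements for timepoint/condition pairs: {missing}")
    return {key: math.log2(s_means[key] / r_means[key]) for key in s_means}


def induction_ratio(
    with_stress: FluorescenceMeasurement,
    without_stress: FluorescenceMeasurement,
    *,
    log2_output: bool = False,
) -> float:
    """Fold change of a strain's signal under stress over its unstressed self.

    Both measurements must come from the same strain and timepoint; only
    the condition differs.  Linear-scale ratio by default.
    """
    if with_stress.strain_label != without_stress.strain_label:
        raise ValueError(
            f"strain mismatch: {with_stress.strain_label!r} vs {without_stress.strain_label!r}"
        )
    if with_stress.timepoint != without_stress.timepoint:
        raise ValueError(
            f"timepoint mismatch: {with_stress.timepoint!r} vs {without_stress.timepoint!r}"
        )
    ratio = with_stress.median_intensity / without_stress.median_intensity
    return math.log2(ratio) if log2_output else ratio
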
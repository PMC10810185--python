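"""Spike-in calibration: read ratios -> percent repair relative to wild type.

Every library receives a constant amount of excised-oligo material from a
second (spike-in) species, so the sample:spike read-count ratio is
proportional to the amount of excision repair in the sample.  A serial
dilution series of the wild-type sample (e.g. 1, 1/10, ..., 1/10,000) fixes
the proportionality: a least-squares line through the origin of ratio on
dilution fraction gives the ratio a full-strength WT library would produce,
and any sample's ratio divided by that slope is its repair relative to WT.

``input_scale`` corrects deliberate loading differences: when a mutant
library is prepared from, say, 2000x more starting material than WT, its
measured ratio overstates repair 2000-fold and is divided down at
quantification time (never at counting, so raw ratios stay inspectable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .read_processing import GenomeIndex


@dataclass
class LibraryCounts:
    """Filtered read counts for one library (sample species vs spike species)."""

    sample_id: str
    n_sample: int
    n_spike: int
    dilution: float | None = None
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sample < 0 or self.n_spike < 0:
            raise ValueError("counts must be non-negative")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")


@dataclass
class CalibrationFit:
    """Slope of ratio vs dilution for the WT series (line through the origin)."""

    slope: float
    r_squared: float
    n_points: int
    intercept: float = 0.0
    method: str = "origin"


@dataclass
class QuantResult:
    sample_id: str
    ratio: float
    percent_of_wt: float
    fold_over_background: float | None = None


def partition_by_species(sequences: Iterable[str],
                         sample_index: GenomeIndex,
                         spike_index: GenomeIndex,
                         ) -> tuple[list[str], list[str], dict[str, int]]:
    """Assign reads to the species where they align uniquely.

    A read counts for a species when it has exactly one exact-match locus in
    that genome and none in the other.  Reads hitting both genomes are
    dropped as ambiguous; multi-locus and unmapped reads are dropped too.
    Returns (sample_seqs, spike_seqs, stats).
    """
    if sample_index is spike_index:
        raise ValueError("sample and spike genomes must differ")
    sample_hits, spike_hits = [], []
    stats = {"sample": 0, "spike": 0, "ambiguous": 0, "multi": 0,
             "unmapped": 0, "with_n": 0}
    for seq in sequences:
        if "N" in seq:
            stats["with_n"] += 1
            continue
        a = sample_index.occurrences(seq)
        b = spike_index.occurrences(seq)
        if a and b:
            stats["ambiguous"] += 1
        elif len(a) == 1:
            sample_hits.append(seq)
            stats["sample"] += 1
        elif len(b) == 1:
            spike_hits.append(seq)
            stats["spike"] += 1
        elif a or b:
            stats["multi"] += 1
        else:
            stats["unmapped"] += 1
    return sample_hits, spike_hits, stats


def ratio(counts: LibraryCounts) -> float:
    """Sample:spike read-count ratio; the quantification currency."""
    if counts.n_spike == 0:
        raise ZeroDivisionError(
            f"library {counts.sample_id!r}: spike count is zero, ratio undefined")
    return counts.n_sample / counts.n_spike


def fit_dilution_curve(series: Sequence[LibraryCounts],
                       method: str = "origin") -> CalibrationFit:
    """Fit ratio = slope * dilution over the WT dilution series.

    ``method="origin"`` (default): least squares through the origin,
    slope = sum(d*R)/sum(d^2); the ratio must vanish at dilution zero.
    ``method="intercept"``: ordinary least squares with a free intercept.
    ``method="loglog"``: slope-one fit in log space (geometric mean of R/d),
    robust when the series spans several decades.
    Warns when r^2 < 0.9 (nonlinear series).
    """
    points = [c for c in series if c.dilution is not None]
    if len(points) < 2:
        raise ValueError("dilution-curve fit needs at least 2 points")
    d = np.array([c.dilution for c in points], dtype=float)
    if len(set(d)) < 2:
        raise ValueError("dilution points must be distinct")
    r = np.array([ratio(c) for c in points])

    intercept = 0.0
    if method == "origin":
        slope = float(np.sum(d * r) / np.sum(d * d))
    elif method == "intercept":
        slope_i, intercept = np.polyfit(d, r, 1)
        slope = float(slope_i)
        intercept = float(intercept)
    elif method == "loglog":
        if np.any(r <= 0):
            raise ValueError("loglog fit requires strictly positive ratios")
        slope = float(np.exp(np.mean(np.log(r) - np.log(d))))
    else:
        raise ValueError(f"unknown fit method {method!r}")
    if slope <= 0:
        raise ValueError(f"non-positive fitted slope {slope}")

    pred = slope * d + intercept
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum(r ** 2)) if method != "intercept" else float(
        np.sum((r - r.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r_squared < 0.9:
        warnings.warn(
            f"dilution series fits poorly (r^2={r_squared:.3f}); the series "
            "may be outside the linear range", stacklevel=2)
    return CalibrationFit(slope, r_squared, len(points), intercept, method)


def percent_of_wt(counts: LibraryCounts, fit: CalibrationFit) -> QuantResult:
    """Convert a library's ratio to percent of full-strength WT repair."""
    r = ratio(counts)
    percent = 100.0 * ((r - fit.intercept) / fit.slope) / counts.input_scale
    return QuantResult(counts.sample_id, r, max(0.0, percent))


def fold_over_background(signal: QuantResult | float,
                         background: QuantResult | float) -> float:
    """Signal-to-background ratio of two percent-of-WT values."""
    p_sig = signal.percent_of_wt if isinstance(signal, QuantResult) else signal
    p_bg = (background.percent_of_wt if isinstance(background, QuantResult)
            else background)
    if p_bg <= 0:
        raise ZeroDivisionError("background percent must be positive")
    return p_sig / p_bg
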
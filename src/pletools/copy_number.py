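"""Absolute transgene copy number from qPCR standard curves.

A dilution series of a plasmid with known copy number defines the linear
standard curve Ct = intercept + slope * log10(copies); sample Ct values are
inverted through the curve, and copies per cell are obtained by normalizing
the transgene count to the RNaseP reference, present at 2 copies per human
diploid genome:

    copies_per_cell = 2 * target_copies / reference_copies

An amplification efficiency of 100% corresponds to slope -1/log10(2)
(about -3.32 Ct per 10-fold dilution); fitted slopes outside the 90-110%
efficiency band ([-3.6, -3.1]) trigger a warning but are never rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
import scipy.stats

logger = logging.getLogger("pletools")

__all__ = [
    "StandardCurve",
    "SampleQuant",
    "fit_standard_curve",
    "predict_ct",
    "quantify",
    "copies_per_cell",
    "quantify_samples",
]

RNASEP_COPIES_PER_CELL = 2.0


@dataclass(frozen=True)
class StandardCurve:
    slope: float        # Ct per log10(copies)
    intercept: float    # Ct at 1 copy
    r2: float
    target: str = ""

    def __post_init__(self) -> None:
        if self.slope >= 0:
            logger.warning("standard curve for %r has non-negative slope", self.target)


@dataclass(frozen=True)
class SampleQuant:
    sample: str
    target_copies: float
    reference_copies: float
    copies_per_cell: float


def fit_standard_curve(points: list[tuple[float, float]], target: str = "") -> StandardCurve:
    """Least-squares fit of Ct against log10(copies).

    ``points`` are (copies, Ct) pairs; replicate Ct values at the same copy
    number are averaged before fitting. Requires >= 3 distinct dilution
    levels and strictly positive copy numbers.
    """
    if any(c <= 0 for c, _ in points):
        raise ValueError("copy numbers must be positive")
    by_level: dict[float, list[float]] = {}
    for copies, ct in points:
        by_level.setdefault(copies, []).append(ct)
    if len(by_level) < 3:
        raise ValueError(f"need >= 3 distinct dilution levels, got {len(by_level)}")
    xs = [math.log10(c) for c in sorted(by_level)]
    ys = [sum(by_level[c]) / len(by_level[c]) for c in sorted(by_level)]
    fit = scipy.stats.linregress(xs, ys)
    slope, intercept, r = fit.slope, fit.intercept, fit.rvalue
    if not (-3.6 <= slope <= -3.1):
        eff = (10 ** (-1 / slope) - 1) * 100 if slope != 0 else float("nan")
        logger.warning(
            "standard-curve slope %.3f outside [-3.6, -3.1] "
            "(amplification efficiency %.0f%% outside 90-110%%)", slope, eff,
        )
    return StandardCurve(slope=slope, intercept=intercept, r2=r ** 2, target=target)


def predict_ct(copies: float, curve: StandardCurve) -> float:
    """Expected Ct for a given copy number under the curve."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return curve.intercept + curve.slope * math.log10(copies)


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept)/slope)."""
    if curve.slope == 0:
        raise ValueError("curve slope is zero; cannot invert")
    return 10 ** ((ct - curve.intercept) / curve.slope)


def copies_per_cell(target_copies: float, ref_copies: float) -> float:
    """Transgene copies per cell, normalized to the 2-copy RNaseP reference."""
    if ref_copies <= 0:
        raise ValueError("reference copies must be positive")
    if target_copies < 0:
        raise ValueError("target copies must be >= 0")
    return RNASEP_COPIES_PER_CELL * target_copies / ref_copies


def quantify_samples(
    standards: pd.DataFrame,
    samples: pd.DataFrame,
    target: str,
    reference: str = "RNaseP",
) -> list[SampleQuant]:
    """End-to-end quantification from standards and sample Ct tables.

    ``standards`` columns: target, copies, replicate, Ct. ``samples``
    columns: sample, target, replicate, Ct. Replicates are averaged. One
    curve is fitted per assay target; each sample's transgene copies are
    normalized to its reference copies.
    """
    curves: dict[str, StandardCurve] = {}
    for name, group in standards.groupby("target"):
        pts = list(zip(group["copies"].astype(float), group["Ct"].astype(float)))
        curves[str(name)] = fit_standard_curve(pts, target=str(name))
    for needed in (target, reference):
        if needed not in curves:
            raise ValueError(f"no standard curve for {needed!r}")

    out: list[SampleQuant] = []
    for sample_id, group in samples.groupby("sample"):
        mean_ct = group.groupby("target")["Ct"].mean()
        if target not in mean_ct.index or reference not in mean_ct.index:
            raise ValueError(f"sample {sample_id!r} missing target or reference Ct")
        t = quantify(float(mean_ct[target]), curves[target])
        r = quantify(float(mean_ct[reference]), curves[reference])
        out.append(SampleQuant(str(sample_id), t, r, copies_per_cell(t, r)))
    return out
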
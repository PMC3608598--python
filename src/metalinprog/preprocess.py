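"""Count normalization and variance-stabilizing transforms.

Metagenomic counts are compositional and overdispersed: the variance of a
proportion p is a function of p itself, which violates the homoscedasticity
assumed by linear decision rules.  The pipeline therefore (1) converts raw
counts to relative abundances to remove sequencing-depth differences, and
(2) applies a variance-stabilizing transform — the square root sqrt(p) or
the arcsine arcsin(sqrt(p)) — before any model is fitted.  Bartlett's test
of variance homogeneity across samples guides whether a transform is needed
at all; the default end-to-end pipeline applies the arcsine transform
unconditionally, which is the safe choice for proportion data spanning the
whole [0, 1] range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .io_tables import CountTable

Stage = Literal["relative", "sqrt_transformed", "arcsine_transformed"]

_STAGE_RANGE = {
    "relative": (0.0, 1.0),
    "sqrt_transformed": (0.0, 1.0),
    "arcsine_transformed": (0.0, np.pi / 2),
}


@dataclass
class AbundanceTable:
    """Real-valued n x m abundance matrix at a known transform stage."""

    samples: list[str]
    features: list[str]
    values: np.ndarray
    stage: Stage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("values shape does not match identifier lists")
        lo, hi = _STAGE_RANGE[self.stage]
        if self.values.min() < lo - 1e-12 or self.values.max() > hi + 1e-12:
            raise ValueError(
                f"values outside [{lo}, {hi:.6g}] for stage {self.stage!r}"
            )
        if self.stage == "relative":
            row_sums = self.values.sum(axis=1)
            if np.any(np.abs(row_sums - 1.0) > 1e-12):
                i = int(np.argmax(np.abs(row_sums - 1.0)))
                raise ValueError(
                    f"relative-abundance row {self.samples[i]!r} sums to "
                    f"{row_sums[i]!r}, not 1"
                )


@dataclass
class BartlettResult:
    """Bartlett's chi-squared test of equal variances across samples."""

    statistic: float
    df: int
    p_value: float
    group_variances: np.ndarray


def to_relative_abundance(table: CountTable) -> AbundanceTable:
    """Divide each sample's counts by its total: p_ij = x_ij / sum_j x_ij."""
    totals = table.counts.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        names = [table.samples[i] for i in zero]
        raise ValueError(f"samples with zero total count: {names}")
    values = table.counts / totals[:, None]
    return AbundanceTable(
        samples=list(table.samples),
        features=list(table.features),
        values=values,
        stage="relative",
    )


def _require_stage(table: AbundanceTable, stage: Stage) -> None:
    if table.stage != stage:
        raise ValueError(f"expected stage {stage!r}, got {table.stage!r}")


def transform_sqrt(table: AbundanceTable) -> AbundanceTable:
    """Elementwise sqrt(p); variance-stabilizing for small proportions."""
    _require_stage(table, "relative")
    return AbundanceTable(
        samples=list(table.samples),
        features=list(table.features),
        values=np.sqrt(table.values),
        stage="sqrt_transformed",
    )


def transform_arcsine(table: AbundanceTable) -> AbundanceTable:
    """Elementwise arcsin(sqrt(p)), in radians; maps [0, 1] to [0, pi/2]."""
    _require_stage(table, "relative")
    if table.values.min() < 0 or table.values.max() > 1:
        raise ValueError("arcsine transform requires values in [0, 1]")
    return AbundanceTable(
        samples=list(table.samples),
        features=list(table.features),
        values=np.arcsin(np.sqrt(table.values)),
        stage="arcsine_transformed",
    )


_TRANSFORMS = {
    "none": lambda t: t,
    "sqrt": transform_sqrt,
    "arcsine": transform_arcsine,
}


def apply_transform(table: AbundanceTable, name: str) -> AbundanceTable:
    """Apply a named transform ('none', 'sqrt' or 'arcsine') to proportions."""
    if name not in _TRANSFORMS:
        raise ValueError(f"unknown transform {name!r}")
    return _TRANSFORMS[name](table)


def bartlett_homogeneity(table: AbundanceTable) -> BartlettResult:
    """Bartlett's test with samples as groups.

    Each sample contributes its m feature values as one group of
    observations, so the test asks whether within-sample variance is the
    same across samples.  df = n - 1; the p-value is the chi-squared upper
    tail.
    """
    n, m = table.values.shape
    if m < 2:
        raise ValueError("Bartlett's test needs at least 2 features per sample")
    variances = table.values.var(axis=1, ddof=1)
    zero = np.nonzero(variances == 0)[0]
    if zero.size:
        names = [table.samples[i] for i in zero]
        raise ValueError(f"zero within-sample variance for samples: {names}")
    statistic, p_value = stats.bartlett(*table.values)
    return BartlettResult(
        statistic=float(statistic),
        df=n - 1,
        p_value=float(p_value),
        group_variances=variances,
    )


def choose_transform(table: AbundanceTable, alpha: float = 0.05) -> str:
    """Advisory transform choice from variance homogeneity and data range.

    Homogeneous variances (Bartlett p >= alpha) need no transform.  Under
    heterogeneity, proportions confined to a single band — all <= 0.3, or
    every nonzero value >= 0.7 — are handled by the square root; data
    spanning both bands (or neither) get the arcsine.  Zeros are treated as
    structural and allowed in the high band.
    """
    _require_stage(table, "relative")
    result = bartlett_homogeneity(table)
    if result.p_value >= alpha:
        return "none"
    values = table.values
    nonzero = values[values > 0]
    low_band = values.max() <= 0.3
    high_band = nonzero.size > 0 and nonzero.min() >= 0.7
    if low_band != high_band:  # exactly one band
        return "sqrt"
    return "arcsine"
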
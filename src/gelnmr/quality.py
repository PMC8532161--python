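"""Closed-form gel quality descriptors: CIELAB color difference, texture
profile algebra, moisture relative change, and a Pearson correlation
utility for relating quality descriptors to relaxation parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ColorLab",
    "TPAMeasures",
    "delta_e",
    "tpa_derived",
    "relative_change",
    "pearson_r",
    "COLOR_TABLE",
    "TPA_TABLE",
]


@dataclass(frozen=True)
class ColorLab:
    """CIELAB color coordinates: L* lightness (0-100), a* red/green, b* yellow/blue."""

    L: float
    a: float
    b: float

    def __post_init__(self):
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")


@dataclass(frozen=True)
class TPAMeasures:
    """Texture-profile-analysis descriptors of one sample.

    hardness N; adhesiveness g cm; cohesiveness dimensionless (0-1);
    springiness mm; gumminess N; chewiness g cm.
    """

    hardness: float
    cohesiveness: float
    springiness: float
    adhesiveness: float | None = None
    gumminess: float | None = None
    chewiness: float | None = None

    def __post_init__(self):
        if self.hardness < 0:
            raise ValueError("hardness must be non-negative")
        if not 0.0 <= self.cohesiveness <= 1.0:
            raise ValueError("cohesiveness must lie in [0, 1]")


def delta_e(sample: ColorLab, reference: ColorLab) -> float:
    """Total color change: CIE76 Euclidean distance in L*a*b* space."""
    return math.sqrt(
        (sample.L - reference.L) ** 2
        + (sample.a - reference.a) ** 2
        + (sample.b - reference.b) ** 2
    )


def tpa_derived(hardness: float, cohesiveness: float, springiness: float):
    """Gumminess = hardness x cohesiveness; chewiness = gumminess x springiness."""
    if hardness < 0 or cohesiveness < 0 or springiness < 0:
        raise ValueError("TPA inputs must be non-negative")
    gumminess = hardness * cohesiveness
    return gumminess, gumminess * springiness


def relative_change(value: float, reference: float) -> float:
    """Plain ratio value / reference (reference sample = 1.0)."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return value / reference


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("inputs must have non-zero variance")
    return float(stats.pearsonr(x, y).statistic)


# Published descriptor tables for the four gel formulations (means).
COLOR_TABLE: dict[str, ColorLab] = {
    "SUC": ColorLab(30.98, 0.18, 1.05),
    "SBF10": ColorLab(37.35, 0.38, 1.29),
    "SCG40": ColorLab(30.20, 0.14, 0.38),
    "SCG60": ColorLab(33.67, 0.25, 0.65),
}

TPA_TABLE: dict[str, TPAMeasures] = {
    "SUC": TPAMeasures(hardness=0.64, cohesiveness=0.19, springiness=2.08,
                       gumminess=0.13),
    "SBF10": TPAMeasures(hardness=1.78, cohesiveness=0.43, springiness=6.36,
                         adhesiveness=23.50, gumminess=0.76, chewiness=49.00),
    "SCG40": TPAMeasures(hardness=2.60, cohesiveness=0.37, springiness=5.08,
                         adhesiveness=11.00, gumminess=0.95, chewiness=49.00),
    "SCG60": TPAMeasures(hardness=1.92, cohesiveness=0.28, springiness=3.74,
                         adhesiveness=5.50, gumminess=0.53, chewiness=20.00),
}
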
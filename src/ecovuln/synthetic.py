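"""Seeded synthetic decision matrices with controllable dispersion.

Columns are drawn i.i.d. across regions from a log-normal distribution
parameterized by its mean (``base_scale``) and coefficient of variation
(``dispersion``), mirroring the statistical shape the method consumes:
small n, strictly positive values, heterogeneous column scales.  Higher
cross-region dispersion concentrates the translated proportions, lowers
the column entropy and raises its weight — the property the generator
exists to exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    IndicatorDescriptor,
    IndicatorMatrix,
    MatrixValidationError,
    Orientation,
)

__all__ = ["SynthSpec", "generate_matrix", "degenerate_fixtures"]


@dataclass
class SynthSpec:
    """Recipe for one random decision matrix."""

    n_regions: int = 9
    m_indicators: int = 10
    dispersion: Optional[Sequence[float]] = None  # target CV per column, default 0.3
    base_scale: Optional[Sequence[float]] = None  # column means, default 1.0
    orientation_pattern: Optional[Sequence[Orientation]] = None  # default contrarian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise MatrixValidationError("n_regions must be >= 2")
        if self.m_indicators < 1:
            raise MatrixValidationError("m_indicators must be >= 1")
        m = self.m_indicators
        self.dispersion = np.asarray(
            [0.3] * m if self.dispersion is None else self.dispersion, dtype=float
        )
        self.base_scale = np.asarray(
            [1.0] * m if self.base_scale is None else self.base_scale, dtype=float
        )
        if self.dispersion.shape != (m,) or self.base_scale.shape != (m,):
            raise MatrixValidationError("dispersion/base_scale length must equal m")
        if (self.dispersion <= 0).any() or (self.base_scale <= 0).any():
            raise MatrixValidationError("dispersion and base_scale must be > 0")
        if self.orientation_pattern is None:
            self.orientation_pattern = [Orientation.CONTRARIAN] * m
        else:
            self.orientation_pattern = [Orientation(o) for o in self.orientation_pattern]
            if len(self.orientation_pattern) != m:
                raise MatrixValidationError("orientation_pattern length must equal m")


def generate_matrix(spec: SynthSpec) -> IndicatorMatrix:
    """Draw a matrix per the spec; fully reproducible from ``spec.seed``.

    Log-normal moments: for target mean mu and CV c,
    sigma^2 = ln(1 + c^2) and the log-mean is ln(mu) - sigma^2 / 2.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_regions, spec.m_indicators
    sigma2 = np.log1p(np.asarray(spec.dispersion) ** 2)
    mu_log = np.log(np.asarray(spec.base_scale)) - sigma2 / 2
    values = rng.lognormal(mean=mu_log, sigma=np.sqrt(sigma2), size=(n, m))
    regions = [f"R{j + 1}" for j in range(n)]
    indicators = [
        IndicatorDescriptor(id=f"I{i + 1}", orientation=spec.orientation_pattern[i])
        for i in range(m)
    ]
    return IndicatorMatrix(regions=regions, indicators=indicators, values=values)


@dataclass
class DegenerateFixture:
    """Raw ingredients for one deliberately invalid/degenerate input.

    Kept pre-construction because some fixtures (e.g. a single region)
    must fail IndicatorMatrix validation itself; tests feed these to the
    constructors or pipeline stages to fire the declared error paths.
    """

    regions: list[str]
    indicator_ids: list[str]
    values: np.ndarray
    triggers: str = ""
    descriptors: list[IndicatorDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.descriptors:
            self.descriptors = [IndicatorDescriptor(id=i) for i in self.indicator_ids]


def degenerate_fixtures() -> dict[str, DegenerateFixture]:
    """Named inputs exercising every declared error path."""
    return {
        "zero_variance": DegenerateFixture(
            regions=["R1", "R2", "R3"],
            indicator_ids=["flat", "ok"],
            values=np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]),
            triggers="zscore_standardize(policy=error) raises ZeroVarianceError",
        ),
        "single_region": DegenerateFixture(
            regions=["only"],
            indicator_ids=["I1"],
            values=np.array([[1.0]]),
            triggers="IndicatorMatrix construction raises MatrixValidationError",
        ),
        "non_finite": DegenerateFixture(
            regions=["R1", "R2"],
            indicator_ids=["I1"],
            values=np.array([[1.0], [np.nan]]),
            triggers="IndicatorMatrix construction raises MatrixValidationError",
        ),
        "all_uniform": DegenerateFixture(
            # every column constant => after drop nothing remains; with a
            # uniform-proportions p fed directly, weights() raises
            regions=["R1", "R2", "R3"],
            indicator_ids=["I1", "I2"],
            values=np.array([[2.0, 7.0], [2.0, 7.0], [2.0, 7.0]]),
            triggers="weights() on uniform proportions raises DegenerateWeightsError",
        ),
    }
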
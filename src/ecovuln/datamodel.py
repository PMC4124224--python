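"""Domain types for entropy-weight vulnerability assessment.

The method operates on a decision matrix of *n* regions by *m* indicators.
Following the field's indexing convention, the subscript ``i`` runs over
indicators and ``j`` over regions; in memory, however, the grids are stored
regions-as-rows (shape ``(n, m)``), which is the natural tabular layout for
CSV files and pandas.  All code in this package uses the in-memory layout
and reserves the i/j vocabulary for docstrings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Category",
    "Orientation",
    "AggregationMode",
    "ZeroVariancePolicy",
    "IndicatorDescriptor",
    "IndicatorMatrix",
    "StandardizedMatrix",
    "WeightingResult",
    "AssessmentResult",
    "AssessmentConfig",
    "EcovulnError",
    "MatrixValidationError",
    "ZeroVarianceError",
    "AmplitudeError",
    "DegenerateWeightsError",
    "AggregationModeError",
]


class EcovulnError(Exception):
    """Base class for all domain errors raised by this package."""


class MatrixValidationError(EcovulnError):
    """A decision matrix or catalog violates a structural invariant."""


class ZeroVarianceError(EcovulnError):
    """An indicator column is constant across regions (population SD = 0)."""


class AmplitudeError(EcovulnError):
    """A translation amplitude violates A > |min z| (or A < 0)."""


class DegenerateWeightsError(EcovulnError):
    """Every indicator is perfectly uniform (all entropies 1); entropy
    weights are undefined.  Equal weights are a possible fallback but are
    never applied silently."""


class AggregationModeError(EcovulnError):
    """The requested aggregation mode is undefined for the given
    orientation pattern (e.g. a ratio with no positive indicators)."""


class Category(str, enum.Enum):
    """Principle layer an indicator belongs to."""

    CLIMATE = "climate"
    WATER = "water"
    SOIL = "soil"
    HUMAN = "human"


class Orientation(str, enum.Enum):
    """Benefit-type (positive) vs cost-type (contrarian) criterion.

    A contrarian indicator is one whose larger values signal greater
    vulnerability pressure (droughts, degradation, shortage); its
    contribution to the composite index is through ``1 - p`` rather
    than ``p``.
    """

    POSITIVE = "positive"
    CONTRARIAN = "contrarian"


class AggregationMode(str, enum.Enum):
    WEIGHTED_COMPLEMENT = "weighted_complement"
    LITERAL_RATIO = "literal_ratio"


class ZeroVariancePolicy(str, enum.Enum):
    ERROR = "error"
    DROP = "drop"


@dataclass(frozen=True)
class IndicatorDescriptor:
    """Metadata for one indicator column."""

    id: str
    label: str = ""
    category: Category = Category.CLIMATE
    orientation: Orientation = Orientation.CONTRARIAN

    def __post_init__(self) -> None:
        if not self.id:
            raise MatrixValidationError("indicator id must be nonempty")
        if not isinstance(self.category, Category):
            object.__setattr__(self, "category", Category(self.category))
        if not isinstance(self.orientation, Orientation):
            object.__setattr__(self, "orientation", Orientation(self.orientation))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise MatrixValidationError(f"duplicate {what} ID {x!r}")
        seen.add(x)


@dataclass
class IndicatorMatrix:
    """Raw decision matrix: ``values[j, i]`` is indicator *i* in region *j*.

    Invariants enforced at construction: at least two regions (the
    population SD of a single observation is degenerate), at least one
    indicator, unique region and indicator IDs, and no missing or
    non-finite cells.
    """

    regions: list[str]
    indicators: list[IndicatorDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.regions), len(self.indicators)
        if n < 2:
            raise MatrixValidationError(
                f"need at least 2 regions, got {n} (population SD of a "
                "single observation is degenerate)"
            )
        if m < 1:
            raise MatrixValidationError("need at least 1 indicator")
        if self.values.shape != (n, m):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} regions x {m} indicators"
            )
        _check_unique(self.regions, "region")
        _check_unique([d.id for d in self.indicators], "indicator")
        if not np.all(np.isfinite(self.values)):
            j, i = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise MatrixValidationError(
                f"non-finite cell at region {self.regions[j]!r}, "
                f"indicator {self.indicators[i].id!r}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def indicator_ids(self) -> list[str]:
        return [d.id for d in self.indicators]

    @property
    def orientations(self) -> list[Orientation]:
        return [d.orientation for d in self.indicators]


@dataclass
class StandardizedMatrix:
    """Z-scores and (once translated) strictly positive shifted values.

    ``z_values[j, i] = (X[j, i] - mean_i) / sd_i`` with the population
    standard deviation (divide by n).  ``shifted_values = z_values + A``.
    ``amplitude`` is ``None`` until :func:`~ecovuln.standardization.translate`
    fills the shifted part.
    """

    regions: list[str]
    indicators: list[IndicatorDescriptor]
    z_values: np.ndarray
    col_means: np.ndarray
    col_stds: np.ndarray
    amplitude: Optional[float] = None
    shifted_values: Optional[np.ndarray] = None

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def indicator_ids(self) -> list[str]:
        return [d.id for d in self.indicators]


@dataclass
class WeightingResult:
    """Per-indicator entropy weighting: proportions p, entropies e,
    difference coefficients g = 1 - e, and normalized weights w."""

    indicator_ids: list[str]
    proportions: np.ndarray  # (n, m); each column sums to 1
    k: float  # 1 / ln(n)
    entropies: np.ndarray  # (m,), each in [0, 1]
    diff_coeffs: np.ndarray  # (m,), 1 - e
    weights: np.ndarray  # (m,), sums to 1


@dataclass
class AssessmentResult:
    """Composite vulnerability indices and the region ranking."""

    regions: list[str]
    composite: np.ndarray  # (n,) V_j
    ranking: list[str]  # region IDs by descending V, ties by input order
    mode: AggregationMode
    amplitude: float
    provenance: dict = field(default_factory=dict)


@dataclass
class AssessmentConfig:
    """Run options for the end-to-end pipeline.

    amplitude
        Translation amplitude A.  When ``None`` the default rule picks the
        smallest multiple of 0.1 strictly greater than ``|min z|``.
    aggregation_mode
        ``weighted_complement`` (default; reproduces the reference case
        study) or ``literal_ratio``.
    zero_variance_policy
        ``error`` (default) or ``drop`` for constant indicator columns.
    report_decimals
        Rounding applied to report files only; computation is always at
        full floating precision.
    """

    amplitude: Optional[float] = None
    aggregation_mode: AggregationMode = AggregationMode.WEIGHTED_COMPLEMENT
    zero_variance_policy: ZeroVariancePolicy = ZeroVariancePolicy.ERROR
    report_decimals: int = 4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.aggregation_mode, AggregationMode):
            self.aggregation_mode = AggregationMode(self.aggregation_mode)
        if not isinstance(self.zero_variance_policy, ZeroVariancePolicy):
            self.zero_variance_policy = ZeroVariancePolicy(self.zero_variance_policy)
        if not (0 <= int(self.report_decimals) <= 10):
            raise MatrixValidationError(
                f"report_decimals must be in [0, 10], got {self.report_decimals}"
            )
        if self.amplitude is not None and self.amplitude < 0:
            raise AmplitudeError(f"amplitude must be >= 0, got {self.amplitude}")
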
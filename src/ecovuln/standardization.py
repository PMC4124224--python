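"""Z-score standardization, coordinate translation, and the textbook
normalizations kept for comparison.

Standardization uses the *population* standard deviation (divide by n, not
n-1); that convention is what makes the reference tables reproducible.
The coordinate translation x' = z + A with A > |min z| makes every value
strictly positive so that proportions can be formed; smaller admissible A
preserves more of the contrast between regions.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .datamodel import (
    AmplitudeError,
    IndicatorMatrix,
    MatrixValidationError,
    StandardizedMatrix,
    ZeroVarianceError,
    ZeroVariancePolicy,
)

log = logging.getLogger("ecovuln")

__all__ = ["zscore_standardize", "default_amplitude", "translate", "alt_normalize"]


def zscore_standardize(
    matrix: IndicatorMatrix,
    policy: ZeroVariancePolicy | str = ZeroVariancePolicy.ERROR,
) -> StandardizedMatrix:
    """Per-indicator z-scores with population statistics.

    For indicator i: ``z[j, i] = (X[j, i] - mean_i) / sd_i`` where ``sd_i``
    divides by n.  A constant column has sd 0 and either raises
    :class:`ZeroVarianceError` (policy ``error``, the default) or is
    dropped with a logged warning (policy ``drop``).
    """
    policy = ZeroVariancePolicy(policy)
    X = matrix.values
    means = X.mean(axis=0)
    stds = X.std(axis=0)  # population (ddof=0)
    zero = stds == 0.0
    indicators = list(matrix.indicators)
    if zero.any():
        bad = [indicators[i].id for i in np.flatnonzero(zero)]
        if policy is ZeroVariancePolicy.ERROR:
            raise ZeroVarianceError(
                f"zero-variance indicator {', '.join(bad)}: constant across "
                "all regions; use policy='drop' to remove it"
            )
        log.warning("dropping zero-variance indicator(s): %s", ", ".join(bad))
        keep = ~zero
        X, means, stds = X[:, keep], means[keep], stds[keep]
        indicators = [d for d, k in zip(indicators, keep) if k]
        if not indicators:
            raise ZeroVarianceError("all indicator columns have zero variance")
    z = (X - means) / stds
    return StandardizedMatrix(
        regions=list(matrix.regions),
        indicators=indicators,
        z_values=z,
        col_means=means,
        col_stds=stds,
    )


def default_amplitude(std: StandardizedMatrix) -> float:
    """Smallest multiple of 0.1 strictly greater than ``|min z|``.

    Returns 0 when no z-score is negative (no translation needed).  The
    admissibility constraint is A > |min z|; keeping A as close to that
    bound as the one-decimal grid allows retains the most discrimination
    between regions.
    """
    zmin = float(std.z_values.min())
    if zmin >= 0.0:
        return 0.0
    m = abs(zmin)
    # 1e-9 guard: |min z| already on the 0.1 grid must still be exceeded
    return (math.floor(m * 10 + 1e-9) + 1) / 10


def translate(std: StandardizedMatrix, amplitude: float) -> StandardizedMatrix:
    """Fill the shifted part: ``x' = z + A``, all entries strictly > 0."""
    if amplitude < 0:
        raise AmplitudeError(f"amplitude must be >= 0, got {amplitude}")
    zmin = float(std.z_values.min())
    if zmin < 0 and amplitude <= abs(zmin):
        raise AmplitudeError(
            f"amplitude {amplitude} violates A > |min z| = {abs(zmin):.6g}; "
            "shifted values would not be strictly positive"
        )
    return StandardizedMatrix(
        regions=std.regions,
        indicators=std.indicators,
        z_values=std.z_values,
        col_means=std.col_means,
        col_stds=std.col_stds,
        amplitude=float(amplitude),
        shifted_values=std.z_values + amplitude,
    )


def alt_normalize(matrix: IndicatorMatrix, scheme: str) -> np.ndarray:
    """Comparison normalizations: ``range``, ``linear_scaling``, ``vector``.

    These are the standard per-column textbook forms.  They are provided
    for side-by-side comparison only and are never part of the default
    pipeline: range transformation discards between-column contrast,
    linear scaling is undefined for non-positive data, and vector
    normalization cannot distinguish benefit from cost indicators.
    """
    X = matrix.values
    ids = matrix.indicator_ids
    if scheme == "range":
        lo, hi = X.min(axis=0), X.max(axis=0)
        flat = hi == lo
        if flat.any():
            bad = [ids[i] for i in np.flatnonzero(flat)]
            raise ZeroVarianceError(
                f"range normalization undefined for constant column(s) {bad}"
            )
        return (X - lo) / (hi - lo)
    if scheme == "linear_scaling":
        if (X <= 0).any():
            j, i = map(int, np.argwhere(X <= 0)[0])
            raise MatrixValidationError(
                f"linear scaling requires all values > 0; offending column "
                f"{ids[i]!r} (region {matrix.regions[j]!r})"
            )
        return X / X.max(axis=0)
    if scheme == "vector":
        norms = np.sqrt((X**2).sum(axis=0))
        if (norms == 0).any():
            bad = [ids[i] for i in np.flatnonzero(norms == 0)]
            raise MatrixValidationError(
                f"vector normalization undefined for all-zero column(s) {bad}"
            )
        return X / norms
    raise ValueError(f"unknown scheme {scheme!r}; expected range|linear_scaling|vector")
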
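"""Shannon-entropy indicator weighting.

An indicator whose translated values are spread unevenly across regions
carries more discriminating information: its proportion vector has lower
entropy, hence a larger difference coefficient g = 1 - e and a larger
normalized weight w.  The normalizing constant k = 1/ln(n) pins the
entropy of the perfectly uniform column at exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import (
    DegenerateWeightsError,
    EcovulnError,
    StandardizedMatrix,
    WeightingResult,
)

log = logging.getLogger("ecovuln")

__all__ = ["proportions", "entropies", "weights", "compute_weighting"]

# floating-point overshoot absorbed when clamping e into [0, 1]
_CLAMP_TOL = 1e-12


def proportions(shifted: StandardizedMatrix) -> np.ndarray:
    """Column-normalized shares: ``p[j, i] = x'[j, i] / sum_j x'[j, i]``.

    Requires the translated matrix (all entries strictly positive).
    """
    xp = shifted.shifted_values
    if xp is None:
        raise EcovulnError("matrix has not been translated; run translate() first")
    if (xp <= 0).any():
        j, i = map(int, np.argwhere(xp <= 0)[0])
        raise EcovulnError(
            f"non-positive shifted value at region {shifted.regions[j]!r}, "
            f"indicator {shifted.indicator_ids[i]!r}; check the amplitude"
        )
    return xp / xp.sum(axis=0)


def entropies(p: np.ndarray, n: int) -> np.ndarray:
    """Per-indicator entropy ``e_i = -(1/ln n) sum_j p_ij ln p_ij``.

    Each column of ``p`` must sum to 1.  Entries are expected strictly
    positive (guaranteed upstream by the translation); should a zero ever
    reach this point the 0*ln 0 = 0 convention is applied defensively with
    a logged warning.  Results are clamped into [0, 1] only against
    floating-point overshoot below 1e-12.
    """
    p = np.asarray(p, dtype=float)
    if n < 2:
        raise EcovulnError(f"entropy normalization k = 1/ln(n) undefined for n = {n}")
    if p.ndim == 1:
        p = p[:, None]
    if (p == 0).any():
        log.warning("zero proportion encountered; applying 0*ln(0) = 0 convention")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    over = (e < -_CLAMP_TOL) | (e > 1 + _CLAMP_TOL)
    if over.any():
        raise EcovulnError(
            f"entropy outside [0, 1] beyond tolerance: {e[over]} — proportion "
            "columns likely do not sum to 1"
        )
    return np.clip(e, 0.0, 1.0)


def weights(e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Difference coefficients ``g = 1 - e`` and weights ``w = g / sum g``.

    Raises :class:`DegenerateWeightsError` when every entropy equals 1
    (all columns perfectly uniform): the weights are then undefined, and
    the caller may choose equal weights explicitly instead.
    """
    e = np.asarray(e, dtype=float)
    g = 1.0 - e
    total = g.sum()
    if total <= _CLAMP_TOL * max(len(e), 1):
        raise DegenerateWeightsError(
            "all entropies equal 1 (every indicator uniform across regions); "
            "entropy weights are undefined — consider explicit equal weights"
        )
    return g, g / total


def compute_weighting(shifted: StandardizedMatrix) -> WeightingResult:
    """Run proportions -> entropies -> weights on a translated matrix."""
    p = proportions(shifted)
    n = shifted.n_regions
    e = entropies(p, n)
    g, w = weights(e)
    return WeightingResult(
        indicator_ids=shifted.indicator_ids,
        proportions=p,
        k=1.0 / np.log(n),
        entropies=e,
        diff_coeffs=g,
        weights=w,
    )
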
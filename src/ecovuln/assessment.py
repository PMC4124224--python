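"""Composite vulnerability index, ranking, the end-to-end pipeline, and
amplitude sensitivity analysis.

Two aggregation modes are offered.  The default, ``weighted_complement``,
forms ``V_j = sum_{positive i} w_i p_ij + sum_{contrarian k} w_k (1 - p_kj)``;
with every indicator cost-type this is a weighted sum of complements, the
form consistent with the reference case-study results (whose mean is
exactly (n-1)/n for any weights summing to 1).  ``literal_ratio`` computes
the quotient ``(sum_pos w_i p_ij) / (sum_con w_k (1 - p_kj))`` instead; it
requires both orientation groups to be non-empty and is documented as NOT
matching the reference case-study numbers.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .datamodel import (
    AggregationMode,
    AggregationModeError,
    AmplitudeError,
    AssessmentConfig,
    AssessmentResult,
    EcovulnError,
    IndicatorMatrix,
    Orientation,
    StandardizedMatrix,
    WeightingResult,
)
from .entropy_weighting import compute_weighting
from .standardization import default_amplitude, translate, zscore_standardize

__all__ = ["composite_index", "rank_regions", "assess", "amplitude_sensitivity"]


def composite_index(
    p: np.ndarray,
    w: np.ndarray,
    orientations: Sequence[Orientation],
    mode: AggregationMode | str = AggregationMode.WEIGHTED_COMPLEMENT,
) -> np.ndarray:
    """Per-region composite index V_j from proportions and weights."""
    mode = AggregationMode(mode)
    orient = [Orientation(o) for o in orientations]
    pos = np.array([o is Orientation.POSITIVE for o in orient])
    con = ~pos
    pos_part = (w[pos] * p[:, pos]).sum(axis=1)
    con_part = (w[con] * (1.0 - p[:, con])).sum(axis=1)
    if mode is AggregationMode.WEIGHTED_COMPLEMENT:
        return pos_part + con_part
    # literal_ratio
    if not pos.any() or not con.any():
        raise AggregationModeError(
            "literal_ratio requires at least one positive and one contrarian "
            "indicator; the ratio is undefined otherwise"
        )
    if (con_part == 0).any():
        raise EcovulnError("literal_ratio denominator is zero for some region")
    return pos_part / con_part


def rank_regions(regions: Sequence[str], composite: np.ndarray) -> list[str]:
    """Regions sorted by descending V; exact ties keep input order."""
    order = np.argsort(-np.asarray(composite, dtype=float), kind="stable")
    return [regions[j] for j in order]


def assess(
    matrix: IndicatorMatrix, config: AssessmentConfig | None = None
) -> tuple[StandardizedMatrix, WeightingResult, AssessmentResult]:
    """Full pipeline: z-scores, amplitude, translation, entropy weights,
    composite index, ranking.  All intermediates are returned so reports
    can mirror each stage."""
    config = config or AssessmentConfig()
    try:
        std = zscore_standardize(matrix, config.zero_variance_policy)
    except EcovulnError as err:
        raise type(err)(f"standardization: {err}") from err
    A = config.amplitude if config.amplitude is not None else default_amplitude(std)
    try:
        std = translate(std, A)
    except EcovulnError as err:
        raise type(err)(f"translation: {err}") from err
    try:
        weighting = compute_weighting(std)
    except EcovulnError as err:
        raise type(err)(f"weighting: {err}") from err
    try:
        V = composite_index(
            weighting.proportions,
            weighting.weights,
            [d.orientation for d in std.indicators],
            config.aggregation_mode,
        )
    except EcovulnError as err:
        raise type(err)(f"aggregation: {err}") from err
    result = AssessmentResult(
        regions=std.regions,
        composite=V,
        ranking=rank_regions(std.regions, V),
        mode=config.aggregation_mode,
        amplitude=float(A),
        provenance={
            "n_regions": std.n_regions,
            "n_indicators": len(std.indicators),
            "amplitude_source": "config" if config.amplitude is not None else "auto",
            "zero_variance_policy": config.zero_variance_policy.value,
        },
    )
    return std, weighting, result


def amplitude_sensitivity(
    matrix: IndicatorMatrix,
    config: AssessmentConfig,
    amplitudes: Sequence[float],
) -> list[dict]:
    """One pipeline run per amplitude; reports the weight spread
    (max w - min w) and the ranking so discrimination decay with growing A
    is inspectable.  An inadmissible A yields an ``error`` entry; the
    remaining amplitudes still run.
    """
    rows: list[dict] = []
    for A in amplitudes:
        try:
            _, weighting, result = assess(matrix, replace(config, amplitude=float(A)))
        except (AmplitudeError, EcovulnError) as err:
            rows.append({"amplitude": float(A), "error": str(err)})
            continue
        w = weighting.weights
        rows.append(
            {
                "amplitude": float(A),
                "weights": w,
                "weight_spread": float(w.max() - w.min()),
                "composite": result.composite,
                "ranking": result.ranking,
            }
        )
    return rows
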
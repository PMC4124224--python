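"""CSV / config readers and writers, the packaged case-study fixture, and
report emission.

The on-disk decision matrix is a UTF-8 CSV with header
``region,<id1>,...,<idm>``: regions as rows (human convention), indicators
as columns.  The indicator catalog and run options travel in one YAML or
JSON config with an ``indicators`` list plus optional ``amplitude``,
``aggregation_mode``, ``zero_variance_policy``, ``report_decimals`` and
``seed`` keys.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AssessmentConfig,
    AssessmentResult,
    IndicatorDescriptor,
    IndicatorMatrix,
    MatrixValidationError,
    StandardizedMatrix,
    WeightingResult,
)

log = logging.getLogger("ecovuln")

Catalog = Sequence[IndicatorDescriptor]
PathLike = Union[str, Path]


def read_config(path: PathLike) -> tuple[list[IndicatorDescriptor], AssessmentConfig]:
    """Parse a YAML/JSON config into (catalog, run options)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "indicators" not in data:
        raise MatrixValidationError(f"config {path}: missing 'indicators' list")
    catalog = [
        IndicatorDescriptor(
            id=str(entry["id"]),
            label=str(entry.get("label", "")),
            category=entry.get("category", "climate"),
            orientation=entry.get("orientation", "contrarian"),
        )
        for entry in data["indicators"]
    ]
    cfg = AssessmentConfig(
        amplitude=data.get("amplitude"),
        aggregation_mode=data.get("aggregation_mode", "weighted_complement"),
        zero_variance_policy=data.get("zero_variance_policy", "error"),
        report_decimals=data.get("report_decimals", 4),
        seed=data.get("seed"),
    )
    return catalog, cfg


def read_matrix(path: PathLike, catalog: Catalog) -> IndicatorMatrix:
    """Read a decision-matrix CSV and validate it against a catalog.

    Row and column order are preserved from the file.  Every indicator
    column must appear in the catalog; missing or non-numeric cells are
    parse errors naming the offending row and column.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise MatrixValidationError(f"{path}: expected a region column plus indicators")
    region_col = df.columns[0]
    regions = df[region_col].tolist()
    ids = [str(c) for c in df.columns[1:]]
    by_id = {d.id: d for d in catalog}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise MatrixValidationError(
            f"{path}: indicator column(s) {missing} not present in catalog"
        )
    values = np.empty((len(regions), len(ids)))
    for ci, col in enumerate(df.columns[1:]):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            j = int(bad[0])
            raise MatrixValidationError(
                f"{path}: missing or non-numeric cell at row {regions[j]!r}, "
                f"column {ids[ci]!r}"
            )
        values[:, ci] = parsed.to_numpy()
    return IndicatorMatrix(
        regions=regions, indicators=[by_id[i] for i in ids], values=values
    )


def write_matrix(matrix: IndicatorMatrix, path: PathLike) -> None:
    """Write a matrix back to CSV at full precision (round-trip safe)."""
    df = pd.DataFrame(matrix.values, columns=matrix.indicator_ids)
    df.insert(0, "region", matrix.regions)
    # shortest round-trip repr; reader uses float_precision="round_trip"
    df.to_csv(path, index=False)


def load_jilin_fixture() -> IndicatorMatrix:
    """The packaged western-Jilin 9-region x 10-indicator decision matrix.

    All ten indicators are vulnerability-driving (cost-type) and encoded
    ``contrarian``; under the default weighted-complement aggregation this
    reproduces the published case-study results.
    """
    pkg = resources.files("ecovuln").joinpath("data")
    with resources.as_file(pkg.joinpath("jilin_catalog.yaml")) as cfg_path:
        catalog, _ = read_config(cfg_path)
    with resources.as_file(pkg.joinpath("jilin_matrix.csv")) as csv_path:
        return read_matrix(csv_path, catalog)


def load_jilin_config() -> AssessmentConfig:
    """Run options matching the published case study (A = 2.2)."""
    pkg = resources.files("ecovuln").joinpath("data")
    with resources.as_file(pkg.joinpath("jilin_catalog.yaml")) as cfg_path:
        _, cfg = read_config(cfg_path)
    return cfg


def _grid_frame(
    regions: list[str], ids: list[str], grid: np.ndarray, decimals: int
) -> pd.DataFrame:
    df = pd.DataFrame(np.round(grid, decimals), columns=ids)
    df.insert(0, "region", regions)
    return df


def write_report(
    result: AssessmentResult,
    weighting: WeightingResult,
    std: StandardizedMatrix,
    out_dir: PathLike,
    decimals: int = 4,
) -> dict[str, Path]:
    """Emit the report files for one pipeline run.

    Writes CSV tables for the z-scores, translated values, proportions and
    per-indicator weights, plus a JSON summary with the composite indices,
    ranking, amplitude and mode.  Rounding to ``decimals`` is presentation
    only; upstream computation is at full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions, ids = std.regions, std.indicator_ids
    fmt = f"%.{decimals}f"
    files: dict[str, Path] = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format=fmt)
        files[name] = p

    _csv("standardized.csv", _grid_frame(regions, ids, std.z_values, decimals))
    if std.shifted_values is not None:
        _csv("translated.csv", _grid_frame(regions, ids, std.shifted_values, decimals))
    _csv("proportions.csv", _grid_frame(regions, ids, weighting.proportions, decimals))
    wdf = pd.DataFrame(
        {
            "indicator": weighting.indicator_ids,
            "entropy": np.round(weighting.entropies, decimals),
            "diff_coeff": np.round(weighting.diff_coeffs, decimals),
            "weight": np.round(weighting.weights, decimals),
        }
    )
    _csv("weights.csv", wdf)

    summary = {
        "composite": {
            r: round(float(v), decimals) for r, v in zip(regions, result.composite)
        },
        "ranking": result.ranking,
        "amplitude": result.amplitude,
        "mode": result.mode.value,
        "k": weighting.k,
        "provenance": result.provenance,
    }
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2), encoding="utf-8")
    files["summary.json"] = p
    log.info(
        "report written to %s (A=%s, k=%.6f, mode=%s)",
        out,
        result.amplitude,
        weighting.k,
        result.mode.value,
    )
    return files
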
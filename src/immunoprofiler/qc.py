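"""Housekeeping-gene QC gate and two-stage geometric-mean normalization.

QC: the geometric mean of the housekeeping probes measures overall RNA
quality/quantity; samples below the threshold (default 100 counts) are
excluded before normalization.

Normalization is sequential and cohort-wise.  For each stage (positive
controls first, then housekeeping genes) a per-sample geometric mean of the
reference probes is computed (geomean_s), the cohort geometric mean of those
geomeans (geomean_geomeans), and every count of sample s is multiplied by
f_s = geomean_geomeans / geomean_s.  After each stage the reference-probe
geometric mean is identical across samples.  Because geomean_geomeans is a
cohort quantity, the batch composition is part of the provenance.

Zero counts are floored (default 1) before logs; the floor is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nanostring import CountsMatrix, PanelDefinition

DEFAULT_QC_THRESHOLD = 100.0
DEFAULT_FLOOR = 1.0


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    hk_geomean: float
    passed: bool
    threshold: float


def geometric_mean(values: Sequence[float] | np.ndarray, floor: float = DEFAULT_FLOOR) -> float:
    """exp(mean(log(max(v, floor)))) over the values; empty input is an error."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric_mean of empty list")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return float(np.exp(np.mean(np.log(np.maximum(arr, floor)))))


def _row_geomeans(data: pd.DataFrame, probes: Sequence[str], floor: float) -> pd.Series:
    sub = data[list(probes)].to_numpy(float)
    return pd.Series(np.exp(np.mean(np.log(np.maximum(sub, floor)), axis=1)), index=data.index)


def qc_filter(counts: CountsMatrix, panel: PanelDefinition,
              threshold: float = DEFAULT_QC_THRESHOLD,
              floor: float = DEFAULT_FLOOR) -> tuple[list[QCReport], CountsMatrix]:
    """Gate samples on the housekeeping geometric mean.

    A sample passes iff hk_geomean >= threshold (the exclusion rule is
    "< threshold", so a sample exactly at the threshold passes).  The
    returned matrix keeps passing samples in their original order.
    """
    if counts.stage != "raw":
        raise ValueError(f"qc_filter expects a raw counts matrix, got stage {counts.stage!r}")
    hk = panel.housekeeping_probes
    if not hk:
        raise ValueError("panel has no Housekeeping probes")
    geo = _row_geomeans(counts.data, hk, floor)
    reports = [QCReport(sample_id=s, hk_geomean=float(g), passed=bool(g >= threshold),
                        threshold=threshold)
               for s, g in geo.items()]
    keep = [r.sample_id for r in reports if r.passed]
    passed = CountsMatrix(data=counts.data.loc[keep].copy(), stage="raw")
    return reports, passed


def qc_report_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": [r.sample_id for r in reports],
         "hk_geomean": [r.hk_geomean for r in reports],
         "pass": [r.passed for r in reports]})


def normalize_stage(counts: CountsMatrix, reference_probes: Sequence[str],
                    floor: float = DEFAULT_FLOOR) -> CountsMatrix:
    """Scale each sample by geomean_geomeans / geomean_s of the reference probes.

    Advances the stage by one (raw -> posctrl_normalized -> fully_normalized)
    and stores the factor vector in the matching provenance slot.
    """
    if counts.stage == "fully_normalized":
        raise ValueError("counts are already fully normalized")
    reference_probes = list(reference_probes)
    if not reference_probes:
        raise ValueError("reference_probes must be non-empty")
    missing = set(reference_probes) - set(counts.probes)
    if missing:
        raise ValueError(f"reference probes not in matrix: {sorted(missing)}")

    geo = _row_geomeans(counts.data, reference_probes, floor)
    zero = geo[geo <= 0]
    if len(zero):
        raise ValueError(f"zero reference geomean for samples: {zero.index.tolist()}")
    geomean_geomeans = geometric_mean(geo.to_numpy(), floor=np.finfo(float).tiny)
    factors = geomean_geomeans / geo
    data = counts.data.mul(factors, axis=0)
    if counts.stage == "raw":
        return CountsMatrix(data=data, stage="posctrl_normalized",
                            posctrl_factor=factors)
    return CountsMatrix(data=data, stage="fully_normalized",
                        posctrl_factor=counts.posctrl_factor, hk_factor=factors)


def normalize(counts: CountsMatrix, panel: PanelDefinition,
              floor: float = DEFAULT_FLOOR) -> CountsMatrix:
    """Sequential positive-control then housekeeping normalization."""
    if counts.stage != "raw":
        raise ValueError(f"normalize expects a raw counts matrix, got stage {counts.stage!r}")
    pos = panel.positive_probes
    if not pos:
        raise ValueError("panel has no Positive probes")
    stage1 = normalize_stage(counts, pos, floor=floor)
    return normalize_stage(stage1, panel.housekeeping_probes, floor=floor)


def factors_frame(counts: CountsMatrix) -> pd.DataFrame:
    """Per-sample normalization factors as a table (provenance export)."""
    cols = {}
    if counts.posctrl_factor is not None:
        cols["posctrl_factor"] = counts.posctrl_factor
    if counts.hk_factor is not None:
        cols["hk_factor"] = counts.hk_factor
    return pd.DataFrame(cols)
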
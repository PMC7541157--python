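"""Probe quality control against a 0/25/50/75/100% methylation dilution series.

A probe passes when its five measured betas track the expected fractions
closely (max absolute error <= epsilon) and monotonically (Pearson r >=
rho). Probes with a flat or inverted dose response — which cannot quantify
methylation — fail both criteria. Filtering is global: downstream stages
only ever see passing probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import QCParams, ValidationError

EXPECTED_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class ProbeQCResult:
    probe_id: str
    max_abs_error: float
    pearson_r: float  # NaN when the measured series is constant
    passed: bool


def _pearson(measured: np.ndarray, expected: np.ndarray) -> float:
    m = measured - measured.mean()
    e = expected - expected.mean()
    denom = np.sqrt((m * m).sum() * (e * e).sum())
    if denom == 0:
        return float("nan")  # constant series: undefined, treated as fail
    return float((m * e).sum() / denom)


def evaluate_probe(
    probe_id: str,
    measured: Sequence[float],
    params: Optional[QCParams] = None,
    expected: Sequence[float] = EXPECTED_FRACTIONS,
) -> ProbeQCResult:
    """Score one probe's dilution response against the expected fractions."""
    params = (params or QCParams()).validate()
    measured = np.asarray(measured, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if measured.shape != expected.shape or len(measured) != len(EXPECTED_FRACTIONS):
        raise ValidationError(
            f"probe {probe_id}: expected {len(EXPECTED_FRACTIONS)} calibration "
            f"points, got {len(measured)}"
        )
    if ((measured < 0) | (measured > 1)).any():
        raise ValidationError(f"probe {probe_id}: measured betas outside [0, 1]")
    max_err = float(np.abs(measured - expected).max())
    r = _pearson(measured, expected)
    passed = (max_err <= params.max_abs_error) and (
        not np.isnan(r) and r >= params.min_pearson_r
    )
    return ProbeQCResult(probe_id, max_err, r, passed)


def filter_probes(
    calibration: pd.DataFrame, params: Optional[QCParams] = None
) -> Tuple[set, pd.DataFrame]:
    """Evaluate every probe of a long-format calibration table.

    Returns the set of passing probe ids and a per-probe report with columns
    ``max_abs_error``, ``pearson_r``, ``pass``. Raises when no probe passes,
    since the downstream analysis would be empty.
    """
    params = (params or QCParams()).validate()
    wide = calibration.pivot_table(
        index="probe_id", columns="expected_fraction", values="measured_beta"
    )
    missing = [f for f in EXPECTED_FRACTIONS if f not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValidationError(
            "calibration table must provide all five expected fractions per probe"
        )
    wide = wide[list(EXPECTED_FRACTIONS)]
    measured = wide.to_numpy()
    expected = np.asarray(EXPECTED_FRACTIONS)

    max_err = np.abs(measured - expected).max(axis=1)
    m = measured - measured.mean(axis=1, keepdims=True)
    e = expected - expected.mean()
    denom = np.sqrt((m * m).sum(axis=1) * (e * e).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (m * e).sum(axis=1) / np.where(denom == 0, 1, denom),
                     np.nan)
    passed = (max_err <= params.max_abs_error) & ~np.isnan(r) & (
        np.nan_to_num(r, nan=-np.inf) >= params.min_pearson_r
    )
    report = pd.DataFrame(
        {"max_abs_error": max_err, "pearson_r": r, "pass": passed},
        index=wide.index,
    )
    pass_set = set(report.index[report["pass"]])
    if not pass_set:
        raise ValidationError("probe QC excluded every probe; tolerances too strict")
    return pass_set, report
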
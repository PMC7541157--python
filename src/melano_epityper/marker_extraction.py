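"""Binary methylation calls and four-way classifier gene categories.

Each analyzed gene (HCP/ICP promoter, representative probe) is classified
from its per-sample methylation calls into one of four categories, matching
the classifier structure of methylation epigenotyping studies:

* ``unmethylated`` — unmethylated in normals and in both tumor subgroups;
* ``high_meth_marker`` — unmethylated in normals, hypermethylated
  specifically in the high-methylation subgroup;
* ``commonly_methylated`` — unmethylated in normals, hypermethylated in
  both subgroups;
* ``normally_methylated`` — methylated in normals and in essentially all
  tumors;

with ``unclassified`` for everything in between. Frequencies are reported
as percentages within the high subgroup, the low subgroup and the whole
tumor cohort; "frequent" markers are those exceeding a cohort-frequency
floor (default 25%).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import CallThresholds, ValidationError

UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"
INDETERMINATE = "indeterminate"

CAT_UNMETH = "unmethylated"
CAT_MARKER = "high_meth_marker"
CAT_COMMON = "commonly_methylated"
CAT_NORMAL = "normally_methylated"
CAT_UNCLASSIFIED = "unclassified"

CATEGORY_ORDER = (CAT_UNMETH, CAT_MARKER, CAT_COMMON, CAT_NORMAL, CAT_UNCLASSIFIED)


def call_state(beta: float, thresholds: Optional[CallThresholds] = None) -> str:
    """Three-state methylation call for one beta value."""
    thr = (thresholds or CallThresholds()).validate()
    if not 0.0 <= beta <= 1.0:
        raise ValidationError(f"beta value {beta} outside [0, 1]")
    if beta <= thr.beta_unmeth_max:
        return UNMETHYLATED
    if beta >= thr.beta_meth_min:
        return METHYLATED
    return INDETERMINATE


def _meth_calls(betas: np.ndarray, thr: CallThresholds) -> np.ndarray:
    """Boolean methylated-call matrix (indeterminates are False)."""
    return betas >= thr.beta_meth_min


def methylation_frequency(
    betas: pd.Series, thresholds: Optional[CallThresholds] = None
) -> float:
    """Percentage of samples called methylated in a cohort subset.

    Indeterminate calls stay in the denominator but never in the numerator.
    """
    thr = (thresholds or CallThresholds()).validate()
    if len(betas) == 0:
        raise ValidationError("methylation frequency over an empty subset")
    values = np.asarray(betas, dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValidationError("beta values outside [0, 1]")
    return 100.0 * float(_meth_calls(values, thr).sum()) / len(values)


def classify_gene(
    normal_state: str,
    freq_high: float,
    freq_low: float,
    thresholds: Optional[CallThresholds] = None,
) -> str:
    """Apply the four category rules (normally/unmethylated/marker/common).

    ``freq_high``/``freq_low`` are percentages within each tumor subgroup;
    ``normal_state`` is the consensus call of the normal reference samples.
    Rules are evaluated in a fixed order and are mutually exclusive by
    construction of the thresholds.
    """
    thr = (thresholds or CallThresholds()).validate()
    for f in (freq_high, freq_low):
        if not 0.0 <= f <= 100.0:
            raise ValidationError("frequencies must be percentages in [0, 100]")
    common_pct = 100.0 * thr.common_freq_min
    marker_pct = 100.0 * thr.marker_freq_min
    absent_pct = 100.0 * thr.absent_freq_max

    if normal_state == METHYLATED and freq_high >= common_pct and freq_low >= common_pct:
        return CAT_NORMAL
    if normal_state == UNMETHYLATED:
        if freq_high <= absent_pct and freq_low <= absent_pct:
            return CAT_UNMETH
        if freq_high >= marker_pct and freq_low <= absent_pct:
            return CAT_MARKER
        if freq_high >= marker_pct and freq_low >= marker_pct:
            return CAT_COMMON
    return CAT_UNCLASSIFIED


def build_marker_table(
    gene_betas: pd.DataFrame,
    epigenotypes: pd.Series,
    normal_samples: list,
    thresholds: Optional[CallThresholds] = None,
) -> pd.DataFrame:
    """Classify every gene of a genes x samples beta matrix.

    ``epigenotypes`` maps tumor sample -> "high"/"low"; ``normal_samples``
    lists the normal reference columns. The per-gene normal reference state
    is called on the mean beta across normals. Returns a frame indexed by
    gene with columns category, freq_high, freq_low, freq_all, normal_state.
    """
    thr = (thresholds or CallThresholds()).validate()
    tumors = list(epigenotypes.index)
    missing = [s for s in tumors + list(normal_samples) if s not in gene_betas.columns]
    if missing:
        raise ValidationError(f"beta matrix lacks samples {missing}")
    if not set(epigenotypes.unique()) <= {"high", "low"}:
        raise ValidationError("epigenotype labels must be 'high'/'low'")
    high = [s for s in tumors if epigenotypes[s] == "high"]
    low = [s for s in tumors if epigenotypes[s] == "low"]
    if not high or not low:
        raise ValidationError("both epigenotype subgroups must be non-empty")

    vals = gene_betas[tumors + list(normal_samples)].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("beta values outside [0, 1]")

    calls_high = _meth_calls(gene_betas[high].to_numpy(), thr)
    calls_low = _meth_calls(gene_betas[low].to_numpy(), thr)
    freq_high = 100.0 * calls_high.mean(axis=1)
    freq_low = 100.0 * calls_low.mean(axis=1)
    freq_all = 100.0 * (calls_high.sum(axis=1) + calls_low.sum(axis=1)) / len(tumors)

    normal_mean = gene_betas[list(normal_samples)].to_numpy().mean(axis=1)
    normal_state = np.where(
        normal_mean <= thr.beta_unmeth_max,
        UNMETHYLATED,
        np.where(normal_mean >= thr.beta_meth_min, METHYLATED, INDETERMINATE),
    )

    categories = [
        classify_gene(ns, fh, fl, thr)
        for ns, fh, fl in zip(normal_state, freq_high, freq_low)
    ]
    out = pd.DataFrame(
        {
            "category": categories,
            "freq_high": freq_high,
            "freq_low": freq_low,
            "freq_all": freq_all,
            "normal_state": normal_state,
        },
        index=gene_betas.index,
    )
    out.index.name = "gene"
    return out


def category_counts(marker_table: pd.DataFrame) -> dict:
    """Gene counts per category, in canonical category order."""
    counts = marker_table["category"].value_counts()
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORY_ORDER}


def rank_frequent_markers(
    marker_table: pd.DataFrame,
    freq_floor: float = 25.0,
    second_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """High-methylation marker genes above a cohort-frequency floor.

    Keeps ``high_meth_marker`` genes with ``freq_all`` strictly above
    ``freq_floor`` (percent), sorted by descending frequency. When a second
    cohort's marker table is given, only genes exceeding the floor in both
    cohorts survive (frequencies of both are reported).
    """
    markers = marker_table[marker_table["category"] == CAT_MARKER]
    keep = markers[markers["freq_all"] > freq_floor][["freq_all"]].copy()
    if second_table is not None:
        other = second_table[second_table["category"] == CAT_MARKER]
        other = other[other["freq_all"] > freq_floor]
        keep = keep.join(
            other[["freq_all"]].rename(columns={"freq_all": "freq_all_cohort2"}),
            how="inner",
        )
    return keep.sort_values(
        by="freq_all", ascending=False, kind="mergesort"
    )
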
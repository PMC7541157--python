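"""Promoter annotation: CpG scores, HCP/ICP/LCP classes, representative probes.

The promoter methylation status of a gene is read from a single array probe —
the one closest to the transcription start site (TSS). Promoters are graded
by CpG-island character using the observed/expected CpG dinucleotide ratio
("CpG score") of the sequence around the TSS: high-CpG promoters (HCP) score
above 0.72, intermediate (ICP) above 0.48, and low-CpG promoters (LCP) at or
below 0.48. Downstream epigenotyping uses HCP and ICP genes only, where
aberrant hypermethylation is informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import PromoterParams, ValidationError

HCP = "HCP"
ICP = "ICP"
LCP = "LCP"

_VALID_BASES = set("ACGTN")


def compute_cpg_score(sequence: str, window: Optional[tuple] = None) -> float:
    """Observed/expected CpG ratio of ``sequence`` (or a slice of it).

    score = (#CG dinucleotides * L) / (#C * #G), with N bases excluded from
    the single-base counts and from the effective length L. Returns 0.0 when
    either single-base count is zero. ``window`` is an optional ``(start,
    end)`` half-open slice in sequence coordinates.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    if set(seq) - _VALID_BASES:
        raise ValidationError("sequence must contain only A, C, G, T, N")
    if window is not None:
        start, end = window
        if start < 0 or end > len(seq) or start >= end:
            raise ValidationError(f"window {window} outside sequence of length {len(seq)}")
        seq = seq[start:end]
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    length = len(seq) - seq.count("N")
    return (n_cg * length) / (n_c * n_g)


def classify_promoter(cpg_score: float, params: Optional[PromoterParams] = None) -> str:
    """Map a CpG score to HCP (> 0.72), ICP (> 0.48) or LCP (<= 0.48).

    Both thresholds are strict, so a score exactly at 0.48 is LCP.
    """
    params = params or PromoterParams()
    if cpg_score < 0:
        raise ValidationError("CpG score must be >= 0")
    if cpg_score > params.hcp_threshold:
        return HCP
    if cpg_score > params.icp_threshold:
        return ICP
    return LCP


def signed_tss_distance(position: int, tss: int, strand: str) -> int:
    """Signed probe-to-TSS distance in transcription orientation.

    Negative values are upstream of the TSS: on the + strand the distance is
    ``position - tss``, on the - strand ``tss - position``.
    """
    if strand == "+":
        return position - tss
    if strand == "-":
        return tss - position
    raise ValidationError(f"strand must be '+' or '-', got {strand!r}")


def annotate_tss_distance(manifest: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the manifest with a ``tss_distance`` column."""
    out = manifest.copy()
    sign = out["strand"].map({"+": 1, "-": -1})
    if sign.isna().any():
        raise ValidationError("manifest strand column must be '+' or '-'")
    out["tss_distance"] = (out["position"] - out["tss"]) * sign
    return out


def select_representative_probe(probes: pd.DataFrame) -> str:
    """Pick the probe of one gene nearest to the TSS.

    Ties in |distance| prefer the upstream (negative) probe, then the
    lexicographically smallest probe_id, so selection is deterministic.
    """
    if len(probes) == 0:
        raise ValidationError("cannot select a representative probe from no probes")
    ranked = probes.sort_values(
        by=["tss_distance", "probe_id"],
        key=lambda s: s.abs() if s.name == "tss_distance" else s,
        kind="mergesort",
    )
    # mergesort is stable: among equal |distance| the upstream probe must win
    best = ranked.iloc[0]
    dist = ranked["tss_distance"].abs()
    tied = ranked[dist == dist.iloc[0]]
    if len(tied) > 1:
        tied = tied.sort_values(by=["tss_distance", "probe_id"], kind="mergesort")
        best = tied.iloc[0]
    return str(best["probe_id"])


def select_representatives(
    manifest: pd.DataFrame, passing: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """One representative probe per gene, optionally restricted to QC passers.

    When a gene's nearest probe fails QC the next-nearest passing probe is
    used; genes with no passing probe are dropped. Returns a frame indexed by
    gene with columns ``representative_probe`` and ``tss_distance``.
    """
    ann = annotate_tss_distance(manifest)
    if passing is not None:
        ann = ann[ann["probe_id"].isin(set(passing))]
    if len(ann) == 0:
        raise ValidationError("no genes retained a representative probe")
    ranked = ann.assign(_absd=ann["tss_distance"].abs()).sort_values(
        ["gene", "_absd", "tss_distance", "probe_id"], kind="mergesort"
    )
    out = (
        ranked.groupby("gene", sort=True)
        .first()[["probe_id", "tss_distance"]]
        .rename(columns={"probe_id": "representative_probe"})
    )
    out.index.name = "gene"
    return out


@dataclass
class GenePromoterTable:
    """Per-gene promoter annotation produced by the annotate stage."""

    table: pd.DataFrame  # index gene; cpg_score, promoter_class,
    #                      representative_probe, tss_distance

    def genes_in_classes(self, classes: Sequence[str]) -> pd.Index:
        return self.table.index[self.table["promoter_class"].isin(classes)]


def annotate_genes(
    manifest: pd.DataFrame,
    promoter_seqs: Mapping[str, str],
    params: Optional[PromoterParams] = None,
    passing: Optional[Iterable[str]] = None,
    tss_index: Optional[int] = None,
) -> GenePromoterTable:
    """Score and classify every gene promoter and pick representative probes.

    ``promoter_seqs`` maps gene -> promoter sequence; the CpG score is taken
    over ``[tss_index - window_upstream, tss_index + window_downstream)``.
    ``tss_index`` defaults to the sequence midpoint (records centered on the
    TSS).
    """
    params = (params or PromoterParams()).validate()
    reps = select_representatives(manifest, passing=passing)
    records = {}
    for gene in reps.index:
        seq = promoter_seqs.get(gene)
        if seq is None:
            raise ValidationError(f"no promoter sequence for gene {gene!r}")
        center = len(seq) // 2 if tss_index is None else tss_index
        start = max(0, center - params.window_upstream)
        end = min(len(seq), center + params.window_downstream)
        score = compute_cpg_score(seq, window=(start, end))
        records[gene] = {
            "cpg_score": score,
            "promoter_class": classify_promoter(score, params),
            "representative_probe": reps.loc[gene, "representative_probe"],
            "tss_distance": reps.loc[gene, "tss_distance"],
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "gene"
    return GenePromoterTable(table=table)
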
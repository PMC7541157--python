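"""End-to-end orchestration: QC -> annotate -> epigenotype -> markers -> stats.

:func:`analyze` runs the full analysis on in-memory objects and returns an
:class:`AnalysisResult`; :func:`run_pipeline` wraps it with file IO, writes
every stage's TSV output and a machine-readable ``run_report.json`` whose
counts are all re-derivable from the stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

from . import cohort_stats as cs
from . import epigenotyping as ep
from . import io as eio
from . import marker_extraction as mk
from . import manifest_promoters as mp
from . import probe_qc as qc
from .config import RunConfig, ValidationError

log = logging.getLogger("melano_epityper")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class AnalysisResult:
    qc_report: pd.DataFrame
    passing_probes: set
    gene_table: pd.DataFrame           # promoter annotation incl. class
    epigenotypes: ep.EpigenotypeResult
    marker_table: pd.DataFrame
    frequent_markers: pd.DataFrame
    association: pd.DataFrame
    enrichment: pd.DataFrame
    survival: pd.DataFrame
    thickness: dict
    counts: dict = field(default_factory=dict)
    clustered_betas: Optional[pd.DataFrame] = None  # selected genes x tumors


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # surface the failing stage by name
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return out

        return inner

    return wrap


def analyze(
    manifest: pd.DataFrame,
    promoters: Mapping[str, str],
    betas: pd.DataFrame,
    calibration: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_sets: Mapping[str, set],
    config: RunConfig,
) -> AnalysisResult:
    """Run all analysis stages on in-memory inputs."""
    config.validate()

    pass_set, qc_report = _stage("qc")(qc.filter_probes)(calibration, config.qc)

    gene_table = _stage("annotate")(_annotate)(
        manifest, promoters, config, pass_set
    )

    tumors = [s for s in betas.columns if s in set(clinical["sample"])]
    normals = [s for s in betas.columns if s not in set(clinical["sample"])]
    if not tumors or not normals:
        raise StageError(
            "epitype", ValidationError("need both tumor and normal beta columns")
        )

    epity, gene_betas = _stage("epitype")(_epitype)(
        gene_table, betas, tumors, config
    )

    marker_table, frequent = _stage("markers")(_markers)(
        gene_table, gene_betas, epity.labels, normals, config
    )

    association, enrichment, survival, thickness = _stage("stats")(_stats)(
        epity.labels, clinical, marker_table, gene_sets, config
    )

    counts = {
        "probes_total": int(len(manifest)),
        "probes_passing_qc": int(len(pass_set)),
        "genes_annotated": int(len(gene_table)),
        "genes_hcp_icp": int((gene_table["promoter_class"] != mp.LCP).sum()),
        "genes_selected": int(len(epity.selected_genes)),
        "n_high": epity.n_high,
        "n_low": epity.n_low,
        "category_counts": mk.category_counts(marker_table),
        "frequent_markers": list(frequent.index),
    }
    return AnalysisResult(
        qc_report=qc_report,
        passing_probes=pass_set,
        gene_table=gene_table,
        epigenotypes=epity,
        marker_table=marker_table,
        frequent_markers=frequent,
        association=association,
        enrichment=enrichment,
        survival=survival,
        thickness=thickness,
        counts=counts,
        clustered_betas=gene_betas.loc[epity.selected_genes.index, tumors],
    )


def _annotate(manifest, promoters, config: RunConfig, pass_set):
    table = mp.annotate_genes(
        manifest, promoters, config.promoter, passing=pass_set
    ).table
    return table


def _epitype(gene_table, betas, tumors, config: RunConfig):
    analyzed = gene_table[gene_table["promoter_class"].isin((mp.HCP, mp.ICP))]
    rep_probes = analyzed["representative_probe"]
    missing = [p for p in rep_probes if p not in betas.index]
    if missing:
        raise ValidationError(f"beta matrix lacks representative probes {missing[:5]}")
    gene_betas = betas.loc[rep_probes]
    gene_betas.index = pd.Index(analyzed.index, name="gene")
    result = ep.epigenotype(gene_betas[tumors], config.cluster)
    return result, gene_betas


def _markers(gene_table, gene_betas, labels, normals, config: RunConfig):
    table = mk.build_marker_table(gene_betas, labels, normals, config.calls)
    frequent = mk.rank_frequent_markers(table, config.calls.frequent_floor_pct)
    return table, frequent


def _stats(labels, clinical, marker_table, gene_sets, config: RunConfig):
    association = cs.association_report(labels, clinical, config.stats)
    enrichment = cs.prc_enrichment(marker_table, gene_sets)
    survival = cs.survival_curves(clinical, labels)
    thickness = cs.thickness_by_subgroup(labels, clinical)
    return association, enrichment, survival, thickness


# ------------------------------------------------------------------- IO


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


BUNDLE_FILES = {
    "manifest": "manifest.tsv",
    "promoters": "promoters.fasta",
    "betas": "betas.tsv",
    "calibration": "calibration.tsv",
    "clinical": "clinical.tsv",
    "gmt": "prc_targets.gmt",
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis from a bundle directory and write all outputs.

    Returns the run report (also written as ``run_report.json``).
    """
    config.validate()
    bundle = Path(config.bundle_dir)
    paths = {k: bundle / v for k, v in BUNDLE_FILES.items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise StageError("load", ValidationError(f"missing input files: {missing}"))

    manifest = eio.read_manifest(paths["manifest"])
    promoters = eio.read_promoter_fasta(paths["promoters"])
    betas = eio.read_beta_matrix(paths["betas"])
    calibration = eio.read_calibration(paths["calibration"])
    clinical = eio.read_clinical(paths["clinical"])
    gene_sets = eio.read_gmt(paths["gmt"])

    result = analyze(
        manifest, promoters, betas, calibration, clinical, gene_sets, config
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_outputs(result, outdir)

    report = {
        "inputs": {k: _sha256(p) for k, p in paths.items()},
        "parameters": config.to_dict(),
        "stage_order": ["qc", "annotate", "epitype", "markers", "stats"],
        "counts": result.counts,
        "cluster_means": result.epigenotypes.cluster_means,
        "thickness": result.thickness,
        "tests": result.association[
            ["factor", "test", "statistic", "p_value", "significant"]
        ].to_dict(orient="records"),
        "enrichment": result.enrichment.to_dict(orient="records"),
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    if config.make_plots:
        _write_plots(result, outdir)
    return report


def _write_outputs(result: AnalysisResult, outdir: Path) -> None:
    result.qc_report.rename_axis("probe_id").to_csv(
        outdir / "probe_qc.tsv", sep="\t", float_format="%.4f"
    )
    result.gene_table.to_csv(
        outdir / "gene_promoters.tsv", sep="\t", float_format="%.4f"
    )
    epi = pd.DataFrame(
        {
            "sample": result.epigenotypes.labels.index,
            "label": result.epigenotypes.labels.values,
        }
    )
    epi["mean_beta"] = [
        result.epigenotypes.cluster_means[l] for l in epi["label"]
    ]
    epi.to_csv(outdir / "epigenotypes.tsv", sep="\t", index=False,
               float_format="%.4f")
    result.epigenotypes.selected_genes.to_csv(
        outdir / "selected_genes.tsv", sep="\t", float_format="%.4f"
    )
    result.marker_table.to_csv(
        outdir / "marker_table.tsv", sep="\t", float_format="%.2f"
    )
    result.frequent_markers.to_csv(
        outdir / "frequent_markers.tsv", sep="\t", float_format="%.2f"
    )
    result.association.to_csv(
        outdir / "association_report.tsv", sep="\t", index=False,
        float_format="%.5g",
    )
    result.enrichment.to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.5g"
    )
    result.survival.to_csv(
        outdir / "survival_curves.tsv", sep="\t", index=False,
        float_format="%.4f",
    )


def _write_plots(result: AnalysisResult, outdir: Path) -> None:
    """Optional clustered heatmap and per-subgroup KM plot (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    epity = result.epigenotypes
    sub = result.clustered_betas
    if sub is not None:
        order_samples = hierarchy.leaves_list(epity.sample_linkage)
        order_genes = hierarchy.leaves_list(epity.gene_linkage)
        fig, ax = plt.subplots(figsize=(8, 6))
        ax.imshow(
            sub.to_numpy()[order_genes][:, order_samples],
            aspect="auto", cmap="viridis", vmin=0, vmax=1,
        )
        ax.set_title("selected promoter betas (genes x tumors)")
        ax.set_xlabel("tumors (dendrogram order)")
        ax.set_ylabel("selected genes")
        fig.savefig(outdir / "heatmap.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, grp in result.survival.groupby("group"):
        ax.step(grp["time"], grp["survival"], where="post", label=str(lab))
    ax.set_xlabel("days")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.savefig(outdir / "km.png", dpi=120)
    plt.close(fig)
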
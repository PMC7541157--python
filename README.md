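# melano-epityper

Promoter-methylation epigenotyping of melanoma DNA-methylation-array
cohorts, with a fully synthetic, seeded cohort generator for offline
validation.

## The problem

Malignant melanoma can be stratified into molecular subgroups by the DNA
methylation state of promoter CpG islands: a *high-methylation* epigenotype
with aberrant hypermethylation at many gene promoters, and a
*low-methylation* epigenotype without it. The high-methylation subgroup is
clinically meaningful — thicker primary tumors (Breslow thickness) and
worse overall survival — and the genes that define it (e.g. *TFPI2*) are
candidate tumor suppressors silenced by methylation.

This package implements that analysis as a tested pipeline for
Infinium-450k-style data:

1. **Probe QC** against a 0/25/50/75/100% methylation dilution series:
   a probe passes when max |measured − expected| ≤ ε (default 0.15 beta
   units) and Pearson r ≥ ρ (default 0.95) over the five points.
2. **Promoter annotation** — each gene is represented by the probe nearest
   its TSS (signed distance, transcription orientation; QC failures fall
   back to the next-nearest passing probe). Promoters are classed by CpG
   score, the observed/expected CpG dinucleotide ratio over ±500 bp around
   the TSS:

   `score = (#CG × L) / (#C × #G)`,  HCP > 0.72 ≥ ICP > 0.48 ≥ LCP.

3. **Epigenotyping** — among HCP/ICP genes, those with cross-tumor beta
   SD > 0.15 (top 2000 by SD) are clustered two-way (Ward linkage,
   Euclidean distance); the two-cluster cut of the sample dendrogram
   defines the epigenotypes, "high" being the cluster with greater mean
   beta.
4. **Marker extraction** — per-sample binary methylation calls
   (beta ≤ 0.25 unmethylated, ≥ 0.55 methylated) classify every analyzed
   gene into four categories: *unmethylated* (in normals and all tumors),
   *high-methylation marker* (unmethylated in normals, hypermethylated
   specifically in the high subgroup), *commonly methylated* (both
   subgroups), *normally methylated* (everywhere incl. normals).
   Markers exceeding 25% cohort frequency are ranked as "frequent".
5. **Cohort statistics** — Fisher exact tests for clinical factors and
   Polycomb (PRC) target enrichment, Welch t for thickness, Kaplan–Meier +
   log-rank for overall survival, and quartile-based expression grouping.
   All statistics are implemented from first principles and tested against
   exact-enumeration and hand-computed oracles.

The synthetic generator plants all of this structure — 51 tumors (17
high-epigenotype), melanocyte/PBMC/fibroblast references, gene categories
of sizes 4444/27/25/405 (+2000 low-CpG fillers), marker cohort frequencies
of 22–33%, thickness 8.3 ± 5.3 vs 4.5 ± 2.9 mm, BRAF/NRAS/acral
prevalences of 18/77, 20/77, 35/77 — and records it in `truth.json`.

## Worked example

```python
from pathlib import Path
from melano_epityper import GeneratorConfig, RunConfig, run_pipeline, simulate

simulate(GeneratorConfig(seed=1), Path("cohort"))
report = run_pipeline(RunConfig(bundle_dir="cohort", outdir="results"))

print(report["counts"]["category_counts"])
thick = report["thickness"]
print(f"high {thick['high']['mean']:.1f} ± {thick['high']['sd']:.1f} mm, "
      f"low {thick['low']['mean']:.1f} ± {thick['low']['sd']:.1f} mm")
print({t["factor"]: round(t["p_value"], 4) for t in report["tests"]})
```

prints (seed 1):

```
{'unmethylated': 4444, 'high_meth_marker': 27, 'commonly_methylated': 25,
 'normally_methylated': 405, 'unclassified': 0}
high 6.1 ± 4.7 mm, low 4.3 ± 2.6 mm
{'braf_mut': 0.6536, 'nras_mut': 0.1811, 'acral_site': 1.0, 'ulcer': 0.7712,
 'stage_3_4': 0.0163, 'thickness_gt_4mm': 0.1425, 'age_ge_median': 1.0,
 'breslow_mm': 0.1484, 'overall_survival': 0.1589}
```

The pipeline recovered every planted gene category exactly (27 markers,
25 commonly methylated, 405 normally methylated, 4444 unmethylated, none
unclassified) and both subgroups (17/34). Thickness and survival were
planted with a real but moderate effect at n = 51, so their tests reach
significance on some seeds and not others — seed 1 is one of the misses;
the subgroup means still sit within two standard errors of the planted
8.3 and 4.5 mm. The PRC-target gene set comes out strongly enriched in the
marker category (P ≈ 6e-10 vs unmethylated genes).

The same run is available from the shell:

```sh
melano-epityper simulate --seed 1 --outdir cohort
melano-epityper all --bundle cohort --outdir results
```

Stage outputs (`probe_qc.tsv`, `gene_promoters.tsv`, `epigenotypes.tsv`,
`marker_table.tsv`, `frequent_markers.tsv`, `association_report.tsv`,
`survival_curves.tsv`, `enrichment.tsv`) and a `run_report.json` with
content hashes, parameters and all counts are written to `results/`.

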
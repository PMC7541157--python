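"""Generator contracts: determinism, planted structure, clinical draws."""

import json

import numpy as np
import pandas as pd
import pytest

from melano_epityper import GeneratorConfig, ValidationError
from melano_epityper.cohort_stats import logrank_test
from melano_epityper.manifest_promoters import classify_promoter, compute_cpg_score
from melano_epityper.synthetic_cohort import (
    generate_bundle,
    generate_clinical,
    generate_gene_states,
    plant_truth,
    write_bundle,
)
from conftest import small_config


def test_config_invariants_enforced():
    with pytest.raises(ValidationError):
        GeneratorConfig(n_high=51, n_tumors=51).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(marker_freq_range=(0.0, 0.3)).validate()
    with pytest.raises(ValidationError):
        GeneratorConfig(frac_bad_probes=1.2).validate()


def test_minimal_manifest_shape():
    cfg = small_config(
        n_genes_by_category={
            "unmethylated": 1,
            "high_meth_marker": 4,
            "commonly_methylated": 1,
            "normally_methylated": 1,
            "filler_low_cpg": 1,
        },
        max_probes_per_gene=1,
    )
    bundle = generate_bundle(cfg)
    non_tfpi2 = bundle.manifest[bundle.manifest["gene"] != "TFPI2"]
    assert non_tfpi2.groupby("gene").size().eq(1).all()
    assert all(len(rec["seq"]) == 2000 for rec in bundle.promoters.values())


def test_bundle_determinism_byte_identical(tmp_path):
    cfg = small_config(seed=1)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_bundle(generate_bundle(cfg), d1)
    write_bundle(generate_bundle(cfg), d2)
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f
    d3 = tmp_path / "c"
    write_bundle(generate_bundle(small_config(seed=2)), d3)
    assert (d1 / "betas.tsv").read_bytes() != (d3 / "betas.tsv").read_bytes()
    # same shapes regardless of seed
    b1 = pd.read_csv(d1 / "betas.tsv", sep="\t", index_col=0)
    b3 = pd.read_csv(d3 / "betas.tsv", sep="\t", index_col=0)
    assert list(b1.columns) == list(b3.columns)


def test_category_counts_conserved(default_bundle):
    counts = default_bundle.truth.category_counts()
    assert counts == default_bundle.config.n_genes_by_category
    assert len(default_bundle.truth.gene_category) == default_bundle.config.n_genes


def test_promoter_classes_match_planted_categories(default_bundle):
    """Marker/common/normal/unmethylated genes get HCP or ICP sequence,
    filler genes LCP, as verified by the package's own CpG score."""
    rng = np.random.default_rng(0)
    genes = list(default_bundle.promoters)
    for g in rng.choice(genes, size=150, replace=False):
        seq = default_bundle.promoters[g]["seq"]
        score = compute_cpg_score(seq, window=(500, 1500))
        assert classify_promoter(score) == default_bundle.truth.promoter_class[g]
        cat = default_bundle.truth.gene_category[g]
        if cat == "filler_low_cpg":
            assert default_bundle.truth.promoter_class[g] == "LCP"
        else:
            assert default_bundle.truth.promoter_class[g] in ("HCP", "ICP")


def test_noise_free_betas_hit_base_levels_exactly(noisefree_bundle):
    truth = noisefree_bundle.truth
    betas = noisefree_bundle.betas
    manifest = noisefree_bundle.manifest
    cfg = noisefree_bundle.config
    gene_of = dict(zip(manifest["probe_id"], manifest["gene"]))
    unmeth_probes = [p for p in betas.index
                     if truth.gene_category[gene_of[p]] == "unmethylated"]
    assert (betas.loc[unmeth_probes].to_numpy() == cfg.base_unmeth).all()
    normal_probes = [p for p in betas.index
                     if truth.gene_category[gene_of[p]] == "normally_methylated"]
    assert (betas.loc[normal_probes].to_numpy() == cfg.base_meth).all()


def test_marker_methylation_confined_to_high_subgroup(noisefree_bundle):
    truth = noisefree_bundle.truth
    cfg = noisefree_bundle.config
    rng = np.random.default_rng(0)
    states = generate_gene_states(cfg, truth, rng)
    low_and_normals = [s for s in states.columns
                       if truth.epigenotype.get(s) != "high"]
    for g, cat in truth.gene_category.items():
        if cat == "high_meth_marker":
            row = states.loc[g]
            assert (row[low_and_normals] == cfg.base_unmeth).all()
            assert (row == cfg.base_meth).sum() == truth.marker_cohort_k[g]


def test_marker_cohort_frequencies_in_planted_window(default_bundle):
    """Every marker's whole-cohort methylation frequency lies in 22-33%."""
    truth = default_bundle.truth
    n = default_bundle.config.n_tumors
    lo, hi = default_bundle.config.marker_freq_range
    for g, k in truth.marker_cohort_k.items():
        assert lo <= k / n <= hi
    assert truth.marker_cohort_k["TFPI2"] == max(truth.marker_cohort_k.values())


def test_clinical_null_hazards_give_null_logrank():
    cfg = small_config(
        n_tumors=40, n_high=13,
        survival_params={"median_days_high": 1000.0,
                         "median_days_low": 1000.0,
                         "censoring": 0.3},
    )
    non_sig = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        truth = plant_truth(cfg, rng)
        clin = generate_clinical(cfg, truth, rng)
        groups = [truth.epigenotype[s] for s in clin["sample"]]
        res = logrank_test(clin["os_days"], clin["os_event"], groups)
        non_sig += not res.significant
    assert non_sig >= 8


def test_zero_sd_thickness_is_exact():
    cfg = small_config(
        thickness_params={"high": (8.3, 0.0), "low": (4.5, 0.0), "min_mm": 0.1}
    )
    rng = np.random.default_rng(0)
    truth = plant_truth(cfg, rng)
    clin = generate_clinical(cfg, truth, rng).set_index("sample")
    for s, row in clin.iterrows():
        expected = 8.3 if truth.epigenotype[s] == "high" else 4.5
        assert row["breslow_mm"] == pytest.approx(expected)


def test_braf_prevalence_matches_config():
    cfg = GeneratorConfig(seed=11)
    rng = np.random.default_rng(cfg.seed)
    truth = plant_truth(cfg, rng)
    clin = generate_clinical(cfg, truth, rng)
    p = cfg.mutation_freqs["braf"]
    expected = cfg.n_tumors * p
    tol = 3 * np.sqrt(cfg.n_tumors * p * (1 - p))
    assert abs(clin["braf_mut"].sum() - expected) <= tol


def test_truth_json_round_trip(tmp_path, small_bundle):
    paths = write_bundle(small_bundle, tmp_path)
    with open(paths["truth"]) as fh:
        doc = json.load(fh)
    assert doc["gene_category"] == small_bundle.truth.gene_category
    assert doc["epigenotype"] == small_bundle.truth.epigenotype
    assert doc["bad_probes"] == sorted(small_bundle.truth.bad_probes)
    assert doc["config"]["seed"] == small_bundle.config.seed
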
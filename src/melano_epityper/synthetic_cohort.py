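"""Seeded synthetic melanoma methylation cohorts with planted ground truth.

The generator emits everything the pipeline consumes — probe manifest,
promoter FASTA, probe-level beta matrix, calibration dilution series,
clinical table and a Polycomb-target gene set — plus a ``truth`` record of
the planted gene categories, sample epigenotypes and corrupted probes, so
every downstream stage can be validated without any external download.

Planted structure, by gene category:

* ``unmethylated`` genes sit at the unmethylated base level (0.1) in every
  sample;
* ``high_meth_marker`` genes are methylated (0.8) in a subset of
  high-epigenotype tumors sized so that the gene's whole-cohort methylation
  frequency lands in ``marker_freq_range`` (22-33% of tumors by default) —
  methylation that is specific to the high subgroup;
* ``commonly_methylated`` genes are methylated in comparable fractions of
  both subgroups;
* ``normally_methylated`` genes are methylated in all normals and tumors;
* ``filler_low_cpg`` genes carry intermediate, subgroup-independent betas
  and low-CpG promoter sequence, so they are excluded by the HCP/ICP
  filter and separate nothing.

Gaussian beta-scale noise (clamped to [0, 1]) is added per cell; the
calibration series additionally plants a configurable fraction of probes
with flat or inverted dose response for QC to catch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as eio
from .config import GeneratorConfig, NAMED_MARKERS, ValidationError

TSS_DISTANCE_RANGE = (-1500, 500)  # bp, inclusive, transcription orientation
PROMOTER_RECORD_LENGTH = 2000      # bp, centered on the TSS
_WINDOW = 1000                     # scored central window of the record
_N_C = _N_G = 130                  # fixed C/G content of the scored window

# target CpG-score ranges per promoter class; HCP/ICP bands sit safely
# inside the >0.72 / (0.48, 0.72] classification intervals
_SCORE_RANGES = {"HCP": (0.90, 1.30), "ICP": (0.55, 0.68), "LCP": (0.12, 0.40)}

PRC_SET_NAME = "PRC_TARGETS_ES"


@dataclass
class PlantedTruth:
    """Ground truth of one synthetic bundle."""

    samples: list                    # tumor ids then normal ids
    epigenotype: Dict[str, str]      # tumor -> "high" | "low"
    normal_roles: Dict[str, str]     # normal sample -> role
    gene_category: Dict[str, str]
    promoter_class: Dict[str, str]
    marker_cohort_k: Dict[str, int]  # marker gene -> methylated tumor count
    common_k: Dict[str, tuple]       # common gene -> (k_high, k_low)
    bad_probes: list = field(default_factory=list)

    @property
    def tumors(self) -> list:
        return [s for s in self.samples if s in self.epigenotype]

    @property
    def normals(self) -> list:
        return [s for s in self.samples if s not in self.epigenotype]

    def category_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for cat in self.gene_category.values():
            counts[cat] = counts.get(cat, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "samples": self.samples,
            "epigenotype": self.epigenotype,
            "normal_roles": self.normal_roles,
            "gene_category": self.gene_category,
            "promoter_class": self.promoter_class,
            "marker_cohort_k": self.marker_cohort_k,
            "common_k": {g: list(v) for g, v in self.common_k.items()},
            "bad_probes": sorted(self.bad_probes),
        }


@dataclass
class Bundle:
    """In-memory fixture bundle (see :func:`write_bundle` for the on-disk form)."""

    config: GeneratorConfig
    truth: PlantedTruth
    manifest: pd.DataFrame
    promoters: Dict[str, dict]       # gene -> {seq, chrom, tss, strand}
    betas: pd.DataFrame              # probes x samples
    calibration: pd.DataFrame        # long format
    clinical: pd.DataFrame
    gene_sets: Dict[str, set]


# ------------------------------------------------------------------ truth

def plant_truth(config: GeneratorConfig, rng: np.random.Generator) -> PlantedTruth:
    """Draw the latent design: epigenotypes, gene categories, marker sizes."""
    config.validate()
    width = max(2, len(str(config.n_tumors)))
    tumors = [f"MM{i + 1:0{width}d}" for i in range(config.n_tumors)]
    normals = list(config.normal_roles)
    high_idx = rng.choice(config.n_tumors, size=config.n_high, replace=False)
    epigenotype = {
        s: ("high" if i in set(high_idx.tolist()) else "low")
        for i, s in enumerate(tumors)
    }

    counts = config.n_genes_by_category
    n_named = len(NAMED_MARKERS)
    other_genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes - n_named)]
    pool = (
        ["high_meth_marker"] * (counts["high_meth_marker"] - n_named)
        + ["unmethylated"] * counts["unmethylated"]
        + ["commonly_methylated"] * counts["commonly_methylated"]
        + ["normally_methylated"] * counts["normally_methylated"]
        + ["filler_low_cpg"] * counts["filler_low_cpg"]
    )
    pool = [pool[i] for i in rng.permutation(len(pool))]
    gene_category = dict(zip(other_genes, pool))
    for g in NAMED_MARKERS:
        gene_category[g] = "high_meth_marker"

    promoter_class = {}
    for gene, cat in gene_category.items():
        if cat == "filler_low_cpg":
            promoter_class[gene] = "LCP"
        else:
            promoter_class[gene] = "HCP" if rng.random() < 0.7 else "ICP"

    lo, hi = config.marker_freq_range
    k_min = max(1, int(np.ceil(lo * config.n_tumors)))
    k_max = min(config.n_high, int(np.floor(hi * config.n_tumors)))
    if k_min > k_max:
        k_min = k_max
    markers = [g for g, c in gene_category.items() if c == "high_meth_marker"]
    marker_k = {
        g: int(rng.integers(k_min, k_max + 1))
        for g in sorted(markers)
    }
    # the named markers anchor the top of the frequency range, TFPI2 first
    for rank, g in enumerate(NAMED_MARKERS[:3]):
        marker_k[g] = max(k_min, k_max - rank)
    if len(NAMED_MARKERS) > 3:
        marker_k[NAMED_MARKERS[3]] = k_min

    common_k = {}
    n_low = config.n_low
    for g in sorted(g for g, c in gene_category.items() if c == "commonly_methylated"):
        f = rng.uniform(lo, hi)
        common_k[g] = (
            int(np.clip(round(f * config.n_high), 1, config.n_high)),
            int(np.clip(round(f * n_low), 1, n_low)),
        )

    return PlantedTruth(
        samples=tumors + normals,
        epigenotype=epigenotype,
        normal_roles=dict(zip(normals, config.normal_roles)),
        gene_category=gene_category,
        promoter_class=promoter_class,
        marker_cohort_k=marker_k,
        common_k=common_k,
    )


# --------------------------------------------------------------- manifest

def _promoter_sequence(rng: np.random.Generator, promoter_class: str) -> str:
    """Synthesize a 2 kb promoter whose central 1 kb scores in the class.

    The scored window is assembled from 3-mers with fixed C/G content and a
    controlled number of CG dinucleotides (none can arise across 3-mer
    boundaries), so the observed/expected CpG ratio is exact by
    construction; AT-rich random flanks pad the record to 2 kb.
    """
    lo, hi = _SCORE_RANGES[promoter_class]
    target = rng.uniform(lo, hi)
    n_cg = int(round(target * _N_C * _N_G / _WINDOW))
    tokens = (
        ["ACG"] * n_cg
        + ["ACT"] * (_N_C - n_cg)
        + ["AGT"] * (_N_G - n_cg)
    )
    n_filler = _WINDOW // 3 - len(tokens)
    filler = ["ATT", "TAA", "TTA"]
    tokens += [filler[int(i)] for i in rng.integers(0, 3, size=n_filler)]
    tokens = [tokens[i] for i in rng.permutation(len(tokens))]
    window = "".join(tokens)
    window += "A" * (_WINDOW - len(window))
    flank_len = (PROMOTER_RECORD_LENGTH - _WINDOW) // 2
    bases = np.array(list("ACGT"))
    probs = [0.4, 0.1, 0.1, 0.4]  # AT-rich, so flanks never look like islands
    left = "".join(rng.choice(bases, size=flank_len, p=probs))
    right = "".join(rng.choice(bases, size=flank_len, p=probs))
    return left + window + right


def generate_manifest(
    config: GeneratorConfig, truth: PlantedTruth, rng: np.random.Generator
):
    """Probe manifest plus promoter records for every planted gene.

    Each gene receives 1 to ``max_probes_per_gene`` probes at distinct
    signed TSS distances in [-1500, +500] bp; TFPI2 is given 21 probes with
    the nearest at 15 bp upstream of the TSS, mirroring its real promoter
    design.
    """
    d_lo, d_hi = TSS_DISTANCE_RANGE
    span = np.arange(d_lo, d_hi + 1)
    genes = sorted(truth.gene_category)
    chroms = [f"chr{(i % 22) + 1}" for i in range(len(genes))]
    rows = []
    promoters: Dict[str, dict] = {}
    probe_counter = 1
    for idx, gene in enumerate(genes):
        if gene == "TFPI2":
            n_probes = 21
            others = span[np.abs(span) > 15]  # keep -15 the nearest probe
            dists = np.concatenate(
                ([-15], rng.choice(others, size=n_probes - 1, replace=False))
            )
        else:
            n_probes = int(rng.integers(1, config.max_probes_per_gene + 1))
            dists = rng.choice(span, size=n_probes, replace=False)
        strand = "+" if rng.random() < 0.5 else "-"
        tss = 100_000 + idx * 10_000
        for d in np.sort(dists):
            position = tss + int(d) if strand == "+" else tss - int(d)
            rows.append(
                (f"cg{probe_counter:08d}", gene, chroms[idx], position, strand, tss)
            )
            probe_counter += 1
        promoters[gene] = {
            "seq": _promoter_sequence(rng, truth.promoter_class[gene]),
            "chrom": chroms[idx],
            "tss": tss,
            "strand": strand,
        }
    manifest = pd.DataFrame(
        rows, columns=["probe_id", "gene", "chrom", "position", "strand", "tss"]
    )
    return manifest, promoters


# ------------------------------------------------------------------ betas

def generate_gene_states(
    config: GeneratorConfig, truth: PlantedTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Noise-free per-gene base beta levels (genes x samples)."""
    genes = sorted(truth.gene_category)
    samples = truth.samples
    tumors = truth.tumors
    high_pos = np.array([i for i, s in enumerate(samples)
                         if truth.epigenotype.get(s) == "high"])
    low_pos = np.array([i for i, s in enumerate(samples)
                        if truth.epigenotype.get(s) == "low"])
    base = np.full((len(genes), len(samples)), config.base_unmeth)
    for gi, gene in enumerate(genes):
        cat = truth.gene_category[gene]
        if cat == "normally_methylated":
            base[gi, :] = config.base_meth
        elif cat == "high_meth_marker":
            k = truth.marker_cohort_k[gene]
            hit = rng.choice(high_pos, size=min(k, len(high_pos)), replace=False)
            base[gi, hit] = config.base_meth
        elif cat == "commonly_methylated":
            k_h, k_l = truth.common_k[gene]
            base[gi, rng.choice(high_pos, size=k_h, replace=False)] = config.base_meth
            base[gi, rng.choice(low_pos, size=k_l, replace=False)] = config.base_meth
        elif cat == "filler_low_cpg":
            center = rng.uniform(0.35, 0.65)
            base[gi, :] = center + rng.uniform(-0.12, 0.12, size=len(samples))
        # unmethylated genes keep the base_unmeth default
    return pd.DataFrame(base, index=genes, columns=samples)


def _add_noise(
    base: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    if sd > 0:
        base = base + rng.normal(0.0, sd, size=base.shape)
    return np.clip(base, 0.0, 1.0)


def generate_cohort_betas(
    config: GeneratorConfig,
    manifest: pd.DataFrame,
    truth: PlantedTruth,
    rng: np.random.Generator,
    gene_states: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Probe-level beta matrix: the gene's base level plus per-cell noise."""
    if gene_states is None:
        gene_states = generate_gene_states(config, truth, rng)
    unknown = set(manifest["gene"]) - set(gene_states.index)
    if unknown:
        raise ValidationError(f"manifest genes missing from truth: {sorted(unknown)[:5]}")
    base = gene_states.loc[manifest["gene"]].to_numpy()
    betas = _add_noise(base, config.beta_noise_sd, rng)
    return pd.DataFrame(betas, index=pd.Index(manifest["probe_id"], name="probe_id"),
                        columns=gene_states.columns)


def generate_representative_betas(
    config: GeneratorConfig, truth: PlantedTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Gene-level beta matrix (one representative draw per gene and sample)."""
    states = generate_gene_states(config, truth, rng)
    return pd.DataFrame(
        _add_noise(states.to_numpy(), config.beta_noise_sd, rng),
        index=states.index, columns=states.columns,
    )


# ------------------------------------------------------------ calibration

def generate_calibration(
    config: GeneratorConfig,
    manifest: pd.DataFrame,
    truth: PlantedTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Five-point dilution series per probe, with planted inaccurate probes.

    ``frac_bad_probes`` of all probes (rounded) respond flat or inverted.
    One probe per gene is protected from corruption so that no gene can lose
    its entire promoter coverage to QC.
    """
    expected = np.array(probe_qc_expected())
    probe_ids = manifest["probe_id"].to_numpy()
    n_probes = len(probe_ids)

    protected = set(
        manifest.groupby("gene", sort=True)["probe_id"]
        .apply(lambda s: s.iloc[int(rng.integers(0, len(s)))])
    )
    pool = np.array([p for p in probe_ids if p not in protected])
    n_bad = min(int(round(config.frac_bad_probes * n_probes)), len(pool))
    bad = set(rng.choice(pool, size=n_bad, replace=False).tolist()) if n_bad else set()
    truth.bad_probes = sorted(bad)

    measured = np.tile(expected, (n_probes, 1)).astype(float)
    bad_mask = np.isin(probe_ids, list(bad))
    bad_idx = np.where(bad_mask)[0]
    for j, i in enumerate(bad_idx):
        if j % 2 == 0:
            measured[i, :] = rng.uniform(0.3, 0.7)  # flat response
        else:
            measured[i, :] = 1.0 - expected          # inverted response
    measured = _add_noise(measured, config.cal_noise_sd, rng)

    long = pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, len(expected)),
            "expected_fraction": np.tile(expected, n_probes),
            "measured_beta": measured.ravel(),
        }
    )
    return long


def probe_qc_expected() -> tuple:
    from .probe_qc import EXPECTED_FRACTIONS

    return EXPECTED_FRACTIONS


# --------------------------------------------------------------- clinical

def _truncnorm_params(
    target_mean: float, target_sd: float, lower: float
) -> tuple:
    """Location/scale of a lower-truncated normal with the given moments.

    Solved numerically so that the distribution actually drawn has mean
    ``target_mean`` and SD ``target_sd`` despite the truncation at
    ``lower``. Falls back to the naive (biased) parametrization when the
    solver does not converge.
    """
    from scipy.optimize import fsolve

    def moments(params):
        loc, scale = params
        scale = abs(scale)
        a = (lower - loc) / scale
        m, v = sps.truncnorm.stats(a, np.inf, loc=loc, scale=scale, moments="mv")
        return [m - target_mean, np.sqrt(v) - target_sd]

    sol, info, ok, _ = fsolve(
        moments, x0=[target_mean, target_sd], full_output=True
    )
    if ok != 1 or not np.all(np.isfinite(sol)):
        return target_mean, target_sd
    return float(sol[0]), float(abs(sol[1]))

def generate_clinical(
    config: GeneratorConfig, truth: PlantedTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical covariates for the tumor samples.

    Breslow thickness is drawn per subgroup from normals truncated at
    ``min_mm``; overall survival is exponential with a worse hazard in the
    high subgroup and independent exponential censoring; stage is enriched
    for 3-4 in the high subgroup; mutations, site and ulcers are sampled at
    their configured prevalences independently of the epigenotype.
    """
    tumors = truth.tumors
    groups = np.array([truth.epigenotype[s] for s in tumors])
    n = len(tumors)

    thickness = np.empty(n)
    min_mm = config.thickness_params["min_mm"]
    for lab in ("high", "low"):
        mu, sd = config.thickness_params[lab]
        mask = groups == lab
        if sd == 0:
            thickness[mask] = max(mu, min_mm)
        else:
            # moment-match so the truncated draw realizes the configured
            # mean/SD rather than the pre-truncation location/scale
            loc, scale = _truncnorm_params(mu, sd, min_mm)
            a = (min_mm - loc) / scale
            thickness[mask] = sps.truncnorm.rvs(
                a, np.inf, loc=loc, scale=scale, size=mask.sum(), random_state=rng
            )

    sv = config.survival_params
    cens = sv["censoring"]
    os_days = np.empty(n)
    os_event = np.empty(n, dtype=int)
    for lab, med_key in (("high", "median_days_high"), ("low", "median_days_low")):
        mask = groups == lab
        lam = np.log(2.0) / sv[med_key]
        t_event = rng.exponential(1.0 / lam, size=mask.sum())
        if cens > 0:
            mu_c = lam * cens / (1.0 - cens)
            t_cens = rng.exponential(1.0 / mu_c, size=mask.sum())
        else:
            t_cens = np.full(mask.sum(), np.inf)
        os_days[mask] = np.minimum(t_event, t_cens)
        os_event[mask] = (t_event <= t_cens).astype(int)

    stage = np.empty(n, dtype=int)
    for lab in ("high", "low"):
        mask = groups == lab
        stage[mask] = rng.choice(
            [1, 2, 3, 4], size=mask.sum(), p=config.stage_probs[lab]
        )

    mf = config.mutation_freqs
    clinical = pd.DataFrame(
        {
            "sample": tumors,
            "age": np.clip(np.round(rng.normal(64, 14, size=n)), 25, 92).astype(int),
            "site": np.where(rng.random(n) < mf["acral"], "acral", "non_acral"),
            "stage": stage,
            "breslow_mm": np.round(thickness, 2),
            "ulcer": (rng.random(n) < config.ulcer_freq).astype(int),
            "braf_mut": (rng.random(n) < mf["braf"]).astype(int),
            "nras_mut": (rng.random(n) < mf["nras"]).astype(int),
            "os_days": np.maximum(1, np.round(os_days)).astype(int),
            "os_event": os_event,
        }
    )
    return clinical


# -------------------------------------------------------------- gene sets

def generate_prc_set(
    config: GeneratorConfig, truth: PlantedTruth, rng: np.random.Generator
) -> Dict[str, set]:
    """Polycomb-target gene set enriched among the planted marker genes."""
    members = set()
    for gene, cat in sorted(truth.gene_category.items()):
        if cat == "high_meth_marker":
            p = config.prc_marker_frac
        elif cat == "filler_low_cpg":
            continue
        else:
            p = config.prc_background_frac
        if rng.random() < p:
            members.add(gene)
    return {PRC_SET_NAME: members}


# ----------------------------------------------------------------- bundle

def generate_bundle(config: GeneratorConfig) -> Bundle:
    """Generate the full fixture bundle in memory, deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = plant_truth(config, rng)
    manifest, promoters = generate_manifest(config, truth, rng)
    gene_states = generate_gene_states(config, truth, rng)
    betas = generate_cohort_betas(config, manifest, truth, rng, gene_states)
    calibration = generate_calibration(config, manifest, truth, rng)
    clinical = generate_clinical(config, truth, rng)
    gene_sets = generate_prc_set(config, truth, rng)
    return Bundle(
        config=config,
        truth=truth,
        manifest=manifest,
        promoters=promoters,
        betas=betas,
        calibration=calibration,
        clinical=clinical,
        gene_sets=gene_sets,
    )


def write_bundle(bundle: Bundle, outdir: Path) -> dict:
    """Write the bundle directory; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.tsv",
        "promoters": outdir / "promoters.fasta",
        "betas": outdir / "betas.tsv",
        "calibration": outdir / "calibration.tsv",
        "clinical": outdir / "clinical.tsv",
        "gmt": outdir / "prc_targets.gmt",
        "truth": outdir / "truth.json",
    }
    eio.write_manifest(bundle.manifest, paths["manifest"])
    eio.write_promoter_fasta(bundle.promoters, paths["promoters"])
    eio.write_beta_matrix(bundle.betas, paths["betas"])
    eio.write_calibration(bundle.calibration, paths["calibration"])
    eio.write_clinical(bundle.clinical, paths["clinical"])
    eio.write_gmt(
        bundle.gene_sets, paths["gmt"],
        descriptions={PRC_SET_NAME: "synthetic Polycomb-target gene set"},
    )
    truth_doc = bundle.truth.to_dict()
    cfg = dataclasses.asdict(bundle.config)
    cfg["marker_freq_range"] = list(cfg["marker_freq_range"])
    cfg["normal_roles"] = list(cfg["normal_roles"])
    for key in ("high", "low"):
        cfg["thickness_params"][key] = list(cfg["thickness_params"][key])
        cfg["stage_probs"][key] = list(cfg["stage_probs"][key])
    truth_doc["config"] = cfg
    eio.write_truth(truth_doc, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def simulate(config: GeneratorConfig, outdir: Path) -> dict:
    """Generate and write a bundle; the CLI ``simulate`` entry point."""
    bundle = generate_bundle(config)
    return write_bundle(bundle, outdir)
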
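"""Shared fixtures: one default synthetic cohort and one scaled-down cohort.

The default bundle mirrors the emulated study cohort (51 tumors, 17 high,
6901 genes); the small bundle keeps the same structure at a fraction of the
size for fast unit tests.
"""

import pytest

from melano_epityper import GeneratorConfig, RunConfig, run_pipeline
from melano_epityper.synthetic_cohort import generate_bundle, write_bundle

DEFAULT_SEED = 7


def small_config(seed: int = 3, **overrides) -> GeneratorConfig:
    kwargs = dict(
        seed=seed,
        n_tumors=12,
        n_high=4,
        n_genes_by_category={
            "unmethylated": 60,
            "high_meth_marker": 6,
            "commonly_methylated": 5,
            "normally_methylated": 10,
            "filler_low_cpg": 20,
        },
        max_probes_per_gene=4,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(GeneratorConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """Full pipeline run on the default bundle; returns (bundle, report, outdir)."""
    root = tmp_path_factory.mktemp("default_run")
    bundle_dir = root / "bundle"
    outdir = root / "out"
    write_bundle(default_bundle, bundle_dir)
    report = run_pipeline(RunConfig(bundle_dir=bundle_dir, outdir=outdir))
    return default_bundle, report, outdir


@pytest.fixture()
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture()
def noisefree_bundle():
    return generate_bundle(small_config(seed=5, beta_noise_sd=0.0, cal_noise_sd=0.0))
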
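"""Parameter containers for the generator and every analysis stage.

All tunables live in small dataclasses with validated invariants so that a
YAML run-config, CLI flags and library calls share one source of defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


class ValidationError(ValueError):
    """Raised when a configuration or input violates a documented invariant."""


# default gene-category sizes mirror the Chiba-cohort classifier counts
DEFAULT_CATEGORY_COUNTS = {
    "unmethylated": 4444,
    "high_meth_marker": 27,
    "commonly_methylated": 25,
    "normally_methylated": 405,
    "filler_low_cpg": 2000,
}

CATEGORIES = tuple(DEFAULT_CATEGORY_COUNTS)

#: marker genes given their real symbols; TFPI2 is planted as the most
#: frequently methylated marker, mirroring the cohort this emulates.
NAMED_MARKERS = ("TFPI2", "P4HTM", "ACADL", "DDIT4L")

NORMAL_ROLES = ("Melanocyte", "PBMC", "Fibroblast")


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic melanoma methylation cohort.

    Defaults reproduce the structure of a 51-tumor FFPE cohort with two
    latent methylation epigenotypes (17 high / 34 low), three normal
    reference samples, classifier gene categories of sizes
    4444/27/25/405 plus 2000 low-CpG filler genes, marker methylation
    frequencies of 22-33% of the cohort, Breslow thickness 8.3 +/- 5.3 mm
    (high) vs 4.5 +/- 2.9 mm (low), and BRAF/NRAS/acral prevalences of
    18/77, 20/77 and 35/77.
    """

    seed: int = 0
    n_tumors: int = 51
    n_high: int = 17
    normal_roles: tuple = NORMAL_ROLES
    n_genes_by_category: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    marker_freq_range: tuple = (0.22, 0.33)
    base_unmeth: float = 0.1
    base_meth: float = 0.8
    beta_noise_sd: float = 0.05
    cal_noise_sd: float = 0.03
    frac_bad_probes: float = 0.03
    max_probes_per_gene: int = 10
    thickness_params: dict = field(
        default_factory=lambda: {
            "high": (8.3, 5.3),
            "low": (4.5, 2.9),
            "min_mm": 0.1,
        }
    )
    survival_params: dict = field(
        default_factory=lambda: {
            "median_days_high": 700.0,
            "median_days_low": 1800.0,
            "censoring": 0.40,
        }
    )
    mutation_freqs: dict = field(
        default_factory=lambda: {
            "braf": 18 / 77,
            "nras": 20 / 77,
            "acral": 35 / 77,
        }
    )
    ulcer_freq: float = 0.45
    stage_probs: dict = field(
        default_factory=lambda: {
            "high": (0.05, 0.20, 0.45, 0.30),
            "low": (0.25, 0.45, 0.20, 0.10),
        }
    )
    prc_marker_frac: float = 0.60
    prc_background_frac: float = 0.10

    @property
    def n_normals(self) -> int:
        return len(self.normal_roles)

    @property
    def n_low(self) -> int:
        return self.n_tumors - self.n_high

    @property
    def n_genes(self) -> int:
        return sum(self.n_genes_by_category.values())

    def validate(self) -> "GeneratorConfig":
        if self.n_tumors <= 0 or self.n_normals <= 0:
            raise ValidationError("sample counts must be positive")
        if not (0 < self.n_high < self.n_tumors):
            raise ValidationError("n_high must lie strictly between 0 and n_tumors")
        for cat, n in self.n_genes_by_category.items():
            if cat not in CATEGORIES:
                raise ValidationError(f"unknown gene category {cat!r}")
            if n <= 0:
                raise ValidationError(f"gene count for {cat!r} must be positive")
        lo, hi = self.marker_freq_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("marker_freq_range must be within (0, 1]")
        for name in ("beta_noise_sd", "cal_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_bad_probes < 1.0:
            raise ValidationError("frac_bad_probes must be in [0, 1)")
        if not 0.0 <= self.base_unmeth < self.base_meth <= 1.0:
            raise ValidationError("base levels must satisfy 0 <= unmeth < meth <= 1")
        if self.max_probes_per_gene < 1:
            raise ValidationError("max_probes_per_gene must be >= 1")
        if self.n_genes_by_category.get("high_meth_marker", 0) < len(NAMED_MARKERS):
            raise ValidationError(
                "high_meth_marker count must cover the named marker genes"
            )
        return self


@dataclass
class PromoterParams:
    """CpG-score window and HCP/ICP class thresholds."""

    window_upstream: int = 500   # bp upstream of TSS included in the score
    window_downstream: int = 500
    hcp_threshold: float = 0.72  # CpG score strictly above -> HCP
    icp_threshold: float = 0.48  # strictly above (and <= hcp) -> ICP

    def validate(self) -> "PromoterParams":
        if self.window_upstream < 0 or self.window_downstream <= 0:
            raise ValidationError("promoter window must span the TSS")
        if not 0 < self.icp_threshold < self.hcp_threshold:
            raise ValidationError("need 0 < icp_threshold < hcp_threshold")
        return self


@dataclass
class QCParams:
    """Calibration-series acceptance rule for a probe."""

    max_abs_error: float = 0.15  # beta units, over the five dilution points
    min_pearson_r: float = 0.95

    def validate(self) -> "QCParams":
        if self.max_abs_error < 0:
            raise ValidationError("max_abs_error must be >= 0")
        if not -1.0 <= self.min_pearson_r <= 1.0:
            raise ValidationError("min_pearson_r must be in [-1, 1]")
        return self


@dataclass
class ClusterParams:
    """Variable-gene selection and clustering settings."""

    sd_threshold: float = 0.15
    top_n: int = 2000
    metric: str = "euclidean"
    linkage: str = "ward"

    def validate(self) -> "ClusterParams":
        if self.sd_threshold < 0:
            raise ValidationError("sd_threshold must be >= 0")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")
        return self


@dataclass
class CallThresholds:
    """Binary methylation-call and category-rule thresholds.

    Beta cutoffs sit midway between typical fully-unmethylated (~0.1) and
    hypermethylated (~0.8) promoter levels so single-sample calls are robust
    to array noise; the per-gene normal reference state is called on the
    mean beta across normal samples.
    """

    beta_unmeth_max: float = 0.25
    beta_meth_min: float = 0.55
    marker_freq_min: float = 0.20
    absent_freq_max: float = 0.05
    common_freq_min: float = 0.95
    frequent_floor_pct: float = 25.0  # cohort-% floor for "frequent" markers

    def validate(self) -> "CallThresholds":
        if not 0 <= self.beta_unmeth_max < self.beta_meth_min <= 1:
            raise ValidationError("need 0 <= beta_unmeth_max < beta_meth_min <= 1")
        if not 0 <= self.absent_freq_max < self.marker_freq_min <= 1:
            raise ValidationError("need absent_freq_max < marker_freq_min in [0,1]")
        if not 0 < self.common_freq_min <= 1:
            raise ValidationError("common_freq_min must be in (0, 1]")
        return self


@dataclass
class StatsParams:
    """Dichotomization rules for the clinical association table."""

    alpha: float = 0.05
    thickness_cut_mm: float = 4.0
    stage_advanced_min: int = 3
    pooled_t: bool = False  # Welch by default

    def validate(self) -> "StatsParams":
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.thickness_cut_mm <= 0:
            raise ValidationError("thickness_cut_mm must be positive")
        return self


@dataclass
class RunConfig:
    """Everything a full pipeline run needs: paths plus stage parameters."""

    bundle_dir: Path
    outdir: Path
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    promoter: PromoterParams = field(default_factory=PromoterParams)
    qc: QCParams = field(default_factory=QCParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    calls: CallThresholds = field(default_factory=CallThresholds)
    stats: StatsParams = field(default_factory=StatsParams)
    make_plots: bool = False

    def validate(self) -> "RunConfig":
        for sub in (self.promoter, self.qc, self.cluster, self.calls, self.stats):
            sub.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bundle_dir"] = str(self.bundle_dir)
        d["outdir"] = str(self.outdir)
        return d


_SECTIONS = {
    "generator": GeneratorConfig,
    "promoter": PromoterParams,
    "qc": QCParams,
    "cluster": ClusterParams,
    "calls": CallThresholds,
    "stats": StatsParams,
}


def load_run_config(
    path: Optional[Path] = None,
    *,
    bundle_dir: Optional[Path] = None,
    outdir: Optional[Path] = None,
    overrides: Optional[dict] = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    YAML layout: top-level keys ``bundle_dir``, ``outdir`` and one mapping
    per section (``generator``, ``promoter``, ``qc``, ``cluster``, ``calls``,
    ``stats``) holding field/value pairs. CLI flags override file values.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict):
                raw.setdefault(key, {}).update(val)
            else:
                raw[key] = val

    sections = {}
    for name, cls in _SECTIONS.items():
        kwargs = raw.get(name, {}) or {}
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown {name} config keys: {sorted(unknown)}")
        for key in ("marker_freq_range",):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        sections[name] = cls(**kwargs)

    bundle = bundle_dir or raw.get("bundle_dir")
    out = outdir or raw.get("outdir")
    if bundle is None or out is None:
        raise ValidationError("bundle_dir and outdir are required")
    cfg = RunConfig(
        bundle_dir=Path(bundle),
        outdir=Path(out),
        make_plots=bool(raw.get("make_plots", False)),
        **sections,
    )
    return cfg.validate()
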
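# Methods

## Model and procedure

The pipeline treats promoter methylation of a gene as a single beta value
in [0, 1] read from the array probe nearest the gene's transcription start
site (TSS). The analysis chain is:

probe QC → representative-probe selection → promoter CpG classification →
variable-gene selection → two-way hierarchical clustering (epigenotypes) →
binary methylation calls and four-way gene categorization → clinical /
enrichment statistics.

Assumptions worth stating explicitly:

* one TSS and one manifest row per gene; multi-TSS resolution is out of
  scope;
* methylation at the representative probe is a proxy for promoter status —
  no region-level (multi-probe) smoothing is done;
* epigenotype is a two-class latent variable; finer cuts of the dendrogram
  are not interpreted;
* normal reference samples (melanocyte, PBMC, fibroblast) define the
  baseline state of each promoter but never influence the clustering.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| QC ε (max abs error) | 0.15 | beta | passes linear probes with small noise; rejects flat/inverted responses outright |
| QC ρ (min Pearson r) | 0.95 | — | monotonicity guard; constant series (undefined r) fail |
| CpG-score window | ±500 | bp around TSS | promoter-island scale; exposed in config |
| HCP / ICP thresholds | 0.72 / 0.48 | score | strict inequalities; 0.48 exactly is LCP |
| SD threshold | 0.15 | beta | variable-gene filter across tumors (sample SD, n−1) |
| top-n cap | 2000 | genes | applied after the SD filter, by descending SD |
| metric / linkage | Euclidean / Ward | — | deterministic, compact clusters; both configurable |
| call thresholds | ≤0.25 unmeth, ≥0.55 meth | beta | midway between typical unmethylated (~0.1) and hypermethylated (~0.8) levels, so single-sample calls sit ≥5 noise-SDs from both planted levels; the in-between band is "indeterminate" |
| marker freq min / absent max / common min | 20% / 5% / 95% | of subgroup | category rules (below) |
| frequent-marker floor | 25% | of cohort | ranks markers by whole-cohort frequency |
| α | 0.05 | — | per-test; a Benjamini–Hochberg column is emitted as a clearly labeled supplement |

Category rules, evaluated in order on (normal consensus state, % methylated
among high-subgroup tumors f_H, among low-subgroup tumors f_L):

1. normally methylated: normals methylated, f_H ≥ 95% and f_L ≥ 95%;
2. unmethylated: normals unmethylated, f_H ≤ 5% and f_L ≤ 5%;
3. high-methylation marker: normals unmethylated, f_H ≥ 20% and f_L ≤ 5%;
4. commonly methylated: normals unmethylated, f_H ≥ 20% and f_L ≥ 20%;
5. otherwise unclassified.

The per-gene normal state is called on the **mean** beta across the normal
columns rather than demanding unanimous per-sample calls: with only three
normals, a single noise excursion into the indeterminate band would
otherwise void the gene, and averaging triples the effective precision of
the baseline call. Indeterminate tumor calls count in frequency
denominators only.

## Statistics

* **Fisher exact** (two-sided): sums hypergeometric probabilities, margins
  fixed, of all tables whose probability is ≤ the observed one (the
  minimum-likelihood convention of mainstream statistics tools, which
  differs from the "double the one-sided p" convention). Sample odds ratio
  ad/bc reported.
* **t test**: Welch with Satterthwaite df by default (a pooled flag
  exists); groups reported as mean ± sample SD.
* **Kaplan–Meier**: product-limit estimator; censored times never drop
  S(t); median = first time with S ≤ 0.5.
* **Log-rank**: 1-df chi-squared from summed observed−expected events over
  distinct event times with the hypergeometric tie variance
  n₁n₂d(n−d)/(n²(n−1)).
* **Quartile expression grouping**: with n samples, the ⌊n/4⌋ highest
  values are "high", the ⌊n/4⌋ lowest "low", the middle half excluded;
  boundary ties break by (value, sample id) rank. All-equal input is an
  error.
* Clinical dichotomizations for the categorical display: stage 1–2 vs 3–4,
  thickness at 4 mm, age at the cohort median; the quantitative Welch test
  on raw thickness is the headline comparison.

All five kernels are verified in the test suite against independent
oracles: exact-rational enumeration (`math.comb`/`Fraction`) for Fisher on
every 2×2 table with N ≤ 30, hand-computed product-limit and
risk-set tabulations for KM/log-rank, plus scipy and lifelines
cross-checks, and a 100-cohort null simulation showing log-rank type-I
error inside the binomial 95% interval around 0.05.

## Synthetic cohort generator

The generator emulates a 51-tumor FFPE melanoma cohort with two latent
epigenotypes (17 high / 34 low) and three normal references. Gene
categories (4444 unmethylated, 27 high-methylation markers, 25 commonly
methylated, 405 normally methylated, 2000 low-CpG fillers) are planted
with base beta levels 0.1 (unmethylated state) and 0.8 (methylated state)
plus clamped Gaussian noise (SD 0.05). The base levels are deliberately
far from the call thresholds so that planted states are unambiguous.

Key generator choices:

* **Marker frequencies.** Each marker gene is methylated in k
  high-subgroup tumors with k chosen so that k / n_tumors lies in the
  configured 22–33% cohort window; all marker methylation is confined to
  the high subgroup, so a high tumor carries most (70–95%) of the markers.
  With 17/51 high tumors, 33% is exactly the attainable maximum — which is
  why the subgroup is sized at one third. TFPI2 is pinned to the top of
  the window, P4HTM and ACADL just below, DDIT4L to the bottom.
* **Commonly methylated genes** draw one frequency from the same window
  and apply it to each subgroup independently, so they add
  subgroup-independent variance without separating the clusters.
* **Promoter sequences** are assembled from 3-mers with fixed C/G content
  and an exact count of CG dinucleotides (no CG can form across 3-mer
  boundaries), so the central 1 kb window scores in the intended
  HCP/ICP/LCP band by construction; flanks are AT-rich random sequence.
* **Calibration series**: good probes report expected + N(0, 0.03)
  (control DNA is cleaner than FFPE tumor DNA, hence the smaller SD);
  3% of probes respond flat (uniform 0.3–0.7) or inverted (1 − expected),
  alternating. One probe per gene is protected from corruption so QC can
  never erase a gene's entire promoter coverage.
* **Thickness** is drawn from lower-truncated (0.1 mm) normals whose
  location/scale are solved numerically so the *realized* truncated
  distribution has the configured mean ± SD (8.3 ± 5.3 / 4.5 ± 2.9 mm);
  using the configured values as pre-truncation parameters would bias the
  high-subgroup mean upward by ~0.7 mm.
* **Survival**: exponential with median 700 days (high) vs 1800 days
  (low) and independent exponential censoring calibrated to 40% expected
  censoring; stage is enriched for 3–4 in the high subgroup
  ([.05,.20,.45,.30] vs [.25,.45,.20,.10]); BRAF (18/77), NRAS (20/77),
  acral site (35/77) and ulcers (45%) are independent of epigenotype.
* Probes per gene: uniform 1–10 at distinct signed TSS distances in
  [−1500, +500] bp (TFPI2: 21 probes, nearest at −15 bp). This keeps the
  probe-level matrix (~38k probes × 54 samples) fast to generate while
  exercising the representative-probe fallback.

What the generator does **not** emulate: Infinium type-I/II probe
chemistry, FFPE restoration artifacts, batch effects, logit-scale
(M-value) error structure, correlated probes within an island, or
realistic genomic coordinates. Passing tests therefore demonstrate that
the pipeline's logic recovers planted structure under idealized noise —
not that it is robust to every artifact of real array data.

## Numerical choices and degenerate inputs

* Representative-probe ties (equal |TSS distance|) prefer the upstream
  probe, then the lexicographically smaller probe id.
* Clustering is deterministic given input order; permuting samples leaves
  memberships invariant (tested via adjusted Rand index).
* The "high" label is a pure function of cluster mean beta; equal means or
  a cut that yields fewer than two clusters raise a degenerate-matrix
  error rather than guessing.
* A QC that excludes every probe, an empty gene selection, an all-equal
  expression vector, a one-group log-rank, and zero-variance t-test groups
  are all errors, not silent results.
* Problem sizes used in the checked examples: the default cohort
  (51 tumors, 6901 genes, ~38k probes) for end-to-end recovery; 20 seeds
  for epigenotype recovery; 100 simulations for log-rank calibration;
  all ~46k tables with N ≤ 30 for Fisher.

## Known limitations

* The CpG-score formula (observed/expected ratio) and its ±500 bp window
  follow the standard promoter-class literature; other island definitions
  would shift scores relative to the 0.72/0.48 thresholds.
* Category thresholds are design choices; no statistical test is applied
  on top of the frequency rules when categorizing genes.
* The dual-cohort marker comparison accepts any second marker table; no
  external-cohort download is performed.
* Survival modeling is nonparametric throughout; no proportional-hazards
  regression or competing risks.
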
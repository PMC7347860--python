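# Methods

This note documents the models and procedures implemented in `tei`, the
choices made where conventions differ, and what the synthetic test bed
does and does not establish about real data.

## The tE/I statistic

For a unit u (a sample, cell, subject or region), with AMPAR panel A
(*GRIA1–4*) and GABA_A_R panel G (the *GABR\** genes):

    tE/I(u) = Σ_{g∈A} x_ug / Σ_{g∈G} x_ug

on the **linear scale**. Log2 tables are exponentiated base 2 before
summation, because the statistic is defined on raw intensity/abundance
sums; FPKM/RPKM/uTPM inputs are already linear. A `use_log2_sums` switch
exists for sensitivity analysis, since published descriptions of
microarray ratios are sometimes ambiguous on this point. The companion
`log2(x + 1)` transform used in regression reporting applies a
pseudo-count of 1 to keep zero sums finite.

Summing all subunits is deliberately the most conservative, non-subunit-
specific estimate: it includes every potential receptor configuration
and makes no claim about synaptic vs extrasynaptic pools. Whether the
rho subunits (*GABRR1–3*) belong in the inhibitory sum is debatable;
they are included in the default 19-gene panel and the panel is
configurable.

Group summaries always report n, mean, SD and SEM (SEM over units in the
group — subjects or cells, matching "each point is one subject/cell"
conventions), so any mean ± SEM/SD presentation has a table counterpart.

## Representative-probe selection

Microarray designs measure each gene with several collinear probes
(here 4 each for *GRIA1–3*, 5 for *GRIA4* in the emulated design).
Clustering at probe level would weight genes by probe count, so one
representative probe per gene is chosen first.

Per gene, the probe × probe Pearson correlation matrix is computed
across **all samples** (whole brain). One factor is extracted by
iterated principal-axis factoring with no rotation:

1. initialise communalities h with squared multiple correlations,
   h_i = 1 − 1/ (R⁻¹)_ii (fallback: max |r| per row if R is singular);
2. replace diag(R) with h, take the leading eigenpair, set loadings
   λ = e₁ √max(ℓ₁, 0), update h = λ²;
3. repeat until max |Δh| < 1e-10 or 1000 iterations.

The iteration on rank-1-plus-diagonal matrices converges only linearly;
the common textbook budget of ~100 iterations leaves ~1e-4 loading
error, so the defaults here are deliberately tighter (1e-10 / 1000,
~300 iterations in practice) to make loadings accurate to well below
1e-6. Heywood cases (h > 1) are clipped to 1 − 1e-12 with a warning.
The loading sign is fixed so Σλ ≥ 0. A two-probe gene has an
under-identified factor model (both loadings collapse to √r); this is
accepted, as selection only needs the ordering.

The selected probe is argmax |λ|; ties (within 1e-9) go to the probe
with higher mean intensity, then lexicographic id. The selection report
carries gene, probe, loading, communality, mean intensity and a
tie-break flag, so the known diagnostic — the chosen probe may also be
the brightest, which can bias cross-probe proportions — stays visible.
A `group_by` option computes within-group-centred correlations instead;
whole-brain is the default as it matches how such selections are
reported. Zero-variance probes are excluded from the correlation and
selected only if they are the sole candidate.

## Age adjustment

Per gene, ordinary least squares of expression on age (years; prenatal
ages negative, birth = 40 post-conception weeks, so 12 pcw = −0.538 y).
The adjusted value is the residual plus the fitted value at the cohort
mean age, preserving global levels. With fewer than three distinct ages
the design is degenerate and the table passes through with a warning.
Adjustment is applied per dataset, never pooled across datasets, and is
idempotent to floating-point tolerance.

## Contributions, enrichment, summaries, nested ANOVA

* **Proportional contribution**: per group, percent_g = 100 ·
  mean_linear(g) / Σ_g' mean_linear(g'). Rows sum to 100 exactly and are
  invariant to global rescaling. All-zero groups are emitted missing.
* **Fold enrichment**: 2^(mean log2 in substructure − mean log2
  overall), i.e. subjects are averaged on the log2 scale **before**
  exponentiation (mean-then-ratio). The alternative (ratio of linear
  means) differs when within-group spread differs; the log2-mean
  convention matches how per-region averages are normally tabulated.
* **Five-number summaries** use linear-interpolation (type-7) quantiles
  — the dominant software default; whiskers at Q1 − 1.5·IQR and
  Q3 + 1.5·IQR clipped to the data range; points beyond are listed as
  outliers with their group label.
* **Nested ANOVA** treats structure and substructure-within-structure as
  **fixed effects**: SS_structure = Σ n_i (ȳ_i − ȳ)², SS_substructure =
  Σ n_ij (ȳ_ij − ȳ_i)², SS_error within substructures;
  F_structure = MS_structure / MS_substructure (the nested denominator),
  F_substructure = MS_substructure / MS_error. A random-effects
  treatment of substructure would be defensible; fixed effects were
  chosen for transparency and because the decomposition is what the
  recovery tests verify. Saturated designs (no residual df) raise an
  error naming the deficient level.

## Ward clustering and multiscale-bootstrap support

Clustering uses Ward's minimum-variance method on Euclidean distances
in the ward.D2 convention (merge heights on the square-root scale),
via the standard nearest-neighbor-chain linkage. Ties in merge order
are resolved deterministically by input order; permuting rows yields
the same tree up to relabeling whenever merges are untied.

Cluster support is computed by feature resampling at multiple scales
r ∈ {0.5, …, 1.4} (step 0.1). At each scale, B resamples of
round(r · n) feature columns are drawn with replacement, rows are
re-clustered, and each reference cluster's recurrence is counted by
**leaf-set identity** (invariant to child order). Then:

* **BP** = recurrence fraction at the scale closest to 1;
* counts are clamped to [0.5, B − 0.5] (continuity correction) rather
  than dropping extreme scales;
* ψ(r) = Φ⁻¹(1 − BP_r) is fitted as ψ ≈ v·√r + c/√r by weighted least
  squares with delta-method binomial weights
  w_r = B·φ(ψ_r)² / (BP_r (1 − BP_r)), falling back to unweighted LS if
  any weight is non-finite;
* **AU** = 1 − Φ(v − c), with its standard error from the WLS
  covariance. AU = BP exactly in the c = 0 limit (ψ ∝ √r); the c term
  absorbs the conservative bias of BP.

A cluster present in every resample at every scale (always the root)
gets BP = AU = 1 exactly. AU is reported missing (BP still reported)
when fewer than three scales are usable. The production default is
10,000 total resamples split evenly over the ten scales; tests and the
acceptance script use 100 per scale, which is ample for the planted
effect sizes they probe.

When clustering brain structures, the feature axis being resampled is
the (gene × subject) expression columns, not the handful of per-gene
means: with only four genes, scale resampling would be degenerate. The
same machinery applied to the transposed matrix clusters genes by their
regional profiles (two-way mode).

## Distance-vector variability

Per unit, the vector of pairwise differences d(x, y) = |x − y| over all
gene pairs in panel order — (1,2), (1,3), (1,4), (2,3), (2,4), (3,4)
for four genes — summarises the collective subunit organisation;
when a unit carries per-gene vectors the entries generalise to Euclidean
norms. The consensus d_c is either the elementwise **average of units**
(default for subjects, and for structures restricted to a reference
structure's units) or the **pooled** elementwise root-sum-of-squares;
both are shipped because the summation convention in published
descriptions is ambiguous, and neither is asserted as canonical.
Per-unit Pearson R against d_c is reported with per-structure
mean ± SD. R is invariant to positive rescaling of all expression and
to adding a constant to every gene of a unit.

## Developmental trends

Cubic smoothing splines with the smoothing parameter chosen by
generalized cross-validation (overridable). Duplicate ages are collapsed
to weighted means because the penalised-spline solver requires strictly
increasing abscissae. The fitted curve is defined only on the observed
age range — no extrapolation. Pre/postnatal linear fits split at birth
(age 0).

## The synthetic test bed

The generators define the study conditions for all recovery tests:

* **Regional microarray** (log2): 20 substructures in two ontogeny
  groups (telencephalic: frontal + hippocampal, GRIA2-high;
  metencephalic: cerebellar + pontine, GRIA3-low), 6 subjects aged
  24–57 y, per-substructure profiles = ontogeny means + jitter (SD 0.3
  log2), probe model λ_j·F_gs + √(1 − λ_j²)·ε with ε ~ N(0, σ = 0.6
  log2), additive per-subject per-gene offsets (SD 0.25) shared across
  regions, optional linear age slopes, and the 4/4/4/5 AMPAR probe
  plan plus three GABA_A_R genes so the ratio stage runs end to end.
* **Single cell** (linear, uTPM-like): seven interneuron types with the
  published per-type tE/I means and sizes (CCKC 0.66 n=64, CHC1 1.7
  n=80, CHC2 1.0 n=52, ISC 0.80 n=63, LPC 1.1 n=136, MNC 10 n=62,
  PVBC 0.96 n=127); dispersion = the printed SD/mean per type. The
  per-cell ratio is drawn lognormal around the type mean, the GABA_A_R
  total lognormal (mean 300 uTPM, CV 0.3), the AMPAR total is ratio ×
  total, and gene shares are Dirichlet — so the ratio is controlled
  exactly and dispersion 0 gives tE/I ≡ μ. Noise is lognormal, not
  negative binomial, because the emulated inputs are normalized
  abundances, not counts; optional zero-inflation is off by default.
* **Developmental** (linear, RPKM-like): total AMPAR constant at 100,
  GABA_A_R rising logistically from 80 to 100/0.31 ≈ 322.6 (midpoint
  −0.1 y, rate 12/y) so the true tE/I falls from 1.25 to a 0.31 adult
  plateau reached before one postnatal year; KCC2 rises and NKCC1
  falls on similar logistics, planting a negative prenatal tE/I ↔
  KCC2/NKCC1 association and none postnatally. Ages span 12 pcw to
  40 y (2 subjects per age, 6 cortical regions); multiplicative
  lognormal noise (log-SD 0.08) keeps values positive and makes the
  zero-noise limit exact.

All generators are pure functions of (config, seed). What passing tests
show: the pipeline recovers planted probes, partitions, slopes, means
and associations under single-factor collinearity, additive subject
effects and lognormal noise. What they do not show: robustness to batch
effects, probe-sequence artefacts, count noise, dropout at scRNA-seq
coverage, postmortem degradation, or ontology misassignment — none of
which the generators model.

## Problem sizes

The test suite and acceptance script run the probe-selection study at
600 samples × 100 replicates, bootstrap support at 100 resamples per
scale, the Welch calibration at 2,000 null replicates and the
nested-ANOVA calibration at 1,000 — sizes at which every Monte-Carlo
bound checked has comfortable margin while the whole suite stays fast.

## Known limitations

* The tE/I ratio weighs all subunit transcripts equally; it is a
  transcriptional marker, not an electrophysiological measurement.
* Fixed-effects nested ANOVA understates uncertainty if substructures
  are better viewed as sampled from a population.
* AU p-values rest on the z-curve approximation; at very small feature
  counts the scale grid degenerates and AU is reported missing rather
  than extrapolated.
* The probe-selection factor model assumes one shared signal per gene;
  genes with genuinely multi-factor probe behaviour will still get a
  single representative, chosen by the dominant factor.
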
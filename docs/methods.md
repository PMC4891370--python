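# Methods

## Scope and data model

The package models the targeted-quantitation workflow for released,
ethyl-esterified N-glycans measured as sodiated ions in
reflectron-positive MALDI-TOF-MS. Its unit of annotation is the
monosaccharide composition `H/N/F/E/L/Ge/Gl/Ac` (hexose, HexNAc,
deoxyhexose, α2-6/α2-3-NeuAc, α2-6/α2-3-NeuGc, O-acetyl); structure
beyond composition (linkage graphs, antenna topology) is deliberately
out of scope, except for the deterministic classification rules below.

## Mass and isotope model

All masses derive from CODATA/IUPAC atomic monoisotopic masses through
residue formulas (Hex C6H10O5, HexNAc C8H13NO5, dHex C6H10O4, NeuAc
C11H17NO8, NeuGc C11H17NO9) and modification formula deltas (ethyl
ester +C2H4, lactone −H2O, O-acetyl +C2H2O), plus terminal H2O and the
adduct (m(Na) − m(e⁻) for [M+Na]⁺). Storing formulas rather than
pre-summed masses makes every reported m/z a computed check; displayed
values are rounded half-up to 2 decimals. Constants can be overridden
one key at a time from YAML, e.g. to emulate a methyl-amidation
chemistry.

Isotope patterns are computed by exact convolution of per-element
isotopologue distributions, aggregating isotopologues by nominal mass
shift and tracking the abundance-weighted mean mass per shift. The
returned pattern is the minimal nominal-mass prefix whose cumulative
raw abundance reaches the requested coverage. The test suite pins this
against an independent exhaustive-enumeration oracle (binomial/
multinomial sums per element) at per-peak 1e-9.

## Structural classification

Deterministic composition rules: high-mannose iff N=2, H≥5, no fucose
or sialic acid; hybrid iff N=3 and H≥5; otherwise complex with
antennae = N−2 (capped at 4) and antennary galactoses
max(0, min(H−3, antennae)). Paucimannose stubs (H3N2/H4N2) classify as
complex with 0 antennae and are excluded from per-antenna denominators.
Hybrid glycans carry one decorated antenna for per-antenna traits but
report 0 structural antennae. These rules reproduce the class label of
every named composition in the mouse fluids they were built for; they
are heuristics for compositions outside that set.

## Default feature list

The 104-composition default list is a rule-based enumeration standing
in for the curated 94-peak panel of the original workflow (whose exact
rows are not published in machine-readable form). Rules: N 2–6;
galactoses ≤ antennae with tri/tetraantennary species at least
(antennae−1)-galactosylated; sialic acids ≤ min(antennae+1,
galactoses+2) with at most one GlcNAc-linked sialic acid on tri/tetra
species; α2-3-NeuGc ≤ 2; at most one NeuAc, only as the sole sialic
acid of the fully galactosylated diantennary backbone; core fucose on
mono–triantennary species (difucosylation only in the two observed
monosialylated diantennary patterns); O-acetylation (1–2) only on
disialylated fully galactosylated diantennary NeuGc species. One
curation rule is driven by resolvability rather than biosynthesis: the
α2-3 variant of the fucosylated monosialylated triantennary glycan is
exactly isobaric (4 × 1.00336 Da) with the H4N4Ge2Gl1 isotopologue tail
and is therefore not targeted. The resulting list has a minimum pair
distance of 3.0 Da; any user list with pairs closer than 0.1 Da
triggers a resolvability warning.

## Preprocessing

**Background/noise.** Around each isotopologue a ±10 Da window is
taken, points within ±0.35 Da of any known peak (all listed features'
isotopologues plus calibrants) are masked, and the lowest 20 % of the
remaining intensities form the background sample — robust because
unmodeled peaks only push intensities up. Because the lowest quintile
of a noisy baseline lies below its true level, the mean and SD of that
sample are corrected with truncated-Gaussian factors (mean shift
1.3998σ, quintile SD 0.4676σ), so that on a flat baseline b with noise
σ the estimator converges to (b, σ). Noise is this corrected σ; S/N is
(apex − background)/noise at the most abundant clean isotopologue.

**Recalibration.** Calibrant apexes are located within ±0.3 Da with
three-point parabolic interpolation (sub-grid accuracy); with ≥5
calibrants at S/N ≥ 9 an unweighted quadratic least-squares map from
observed to theoretical masses is applied to the whole axis, otherwise
the spectrum is excluded. TOF axis errors are smooth and low-order, so
a quadratic reduces the injected ppm-level distortions of the synthetic
spectra to < 5 ppm; recalibration is idempotent to < 1 ppm.

**Extraction.** Isotopologues covering 95 % of the envelope are
integrated over ±0.25 Da (reflectron-TOF peak widths at m/z 900–3800)
as Σ max(intensity − background, 0)·Δm. Windows that coincide (within
0.5 Da) with a major isotopologue (≥10 % of the 99.9 % envelope) of
another listed feature are skipped — the O-acetylated species sit
4.03 Da below their ethyl-esterified partners, so their 5th
isotopologue lands on the partner's monoisotopic peak. The total is
divided by the summed pattern abundance of the windows actually used,
which makes areas comparable across features and, on noiseless
synthetic data, exact: closed-loop recovery error is < 0.06 percentage
points per feature.

**QC and normalization.** Inclusive thresholds: calibration S/N "9 or
above" is ≥9; a spectrum passes when the area fraction from features
with S/N > 9 is ≥ 0.45. Surviving profiles are normalized to total
area 100 %. Per-point flooring at zero biases integrated areas of
near-absent features slightly upward; the bias is identical across
groups and cancels in all group contrasts.

## Derived traits

Nineteen traits (the `trait_glossary()` output is the authoritative
formula text): three glycan-type percentages; four antennarity
percentages of complex glycans (denominator: antenna-bearing complex);
fucosylation, mono-/multifucosylation and acetylation indicator sums;
and per-antenna weighted means for galactosylation, total sialylation,
NeuGc (total, α2-6, α2-3) and NeuAc (α2-6, α2-3), over complex+hybrid
glycans. Branching sialylation is Σ a_i [S_i > ant_i]: a glycan counts
as branching-sialylated iff it carries more sialic acids than antennae,
which reproduces every species-level branching call in the mouse data
(and deliberately does not flag the triantennary trisialylated species,
whose status composition alone cannot decide). A total-NeuAc-per-antenna
column is not included: it is exactly the sum of the two linkage-specific
NeuAc traits, and dropping the redundancy is what makes the table
nineteen columns. Per-antenna denominators include hybrid species
(effective antennae 1).

## Synthetic study generator

The generator is the stand-in for the study's unavailable raw data and
defines the conditions under which the pipeline is validated.

*Profile layer.* The baseline profile (31 nonzero features of the 104)
is constructed so its traits land on the baseline mouse values:
complex > 90 %, antennarity 2.6/87.8/9.1/0.5 %, galactosylation/antenna
97 %, fucosylation 29 %, sialylation/antenna 98.6 %, NeuGc α2-6 79 %
and α2-3 19 % per antenna, acetylation 7.6 % (plasma), branching 6.4 %.
The peritoneal variant multiplies high-mannose (×1.56), acetylated
(×1.45) and branching (×1.28) species and renormalizes, giving
acetylation 10.4 %, branching 7.8 %, high-mannose 1.3 %. ZIP effects
are abundance reallocations between biologically paired features — the
glycan-level drivers of the trait changes: H5N4F1Ge2→H5N4Ge2
(fucosylation −8 pp at the 24 h minimum, flat thereafter),
H5N4F1Ge2Ac1→H5N4F1Ge2 (acetylation decrease), H5N4Ge2→H4N4Ge2Gl1
(α2-3/branching/sialylation rise peaking at 48 h) and
H5N4Ge2→H6N5Ge2Gl1 (triantennary rise). All effects are zero at
0–4 h. Between-animal variation is logistic-normal (Gaussian σ = 0.06
on log-abundances, then softmax), which preserves the simplex and
yields trait SEMs of a few tenths of a percentage point at n = 3–6,
matching the reported dispersion. Design: ZIP n = 6 and control n = 3
per time point on the 0/2/4/12/24/48/72 h grid.

*Spectrum layer.* Gaussian envelopes (FWHM 0.15 Da, optionally
m/z-dependent) with total area proportional to abundance
(100 area-units per percent), on a gently sloping baseline (20 − 0.004
per Da), eight spiked peptide-like calibrant peaks placed > 1 Da from
any feature isotopologue, additive Gaussian noise, and a smooth
quadratic ppm-level axis distortion (≤ ~45 ppm). The default noise
gives base-peak S/N ≈ 2400, the regime of 10,000-shot summed profiles;
this keeps the positive bias from per-point zero-flooring below the
closed-loop tolerance. Noisier regimes (calibration failure, the 45 %
QC exclusion, S/N-driven quality decay) are exercised by raising σ
explicitly in the tests rather than by the default.

*What the generator does not emulate:* matrix/ionization physics
(lactone instability, sodium/potassium adduct competition), detector
saturation, chemical noise with mass-defect structure, correlated
between-feature measurement error, and real biological covariance
between traits. Passing tests therefore demonstrate correctness of the
computational pipeline under the stated acquisition model, not
robustness to every failure mode of real MALDI data.

## Statistics

Equal-variance classical tests throughout (the original analyses used
Prism defaults): paired t-test; one-way ANOVA with Tukey HSD
(statsmodels); two-way ANOVA (group, time, interaction; type-II sums
of squares for unbalanced data) with per-time treated-vs-control
contrasts tested against the pooled residual variance. The
multiplicity adjustment over the k time points is the studentized
maximum modulus probability P(max|T_i| ≥ t) for k contrasts sharing a
χ² denominator — the Dunnett multivariate-t with identity correlation,
which is exact here because distinct-time contrasts share only the
pooled variance. It is computed by numerical integration over the
pooled-SD density; k = 1 reduces to the ordinary two-sided t-test, and
the test suite pins the general case against direct Monte-Carlo
simulation and verifies the familywise error under null simulations.
Zero-variance inputs return flagged degenerate results instead of
infinite statistics. Experiments 1 and 2 are analyzed separately (each
time point is an independent set of sacrificed animals; no longitudinal
correlation modeling).

## Problem sizes used in validation

Closed-loop recovery runs 14 noiseless spectra (one ZIP + one control
per time point) over all 104 features; the longitudinal significance
check uses the default n = 6/3 design at the profile level; the null
calibration uses 500 replicate studies with vectorized trait
computation. These sizes make the full suite complete in a few minutes
while keeping every estimate's Monte-Carlo error well inside the
asserted tolerances.
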
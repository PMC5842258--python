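# Methods

`atscan` implements the statistical core of an Associative Transcriptomics
study of stem lodging resistance in a diversity panel of near-inbred
*Brassica napus* accessions: deriving stem mechanical-strength traits from
three-point-bend tests, scanning transcriptome-derived SNP markers and
gene-expression markers (GEMs) for trait associations under structure and
kinship correction, validating candidate markers by allele-class
comparison, and comparing cell-wall FTIR spectra.  A synthetic panel
generator with a ground-truth ledger makes every stage testable without
field data.

## Stem mechanics

A dried basal stem section rests on two supports a span `L` apart
(default 70 mm; 12 mm for *Arabidopsis*-sized stems) and a probe loads it
at midspan, `a = L/2`.  From the force–displacement trace we read the two
*absolute* strength traits — peak force `Fmax` and elastic slope `F/V` —
and combine them with the cross-section's second moment of area

    I = pi (D2^4 - d1a^4) / 64

into the *material* strength traits

    MOR = Fmax * a * D2 / I
    MOE = (F/V) * (a^2/12) * (3L - 4a) / I        (= (F/V) L^3 / 48 I at a = L/2)

`D2` and `d1a` are always derived from the measured whole-stem and hollow
areas via `d = 2 sqrt(area/pi)`, never measured directly.  Forces are
carried in the instrument's units with no gravity or probe-speed
conversion: published worked values for these traits cannot be reconciled
under any single SI conversion, so the package is unit-agnostic and
treats reported trait magnitudes as descriptive.  Callers may rescale
inputs themselves; all outputs are homogeneous of degree one in force.

### Reading the trace

* **Peak force.** `max(force)` of a noisy trace is biased upward by the
  largest noise excursion, so `Fmax` is taken as the peak of the
  least-squares *unimodal* (rise-then-fall) projection of the trace.
  A clean unimodal trace is its own projection, so noise-free curves are
  returned exactly.  When measurement noise is detected — via the median
  absolute second difference, which annihilates locally linear signal —
  the trace is first smoothed with a quadratic Savitzky–Golay filter
  (window ≈ n/12, clamped to [5, 101]) so the projection pools
  neighbouring samples instead of riding a single excursion.
* **Elastic slope.** `F/V` is the least-squares slope over pre-peak
  samples whose fitted force lies in 10–75% of `Fmax`.  The lower cut
  skips the toe-in region; the upper cut stops before the approach to
  failure.  A narrower window (e.g. 10–40%) is statistically
  information-starved: at white noise of 5% of `Fmax` and any realistic
  sampling rate it leaves a slope standard error near 6%, which no
  estimator can repair.  The window is configurable per call.

With these defaults, simulated traces (500 samples/s at 2 mm/s probe
speed, exponential post-failure tail) give exact recovery when clean and
~99% joint recovery of `Fmax` and `F/V` within 5% at a noise SD of 5% of
`Fmax`.

## Trait statistics

Accession effects are screened by one-way ANOVA of each trait.  Residual
normality is checked with a Shapiro–Wilk test at α = 0.05 as an
automatable proxy for visual assessment; on rejection the ANOVA is
recomputed on log10-transformed values (shifted by half the smallest
positive value when zeros are present; the offset is recorded) and
flagged.  Pairwise trait relationships are summarised by a Pearson
correlation panel with two-sided P-values against zero and the
conventional `*`/`**`/`***` tiers at P ≤ 0.05/0.01/0.001.  Because
published trait tables of this kind are ambiguous about whether entries
are r or R², the result object exposes both (`r` and `r_squared`),
explicitly labelled.

## Association engine

**Marker filtering.** Minor-allele frequency is computed over non-missing
calls; markers with MAF *strictly* below the 5% threshold are removed
(the boundary value is retained), and all-missing markers are removed and
counted separately.

**Kinship.** VanRaden centered cross-product: dosages mean-imputed per
marker, centered by twice the allele frequency, and scaled by
`2 Σ p_j (1-p_j)`.  Because centering puts the ones vector in the null
space, K always has one ~zero eigenvalue; if imputation noise drives any
eigenvalue below −1e−8 the matrix is shifted by `(|min eig| + 1e−10) I`.

**Mixed model.** The SNP scan fits `y = Xb + g_marker + u + e` with
`cov(u) = σ_g² K`.  Fixed effects are an intercept, the ancestry (Q)
fractions with the last column dropped for identifiability, and the
additive marker dosage (0/1/2; heterozygotes contribute 1; no dominance
term — the panel is near-inbred).  The variance ratio
`δ = σ_e²/σ_g²` is estimated once per trait under the null by REML,
profiling the restricted likelihood through the spectral decomposition of
`S K S` (S the projection orthogonal to the fixed effects) and optimizing
over `log δ ∈ [log 1e−5, log 1e5]` by grid search plus bounded
refinement.  Each marker is then tested by generalized least squares at
that `δ̂` with a Wald F-test on `n − p` residual degrees of freedom — the
P3D/EMMAX approximation, matching the default behaviour of the standard
mixed-model association tools; exact per-marker REML is available behind
`p3d=False`.  The GLS is solved by QR of the square-root-weighted design
so P-values are stable to ~1e−9 under affine trait rescaling.  Raw
P-values are reported with Bonferroni and Benjamini–Hochberg columns; no
significance filter is hard-wired (the study this design follows used a
retrospective threshold, so thresholds are the user's choice).

Identifiability note for δ: with only two sub-populations and Q in the
fixed effects, the projected kinship `S K S` of a small unstructured
panel approaches a scaled identity and δ is weakly identified; δ̂ then
drifts to a bound while marker tests remain calibrated (only
`σ_g² (K + δI)` matters, and its profile is flat exactly when the bound
is reached).

**Trait effect.** Marker effects are additionally expressed as the
absolute difference between homozygote-class means as a percentage of the
trait's range across accessions.

**GEM scan.** Per unigene, a fixed-effect model
`trait ~ intercept + Q + expression` with expression on a `log2(x+1)`
scale (variance stabilization for heavy-tailed RPKM; the transform is
configurable).  The default omits kinship, with a `kinship=` argument to
add it, since the corresponding published protocol is ambiguous on this
point.  The coefficient's sign distinguishes positive from negative
expression–trait association; a partial R² for the expression term is
reported.  **Expression-as-trait**: any unigene's (transformed) RPKM
vector can be mapped as a trait in a second-pass MLM SNP scan, marked as
such in the output metadata.

## Marker validation

On an independent test panel, plant replicates are collapsed to accession
means (the default; pooling is available) and the trait is compared
between the two homozygous allele classes with Welch's unequal-variance
t-test (pooled-variance by flag).  Heterozygous or off-ladder calls are
excluded from the comparison and counted.  Allele counts per
sub-population (hard-assigned by argmax of Q) are tabulated with a
chi-square independence test without continuity correction, to check that
allele classes do not simply mirror structure.

## FTIR

Spectra are truncated to the fingerprint window (800–1800 cm⁻¹); the
absorbance at the 1800 cm⁻¹ anchor is subtracted as a constant offset
(a single-point anchor, not a sloped baseline); and each spectrum is
divided by its trapezoidal integral so the window has unit area.  State
flags make preprocessing idempotent.  Group comparisons are pointwise
mean differences (convention `A − B`, stated in the output metadata
because the published description of the subtraction direction is
ambiguous), with signed read-outs at the 1740 cm⁻¹ ester and 1624 cm⁻¹
carboxylate bands; the integrated band ratio over ±8 cm⁻¹ windows tracks
pectin methylesterification and is invariant to global scaling of the
raw spectrum.

## Synthetic panels

`PanelConfig` defaults describe a panel like the real study's: 79
accessions in K = 2 admixed sub-populations, three plant replicates,
markers in pseudomolecule order over paired A/C pseudochromosomes.

* **Genotypes.** Ancestral allele frequencies ~ U(0.1, 0.9); per-marker
  sub-population frequencies from a Balding–Nichols Beta distribution at
  the configured Fst (0.2 by default); accession ancestry from a
  concentrated Dirichlet (each accession leans to its sub-population);
  genotypes drawn near-inbred (one allele copied to both homologues) with
  3% heterozygotes and 2% missing calls.  Homoeologous duplication is
  modelled as marker-pair correlation: a configurable fraction of A-block
  markers is copied to the matching C-block offset with 90% per-accession
  concordance — enough to reproduce paired A/C association peaks at desk
  scale without simulating whole subgenomes.
* **Expression.** `log2 RPKM = baseline + cis_effect × dosage + noise`,
  exponentiated; planted mediator genes carry a cis-eQTL.
* **Traits.** `Fmax = intercept + Σ causal SNP effects + Σ gene→trait
  effects × log2(RPKM+1) + subpop_effect × (centered ancestry) +
  polygenic + plant-level noise`, with the polygenic term drawn from
  `N(0, polygenic_var × K_realized)` and the noise variance set so
  genetic/total variance equals the configured heritability (0.6).
  `subpop_effect` (default 0) adds the classic ancestry-confounded trait
  component used in structure-correction simulations.  Secondary traits
  (F/V, stem geometry, plant height, stem weight, field lodging score)
  are drawn at the accession level with fixed target correlations to
  Fmax (e.g. 0.88 for F/V, 0.42 for the lodging score, mirroring the
  magnitudes reported for real panels) plus small replicate noise.
* **Bend curves / spectra.** As described above; the spectra superpose
  the two esterification bands (1740 cm⁻¹ amplitude ∝ ester level,
  1624 cm⁻¹ ∝ its complement) on fixed carbohydrate/OH background peaks.

What the generator does *not* emulate: linkage disequilibrium beyond
homoeologue pairs, multi-environment effects, read-level expression
noise, or family structure within sub-populations.  Tests passing on
these panels show the estimators are correct and calibrated under the
stated model, not that real *B. napus* data satisfy that model.
Within-accession replicate variance components are not calibrated
against any published value (none is available) and are tunable.

## Calibration and recovery experiments

`atscan.experiments` fixes the problem sizes used by the test suite and
the reproduction script (chosen for desk-scale runtimes):

* **Structured null** (50 panels, 79 accessions, 2000 markers, Fst 0.2,
  `subpop_effect = 1.5`, polygenic 0.3): kinship from the full filtered
  marker set — the field protocol — and every 4th marker scanned, so a
  tested marker is a negligible share of K and the type-I tally stays
  near-independent.  Expected behaviour: MLM median λ ≈ 1 and type-I
  ≈ 5%, naive OLS λ ≈ 3–4.
* **Recovery** (20 replicate panels each): a causal SNP of 0.45 trait
  units/allele planted on a common (MAF 0.35–0.5), non-duplicated
  marker — a realized trait effect of roughly a quarter of the accession
  range — must top the MLM scan; a mediator gene (cis effect 1.5 log2
  units/allele, trait effect 0.4 per log2 unit, 300 competing genes)
  must top the GEM scan, and its cis marker the expression-as-trait
  scan.
* **Curve recovery** (200 traces at noise SD 5% of Fmax) and **FTIR
  signs** (50 runs of high- vs low-esterification groups).

## Numerical choices

* REML grid: 121 points in log δ over [1e−5, 1e5], then bounded
  refinement to `xatol` 1e−10; δ at a grid endpoint is reported with an
  `at_bound` flag.
* Eigenvalues of `S K S` are clipped at zero; P-values are floored at
  the smallest positive double; degenerate scans (monomorphic or
  all-missing markers, zero-variance unigenes) are flagged rows, not
  errors.
* Missing dosages are mean-imputed per marker both in kinship and at
  test time, with the imputation count recorded per marker.
* Correlation panels use pairwise-complete observations; constant
  columns yield missing entries with a warning.
* All tabular outputs are UTF-8 tab-delimited with `#`-prefixed
  provenance headers; reruns under the same configuration and seed are
  byte-identical.

## Known limitations

* P3D uses one δ̂ per trait; for markers of very large effect the exact
  per-marker REML option is slower but more accurate.
* The GEM scan's fixed-effect default can inherit inflation on strongly
  structured panels; pass the kinship matrix when that matters.
* The unimodal-projection peak estimator assumes a single failure event;
  traces with multiple local maxima of comparable height (progressive
  failure) will be read at the largest pooled peak.
* Hudson-style Fst recovery and the other generator checks validate the
  simulator against its own model, not against population-genetic
  reality.
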
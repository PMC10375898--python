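# Methods

This note documents the statistical model behind `chemclipseq`, the
choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Enrichment model

The observed data are per-nucleotide read coverages for paired
libraries: "input" (total RNA before pull-down) and "output" (RNA eluted
after covalent pull-down), per condition and replicate. The enrichment
statistic at nucleotide *i* is the depth-normalized ratio

r_i = ((O_i + c) / N_O) / ((I_i + c) / N_I),

where O, I are replicate-pooled counts, N are total library counts
summed over all contigs, and c is a pseudocount (default 1 read on both
sides) that keeps low-coverage sites finite. Sites with pooled input
coverage below `min_input` (default 1) are masked and receive no
p-value. P-values are computed on replicate-pooled tracks; replicate
consistency is enforced later as a filter, not in the test statistic.
Depth normalization makes the statistic invariant to uniform scaling of
either library.

## The log-normal null and its fit

Under the null, ln r is modelled as Normal(μ, σ²) and each site gets the
one-sided upper-tail p-value of that distribution at ln r_i, reported as
−log10 p. The survival function is evaluated in log space
(−log10 p = −logSF(z)/ln 10), so sites hundreds of standard deviations
out remain finite and ordered; values are capped at 350.

μ and σ must be estimated from the data themselves. Three estimators are
provided:

- **robust** (median, MAD × 1.4826): nearly unaffected by a few percent
  of truly enriched sites; the default for a first pass on data that may
  contain signal.
- **tail** (least-squares line through the normal QQ plot over the
  upper quantiles, default probability range 0.75–0.999 at 60 points):
  anchors the fit to the upper tail that the one-sided test uses.
  The realized ln r is not exactly normal — it is the configured
  log-normal background convolved with Poisson counting noise whose
  variance falls as true enrichment rises — and a centrally fitted
  normal is therefore a few percent conservative in the far upper tail.
  Fitting the upper quantiles instead calibrates exactly the tail
  probabilities that become p-values. The cost is sensitivity to
  contamination, so this estimator is intended for background that has
  already had candidate regions excluded.
- **moments** (mean, sd): provided for completeness.

The pipeline default (`run_enrichment`) combines them: robust first
pass → compile candidate regions → exclude those intervals → tail refit
→ final p-values and regions. On pure-null simulations at one million
nucleotides (μ = 0, σ = 0.5, 30× depth, 3 replicates) the resulting
empirical frequencies of −log10 p > t match 10⁻ᵗ at t = 1, 2, 3 within
about twice the binomial sampling error; a single-pass median/MAD fit
is measurably conservative (tail frequencies 3–11% low, relative). The
exclusion step also keeps the refit honest when a nontrivial fraction
of the transcriptome is genuinely bound. Residual sub-threshold
enrichment that escapes exclusion biases the refit slightly upward,
which is conservative.

Zero dispersion (all ratios identical) and fits on fewer than
`min_fit_n` (default 100) sites are errors, not silent successes. The
tail fit needs enough sites for its highest quantile to be meaningful;
at the default range, ~10⁴ background sites or more are recommended.

## Region compilation and the filter cascade

Maximal runs of adjacent nucleotides with −log10 p strictly above the
cutoff (default 10) become candidate regions; runs separated by at most
`max_gap` sub-threshold or masked nucleotides are merged (default 0,
strict adjacency; a gap of 1–2 is useful when isolated masked
nucleotides would otherwise shatter long regions).

Four filters then apply, all at published operating-point defaults:

1. **AUC ≥ 200.** "Area under the curve" of a thresholded signal is
   ambiguous; the default is the area *above* the cutoff,
   Σ max(0, −log10 p_i − cutoff), which is zero exactly at threshold
   and is the stricter reading. The raw sum Σ −log10 p_i is available
   as `auc_mode="raw"`; neither is asserted to be what any particular
   external tool computes.
2. **Length 400–1000 nt**, inclusive on both ends — the fragment-size
   range a pull-down library typically shows.
3. **Pooled reads ≥ 10**, counted on the output side by default (the
   measured quantity of interest; the input side is configurable).
4. **Per-replicate log₂ fold change ≥ 0.8 in every replicate**, where
   each replicate's fold change uses its own library totals and the
   region-summed counts with pseudocount 1.

Failing regions are retained in the verdict table with one boolean per
filter, so the cascade is auditable. No multiple-testing correction is
applied across nucleotides: the published procedure is a fixed
−log10 p cutoff, and the extreme threshold (p < 10⁻¹⁰) together with
the length filter makes chance regions of 400+ adjacent passing
nucleotides essentially impossible under the null.

## Transcript-level aggregation

Regions map to transcripts by span overlap of at least one nucleotide
(exon structure is deliberately ignored; the default simulation is
transcriptome-space where each transcript is its own contig). A region
overlapping several transcripts counts toward all of them and is
flagged ambiguous — double counting across transcripts is accepted so
that no signal silently disappears. Within one transcript regions are
disjoint, so reads are never double-counted there.

Per transcript and side, region reads are summed, scaled to
reads-per-million of the library total ("normalized to total reads";
the denominator is the whole library, not the region universe), and

log₂ enrichment = log₂((output_rpm + 0.5) / (input_rpm + 0.5)),

with the 0.5 pseudocount in rpm units. The hit threshold is log₂ ≥ 0.8,
matching the replicate filter's scale.

## Repeat-window quantification

A pure-repeat segment cannot be quantified by region calling: reads
consisting solely of repeat sequence do not align to a reference lacking
the expansion, and repeats amplify and clone poorly, so coverage — and
with it the significance mass (AUC) — collapses even at a genuinely
bound locus. The window quantifier instead reports, per replicate, the
depth-normalized output/input fold over a fixed-width window (default
500 nt) centered on the locus midpoint and shifted (never truncated) to
stay within the contig; a contig shorter than the window is an error.
Symmetric dropout — the same fraction of reads lost from both
libraries — divides out of the ratio exactly; *asymmetric* dropout does
not and remains the user's risk. Cross-condition comparison is provided
as Welch's t-test on the per-replicate folds, a deliberate
simplification of a full two-way ANOVA, adequate for one locus and two
groups.

## Rescue classification

Expression is tested as log₂(TPM + 1), splicing as Ψ on [0, 1]
(untransformed by default; arcsine-square-root by flag). Per feature,
Welch's t compares disease-vehicle vs healthy-vehicle; *dysregulated*
means p < α (default 0.05). *Shifted toward WT* compares group means on
the tested scale; *rescued* additionally requires the treated-vs-healthy
test to be non-significant. With 2–3 replicates per group the Welch
test is conservative (empirical size ≈ 0.03 at nominal 0.05), which the
tests document rather than hide.

For the transcriptome-scale **summary estimator**
(`estimate_rescue_fraction`, and the `rescue` CLI subcommand) the
dysregulation call additionally requires a volcano-style effect-size
floor, |Δmean| ≥ 1 log₂ unit (expression) or ≥ 0.1 (Ψ). The reason is
structural: with thousands of truly unchanged features, a raw
per-feature α admits α × n false discoveries; being selected for
extreme vehicle values, these are classified "rescued" most of the
time, and at realistic scales they can outnumber the true dysregulated
set, dragging the estimated rescue fraction toward a fixed selection
artifact regardless of the truth. Benjamini–Hochberg control is
implemented (`correction="bh"`) but is not the default remedy because
at n = 3 per group the Welch null distribution cannot produce p-values
small enough to survive it — the fold-change floor preserves power
while removing essentially all false discoveries at these effect
sizes. The per-feature classifier (`classify_dysregulated`) keeps the
plain p < α rule as its default; the floor and the correction are
explicit options.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the sequencing process:

- One contig per transcript, lengths uniform in a configurable range
  (default 2000–8000 nt), written as valid GTF (1-based closed at the
  file boundary; everything in memory is 0-based half-open).
- A latent true-ratio field per nucleotide: exp(Normal(μ, σ²)) under
  the background, multiplied by the configured fold inside spiked
  intervals. The field is drawn once per site and shared across
  replicates — true binding is a property of the site, which is what
  the replicate-consistency filter assumes — while counts are drawn
  independently per replicate: input ~ Poisson(depth), output ~
  Poisson(depth × ratio).
- Defaults: 3 replicates, 30× input depth, background μ = 0 and
  σ = 0.1. The σ default keeps library-level pull-down variability
  modest relative to Poisson counting noise at 30× (log-scale sd ≈ 0.19
  for a pooled triplicate), which is the regime where a fold-6 site is
  cleanly separable — the situation the assay is designed for.
  Calibration is additionally exercised at σ = 0.5 in the tests.
- An optional repeat locus multiplies coverage on *both* sides by
  (1 − dropout_fraction), emulating alignment dropout of pure-repeat
  reads. Zero-coverage nucleotides are written as 0, not masked, so
  pseudocount handling is exercised downstream.
- Rescue matrices: gene baselines uniform in log₂ [3, 10] (expression,
  emitted as TPM with log₂(TPM+1) exactly Gaussian) or in [0.15, 0.85]
  (Ψ, clipped to [0, 1]); a chosen subset of genes offset by
  ±effect_size in disease-vehicle; a chosen fraction of those returned
  to the healthy mean in disease-treated; i.i.d. Gaussian noise per
  replicate.

Not emulated: fragment-level read sampling and positional
autocorrelation of coverage, GC/mappability bias, exon structure,
stranded libraries, overdispersed counts, asymmetric dropout, and
correlated replicates. Passing the synthetic suite therefore shows the
statistics are implemented correctly and calibrated under the stated
model; it does not certify performance on real libraries, where
coverage autocorrelation in particular makes adjacent nucleotides
non-independent and region boundaries fuzzier than simulated.

## Problem sizes and numerical choices

The test and acceptance workloads use: 10⁶ nucleotides for null
calibration; 10 simulations of 100 transcripts (≈ 5 × 10⁵ nt each) with
ten fold-6 spikes for recovery; 250 random tracks per gap mode (lengths
10³–10⁵) against a brute-force scanner; 10 seeds × three true rescue
fractions at 5000 genes for parameter recovery — sizes chosen so the
whole suite runs in a couple of minutes on one CPU while keeping
binomial error bars tight enough to detect real miscalibration.

Ties and edges: the region cutoff is a strict inequality (−log10 p
exactly at the cutoff does not seed a region); filter thresholds are
inclusive (AUC exactly 200, lengths exactly 400 or 1000, log₂ fold
exactly 0.8 all pass); window placement clamps to contig bounds;
determinism is guaranteed by seeding `numpy.random.default_rng` once
per generator call and by timestamp-free outputs.

## Known limitations

- The null fit assumes the background dominates: if a majority of sites
  were truly enriched, even the exclude-and-refit loop would
  overestimate σ and lose power.
- Transcript-span (not exon-resolved) assignment can attach an intronic
  region to a transcript, and ambiguous regions are intentionally
  counted multiple times across overlapping transcripts.
- The repeat-window fold inherits a small downward bias from library
  normalization when strong enrichment elsewhere inflates the output
  library total (visible as ~2–5% in the simulations).
- Rescue classification is per-feature Welch with no dispersion
  sharing; with n = 3 it is conservative, and its summary estimator's
  effect-size floor means sub-floor (|Δ| < 1 log₂ unit) dysregulation
  is invisible to the headline rescue fraction.
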
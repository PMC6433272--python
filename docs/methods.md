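# Methods

This note documents the models, numerical choices and open design decisions
behind `pawmeth`, and what the synthetic-data generators do and do not
emulate.

## Study design being modelled

A case-control cohort of dogs: 10 healthy controls and 9 with untreated
multicentric non-Hodgkin lymphoma. Stage 1 measures *global* leukocyte DNA
methylation two ways — %5MeCyt by HPLC-UV of digested DNA, and an
anti-5-methylcytosine immunoreactivity H-score — and compares groups.
Stage 2 profiles a 4+4 age-matched subset on a human 850K methylation
array and tests each CpG for a group difference, mapping hits into the dog
genome (canFam3.1) through homology/orthology.

## Stage 1

### Chromatogram quantification

The trace model used by the simulator, and assumed by the quantifier, is
Gaussian peaks on a linear baseline with IID normal detector noise. This is
the simplest model that exercises every step the quantifier performs
(baseline correction, boundary finding, integration); real chromatograms
add tailing and drift curvature that this model does not produce.

Quantification steps, per sample:

1. **Peak detection** — within each analyte's retention window, the local
   maximum of highest prominence (`scipy.signal.find_peaks`); default
   minimum prominence is 3× the noise estimate. At most one apex per
   window; overlapping windows are rejected.
2. **Noise estimate** — 1.4826·MAD of the first-differenced signal divided
   by √2: differencing suppresses baseline and peak structure, MAD makes
   the estimate robust to the peaks themselves.
3. **Boundaries** — walk outward from the apex on a lightly smoothed trace
   (boxcar, ~2% of the window) until the signal falls to baseline + 3·noise,
   capped at the window edges. Smoothing prevents single downward noise
   excursions on a flank from truncating the peak; the walk stops at the
   first qualifying sample, which resolves ties toward the wider boundary.
4. **Baseline and area** — a straight line anchored on the *provisional
   edge baseline* at the boundary times (anchoring on the flank signal
   itself would systematically clip threshold×width of area), then the
   trapezoidal integral of signal − baseline, floored at 0.
5. **Calibration** — linear `amount = slope·area + intercept`, identity by
   default: the final percentage `100·5MeCyt/(5MeCyt+dC)` is invariant to
   any common scale, so calibration only matters if the two analytes have
   different response factors.

Known bias: the 3·noise boundary rule discards the tail area below the
threshold. At noise ≤ 1% of the (smaller) peak height this costs under ~1%
of that peak's area; the end-to-end recovery test holds mean relative error
of the recovered fraction below 2% in that regime. At noise levels
approaching 10% of a peak's height the truncation becomes material — that
is a property of the boundary rule, not of the integration.

### H-score

`H = Σ_{g=1..3} g · (100·n_g/N)`, range 0–300. Two readings of the verbal
definition exist (average per-field scores vs pool counts; percent of all
cells vs of positive cells). We pool counts across fields — equivalent to a
cell-count-weighted mean of per-field scores (tested as an algebraic
identity) — and take percentages of all graded cells; this is the classic
H-score and the only reading consistent with the observed 181–254 range on
leukocytes that are nearly all positive.

### Statistical battery

- **Normality**: one-sample KS against a normal with estimated mean/SD;
  since parameters are estimated, p-values use the Lilliefors null
  (statsmodels). Constant input is an error, not a p-value.
- **Group comparison**: pooled-variance Student t, two-sided, accepting raw
  vectors or `(n, mean, sd)` summaries (identical to machine precision when
  the summaries describe the raw data). The pooled form is the default
  because it reproduces the published p = 0.027 / 0.015 from the group
  summaries; Welch (which gives ~0.04 for the HPLC contrast owing to the
  2.4× SD ratio) is exposed via `equal_var=False`.
- **Correlations**: Pearson with the t-based two-sided p; Spearman as
  Pearson on mid-ranks (average ranks on ties).
- **Mann-Whitney**: U = min(U₁, U₂). Exact two-sided p by the
  dynamic-programming recurrence for the full U null distribution
  (equivalent to enumerating all C(n₁+n₂, n₁) labelings, used when
  n₁·n₂ ≤ 400 and the data are tie-free; two-sided p = 2·P(U ≤ U_obs) by
  symmetry). Otherwise the tie-corrected normal approximation.
- **Two-factor ANOVA**: additive (no interaction) linear model with Type-II
  sums of squares — appropriate for unbalanced two-factor designs where
  main effects are reported. Age enters as a binary factor, ≤10 vs >10
  years. Aliased designs raise an error naming the confounded factor.
  The originally printed ANOVA p-values depend on per-dog data and an
  unstated SS convention, so they are not asserted anywhere; the
  implementation is validated instead by orthogonal-design identities,
  power and null-uniformity simulations.

### The calibrated reference cohort

Per-dog measurements were never deposited, so `synthdata.reference_cohort`
builds a synthetic 19-dog stand-in whose *group* means and sample SDs equal
the published summary table exactly (affine standardisation of seeded
normal draws) and whose pooled 19-dog Pearson correlation between %5MeCyt
and H-score is exactly 0.50: the H-score component is a rotation
`cos θ·x̃ + sin θ·ẽ` against an orthogonalised residual, with θ solved by
Brent's method so the pooled correlation (within-group association plus the
between-group mean structure) hits the target. Covariates (sex, age,
lymphocyte counts) are plausible draws matching the published demographic
summaries; they carry no calibrated structure.

## Stage 2

### Array simulation

Baseline betas are a three-mode mixture — Beta(2,18), Beta(20,20),
Beta(18,2) with weights 0.45/0.10/0.45 — giving the bimodal-with-shoulder
density that QC inspects. Noise (SD 0.4) and planted group effects (default
|ΔM| 2–3) are injected on the M scale, where array noise is approximately
homoscedastic, then mapped back through the inverse logit2. A fraction of
probes (default 0.35, echoing the ~34.6K/853K cross-species usable subset
at a tractable scale) is detectable in all samples; the rest fail detection
everywhere and their betas pile up near 0.3, as failed hybridisations do.
Detection-p and bead-count contamination can additionally be planted at
given rates in otherwise-good probes. Not emulated: Infinium I/II chemistry
differences, batch/position effects, cell-composition shifts, spatial
artifacts — so passing tests demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
failure modes.

Default problem sizes in tests and the acceptance script (2,000–8,000
probes, 4+4 samples) are chosen so the full suite runs in well under a
minute while keeping Monte-Carlo error small relative to every tolerance
asserted.

### Filtering and subsetting

The removal rule reads the two QC clauses as independent: a probe is
dropped when detection p > 0.05 in ≥ 5% of samples, or bead count < 3 in
≥ 5% of samples (with 8 samples, one bad sample = 12.5% triggers removal).
Each removed probe is logged with its reason. The analysis set is then
restricted to probes detected in *every* sample. "Normalization" between
samples is available (quantile normalization of beta) but OFF by default
and logged when used, since the original processing step is unnamed.

### M-values and moderated testing

`M = log2(β′/(1−β′))` with β clipped to [ε, 1−ε], ε = 1e-6. Per probe,
`logFC` is the difference of group mean M-values (lymphoma − control) and
`s²` the pooled two-group residual variance on d = n₁+n₂−2 df.

Empirical-Bayes moderation follows the scaled-inverse-chi-square
hierarchical model: on z = log s², `e = z − ψ(d/2) + log(d/2)` is an
unbiased estimate of log σ² up to the trigamma variance term, so

- `trigamma(d₀/2) = Var(e) − trigamma(d/2)` (method of moments), solved by
  a monotonically convergent Newton iteration on the trigamma inverse
  (asymptotic branches for arguments beyond [1e−6, 1e7]; round-trip error
  < 1e−8 across the working range);
- `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`;
- if `Var(e) ≤ trigamma(d/2)` the variances are consistent with a single
  σ²: d₀ = ∞ and every posterior variance equals s₀².

Posterior variance `s̃² = (d₀s₀² + d·s²)/(d₀+d)` always lies between s²
and s₀²; the moderated t uses d₀+d df (normal in the d₀ = ∞ limit).
The implementation is verified against limma's `eBayes` on the same M
matrix to ~1e−8 in a cross-check test, and calibrated under the null
(type-I rate 0.05 ± 0.02; p-values uniform).

MVPs are probes below the p threshold (default 0.05, the study's choice;
BH-adjusted p is reported alongside but not used for the default call, as
the original analysis thresholds raw p). Direction: hyper = logFC > 0 =
more methylated in lymphoma. The published per-probe logFC values are
typographically corrupted in the source table and are not used anywhere.

### Gene mapping and census

A gene survives mapping iff its ortholog-table row has both flags true.
Gene direction is the direction of its minimum-p probe — the original
aggregation rule is unstated, so this is a package decision; ties break by
larger |logFC|, then lexicographic probe id, making the census
deterministic. Mapped + unmapped genes always partition the input.

### Enrichment

Plain hypergeometric upper-tail over-representation with BH adjustment,
not a GO-graph-aware algorithm (topGO's elim/weight decorrelation is
deliberately out of scope: no algorithm parameters were published, and the
exact test is reproducible). The universe is the set of mapped genes on
the retained probe set — an array-aware background guarding against
composition bias. Set members outside the universe are ignored. For
universes ≤ 20 genes the closed-form tail is tested against brute-force
enumeration of all foreground draws.

## Degenerate inputs and tie-breaks (summary)

- Both analyte amounts zero → explicit undefined-ratio error; a genuinely
  unmethylated sample (no 5MeCyt peak) yields 0%, a missing dC peak is an
  error naming the analyte.
- Zero graded cells → error; H-score is scale-invariant and monotone under
  grade promotion (property-tested).
- Constant vectors → errors in normality/correlation tests rather than
  NaN p-values.
- Empty retained probe set, all-flagged QC, <2 samples per group → errors
  that abort the stage with a named reason.
- MDS sign convention: each coordinate's largest-|loading| sample is made
  positive, so embeddings are reproducible across runs.

## Known limitations

- The chromatogram model omits peak tailing and nonlinear drift; windows
  and calibration for real instruments must be supplied by the user.
- Stage-2 simulations are scaled down (10⁴ rather than 8.5×10⁵ probes);
  all rates and calibrations are size-free, but absolute counts from the
  original study (34,574 common probes; 8,433 variable regions; 748→525
  genes) parameterise the simulators rather than being reproduced.
- The exact Mann-Whitney requires tie-free data; ties fall back to the
  corrected normal approximation.
- No multiple-testing correction is applied across the Stage-1 battery,
  matching the original analysis.
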
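# Methods notes

This note records the models, defaults and numerical choices behind
`epiage`, and what the synthetic data do and do not establish.

## Synthetic cohort generator

The generator emulates pooled whole-blood methylation array data as a
sample × CpG beta matrix with annotations (age, sex, study label,
tissue). Its structural assumptions:

* **Age trends.** Each informative CpG's mean beta is a deterministic
  function of age — polynomial (degree ≤ 3) or a clamped logistic — with
  both directions represented. The default candidate set has 45 CpGs: 16
  informative (ids and trend directions follow the published 16-marker
  aging signature; e.g. the CSNK1D, SSRP1, FXN and P2RXL1 sites lose
  methylation with age while the FZD9, KLF14, VGF and NHLRC1 sites gain
  it) and 29 null CpGs, one of which has a large variance but no trend to
  model the "wide range, no age signal" behaviour real panels contain.
  The coefficient values themselves are package fixtures, not published
  estimates: ranges span roughly 0.15–0.70 beta units over ages 2–90 with
  mixed curvature. Trends are validated to stay inside [0, 1] without
  clamping over the cohort's age range, so clamping never distorts the
  noiseless signal.
* **Noise.** Additive Gaussian on the beta scale, truncated to [0, 1];
  default SD 0.035 per informative CpG (a logit-normal mode is available
  for heteroscedastic behaviour near the boundaries). This makes each
  marker individually worth ≈ σ·(Δage/Δbeta) ≈ 6–15 years of age
  resolution, so a multi-marker model lands in the few-years MAE regime
  that array clocks actually occupy.
* **Ages** are drawn stratified-uniform per decade (2–90), ≈ 128 samples
  per decade at n=1156, mirroring a pooling design that balances age
  groups.
* **Batch structure.** Seven study labels with additive constant offsets
  in ±0.05 applied after noise. Because offsets are constant within a
  study, a per-CpG mean shift removes them exactly; this is the
  assumption under which the cross-dataset normalization is correct.
* **Sex** is generated but never enters any mean — a true null covariate
  for calibrating the covariate association test.
* **Twins** share one age and one pair-level deviation per CpG; only the
  individual deviation (default SD 0.01) separates the members, so
  within-pair prediction differences isolate the individual term.
* **Disease cohorts** add per-sample Gaussian shifts at a chosen CpG
  subset; "blood-related" is a label — severity is the shift SD, which
  callers set larger for blood-related conditions.

What passing tests on this generator show: that the statistical machinery
(screening, selection, kernel regression, calibration, sequencing
round-trip) is correct under its own assumptions, at realistic effect and
noise scales. What they do not show: performance on real arrays —
the generator has no probe chemistry, no detection p-values, no
cell-composition variation, no ethnicity structure, and its batch effects
are exactly the constant-offset kind the normalization removes. Absolute
errors on synthetic cohorts (MAE ≈ 2–3 yr) are therefore better than real
clocks achieve and should be read as internal-consistency numbers only.

## Marker funnel

* Screening is per-CpG ordinary least squares of beta on age; raw p < 0.05
  defines "age-associated" (no multiplicity correction by default, with a
  Benjamini–Hochberg option), and constant CpGs are flagged degenerate.
* Forward stepwise selection adds, at each step, the candidate with the
  smallest partial-F p-value, computed incrementally via an orthonormal
  basis of the current design (numerically stable and O(n·p) per step).
  Entry requires the winning p-value, **Bonferroni-adjusted by the number
  of candidates examined at that step**, to stay below α = 0.05, and the
  R² gain to reach 1e-4. The adjustment matters: the best of k null
  candidates has a selection-biased p-value, and an unadjusted rule lets
  a noise CpG in ~40% of the time with 10 null candidates, where the
  adjusted rule keeps null selections below ~5%. Ties break on candidate
  id, which also makes the result invariant to column order.
* R² is reported as the squared Pearson correlation of fitted vs true
  age. VIFs are computed directly (1/(1−R²) of each input on the rest),
  capped at 1e6 with a flag for exact collinearity.

## GRNN

* Inputs are standardized to zero mean/unit SD over the training
  exemplars before Euclidean distances: beta ranges differ several-fold
  across CpGs and an unstandardized kernel would be dominated by the
  widest markers. Prediction uses a log-sum-exp-stabilised kernel
  average; σ → 0 degrades gracefully to the nearest exemplar and σ → ∞
  to the training mean, and every prediction lies in [min age, max age].
* σ is tuned by golden-section search on log σ over [0.01, 10]
  (standardized units) against verification MAE, ~25 evaluations;
  optima at the bracket edge raise a warning. A per-input σ vector is
  supported but off by default.
* Splits follow the rounding convention train = round(p·n),
  verify = round(p·n), blind = remainder, which reproduces the canonical
  694/231/231 partition of 1156 at 60:20:20. Training proportions are
  restricted to [0.5, 0.7].
* The staged protocol: stage 1 scores each candidate proportion by mean
  blind MAE over repeated random splits (default 3 proportions × small
  repeat counts — the structure of the published protocol at desk scale);
  stage 2 re-samples train/verify with the blind cases frozen; stage 3
  builds k = 10 replicates on the frozen blind set and reports per-subset
  error mean ± SD as the reproducibility measure.
* Sensitivity ratios are MAE-with-input-removed / MAE-with-all-inputs on
  the blind set (ratio > 1 ⇒ the input contributes), with the reduced
  model re-standardised over the remaining inputs and ranked by mean
  ratio across replicates. On the default cohort the weakest informative
  input sits just below 1 and null inputs sit at 0.96–0.98 — removing a
  pure-noise dimension slightly *helps* a kernel model, which is the
  expected sign.
* The input subset search (greedy forward growth, then random
  add/drop/swap moves, all scored by verification MAE under an explicit
  evaluation budget) saturates near 12 of the 16 informative inputs on
  the default cohort: beyond that, extra weakly-informative correlated
  inputs dilute the standardized distances more than they add signal.
  This is a property of verification-optimal kernel regression, not a
  search failure; the search reliably excludes noise inputs.
* Collinear inputs are kept (with VIF warnings) rather than dropped —
  removing either member of a correlated pair worsens predictions.

## Amplicon panel and sequencing

* The packaged panel carries the published 16 primer pairs, amplicon
  lengths, annealing temperatures and GRCh37 target coordinates. The
  amplicon **reference sequences are synthetic**: constructed genomic
  regions that honour the primers, the printed product lengths, and
  design rules (primers free of CpGs; 2–4 CpG sites and ~8 non-CpG
  cytosine conversion controls per amplicon interior). In-silico
  bisulfite PCR derives each reference at load time, so the panel file
  is itself a regression test of the PCR predictor.
* In-silico PCR converts both strands (non-CpG C→T; CpG C→Y, matching C
  or T, so methylation state can never alter primer binding), searches
  the forward primer and the reverse-complement of the reverse primer,
  and returns the unique product; multiple compatible sites raise an
  explicit multi-hit error.
* Read simulation draws per-fragment CpG methylation Bernoulli(β),
  converts unmethylated CpG and all control cytosines with the given
  conversion rate, applies substitution errors per mate, and reports
  both 150-bp mates. Assignment deduplicates identical read sequences,
  sends error-free reads through anchored exact matching (CpG/control
  positions accept C or T) and everything else through semi-global
  edit-distance alignment (edlib) against Y-marked references; ties and
  sub-90%-identity reads land in an unassigned bin.
* Calling counts C/T per interrogated offset; overlapping mate bases are
  counted once with mate 1 winning (the convention is configurable in
  principle but fixed here and flagged, since either choice changes
  counts by at most the overlap). N/other bases are tallied separately;
  coverage = C+T, and the coverage filter defaults to ≥ 1000 reads.
* The conversion rate is pooled T/(C+T) over a marker's control offsets
  (a per-fragment mean is available behind a flag); correction inverts
  the conversion process, β = (β_raw − (1−c))/c, clamped to [0, 1], and
  refuses rates ≤ 0.5 as assay failure.
* The validation loop averages corrected target-CpG betas over the
  replicates that pass coverage (a marker failing in every replicate
  refuses prediction by default), applies standard curves, then the same
  mean-shift harmonisation used between arrays, treating the sequencing
  batch as one more dataset. Mean-shift harmonisation assumes the batch
  is demographically comparable to the reference cohort; a small or
  age-skewed batch makes the estimated shift itself a bias (visible in
  `examples/05`), which is why validation batches should span the age
  range.

## Calibration

* Cross-dataset normalization: per CpG, shift each dataset by
  (grand mean − dataset mean); variance and within-study age slopes are
  untouched, the transform is idempotent, and clamping events are
  counted in the report. A global single-shift mode exists because the
  right granularity is ambiguous in general; the mode used is recorded
  in run manifests.
* Standard curves fit observed = poly(known) by least squares; with no
  degree given, linear is kept unless a cubic improves residual SD by
  more than 20% and stays monotone (checked on a 0.001 grid). Inversion
  is by bisection to 1e-6 with clamping outside the curve's range;
  non-monotone fits fall back to linear.

## Problem sizes and determinism

Tests and the acceptance script run the cohort analyses at the study's
sample sizes (n = 1156; 53 twin pairs; 265 saliva-like samples; 46
sequencing donors in triplicate) and scale only the sequencing depth
(2000 fragments/marker/replicate in the validation loop, 50,000 for the
depth-convergence check — the ≥1000-read coverage rule is always active).
Every stochastic component draws from an explicit seed; pipeline runs
write a manifest (config, seeds, version, input hash) sufficient to
reproduce deterministic stages bit-identically.

## Known limitations

* Synthetic-only validation; no real array or FASTQ data ships with the
  package (see the generator caveats above).
* Alignment is substitution-only at panel scale; indel-containing reads
  are handled by edlib's alignment but the simulator never produces
  them, and genome-wide alignment is out of scope.
* The GRNN stores all exemplars; prediction is O(n_train · p) per query,
  fine at thousands of cases, unsuitable for 450K-scale input sets.
* Mean-shift is the only cross-platform harmonisation implemented —
  no quantile or beta-mixture normalization.
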
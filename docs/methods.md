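# Methods

This note records the models, conventions and numerical choices behind
`laterotrace`, in the spirit of a package's own methods documentation. It
states no empirical result that the test suite does not itself compute.

## Response magnitudes

Both measures are two-window RMS differences on trial-aligned voltage
traces (volts, seconds):

- control window: `[onset − 0.5 s, onset)`;
- stimulus window: `[onset, onset + duration + 0.1 s)`.

**Discretization.** Windows are half-open on the sample grid,
`[floor(start·fs), floor(end·fs))`, so the onset sample belongs to the
stimulus window only and adjacent windows never share a sample. A 1e-9
epsilon guards `floor` against float representation of exact products.

**ARM** is computed per presentation; **eARM** averages the first
`min(25, available)` presentations of a stimulus sample-wise and then takes
the RMS difference on the averaged waveform. On noiseless input the two
orders coincide; on noisy input they do not, because per-trial RMS
rectifies noise that waveform averaging cancels. The traces are assumed
already band-limited by the acquisition chain; no rectification or
re-filtering is applied before the RMS.

## Adaptation rate and site filter

Per site and stimulus, `AdR = slope / mean`, where `slope` is the OLS slope
of ARM on presentation index over presentations 6–25 inclusive (20 points)
and `mean` is the mean ARM over the same presentations. AdR is
dimensionless and invariant to rescaling all ARMs. Groups with missing
presentations, or with non-positive mean ARM (non-responsive site, the
normalization is meaningless), are flagged `defined = False` and never
imputed.

The inclusion filter keeps a site iff its aggregated AdR is **strictly**
below −0.05. Aggregation across stimuli defaults to the mean of defined
AdRs; `median` and `any` (keep if any stimulus qualifies) are selectable.
Whether published analyses filtered per stimulus or per site is not
specifiable from the protocol alone; the per-site mean is the documented
default.

## Lateralization index

`LI = (R − L) / ((R + L)/2)`, with R and L hemisphere means of per-channel
magnitudes, where per-stimulus values are averaged within channel first
(equal stimulus weighting regardless of trial counts). The "absolute
difference" sometimes used to describe the numerator is implemented as the
signed difference: the sign carries the direction of the bias (negative =
left). For epidural arrays, hemisphere averaging uses all four pins per
side by default, with a caudal-only option since the caudal pins overlie
the auditory lobule.

Baseline correction subtracts, per subject, the mean LI over that subject's
silent-baseline sessions (day < 0) from every LI. Exposure days bin as
`[3⌊d/3⌋, 3⌊d/3⌋+2]`, producing the labels 0–2 … 18–20 over a 21-day
exposure; baseline days are labelled `baseline`. Day 0 is exposure onset.

**Estimator bias under noise.** eARM subtracts the baseline-window RMS — a
noise-floor estimate that is common to both hemispheres. Subtracting a
common positive quantity from R and L increases |LI|, so with residual
averaged-waveform noise σ̄ the recovered LI is biased away from zero by a
term of order σ̄/S (S the evoked RMS). The acceptance test for noisy
recovery therefore compares the Monte-Carlo mean against the closed-form
estimator expectation `E[eARM] ≈ sqrt(S² + σ̄²) − σ̄` with σ̄ = σ_b/√25,
rather than against the noiseless value; at the simulated noise level
(σ_b = 0.3·S, 25 trials averaged) the bias is ≈ +0.013 LI units.

## Synthetic data

The generator states a world; its defaults are the emulated design, not
tuning knobs.

- **Depth sessions**: 10 song stimuli × 25 shuffled presentations, 8
  channels per hemisphere, 8 s ISI. Each trial is i.i.d. Gaussian noise of
  RMS σ_b plus, in the stimulus window, a frozen per-stimulus unit-RMS
  noise token scaled to `A · h(c) · (1 − k)^(t−1)` for presentation t —
  geometric decay chosen because it yields an approximately linear ARM
  decline over presentations 6–25 for small k, matching the linear
  regression estimator (for k ≤ 0.05 the recovered AdR is within 1 % of
  −k). `h(c)` is the condition/day gain ratio g on right-hemisphere
  channels and 1 on the left. A configurable fraction of channels gets
  k = 0 (primary-field-like, to exercise the filter).
- **Epidural sessions**: 3 call stimuli × 100 presentations, 5 s ISI, 8
  pins in left/right × caudal/rostral quadrants (2 each); the trial
  waveform is a deterministic damped 20 Hz oscillation confined to the
  stimulus window and normalized to unit RMS (the analysis must not depend
  on template shape), scaled by `A · h(c)` with caudal pins carrying twice
  the rostral gain; independent Gaussian noise per trial.
- **Gain profiles**: Con-Env g = 1.3 on days 0–20; Het-Env g = 1.0 on days
  0–5, 0.7 on days 6–14 (reversal), 1.4 on days 15–20 (return); Silence
  g = 1 throughout; all baseline days (day < 0) have g = 1. The reversal
  and return magnitudes are chosen to give |LI| ≈ 0.3–0.4, the scale on
  which lateralized responses are typically discussed.
- **Operant logs**: P(correct) on day d follows
  `asymptote − (asymptote − p0)·exp(−rate·d)` with defaults p0 = 0.5,
  asymptote = 0.95, rate = 0.12 — a learner crossing 80 % around days
  9–12, consistent with reported times-to-criterion near 11 days; 100
  trials/day is a realistic operant throughput. Go/NoGo types are exactly
  25/25 balanced within each 50-trial block (the 50/50 probability is
  stated per block, and exact balance makes block performance
  well-defined); an i.i.d. mode exists behind a flag.
- **Seeds**: all randomness flows from one master seed through
  `numpy.random.SeedSequence([seed, modality_tag, day + 4096, …])`, so any
  session regenerates independently and bit-identically. Sample rates and
  trial counts in tests and the demo pipeline are scaled down (2 kHz,
  fewer subjects) to keep runtimes in seconds; analysis constants are
  never scaled.

What a green test does **not** establish: the generator's noise is i.i.d.
Gaussian and its evoked tokens are stationary, so the tests say nothing
about robustness to movement artifacts, line noise, non-stationary
backgrounds, or real spike statistics; hemisphere gain is a pure
multiplicative ratio, so additive offsets between hemispheres are not
modeled.

## Behavior scoring

Blocks are defined purely by trial count (50), may span days, and a
trailing partial block is flagged and excluded from criterion logic.
Criterion: first two consecutive full blocks with p ≥ 0.8, within the
first 21 training days; `day_reached` is the day containing the pair's
last trial; final performance is the proportion correct over **all** of
that day's trials. Days-to-criterion counts days 1-based.

## Statistics

- Factorial ANOVA: statsmodels OLS with sum-to-zero factor coding and
  Type III sums of squares (Type II by flag) — robust to unbalanced cell
  counts; rank-deficient designs raise with the aliasing named.
- Post-hoc: two-sided pooled-variance independent t-tests per pair;
  Bonferroni `p_adj = min(1, p·m)`. A published analysis may instead have
  used the omnibus pooled error term (t with larger df); the independent
  form uses only the two cells' own data and is the default here.
- Repeated-measures ANCOVA: split-plot decomposition for a two-level
  within-unit factor. Between-unit effects and the covariate are tested by
  OLS on per-unit means across the two levels; the within main effect and
  within × between interactions by OLS on per-unit differences (the
  intercept of the difference model is the within main effect). This is
  exact for two within levels; more levels are rejected rather than
  approximated. Units missing a level are dropped and the count reported.
  If all differences are exactly zero the within stratum is degenerate
  (0/0); it is reported as F = 0, p = 1 with a note.
- Kruskal–Wallis with tie correction and chi-square p value; all-identical
  input returns H = 0, p = 1 by convention. In calibration tests the null
  groups have n = 15 because the chi-square approximation's exact size
  there is 0.0502 (rank discreteness inflates it at smaller n).
- Alpha is 0.05 throughout.

## Pipeline and reproducibility

`run_pipeline` executes simulate → metrics → adaptation → lateralization →
behavior → stats, writes every table as CSV with stable column order, and
emits `manifest.json` containing the seed, a config hash and SHA-256
checksums of every output. Re-running the same config and seed is
byte-identical; each stage logs rows in/out and exclusions so the site
accounting is auditable from logs alone. Stage failures halt with the
stage name. CSV events use 0-based trial indices and seconds.

## Known limitations

- The ERP eARM bias under noise (above) is inherent to baseline-RMS
  subtraction; comparisons across conditions at equal noise levels are
  unaffected to first order, but absolute LI values from noisy data are
  slightly inflated.
- No automated outlier/subject exclusion: any exclusion must be explicit
  user input.
- The repeated-measures engine handles exactly one two-level within
  factor; it does not generalize to multi-level sphericity-corrected
  designs or mixed-effects models.
- Modulation power spectra, tuning curves, spike sorting and vendor
  acquisition formats are out of scope (a Spike2 importer would plug in at
  `laterotrace.io.read_session`).
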
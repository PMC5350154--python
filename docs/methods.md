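# Methods notes

This note documents the models, numerical choices and known limitations of
`betachoice`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Observer model

Choices in the flutter-comparison task are modelled in log-frequency space.
The memory of the first frequency combines a Gaussian sensory likelihood
(sd `sigma_like`) with a Gaussian prior (sd `sigma_prior`) centred on
`prior_mean`; the posterior mean

    log f1' = w log f1 + (1 - w) prior_mean,   w = sigma_prior^2 / (sigma_prior^2 + sigma_like^2)

is the contracted estimate entering the comparison. The decision variable
is SPFD = log f2 − log f1' plus an additive response bias `bias`, passed
through a probit link with comparison noise `sigma_d = sqrt(2) * sigma_like`
— both stimulus representations are assumed to carry the same sensory
noise, which keeps the model at exactly three free parameters. An
alternative with free `sigma_d` would trade identifiability of
(`sigma_like`, `sigma_prior`) for flexibility; it is available for the null
model only, where the decision variable is the physical difference
log f2 − log f1 and the free parameters are (`sigma_d`, `bias`).

*Prior centre.* "Centred over all presented frequencies" admits two
readings: the mean log frequency over all f1 and f2 values of the 16-pair
set (default, 21.4 Hz) or over the four f1 values only (21.8 Hz). Both are
selectable via `stimulus_prior_mean(which=...)`; the difference is well
under the resolution of the fits.

*Fitting.* The likelihood aggregates trials by stimulus pair (binomial
sufficient statistics), with probabilities clipped at 1e-9. Optimisation is
bounded L-BFGS-B from 10 seeded start points (sigmas drawn log-uniformly in
[1e-3, 10], bias uniformly in [−2, 2]); fits at a bound are flagged, which
is how degenerate data (e.g. all-identical choices) surface. Bayes factors
use the BIC approximation `BF = exp((BIC_null − BIC_spfd)/2)`; this is an
approximation to a complexity-corrected marginal-likelihood ratio, and only
its threshold behaviour (decisive evidence at BF > 20) is relied upon.

*SPFD levels.* Default bin edges are (−0.18, −0.09, 0, 0.09, 0.17) in
log-frequency units, six bins partitioning the line, edge values falling in
the lower bin. With the default observer all 16 stimulus pairs spread over
all six levels.

## Synthetic data

The generator is first-class, tested code; its defaults define the study
conditions the rest of the package is validated against.

* **Design**: f1 ∈ {16, 20, 24, 28} Hz, f2 = f1 ± 2 or ± 4 Hz (16 pairs,
  f2 spanning 12–32 Hz); 7 blocks × 160 trials = 1120 trials per session.
  Pair counts are balanced per session (remainders drawn without
  replacement) so the per-sign f2 means of 25 and 19 Hz hold exactly in
  every dataset, not just in expectation. Whether the original task
  balanced f1 counts or drew them fully at random is not determinable from
  the task description; balancing is this package's choice and makes the
  stimulus-set arithmetic deterministic.
* **Observer defaults** (`sigma_like = 0.145`, `sigma_prior = 0.26`,
  `bias = 0.02`): chosen by forward-computing the model's per-condition
  accuracies so that a simulated cohort reproduces the canonical behavioural
  pattern of this task family — ≈74% correct overall, 4 Hz pairs ≈81% vs
  2 Hz pairs ≈67%, positive differences judged a few points better than
  negative ones, and a modest criterion shift toward "f2 > f1".
* **Response times**: shifted lognormal, `rt = location * exp(sigma Z −
  sigma²/2)` with `location = base_ms (600) + choice_shift_ms (−50)` for
  "f2 > f1" choices. The negative shift makes the preferred choice faster
  for correct and incorrect trials alike (the RT crossover), and — because
  the median split then enriches fast trials with "f2 > f1" choices — the
  fast/slow criterion dissociation emerges without further assumptions. A
  drift-diffusion account would couple RT and accuracy mechanistically; it
  is deliberately not imposed.
* **EEG**: epochs span −2500 to 1000 ms around saccade onset at 512 Hz
  (tests and the acceptance run use 256 Hz, which still resolves the 4–48 Hz
  analysis range). Components: (i) 1/f background noise (exponent 1,
  broadband RMS 10 µV) per channel and trial; (ii) an SSEP sinusoid at the
  trial's f2 (RMS `ssep_gain` = 3 µV) during the f2 interval
  [−rt, −rt + 250 ms] in channels contralateral to the stimulated left
  index finger (C4, CP4) — placed via each trial's RT so the
  stimulus-frequency confound survives response locking; (iii) a 24–32 Hz
  band-limited noise component in FC2/FC4 with a flat envelope over −750 to
  −450 ms (100 ms cosine ramps), RMS 1.5 µV plus 1.0 µV extra for
  "f2 > f1" choices regardless of correctness. Effect amplitudes were fixed
  a priori by requiring that an independent bandpass-plus-Hilbert envelope
  oracle recovers the injected difference at the single-subject level.
* **Saccade detector**: smoothed-derivative threshold with sustain
  duration; the defaults (10 ms smoothing, 10 ms sustain, robust
  10-MAD threshold) are package choices — the underlying task description
  specifies none.

What the generator does **not** emulate: volume conduction and realistic
topographies, eye blinks and other artefacts, non-stationary background
spectra, between-subject variability in effect latency or channels.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed signal model, not robustness to every property
of recorded EEG.

## Time–frequency analysis

Preprocessing re-references to the common average and applies a zero-phase
(forward–backward) Butterworth band-pass, 0.5–48 Hz, order 6 per pass. The
Morlet wavelet at frequency f spans exactly `n_cycles / f` seconds
(7 cycles: 700 ms at 10 Hz, 350 ms at 20 Hz) with a Gaussian envelope of
sigma = support/6, i.e. the support truncates at ±3 sigma. Wavelets are
normalised to unit total energy so that white noise yields a flat amplitude
profile across frequencies; amplitude is the square root of power, computed
once, before smoothing, at every 50 ms × 1 Hz bin. Bins whose wavelet
support exceeds the epoch are marked invalid (NaN) and excluded from all
statistics rather than zero-padded — this removes edge artefacts at the
cost of a frequency-dependent loss of bins at the epoch boundaries.
Smoothing is a separable Gaussian with 3 Hz × 300 ms FWHM, kernel of unit
sum, renormalised over valid bins at edges so constant maps are preserved.
Single-trial maps are stored as float32; the per-bin statistics are far
above float32 resolution.

## Cluster statistics

Per subject, cell-mean maps over the 2×2 (stimulus sign × correctness)
design are combined with preset contrast vectors (interaction [−1 1 1 −1],
correct-only [−1 1 0 0], incorrect-only [0 0 1 −1]); the interaction equals
"chose f2>f1 minus chose f2<f1" pooled over correctness. Group inference:

* one-sample t per bin, df = n − 1; bins invalid for any subject are
  excluded listwise;
* cluster-defining threshold: |t| above the two-sided t quantile at
  `threshold_p` (0.001 for the main analysis, 0.01 for the conjunction);
* adjacency: ±1 bin in frequency or time within a channel (no TF
  diagonals), plus neighbouring channels at the same TF bin. Channel
  neighbourhoods come from a schematic 2-D template of the 64-channel
  extended 10-20 layout with a distance cutoff giving a median of ~6
  neighbours; individually digitised positions are not meaningful for
  synthetic data. Whether the original analysis included diagonal
  adjacency is unknowable from the description; the definition here is
  explicit and configurable via the `Adjacency` object;
* cluster statistic: mass (sum of t), the field-standard default;
* null distribution: maximum |cluster mass| over both sign families per
  permutation, 500 whole-image subject sign flips;
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)` so p is never zero. Pooling
  both families into one max-statistic controls the two-sided family-wise
  error at alpha (verified by the calibration test: empirical FWE ≈ 0.05 on
  null data).

The conjunction runs the same procedure separately for correct-only and
incorrect-only contrasts, restricted to (and corrected over) the channels
identified by the interaction analysis, and reports per-class clusters,
their bin-level overlap, and the element-wise minimum of the two t maps
(minimum-statistic test of the conjunction null). The mapping-split control
uses a label-permutation two-sample cluster test with pooled-variance t.

## Problem sizes

Full sessions (1120 trials) are used wherever only behaviour is involved.
EEG cohorts in tests and the acceptance script use 22 subjects × 160 trials
× 20 channels at 256 Hz — the channel subset covers the effect sites
(FC2/FC4), the SSEP sites (C4/CP4) and distant controls; cluster-test
calibration uses the reduced 8 × 20 × 40 grid with 22 subjects, 500
permutations and 200 replicate datasets. These sizes are the package's
validation conditions; the code itself is agnostic to grid and cohort size.

## Known limitations

* Per-subject maximum likelihood only; no hierarchical pooling.
* The BIC Bayes factor is an approximation; absolute BF magnitudes should
  not be over-interpreted, only the threshold behaviour.
* No source reconstruction, TFCE, or parametric random-field correction.
* The artifact-rejection stand-in is a simple peak-to-peak threshold
  (visual inspection is not reproducible); synthetic data contain no
  artefacts, so it is exercised only at the API level.
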
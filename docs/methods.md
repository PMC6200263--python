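# Methods

`siprobe` analyses attention to the auditory stream during simultaneous
interpreting (SI). The premise: an interpreter buffers the source speech in
working memory (WM) until it has been translated overtly; the size of that
buffer — the ear-voice span, or décalage — indexes the memory effort, and
the early auditory ERP components (P1, N1) evoked by task-irrelevant probe
tones index how much attention remains for listening. The package estimates
the WM-load time course from time-coded transcripts, reads it off at probe
onsets, and tests whether probe-locked P1/N1 amplitudes and latencies vary
with load and interpreting direction.

## WM-load model

A counted source word enters the WM buffer at its own offset and leaves at
the *clear time* of its aligned translation chunk: the offset of the last
target word sharing its alignment id. This is the only observable proxy for
clearing; self-monitoring (a word lingering after overt translation) and
anticipation (a translation preceding the source offset) are real phenomena
that make the estimate noisy, and are deliberately not modelled. Source
words that are never translated have no observable clear time; they are
excluded from the series and counted in `LoadSeries.n_omitted`.

Three weighting schemes:

* **CW** — each buffered content word adds 1;
* **CL** — each buffered content word adds its min-max normalized
  log corpus frequency,
  `f̂ = (log f − log F_min) / (log F_max − log F_min) ∈ [0, 1]`,
  where `F_min`/`F_max` are the least/most frequent words of the reference
  corpus. As written, a *more* frequent word adds *more* load; the
  surrounding psycholinguistic rationale (frequent words clear faster)
  points the other way, so `invert_cl_weight=True` substitutes `1 − f̂`.
  The literal form is the default. Out-of-vocabulary lemmas get `F_min`
  (maximum unfamiliarity) with a logged warning. Because `f̂ ≤ 1`, CL is
  bounded above by CW pointwise.
* **SYL** — every word (content and function) adds its syllable count,
  reflecting the roughly 2-s capacity of the phonological loop.

Which words each scheme counts is itself ambiguous in the source
descriptions; the default (`word_scope="methods"`) counts content words for
CL and all words for SYL, and `word_scope="fig2"` swaps the two scopes.

Function words — articles, prepositions, auxiliary verbs and "and" for
English; prepositions and "и" for Russian — are assumed to cost negligible
memory. The categories are shipped as explicit closed lists
(`siprobe/data/function_words_*.txt`, user-overridable): reproducibility
requires a concrete list, not a grammatical category. Tokens are lowercased
and stripped of non-letter edge characters before lookup. Hyphenated and
numeral-bearing tokens classify as content words with heuristic syllable
counts. The English syllable counter is a vowel-group heuristic with a
single silent-e rule (exact for the generator's pseudo-words; swap in a
dictionary-based counter for corpus work); the Russian counter — one
syllable per vowel letter — is exact for Russian orthography.

The load series is stored as event breakpoints `(time, load-after-event)`,
coalescing simultaneous events into one breakpoint at the net load and
anchoring the session start at `(0, 0)`. Two evaluations are exposed:
`step_at` returns the exact piecewise-constant buffer content (load `v_i`
on `[t_i, t_{i+1})`), and `interpolate` linearly interpolates between
breakpoints — the estimator used at probe onsets, which generally fall
between word offsets. Both are clamped outside the breakpoint range.

Probe epochs are labelled *low* / *medium* / *high* by strict comparison
against the 10th and 90th linear-interpolation sample quantiles of the load
distribution, computed separately for each subject × direction (the
distributions differ strongly across both). A constant distribution labels
everything medium. The asymmetric 10/80/10 split trades statistical power
in the tails for sensitivity to excursions outside the interpreter's
"comfort zone"; `LabelingScheme` exposes both probabilities.

## ERP chain

Continuous EEG (µV throughout) is resampled to 250 Hz, re-referenced to the
averaged mastoids (TP9/TP10), and bandpassed 0.1–30 Hz with a zero-phase
windowed-sinc FIR (MNE's firwin/Hamming design with its default transition
bandwidths; the rolloff is a consequence of the design, not a parameter).
Epochs are cut on the half-open window [−100, 400) ms around probe onset —
exactly 125 samples at 250 Hz — and baseline-corrected by the mean over
[−100, 0) per channel. A config switch to a 600-ms reading
(`tmax=0.5`) exists for the alternative epoch-length convention. Gross
artifacts are handled by an optional peak-to-peak rejection threshold
(default 150 µV); ICA and artifact-subspace reconstruction are out of
scope because the simulator generates artifact-light data.

Condition averages are arithmetic means across trials; grand averages
weight subjects equally (mean of subject means). Component measures:
window-mean amplitude over 40–80 ms (P1) and 120–160 ms (N1), samples
inclusive at both edges; peak latency as the window argmax (P1) or argmin
(N1) with ties resolved to the earliest sample and a warning on flat
windows. Analyses use the fixed 21-electrode fronto-centro-parietal subset,
with a default Anteriority (Front/Center/Back) × Laterality
(Left/Middle/Right) partition of 7/7/7 and 9/3/9 channels; the map is a
package default (user-overridable YAML), since any such partition is a
convention.

EEG interchange: BrainVision (text header/markers + IEEE float32 data,
reader and writer) and EDF (reader). Probe events travel as BIDS-style TSV
(`onset`, `duration`, `trial_type`).

## Statistics

**Wilcoxon signed-rank.** `V` is the sum of mid-ranks of positive
differences after dropping zeros. For `n ≤ 25` the two-sided p-value is
exact: the 2^n sign-assignment null is enumerated by convolving doubled
ranks (mid-ranks are half-integers, so doubling makes them exact integer
weights), and `p = min(1, 2·min(P(V ≤ v), P(V ≥ v)))`. Ties therefore do
not force an approximation at small n. Above `n = 25` the tie-corrected
normal approximation is used with a warning. Two benchmark results follow
directly from the enumeration at n = 9: all-positive differences give
V = 45, p = 2/512 = 0.003906, and positive differences carrying the three
smallest ranks give V = 6, p = 28/512 = 0.05469.

**Repeated-measures ANOVA.** Any number of fully-crossed within-subject
factors on a balanced design. Each effect is projected onto orthonormal
Helmert contrasts (Kronecker products across factors, with mean vectors for
factors outside the effect); the effect sum of squares is `n·Σ t̄²` over
contrast columns and the error term is the effect-by-subject interaction
`Σ (t − t̄)²`. Sphericity is never assumed: the Greenhouse–Geisser epsilon
`ε = tr(Σ)² / (q·tr(Σ²))` is estimated from the covariance of the contrast
scores, clipped to `[1/q, 1]`, and corrected dfs and p-values are reported
next to the uncorrected ones, together with partial eta squared
`SS_effect / (SS_effect + SS_error)`. Missing subject cells are imputed by
the cell mean over the remaining subjects with a warning; a cell empty for
every subject is an error; fewer than 3 subjects is an error. Constant
data reports F = 0 (a rounding floor of `1e−12·‖X‖²` prevents 0/0).
Mauchly's test and mixed-model alternatives are out of scope. No
multiple-testing correction is applied across the three load estimators,
matching common practice for these parallel descriptive analyses; treat the
three methods' p-values as one family if that matters for your use.

**Jackknife.** Leave-one-subject-out resampling of any analysis callable;
failures on individual resamples are recorded, not fatal, and a failed
resample counts against the all-resamples consistency verdict.

**Group pipeline.** The 4-way ANOVA (Direction × Load × Anteriority ×
Laterality) takes per-cell amplitudes formed by averaging channel
window-means within each topographic cell. The direction analysis feeds
per-subject median probe-onset loads (both directions required; incomplete
subjects are dropped with a warning) into the exact Wilcoxon test.

## Synthetic data generator

The generator emulates the structure of a probe-tone SI session; its
defaults are the study conditions under which the package is validated.

* **Source stream**: exactly 105 words/min in fixed word slots (spoken
  fraction 0.85 of each slot), content-word fraction 0.62. Content lemmas
  are CV pseudo-words of 1–4 syllables (the English inventory excludes
  "e"/"y" so the syllable heuristic is exact) drawn from a 4,000-lemma
  vocabulary with Zipf rank-frequency structure (exponent 1.1, top
  frequency 10^6); function words are drawn from the shipped lists.
  Generated lemmas are kept disjoint from the function-word lists so
  classification round-trips through disk.
* **Lag process**: AR(1) on the log lag in words (mean 4 words, stationary
  log-sd 0.45, autoregression 0.85, clipped to 0.5–15 words), giving the
  right-skewed stationary distribution characteristic of empirical
  ear-voice spans. The L1→L2 mean lag is shifted by +1.5 words (the
  interpreter affords a larger buffer in the native-source direction), so
  every simulated subject's median load is larger in L1→L2 — the
  configuration under which the all-positive signed-rank pattern (V = 45)
  is an analytic consequence. Clear times are made strictly increasing
  (sequential overt translation).
* **Probes**: i.i.d. uniform 450–750 ms inter-stimulus intervals (mean
  600 ms), first probe at 1 s, truncated at session end.
* **EEG**: each probe contributes Gaussian-shaped P1 (peak 60 ms, σ 8 ms,
  base +1.5 µV) and N1 (peak 140 ms, σ 12 ms, base −2.5 µV) bumps. Signed
  amplitude is `base + slope·z(load)` and latency `nominal + shift·z(load)`,
  with the load z-scored within session so slopes are in µV (or ms) per
  z-unit and comparable across estimators. Defaults: P1 amplitude slope
  +0.3 µV/z, N1 amplitude slope −0.5 µV/z, P1 latency shift +2 ms/z, N1
  latency shift 0. The N1 sign is a validation convention (it matches the
  slope the recovery suite is specified against); the attention account of
  SI predicts the opposite sign — less negative N1 under higher load — so
  set `n1_amp_slope_uv=+0.5` to simulate that regime. A fixed
  fronto-central spatial gain (Gaussian falloff from just anterior of Cz
  over approximate 10–20 coordinates) scales the evoked signal per channel;
  the mastoids carry noise only; there is no head-model simulation.
* **Noise**: per-channel Gaussian noise shaped to 1/f (exponent 1) plus a
  narrowband 10 Hz alpha component (relative weight 0.3, width 1 Hz),
  scaled to 2.5 µV RMS. This is deliberately at the clean end of plausible
  — the residual after ocular/muscle artifact removal in a 0.1–30 Hz band —
  chosen once so that the validation conditions (N1 slope −0.5 µV/z, 500
  probes/session) have comfortable power at desk scale. Eye blinks, muscle
  bursts and electrode drift are *not* simulated; passing recovery tests
  therefore demonstrates correctness of the analysis chain, not robustness
  to real-world artifacts.

Everything is a pure function of `SimConfig.seed` (per-stage independent
substreams keyed by stage, subject and direction): the same configuration
regenerates bit-identical transcripts, probe trains and EEG.

What the generator does not emulate: chunked (many-to-many) alignments,
omissions and anticipations, speech acoustics, articulation EMG, or
inter-subject variability in ERP morphology. Conclusions from simulated
data are about the estimator chain, not about interpreters.

## Numerical and design choices

* Probe onsets are continuous; epoch extraction rounds to the nearest
  sample, so noise-free epochs are sample-identical only when onsets sit on
  the sample grid (the oracle tests snap them there). The window-mean
  response to a unit amplitude slope is the sampled unit-template mean over
  the window (≈0.639 for N1) times the channel gain; slope-recovery
  analyses divide by this factor.
* Parameter-recovery validation runs on unfiltered, unreferenced epochs:
  the 0.1–30 Hz FIR attenuates the fast Gaussian templates by a constant
  factor, which would systematically shrink the recovered slope relative to
  the configured truth. The filtering path is validated separately by its
  frequency response (50 Hz ≥ 20 dB down, DC removed, common mode zeroed).
* Null-calibration validation (type-I error of the Load effect under zero
  slope) runs at the summary level — lag-process loads, quantile labels,
  per-epoch window-mean amplitudes as base + noise, condition means,
  1-way RM-ANOVA with GG correction across 9 subjects — because the
  calibration property belongs to the labeling + ANOVA chain, and the
  unequal cell sizes of the 10/80/10 split are exactly the sphericity
  violation GG is there to absorb. 500 cohorts keep the binomial error on
  the rejection rate below one point.
* Sample quantiles use linear interpolation (the numpy default); the exact
  Wilcoxon uses inclusive tails on both sides; ANOVA factor levels are
  ordered lexicographically; peak-latency ties break to the earliest
  sample; simultaneous load events coalesce before the cumulative sum,
  which is clipped at zero against floating-point drift.
* Default problem sizes in tests and the acceptance script (120–302 s
  sessions, 9 subjects, 100 recovery sessions, 500 null cohorts) are the
  package's validation scale: large enough for every targeted property to
  be decided, small enough to run interactively.

## Known limitations

* The clear-time policy is the sole supported buffering semantics; the
  true bookkeeping of a human interpreter's WM is unobservable.
* The CL estimator inherits the directionality ambiguity described above;
  both forms are provided, neither is privileged by data.
* The exact Wilcoxon is limited to n ≤ 25 before falling back to the
  normal approximation.
* `rm_anova` requires a balanced (possibly imputed) fully-crossed design;
  unbalanced designs need a mixed-model treatment that is out of scope.
* Real-data effect sizes for the load modulation are unknown; the
  simulator's slopes are validation conventions, not empirical claims.
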
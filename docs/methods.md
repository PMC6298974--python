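# Methods

This note documents the models implemented in `sfg`, the defaults and the
reasoning behind choices that were genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Stimulus model

An SFG stimulus is a chord sequence on a 50-ms grid. Each chord is a sum of
unit-amplitude pure tones at frequencies taken from a fixed pool, each tone
gated by a 10-ms raised-cosine onset and offset ramp; chords are
concatenated without crossfade and rendered at 44.1 kHz.

**Frequency pool.** The pool is the geometric series
`f_min · 2^(k/24)` truncated at the last term ≤ `f_max`, with defaults
179–7246 Hz. The printed endpoints are *not* a whole number of 1/24-octave
steps apart (128.14 steps), so a pool cannot start at 179 Hz, end at
7246 Hz and keep exact 1/24-octave spacing simultaneously. We generate
upward from 179 Hz with the exact `2^(1/24)` ratio, which preserves the
spacing statement, yields the expected 129 entries, and tops out at
7216.83 Hz — just under the nominal bound. Generating from both endpoints
with a slightly stretched ratio would have been the other defensible
choice.

**Behavioural recipe (incorporated figure).** 60 chords, exactly 15
elements each. For a figure stimulus, `coherence ∈ {4,6,8,10,12}` channels
are drawn once (uniformly, without replacement, no spacing constraint) and
occupy every chord of the figure window; the remaining `15 − coherence`
elements of those chords are drawn from the rest of the pool. Chords
outside the window hold 15 ground elements. Because figure elements
*replace* ground elements, figure and control stimuli are exactly matched
in per-chord element count, hence in expected energy — the level-cue
control the behavioural task depends on.

* *Figure duration*: 20 chords (1 s) by default, configurable. The test
  recipe does not pin this down unambiguously; 1 s matches the example
  spectrogram and the training target.
* *Figure onset*: uniform over chord indices 6–40 (0.3–2.0 s) — onsets are
  quantized to the chord grid because elements exist only as whole chords.

**Imaging recipe (appended figure).** 120 chords; each chord holds a
uniform 5–15 ground elements. During chords 40–79 ten extra elements are
appended on top of the ground: the same ten channels every chord (figure)
or ten freshly drawn channels per chord (control). Per-chord totals
therefore rise by ≈10 during the window in *both* conditions — the
appended design trades the level cue for a simpler construction, which is
acceptable in the imaging context it imitates.

**Duplicate elements are prohibited** within a chord (a doubled tone would
just double its amplitude — an uncontrolled level cue). For the coherent
figure this is enforced by excluding the ten figure channels from the
window's ground draws; re-drawing the *appended* element instead (as one
might for the shuffled control, where we do exactly that) would break the
across-chord identity of the figure. The ground distribution inside the
window is thereby conditioned on avoiding 10 of 129 channels; the marginal
effect on ground statistics is negligible and identical across chords.

**Amplitude model.** All tones share one amplitude before a single global
scale per waveform brings the peak to full scale (|x| ≤ 1). No per-chord
RMS equalization is applied — the incorporated design already controls
level, and equalization would *reintroduce* a cue by compressing chord-to-
chord variability differently in figure and control stimuli. The scale
factor is recorded in the stimulus metadata (and JSON sidecar), so
relative chord levels are always recoverable; level-cue checks in the
test suite compare RMS on the unscaled waveform.

**Reproducibility.** A stimulus set draws one recorded 63-bit seed per
stimulus from the master RNG; any single stimulus regenerates bit-exactly
from its spec alone.

## Synthetic observer

The observer emulates the *statistical structure* of a trained macaque's
behaviour, not its mechanism:

* **Psychometric function** — detection probability
  `p(c) = fa + (asymptote − fa) · logistic(slope · ln(c/c50))`,
  lower-bounded by the false-alarm rate (at c = 0 the "detection"
  probability is exactly the guessing rate) and capped by a lapse-limited
  asymptote. Defaults: asymptote 0.95, c50 4.5 elements, slope 3 — hit
  rates rise from ≈0.46 at coherence 4 to ≈0.91 at coherence 12, matching
  the magnitudes a proficient subject shows, with the detection threshold
  near coherence 4. The analysis pipeline nowhere assumes this family.
* **False alarms** — one uniform release hazard, calibrated so the
  probability of a spurious release over a full 3-s stimulus equals
  `fa_rate_per_stimulus` (default 0.12). On figure trials the same hazard
  runs only until figure onset, so the pre-figure false-alarm probability
  is `fa_rate · onset / stimulus_len`. (Giving the pre-figure interval the
  *full* per-stimulus probability regardless of its length would make the
  hazard non-uniform and inconsistent with catch trials.) Releases on
  figure trials before figure onset are labelled false alarms; they are
  reported but kept out of the catch-based FA denominator (below).
* **Reaction times** — `rt = rt_floor + Exp(mean = rt_scale / (1 +
  gain · c))`: a shifted exponential, chosen for its closed-form mean and
  CDF (used as exact oracles in tests), with mean latency and spread both
  decreasing in coherence. Defaults (floor 0.30 s, scale 0.35 s, gain
  0.08) put mean hit RTs near 0.48–0.57 s.
* **Hit window** — a release counts as a hit within
  `[onset, onset + figure_duration + motor_grace]`, `motor_grace = 0.4 s`.
  A pure figure-period window would misclassify responses initiated just
  before figure offset; the grace term absorbs motor latency. Detections
  whose sampled RT falls beyond the window are misses (probability < 0.002
  at default parameters; the exact truncation term is accounted for in the
  recovery tests).
* **Rewards** — hits earn `max(0.1, 1.2 − rt)` (faster = more), correct
  rejections a fixed 1.5 (larger, since the bar is held longer). Rewards
  are logged but unused by the analysis.
* **Allocation** — exactly `floor(0.6 · n_trials)` figure trials per
  session, split evenly (±1) across coherence levels and randomly
  permuted, so the 60/40 composition is deterministic per session.

What the generator does **not** emulate: learning or motivation drifts
within and across sessions, sequential dependencies, RT distributions
heavier-tailed than exponential, subject idiosyncrasies (it is one
parameter set, not two animals). Passing recovery tests therefore shows
the pipeline is correct and well-calibrated for data *of this structure*,
not that real behaviour follows these parametric families.

## Analysis pipeline

Order of operations: latency correction → anticipatory exclusion →
rates → d′ → CIs / trends / ANOVA.

* **Latency correction** subtracts a configurable output latency
  (default 0) from every response time; responses earlier than the latency
  flag the trial invalid.
* **Exclusion** removes trials with responses strictly below 0.4 s after
  *stimulus* onset; the excluded fraction is reported.
* **Rates** — hit rate = hits / (hits + misses) per coherence × session;
  FA rate = catch-trial false alarms / catch trials, one value per
  session. Pre-figure releases on figure trials are *not* in the FA
  denominator: the denominator is "stimuli without a figure", and mixing
  trial types would make the FA rate depend on the coherence mix.
* **d′ edge correction** — rates of exactly 0 or 1 become `1/(2n)` and
  `1 − 1/(2n)` (Macmillan–Creelman); keeps d′ finite without biasing
  interior rates.
* **Response variability** — the within-session SD (ddof = 1) of hit RTs
  per coherence, averaged across sessions. This is a *choice*: the
  quantity is often left undefined; SD was picked over IQR/CV as the most
  common reading.
* **Bootstrap CIs** — percentile method, default 5000 resamples; interval
  endpoints are the order statistics at 1-based ranks
  `ceil(α/2 · B)` and `floor((1 − α/2) · B)`.
* **rmANOVA** — one-way within-subject: `F = MS_cond / MS_cond×session`,
  df `(k−1, (k−1)(n−1))`. Mauchly's W is computed on the covariance of
  orthonormal (Helmert) contrasts with the standard two-term chi-square
  approximation; if its p < 0.05 the **lower-bound** correction
  `ε = 1/(k−1)` multiplies both df (Greenhouse–Geisser available by
  flag, lower-bound is the default as the most conservative). A
  one-sample KS test per condition (against a normal with estimated
  moments) is reported but does not gate the ANOVA — no principled
  consequence is defined for it, so it stays diagnostic.
* **Pooling** — sessions from all subjects enter one ANOVA (overall-trend
  analysis); per-subject analysis is a matter of passing per-subject
  session lists.

## Numerical and scaling choices

* Waveform rendering is exact sine summation per chord (no additive noise,
  no dither); determinism holds bit-for-bit for fixed seeds on a fixed
  BLAS/NumPy stack.
* Degenerate inputs: empty matrices render silence with scale 1; zero
  catch trials make the FA rate (and d′) undefined for that session, and
  such sessions drop from the affected matrices with a warning; missing
  ANOVA cells raise (no imputation).
* Test problem sizes were chosen so the whole suite runs in well under a
  minute of CPU while keeping Monte-Carlo noise far from the asserted
  bounds: level-cue checks use 200 stimuli; type-I calibration uses 500
  datasets of 10 sessions × 250 trials; power checks 40 replicates of 50
  sessions × 240 trials; parameter recovery 30 sessions × 1000 trials.
  The recovery test uses 99% bootstrap CIs so the five simultaneous
  per-coherence coverage checks keep a ~95% family-wise pass rate.

## Known limitations

* The behavioural figure duration and the pool-endpoint convention are
  reconstructions (documented above), not certainties.
* The observer's false-alarm process is memoryless and stationary; real
  subjects show post-error slowing and time-on-task effects.
* `rm_anova` implements the balanced one-way within-subject design only —
  no between-subject factors, no missing data.
* Audio output is digital full-scale; no SPL calibration or transfer-
  function compensation is attempted.
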
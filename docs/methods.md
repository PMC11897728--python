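# Methods

`emopac` re-implements, as a tested pipeline, an EEG analysis of
emotion-modulated divergent thinking: Morlet-wavelet time-frequency (TF)
power with pre-stimulus baseline normalisation, a permutation/cluster
significance procedure operating on TF maps, surrogate-normalised
fronto-parietal phase-amplitude coupling (PAC), and the behavioral and
correlational group statistics. Because no public recordings exist for
this paradigm, the pipeline ships a first-class synthetic-data generator
with known injected structure; every stage is validated by recovering
that structure.

## Study geometry

The emulated experiment: participants watch a neutral, happy or sad film
clip, rate arousal and pleasure on a 5-point pictorial (SAM) scale, then
perform an alternate-uses task (AUT) while 32-channel 10-20 EEG is
recorded at 512 Hz (average reference offline, downsampled to 256 Hz).
Trials are epoched from −8 s to +18 s around AUT onset; each trial's
idea is scored for originality (1–5) by two raters. Four electrode
clusters stand in for cortical regions: left/right frontal
(F3, FC5, FC1 / F4, FC6, FC2) and left/right parietal
(P3, CP5, CP1 / P4, CP6, CP2).

## Synthetic data generator (`emopac.synth`)

Each trial is an independent pink-noise background (1/f^β via spectral
synthesis, β = 1 by default, 10 µV broadband SD per channel; an optional
shared across-channel source is off by default so null-hypothesis tests
stay clean) plus explicitly injected effects:

* **Oscillations** — `amp · cos(2πft + θ)` with a random phase per
  trial, confined to a channel set and time window with 50 ms cosine
  ramps. Defaults emulate the qualitative condition profile the pipeline
  must detect: a 40 Hz burst at 2–4 s in the happy condition (strongest
  on the left, weaker in neutral) and a sustained left-frontal 5/10 Hz
  increase in the sad condition.
* **Couplings** — a slow carrier `cos(φ(t))`, `φ(t) = 2πf_p t + θ`, is
  added to the frontal (phase) cluster, and a fast oscillation
  `A₀(1 + m·cos φ(t))·cos(2πf_a t + ψ)` to the parietal (amplitude)
  cluster; `m ∈ [0, 1]` is the modulation depth. Defaults: happy
  LF→LP 5 Hz × 40 Hz (m = 0.8), sad LF→RP 5 Hz × 60 Hz (m = 0.5), and a
  weaker all-condition RF→LP 10 Hz × 40 Hz path (m = 0.4). The carrier
  is 5 µV and the fast base amplitude 2 µV against the gamma-band noise
  floor, i.e. clearly detectable at 30 trials but not trivially so.
* **Behavior** — one row per participant × condition with arousal,
  pleasure and originality modelled as condition mean + participant
  intercept (SD 0.45) + residual (SD 0.32), clipped to [1, 5].
  Continuous clipped Gaussians are used instead of ordinal sampling:
  simpler, and sufficient for ANOVA-recovery tests. The condition means
  (originality 2.6/3.1/3.0, pleasure 3.0/4.2/1.9, arousal 2.4/3.4/3.1
  for neutral/happy/sad) reproduce the orderings and the approximate
  effect-size structure reported for this paradigm — a large pleasure
  effect, a moderate arousal effect, and an originality effect where
  happy and sad beat neutral but do not separate from each other — with
  enough power at n = 26 that the qualitative Tukey pattern recurs in
  well over 80 % of simulated studies.

Trial counts default to 15 per condition (the number of AUT items per
condition in the emulated protocol); no trial loss is simulated because
the synthetic path is artifact-free.

What the generator does **not** emulate: volume conduction / realistic
forward fields (channels are independent except for injected effects and
the optional shared source), ocular or muscle artifacts, non-stationary
background statistics, or ordinal rating granularity. Passing tests
therefore show that the estimators and decision procedures are correct
and calibrated on signals of realistic scale and geometry — not that
real-data preprocessing choices (e.g. ICA) are validated.

## Preprocessing (`emopac.preprocess`)

Default chain, order configurable: average re-reference over the 32
scalp channels → polyphase downsampling to 256 Hz → zero-phase filtering
→ spherical-spline reconstruction of bad channels. Filters are
Butterworth cascades run forward-backward: a 47–53 Hz band-stop (order
4; > 40 dB at 50 Hz), a 100 Hz low-pass (order 4), and a 0.1 Hz
high-pass (order 2). The high-pass uses Gustafsson initial conditions:
with a corner this close to DC, a padded `filtfilt` leaves a slow
boundary wander of several percent on epoch-length data, while the
Gustafsson scheme keeps a 50 Hz tone's residual below 10⁻⁶ of its input
amplitude. Channel interpolation follows the spherical-spline
formulation (order m = 4, 50 Legendre terms, ridge 10⁻⁵) on unit-sphere
10-20 template positions; it reproduces constants exactly and is
intended for at most ~2 bad channels. Ocular-artifact correction is a
pass-through hook: the synthetic data are artifact-free, and a callable
can be supplied for real recordings.

## Time-frequency analysis (`emopac.timefreq`)

Complex Morlet wavelets `w(t, f₀) = A·exp(−t²/2σ_t²)·exp(2iπf₀t)` with
constant ratio f₀/σ_f = 7, σ_t = 1/(2πσ_f), unit total energy, on a
1–70 Hz grid in 1 Hz steps (matching the σ_f = f₀/7 resolution without
oversampling). Support is truncated at ±6σ_t so truncation sidelobes
fall below the numerical floor used in baseline normalisation. Power is
|convolution|² per electrode and trial (discrete convolution scaled by
1/rate so unit energy carries over), averaged over a cluster's three
electrodes, then expressed per frequency as natural-log change from the
mean −3 to 0 s baseline power and averaged over trials. A percent-change
mode exists behind a flag; log units are the default because the
symmetric ±2.5 display range typical of such maps matches log scaling.
Values within 3σ_t of an epoch edge are flagged invalid. Log change is
undefined where a signal has essentially no power: validation restricts
flatness claims to frequencies whose baseline power is within 40 dB of
the spectral peak. The whole decomposition is invariant to global
amplitude scaling.

"Reference" vs "activation": the activation map is the 0–10 s task
window. The generator epochs a single trial window with 8 s of
pre-stimulus fixation, so the reference map defaults to −6 to −1 s
(clear of the lowest-frequency edge zone and of the onset), not a
separately epoched 10 s fixation; both windows are configurable.

## Permutation significance (`emopac.permstats`)

For each cluster × condition, the observed statistic is the grand-average
activation − reference difference, smoothed by a truncated moving
average over the centre element and its first and second neighbours
(5 × 5). When the two windows differ in length the reference map enters
through its per-frequency time mean; equal-shape maps (PAC matrices)
difference element-wise. The null is built by, per permutation,
independently permuting the time-axis and frequency-axis indices of each
participant's activation and reference maps (axis-wise shuffling — the
closest reading of "shuffling time points and frequency bands" that
preserves each map's marginal value set) and recomputing the smoothed
grand-average difference, 2000 times by default. Each element's observed
value is z-scored against its permutation mean/SD and converted to a
two-sided p through the normal CDF (an empirical-quantile mode is
available for comparison); elements with p < 0.001 survive, and a
connected-component filter then removes same-sign components smaller
than k (k ≥ 100 for TF maps, k ≥ 12 for PAC matrices; 4-neighbour
adjacency by default, 8 optional; opposite-signed neighbours never merge).
Degenerate zero-variance elements are excluded with a warning. This is a
per-element calibration plus a cluster-extent heuristic — not a
max-statistic family-wise correction — and with very few participants
the spatial correlation among neighbouring elements makes cluster
survival more likely than a bin-independence intuition suggests.

## Phase-amplitude coupling (`emopac.pac`)

Phase comes from the frontal cluster mean, amplitude from the parietal
cluster mean, on four directed paths (LF–LP, RF–RP, LF–RP, RF–LP).
Band-limited phase and envelope are obtained by order-3 Butterworth
band-pass plus Hilbert transform over the full epoch, then cropped to
the analysis window (extraction via filter + analytic signal matches the
mean-vector-length literature; a wavelet-phase mode is not provided).
The raw coupling is the mean vector length
`MVL = |1/N Σ a(t)·e^{iφ(t)}|` over samples concatenated across trials.
It is normalised against 200 trial-shuffled surrogates (paper silent on
the count; 200 is toolbox-typical): each surrogate pairs the phase of
trial j with the amplitude of a different trial (random derangement),
and the reported value is the surrogate z-score (raw − mean)/SD; a
(raw − mean)/mean mode exists. Under no coupling the z-value is a
standardised magnitude of a near-Gaussian complex sum — approximately
standard normal but right-skewed (Rayleigh-like), so its upper tail is
somewhat heavier than N(0, 1); the cluster filter (k ≥ 12 on a 10 × 16
bin grid) absorbs this in practice.

Comodulograms tile phase bins of width 2 Hz every 1 Hz over 1–12 Hz
(10 bins) against amplitude bins of width 10 Hz every 2 Hz over
30–70 Hz (16 bins) — chosen so a k ≥ 12 cluster rule is meaningful on
the resulting ~160-bin matrix. Named bands: delta 1–3, theta 3–7, alpha
7–12 Hz; low gamma 30–50, high gamma 50–70 Hz. Condition-level PAC is
reported by default as activation-window z minus reference-window z
(signed change relative to fixation — one reading of "more/less robust
modulation than baseline"; the activation-only mode is a flag away).
Matrices are smoothed like the TF maps before across-participant
averaging; significance reuses the permutation machinery with k ≥ 12.
The scalar entering correlation analyses is the mean normalised PAC over
a named band rectangle (e.g. theta × low gamma), labelled
`Condition-T-LG` style.

## Group statistics (`emopac.groupstats`)

One-way ANOVAs over condition run in a `within` (repeated-measures,
default) and a `between` (pooled) mode, because published reports of
this design quote degrees of freedom matching the pooled decomposition
while describing a within-subject factor; partial η² is
SS_cond/(SS_cond + SS_error). Tukey post hocs in within mode use the
repeated-measures residual mean square with (k−1)(n−1) df and the
studentized range distribution; between mode uses the standard
independent-groups Tukey HSD. Cohen's κ is computed unweighted from the
contingency table. PAC correlations are Pearson r over participants for
every pair of band features within a path — within one condition and
across conditions — for everyone and per gender subgroup (≥ 4
participants), starred at .05/.01/.001 without family-wise correction
(matching how such tables are usually reported); Holm adjustment is
available behind a flag. Whether such summaries should pool paths is
ambiguous in the field; per-path is the default here.

## Pipeline and reproducibility (`emopac.pipeline`, `emopac.io`)

Stages run in dependency order from a YAML config; each stage writes an
HDF5 result container (named arrays with complete axis metadata and
provenance: config hash, seed, version) or a CSV. EEG epoch containers
are stored float32 (µV data carry nowhere near 7 significant digits);
all result matrices are float64. Sub-seeds derive from the global seed
by stable hashing (CRC-32) of stage names, so runs are bit-reproducible:
`checksums.json` holds a SHA-256 over each container's arrays and two
runs with the same config and seed match exactly. Raw recordings can be
read from and written to plain EDF (16-bit, 1 s records, equal channel
rates; amplitudes round-trip within one quantisation step); the reader
is cross-checked against an independent EDF implementation in the test
suite.

## Validation problem sizes (`emopac.validation`)

Chosen to exercise each property convincingly on one CPU: permutation
calibration on 50 simulated 8-participant datasets of 70 × 100 noise
maps at 2000 permutations (≈ 350 000 element-wise decisions); coupling
recovery on 20 simulated 30-trial recordings (12 cluster channels,
256 Hz, −3 to 10 s epochs) plus a 4-level modulation-depth sweep;
behavioral recovery on 200 simulated 26-participant tables with a
matching 200-table null; determinism on two complete runs of the demo
configuration (4 participants, 10 trials/condition).

## Known limitations

* The synthetic montage has no volume conduction, so average-reference
  effects and spline interpolation are milder than on real scalp data.
* The normal-CDF reading of the permutation distribution is exact only
  insofar as that distribution is Gaussian; the empirical mode exists to
  check this.
* Surrogate-normalised PAC is right-skewed under the null (see above);
  single-bin tail probabilities at |z| > 3.29 are approximate.
* The repeated-measures ANOVA requires a complete participant ×
  condition crossing and at least 3 participants.
* EDF support covers the plain profile this pipeline writes — not
  EDF+ annotations or per-channel sampling rates.
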
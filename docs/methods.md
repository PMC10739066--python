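# Methods

`aggrisk` implements a sliding-window prognostic pipeline for imminent
aggressive behavior in wrist-biosensor recordings, together with a synthetic
corpus generator that stands in for clinical data.  This note documents the
models, the generator, the numerical choices, and what the synthetic
validation does and does not establish.

## Prediction task

A session provides three synchronized channels — electrodermal activity
(EDA, 4 Hz, µS), blood volume pulse (BVP, 64 Hz) and 3-axis acceleration
(ACC, 32 Hz, g) — plus coded episodes of three behaviors: self-injurious
behavior (SIB), emotion dysregulation (ED) and aggression toward others
(ATO).  Every 15 s, at decision time *t*, a classifier maps features of the
past window (*t* − τ_p, *t*] to the probability that an episode **onset**
falls in the future horizon (*t*, *t* + τ_f], with τ_p, τ_f ∈ {60, 120,
180} s.  Both intervals are half-open: an onset at exactly *t* is not a
positive; the sample at exactly *t* − τ_p is outside the window.  The
combined (CMB) target pools all three behaviors; the multiclass target is
three one-vs-rest labels (behaviors can co-occur within a horizon).

### Features

Each window is split into 15-s sub-windows.  Eleven base statistics are
computed per sub-window:

* EDA: tonic level (mean of a robust slow baseline), tonic slope
  (least-squares, µS/s), SCR count and mean SCR amplitude.  The baseline is
  a 10th-percentile filter over ~8 s rather than a linear low-pass: a
  low-pass absorbs a substantial part of each skin-conductance response
  into the tonic estimate, biasing SCR amplitudes down by roughly half.
  Peaks of the phasic residual with prominence ≥ 0.01 µS count as SCRs.
* BVP: beats are local maxima of the 0.7–3.5 Hz band-passed waveform with a
  0.33-s refractory period; inter-beat intervals outside 0.3–2.0 s are
  discarded.  Statistics: mean heart rate (bpm), SDNN and RMSSD (ms).
  Fewer than three usable beats yields NaNs, forward-filled within the
  session and flagged.
* ACC: per-sample magnitude mean/SD/max (g) and mean jerk (|Δ magnitude| ×
  rate, g/s).

The final vector is the mean **and** the SD of each statistic across
sub-windows (22 features).  The SD block realizes feature-variability
augmentation at the only replication level available at a 15-s cadence;
whether variability should instead be taken across sessions is left as a
configuration hook.

Augmented feature vectors (AFVs) append two recency covariates: the number
of episode anchors in the past window, and log1p of the time since the last
anchor, capped at 3600 s (the cap value is used when no anchor exists).
Anchors are onsets in the onset scenario and offsets in the offset
scenario; the offset scenario also removes instances whose decision time
lies inside an episode.

### Classifiers

Ridge logistic regression (LR), RBF support-vector machines (SVM, scored by
margin distance — rank-valid for AUROC) and a small feed-forward network
(NN, 2 × 32 ReLU) share one contract: median imputation and
standardization fitted on training data only, class-weighted losses, and
deterministic fits given a seed.  Hyperparameters (LR ridge strength over
log10 C ∈ [−4, 2]; SVM C ∈ {1, 10}) are selected by **session-grouped**
inner cross-validation.  This grouping is load-bearing: random inner folds
leak through the temporal autocorrelation of overlapping windows and
systematically select undersmoothed models (in our experiments, C = 10
where grouped selection chooses ~0.003, costing ~0.19 AUROC on the honest
test split).  The NN uses no early stopping — an unstratified validation
split is unreliable when positives are rare — and relies on its L2 penalty
(α = 0.01) instead.

### Splits and evaluation

* **SS** (session split): per session, the chronologically first 80% of
  decision instants train and the last 20% test.  A purge gap of
  τ_p + τ_f seconds is removed from the *training* side of the boundary:
  a training instance at t_tr and test instance at t_te interact whenever
  t_te − t_tr < τ_p + τ_f (the training label horizon overlaps the test
  feature window), and purging the training side preserves the full test
  span.  The purge can be disabled (`purge_gap_s = 0`) for a literal
  80/20 split.
* **LIO**: 5-fold over participants, 5 repetitions with reseeded shuffles
  (25 train/test pairs).
* **LSO**: per participant, k-fold over that participant's sessions;
  participants with fewer than two sessions are excluded with a warning.

AUROC is rank-based (ties 0.5); undefined cells (a single class in the
test set) are recorded as missing, never dropped silently.  Cell summaries
report mean, median and a t-interval CI95 over fold values.  The
experiment grid mirrors the seven standard analyses: PM/PDM × SS/LIO/LSO ×
CMB/multiclass, plus intensity stratification (experiment 7) and
test–retest/property-correlation summaries.

Movement intensity per episode is the mean |acceleration magnitude − 1 g|
during the episode, clustered by 1-D k-means (k = 3, seeded, centers
ordered) on the log scale.  The intensity-stratified evaluation trains on
the combined label and scores each cluster with only that cluster's
episodes as positives, excluding instants positive solely for other
clusters.  Differences between stratum AUROCs are reported as relative
percent differences ((high − low)/low × 100), the convention under which
the reference pairs 0.72→0.81 and 0.75→0.81 print as 12.5% and 8.0%.

### Domain adaptation

Pseudolabeling individualization: a population model trained with the
target participant excluded scores the target's unlabeled adaptation split
(chronologically first 80% of their sessions); instances with probability
≥ p_hi (default 0.75) become pseudo-positives, ≤ p_lo (0.25)
pseudo-negatives; the model is refit on population data plus the
pseudolabeled set carrying a `pseudo_weight` share (default 0.5) of the
total training mass, including in the standardization statistics.  The
defaults reflect that class-balanced, strongly regularized probabilities
rarely approach 0 or 1 — thresholds at 0.9/0.1 select ~1% of instances
and make the procedure a no-op.  Iteration stops after 5 rounds or when
the coefficient vector moves less than 1e-3 (L2).  Evaluation reports
per-participant AUROC on the held-out labeled 20% before vs after, with
median/IQR and a one-sided sign test across participants.

## Synthetic corpus generator

The generator emulates the structure of a multi-site inpatient observation
corpus: 70 participants, a median of 5 sessions each, median session
duration 4.46 h, 59.8/31.0/9.3% SIB/ED/ATO episode mixture, log-normal
episode durations with medians 1.97/10.09/2.31 s.

* **Episode process.**  Onsets follow a self-exciting (Hawkes) process,
  λ(t) = μ + Σ α·exp(−β(t − t_i)), so episodes cluster and recency carries
  signal; α = 0 switches clustering off.  Defaults: μ = 3/h, branching
  ratio α/β = 0.3, decay β = 1/60 s⁻¹.  The decay is deliberately on the
  scale of the shortest horizon: with slower decay (β = 1/120), cascades
  blanket multi-minute stretches in which ramp-elevated instants are
  labeled negative (an onset is 1–3 min away but outside τ_f), saturating
  the negatives and destroying the designed pre-onset contrast in
  episode-dense corpora.  The base rate sits between the corpus's
  participant-median (~0.5/h) and its outlier-driven mean (~13/h).
  Corpus-scale structure additionally uses a per-participant log-normal
  rate multiplier (log-SD 1.2 around 0.7/h), reproducing both the
  participant-level median episode counts and a total in the thousands;
  the evaluation presets keep a shared rate so every participant
  contributes positives.  Overlapping same-behavior episodes are merged.
* **Arousal ramp.**  Each onset is preceded by a linear 0→1 ramp over δ
  (default 180 s) that relaxes exponentially (30 s) after onset.  At full
  ramp, heart rate rises by `hr_effect_bpm` (default 15) and the SCR
  arrival rate is multiplied by `scr_rate_effect` (default 3).  Setting
  the effects to 0/1 defines the null mode.  Per-participant log-normal
  coupling multipliers (SD `coupling_sd`) modulate the two channels
  independently; `intensity_arousal_scale` couples arousal strength to
  the episode's movement-intensity class.
* **Waveforms.**  BVP is a two-harmonic pulsatile waveform driven by an
  instantaneous heart rate with slow wander (SD 3 bpm, ~60 s correlation)
  and fast variability (SD 2 bpm); EDA is a drifting tonic baseline plus
  bi-exponential SCRs (1 s rise, 4 s decay, log-normal amplitudes around
  0.3 µS) from an inhomogeneous Poisson driver; ACC is gravity plus
  orientation drift, sensor noise quantized to the E4's 1/64-g grid,
  white-noise movement bursts during episodes (per-axis SD 0.15/0.45/1.35 g
  by intensity class) and occasional benign ambient bursts.
* **Determinism.**  All draws derive from one `SeedSequence`; a fixed seed
  reproduces annotations byte-identically and signal arrays exactly.

### What the generator does *not* emulate

Motion artifacts in BVP, EDA electrode drift/detachment, circadian
structure, behavioral precursors visible in ACC before onset, and any
nonlinear person-specific physiology.  Passing synthetic validation
therefore establishes that the pipeline is leak-free, well-calibrated and
able to recover a designed pre-onset signal — not that real-world AUROCs
of any particular magnitude are attainable.

### Known properties worth noting

* **Session-composition effect.**  Even in null mode, sessions differ by
  chance in episode count, and busy sessions have both higher positive
  prevalence and more episode-driven movement in windows.  Estimands that
  pool across sessions therefore sit slightly off chance even with no
  physiological signal; recency covariates amplify this (a
  person-dependent session-split cell with AFVs measured ~0.66 on null
  data purely from composition).  Within-session estimands (e.g. LSO
  per-session AUROC) are clean (~0.50).  The null-calibration suite
  asserts the physiology-only cells.
* **Imminence ambiguity.**  With δ > τ_f, instants 1–3 min before an
  onset carry partial ramps but negative labels; prediction quality
  degrades intrinsically in episode-dense stretches.  Signal-recovery
  AUROC at the default conditions varies roughly 0.75–0.91 across corpus
  seeds; the validation suite evaluates the mean over three replicate
  corpora (observed ≈ 0.89).
* **Domain-adaptation headroom.**  Sign-preserving multiplicative coupling
  heterogeneity shifts per-person score scales and offsets, which a linear
  scorer's within-person ranking ignores; even oracle-label adaptation
  shows a median AUROC delta of only ~+0.01 (5/9 participants positive).
  The DA machinery is validated for mechanics (thresholds, no-op limit,
  determinism, label hygiene) and for the zero-heterogeneity control; the
  positive-recovery property is documented as failing under this
  heterogeneity model, and the corresponding validation is intentionally
  left failing rather than weakened.

## Problem sizes

Evaluation-scale corpora are deliberately small so the full suite runs on
one CPU: 10 participants × 3 sessions × 30–45 min for population-model
checks, 10 × 4 × 60 min for person-dependent null calibration (shorter
sessions leave too few test positives for defined per-person AUROCs), and
structure-only generation at the full 70-participant scale for corpus
descriptive statistics.
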
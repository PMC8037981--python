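# Methods

## Problem and pipeline

`bcgbp` implements cuffless blood-pressure estimation from a two-channel
chair ballistocardiogram (BCG): one pressure-film channel behind the back,
one under the seat, both sampled at 100 Hz. The physiological premise is
that each cardiac ejection reaches the two sensors with a transit delay
that shortens as blood pressure rises (the pulse-transit-time relation), so
the *phase relation* between the channels carries BP information.

The estimation chain is:

1. **Band-pass filtering.** A third-order Butterworth band-pass with
   corners at 0.5 and 6 Hz isolates the cardiac band. It is applied
   forward–backward (zero phase) by default so the inter-channel phase —
   the information carrier — is not distorted by group delay; this squares
   the magnitude response, which all analytic checks account for. The
   application mode is selectable (`zero_phase=False` gives the causal
   single pass). Edges are handled by reflect-padding three settling
   lengths (`3 * fs / f_lo` samples) and trimming after filtering.
2. **Empirical mode decomposition.** Sifting with natural cubic-spline
   envelopes through the signal extrema. The per-IMF stop is the classic
   Cauchy criterion SD = Σ(h_{k−1} − h_k)² / Σ h_{k−1}² < 0.2, capped at
   100 iterations; the decomposition stops when the residue is
   monotone-like (fewer than two extrema) or can no longer support an
   envelope pair (fewer than two maxima or two minima). Envelope boundary
   knots are obtained by mirroring the two nearest extrema about each end,
   which suppresses end swings. A flat run of equal samples contributes its
   midpoint as a single extremum.
3. **Hilbert instantaneous phase.** The analytic signal of IMF(1) is built
   in the frequency domain over the whole record (no windowing; epochs are
   cut afterwards, avoiding per-epoch edge artifacts). The phase is kept
   wrapped in (−π, π] for the network input — a bounded range suits an
   un-normalized input — with unwrapping available for diagnostics.
4. **CNN regression.** One 1-D CNN per target (SBP, DBP) per session (rest,
   recovery): conv(100 filters, kernel 21) → BN → ReLU → pool/2 →
   conv(200, 5) → BN → ReLU → pool/2 → conv(300, 5) → BN → ReLU → global
   average pooling → dense(1, identity), stride 1 throughout, filter counts
   1×/2×/3× the 100 Hz sampling rate. Convolutions use length-preserving
   padding so the only length reductions (1000 → 500 → 250) come from the
   pools. Loss is MSE, optimizer Adam at learning rate 0.001. Model
   selection is 10-fold cross-validation over the training split: each fold
   trains a fresh network on the other nine folds, and the fold model with
   the lowest validation MSE is kept ("optimal model" = best fold model, the
   most literal reading; refitting on the whole training set is available as
   an option).
5. **Evaluation.** Errors are estimated − reference (mmHg); the summary
   reports mean error (ME), sample (n−1) SD, Bland–Altman bias ± 1.96·SD
   limits of agreement, and the ANSI/AAMI/ISO 2013 verdict |ME| < 5 mmHg
   and SD < 8 mmHg. The ME bound is applied to |ME| — the intent of a bias
   criterion — and a failed verdict names the violated bound.

## The synthetic-data generator

No chair-BCG recordings with paired cuff references are publicly
deposited, so the package ships a generator that emulates the *statistical
structure* the method relies on, not cardiovascular physics:

* Each beat contributes a Gaussian-windowed cosine (centre 2.5 Hz, width
  0.15 s, unit peak) to both channels; ≥ 90 % of the beat-train energy lies
  inside the 0.5–6 Hz analysis band.
* Beat onsets come from integrate-to-threshold placement of the HR
  trajectory with 2 % inter-beat jitter. Rest sessions hold HR and BP at
  the subject's resting values (five 10-s epochs); recovery sessions start
  at 80 % of the age-predicted maximum HR (220 − age) with SBP elevated by
  `delta_sbp` (default 35 mmHg), both decaying exponentially with
  τ = 120 s (ten 10-s epochs). DBP elevation defaults to a third of the
  SBP elevation.
* The seat channel repeats the back channel's beats, each delayed by
  `transit_base_ms + slope · (SBP(t_beat) − resting_sbp)` with slope
  −0.5 ms/mmHg (higher BP → shorter delay). Sub-sample delays are exact:
  wavelets are evaluated in continuous time. Delay positivity over the
  simulated BP range is enforced.
* Nuisance terms: additive 0.25 Hz respiration baseline (amplitude 0.3)
  plus ±3 % beat-amplitude modulation; white sensor noise (SD 0.05 of the
  unit beat peak); Poisson-timed 0.5-s motion bursts (5× amplitude,
  0/min at rest, 2/min in recovery, where breathing and movement noise is
  expected).
* Epoch references are the window means of the underlying BP trajectory
  over each contiguous, non-overlapping 10-s epoch.
* Reproducibility: one seed per session; beats, per-channel noise and
  artifacts draw from deterministically spawned sub-streams, so identical
  configs give bit-identical recordings.

**Cohort coupling.** The within-session delay law above is relative to the
subject's resting SBP, so by itself a rest session carries no
*between-subject* BP information. The cohort sampler therefore couples each
subject's baseline delay to their resting pressure through the same slope,
`transit_base = 30 ms + slope · (resting_sbp − 125 mmHg)`, giving the
population-level delay–BP relation that pulse-transit-time physiology
predicts. Subject covariates: age U(20, 60) y, resting HR N(70, 8) bpm,
resting SBP N(112, 10) clipped to [95, 140] mmHg, resting DBP
28 + 0.4·SBP + N(0, 3) mmHg (population SBP–DBP correlation ≈ 0.8),
recovery `delta_sbp` N(35, 8) clipped to [20, 45] mmHg.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: true I-J-K beat morphology and its inter-subject
variability, posture and contact-pressure effects, HR–BP coupling beyond
the shared exponential recovery, nonlinear or drifting delay–BP relations,
baroreflex dynamics, and cuff measurement error in the references. Results
on this generator demonstrate that the pipeline recovers BP when the
assumed phase encoding is present; they are not evidence about any
particular sensor hardware.

## Numerical and design choices

* **Sifting details.** Natural cubic splines; mirrored boundary knots.
  Cubic-spline envelopes exhibit the well-known small overshoot at the
  opposite envelope's knots; tests allow 5 % of signal range for it.
  Degenerate inputs (monotone or too few extrema) yield zero IMFs with the
  residue equal to the input.
* **Closed-form filter oracle.** The band-pass is checked against the
  analytic magnitude of the bilinear-transform Butterworth design:
  Ω(f) = (v² − v_lo·v_hi)/(v·(v_hi − v_lo)) with v = tan(π f / fs), and
  |H| = (1 + Ω⁶)^(−1/2), squared under zero-phase application — evaluated
  without touching the implemented filter's coefficients.
* **Network engine.** No deep-learning framework is used: the network,
  backpropagation and Adam are implemented in numpy (float32,
  channels-last), with convolutions as shifted batched matrix products so
  the pass runs on BLAS; gradients are verified against finite differences
  in the test suite. Everything is seeded: weight initialization (He normal
  for convolutions), batch shuffling, and the per-fold streams are spawned
  from one `SeedSequence`, so training is bit-reproducible on CPU.
* **Head initialization.** The dense output weight starts at zero and its
  bias at the training-target mean, so initial predictions equal the mean
  and the network learns deviations; with an identity output in mmHg this
  removes a long bias-only warm-up phase.
* **Training budget.** Batch size 16, at most 25 epochs per fold with
  early stopping (patience 7, best-validation weights restored). These are
  the package's desk-scale study conditions: they let the full 30-subject
  replica (10 folds × 2 targets) train in minutes on one CPU while reaching
  held-out error SDs well inside the AAMI bound; longer budgets keep
  improving the fit and can be configured.
* **Splits.** The 8:2 split is per-epoch by default (the most literal
  protocol reading); a subject-disjoint mode exists and is the right choice
  for generalization claims, since per-epoch splits let a network exploit
  subject identity. Sessions are never pooled in one model — pooling rest
  and recovery is known to overfit — and the trainer rejects mixed-session
  input.
* **Study orchestration.** One top-level seed fans out via `SeedSequence`
  spawning to cohort, split and training; every intermediate file is
  SHA-256-checksummed into a manifest, and re-running the same config
  reproduces all checksums.

## Known limitations

* The acceptance-scale replica uses the per-epoch split; subject-disjoint
  evaluation is harder and its errors are larger (as expected when subject
  identity can no longer help).
* EMD is the plain algorithm — no ensemble variants — so mode mixing can
  occur on signals with intermittent amplitude; the BCG beat train is
  regular enough that IMF(1) is stable.
* The simulator's delay–BP coupling is a stipulation (the quantitative
  coupling in real subjects is unknown); absolute error magnitudes on
  synthetic data therefore have no claim to clinical accuracy.
* Training is CPU-only and the architecture is fixed; no hyperparameter
  search is performed beyond the published configuration.
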
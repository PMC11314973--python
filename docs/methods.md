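# Methods

`emgfactors` studies how two extrinsic recording conditions — limb
position and electrode shift — deform the feature space of surface EMG,
and what that deformation does to pattern-recognition control.  Because
the package ships no human recordings, every experiment runs on a
synthetic generator whose job is to reproduce the *structure* of the
recording design, not the physiology of muscle.  This note documents the
model, its parameters, the analysis protocols, the numerical choices,
and what the synthetic results do and do not show.

## Signal model

Each trial is amplitude-modulated band-limited Gaussian noise.  For
channel $c$ of motion $m$, a zero-mean Gaussian source is band-limited
to 20–450 Hz (4th-order Butterworth, zero-phase) and scaled so its RMS
equals an activation target $a_{mc}$, in arbitrary normalized units.
The default 7×6 activation matrix encodes plausible forearm synergies on
a circumferential six-electrode ring (two extensor sites, two flexor
sites, pronator, supinator): close hand shares flexor drive with wrist
flexion, open hand shares extensor drive with wrist extension, rest is
uniformly low (0.05 vs. peaks of 1.8–2.0).  That overlap is deliberate —
it is what makes between-condition transfer fragile, as in real
recordings.

Conditions act as two distinct linear operators:

* **Limb position** $P_k$: a diagonal per-channel gain
  $g_{kc} = \exp(\delta_k z_{kc})$, $z_{kc} \sim N(0,1)$ drawn once per
  (subject, level).  Changing arm posture re-weights the contribution of
  each muscle to each electrode; a log-normal gain with spread
  $\delta_k$ is the minimal model of that re-coordination.  Defaults:
  $\delta = (0, 0.4, 0.4, 0.4)$ for P1–P4 (P1 is the identity).
* **Electrode shift** $S_k$: a ring-mixing matrix
  $M_k = \alpha_k[(1-\lambda_k)I + \lambda_k N]$, where $N$ moves weight
  to the adjacent channel on the ring (the muscle the displaced
  electrode slides toward) and $\alpha_k \le 1$ models the amplitude
  loss of moving off the innervation zone.  Defaults:
  $\lambda = (0, 0.2, 0.35, 0.25, 0.45)$ and
  $\alpha = (1, 0.93, 0.86, 0.90, 0.80)$ for S0–S4, i.e. larger
  displacements mix and attenuate more.

A wide-band sensor noise floor (RMS 0.01) closes the model.  The
baseline is shared by construction: S0 *is* the P1 data, stored once.
All randomness derives from a single seed through keyed seed sequences
(subject, condition, motion, repetition), so datasets are bit-for-bit
reproducible and every condition/repetition is an independent draw —
emulating separately recorded sessions.

Effect-size defaults were fixed a priori to values that a practitioner
would call a clearly perturbed but usable recording (channel gains
mostly within ±2×, mixing below one half), and frozen; the package's
claims about them are directional (orderings), not magnitudes.

### Repetitions

`trial_jitter_sd` (default 0) adds a per-trial log-normal gain.  The
default models repetitions as statistically identical — exchangeable in
the strong sense — because the trial-as-class experiment below uses
repetitions as the negative control, and any systematic trial-level
drift *is* classifiable trial identity.  Jitter is therefore an opt-in
sensitivity parameter: the repeatability-index tests use it to verify
that the baseline RI rises monotonically with drift.

One consequence of scaling each trial to an *exact* RMS target: the
windows of a trial are weakly negatively coupled (a louder-than-average
stretch implies a quieter remainder after normalization).  Under
leave-block-out cross-validation this biases the trial-identity control
slightly *below* chance (≈23% vs. 25% at the defaults) — never above —
which is the conservative direction for a negative control.

## Preprocessing and features

Recordings are band-passed 20–500 Hz (3rd-order Butterworth) and
notch-filtered at 50 Hz (Q = 30), both zero-phase: the analysis is
offline, so forward–backward filtering costs nothing and squares the
magnitude response.  Windows are 200 ms with 50 ms overlap — read
literally as overlap, giving a 150 ms hop and 33 windows per 5 s trial
(429-sample windows, 322-sample hop at 2148 Hz); the
increment-convention reading is available as
`overlap_ms = window_ms − increment`.

Five time-domain features per window per channel: mean absolute value,
waveform length, zero crossings, slope sign changes (product form) and
Willison amplitude — 30 features for six channels, feature-major column
order.  The three counting features need an amplitude threshold; since
units are arbitrary, the default is 1% of the per-channel RMS of the
filtered baseline rest signal, computed once per dataset and recorded in
the provenance.

## Classifiers and folds

LDA is implemented to an explicit contract: per-class means, pooled
within-class covariance, empirical priors, discriminant
$x^\top S^{-1}\mu_k - \tfrac12 \mu_k^\top S^{-1}\mu_k + \log\pi_k$, ties
broken toward the first label in sorted order.  A ridge of
$10^{-6}\times$ the mean covariance diagonal (configurable, scale-free)
stabilizes the 30-dimensional covariances estimated from ~33 windows;
with `ridge=0` a singular covariance raises instead of silently falling
back.

Motion and factor classification use 4-fold cross-validation with
*whole repetitions* as folds: overlapping windows of one trial never
straddle the split.  Trial-as-class classification cannot fold by trial
(the trial is the label), so each trial's window sequence is cut into
four contiguous blocks; fully shuffled window folds are implemented only
to demonstrate the leakage inflation they cause.  Between-factor
transfer (train on P1/S0, test on a changed level) uses no CV — it
measures plain transfer, with variance coming from subjects and seeds.

## Feature-space indices

For $K$ trials with means $\mu_i$ and covariances $S_i$:

$$\mathrm{RI} = \frac1K\sum_i \frac1K\sum_j \tfrac12 (\mu_i-\mu_j)^\top
S_i^{-1} (\mu_i-\mu_j),$$

implemented literally (the $i=j$ terms contribute zero inside the inner
average); the variant excluding the self term rescales by $K/(K-1)$ and
is exposed as `include_self=False`.  For $M$ classes with centroids
$\mu_i$:

$$\mathrm{mSI} = \frac1M\sum_i \min_{j \ne i} \tfrac12
(\mu_i-\mu_j)^\top S^{-1} (\mu_i-\mu_j),$$

with $S$ the average covariance of the compared pair, recomputed per
pair inside the min; the grand-average variant is `cov_mode="global"`.
Both are Mahalanobis constructions and hence invariant under invertible
affine maps of the feature space (exactly with `ridge=0`; the automatic
ridge perturbs at the $10^{-6}$ relative level).

Protocols: baseline RI = RI over the four repetitions of a motion
inside one level, averaged over the factor's levels; between-factor RI
redraws one trial per level (P1–P4, or S1–S4), averaged over seeded
draws.  Baseline mSI = motion separability inside each level, averaged;
between mSI pools every level of the factor.  PCA for visualization
z-scores columns first (amplitudes and counts are incommensurate) and
drops zero-variance columns with a warning.

## Problem sizes

The default campaign is 7 motions × 4 repetitions × 8 distinct levels =
224 recordings of 5 s per subject (7,392 windows).  The test suite's
null- and stressed-condition checks run 20 independent single-subject
campaigns each; the acceptance script runs one four-subject campaign.
These sizes were chosen so that binomial noise on any reported accuracy
is well under a percentage point at the pooled level, while a full
suite run stays in the minutes.

## What passing tests show — and what they do not

The synthetic generator proves the *machinery*: that the indices equal
their definitions, that the classifiers honor their contracts, that a
null condition is not mistaken for an effect, and that condition-level
effects of plausible size reproduce the qualitative signature seen in
real recordings (transfer loss ≥ 10 points, single-motion factor
classification above 90% with pooled-motion classification strictly
lower, RI up and mSI down under factors, trial identity at chance).
Magnitudes are properties of the chosen effect sizes, not measurements:
the generator has no motor-unit dynamics, no force variation, no
fatigue or within-day drift, no inter-electrode crosstalk beyond
first-neighbour mixing, and its noise spectrum is identical across
motions.  Agreement in direction therefore supports the analysis code,
not any physiological claim.
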
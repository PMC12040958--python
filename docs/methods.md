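# Methods

## Overview

`ecgvae` implements a conditional variational autoencoder (cVAE) over 12-lead
ECG median beats whose conditioning vector carries subject anatomy (heart
position, heart orientation, electrode coordinates) and demographics (sex,
age, BMI), together with a Cox partial-likelihood risk head on the learned
latent space for cardiovascular-event risk ranking.  Because the cohort data
such a model is normally trained on is access-restricted, the package ships a
first-class synthetic-data generator — a single-dipole volume-conductor
forward model plus a proportional-hazards outcome simulator — that provides
ground truth for every stage: pose-dependent beat morphology, electrode
dependence, and an ECG-linked hazard whose true risk ranking is known.

## Geometry

A cardiac MRI study yields three imaging planes (short-axis stack, 2-chamber
and 4-chamber long-axis views), each known as a unit normal `n` and a point
`P` with `n·(X−P)=0`.  The heart center is the intersection of the three
planes, solved as a 3×3 linear system; the solve refuses inputs whose
stacked-normal condition number exceeds 1e8 (mm-scale coordinates in double
precision leave ample headroom below that).  The heart-local frame is

    eX = (nSAX × n4CH)/‖·‖ ,   eZ = orth(n4CH, eX) ,   eY = eZ × eX .

`eY = eZ × eX` (rather than `eX × eZ`) is deliberate: only this order makes
`det[eX eY eZ] = +1`, i.e. a rotation rather than a reflection.  The two
conventions differ only in the sign of eY; eX and eZ — the only vectors the
orientation angles use — are unaffected.  Orientation is summarized by three
projection angles in degrees,

    α = arccos(eX·x̂),  β = −arccos(eZ·ẑ),  γ = −arccos(eX·N),  N = ẑ,

which are independent axis projections, not a rotation decomposition; they
are implemented verbatim, with arccos arguments clamped to [−1, 1].
Electrode coordinates are mapped into the heart frame by translating to the
heart center and projecting onto the basis; the transform is rigid, and
layouts flatten to 30-vectors in the fixed order RA, LA, RL, LL, V1–V6.

Note that arccos projections are even functions: around an axis-aligned
orientation, rotations of ±θ about some axes produce identical angle triples.
The synthetic population therefore scatters around a tilted anatomical base
orientation (long axis pointing left–inferior–anterior), where the three
projections separate all the rotations the pose sweeps use.  This mirrors
reality — hearts are tilted in the chest — and is required for the
orientation conditioning to be identifiable from the angles alone.

## Preprocessing

Raw records are 12×T matrices in the raw stored scale (1 unit = 0.01 mV) at
500 Hz.  The band-pass is a windowed-sinc (Hamming) linear-phase FIR with
edges 3–45 Hz and order `4·fs/low` rounded odd (667 taps at 500 Hz); taps are
mean-subtracted for an exactly zero DC gain, and the record is edge-padded by
half the kernel so the symmetric convolution compensates group delay without
boundary transients.  Amplitude QC fails any record with |value| strictly
greater than 800 raw units (8 mV) in any lead; a sample exactly at 800
passes.  R peaks come from a Pan–Tompkins-style squared-derivative energy
envelope (150 ms integration, adaptive threshold at 20% of the 99.9th
percentile, 200 ms refractory period, refinement to the local
absolute-amplitude maximum) on lead II by default — a stated stand-in, since
production systems use vendor detectors.  The median beat takes R-aligned
windows from 300 ms before to 500 ms after each peak, the per-sample median
across beats (robust to a minority of corrupted beats), and linear
resampling to 400 columns; at 500 Hz the native window is already 400
samples, so resampling is the identity there.

Cohort filtering applies, in order: amplitude QC, missing-diagnosis
exclusion, and prevalent-disease exclusion (event date on or before the ECG
date counts as prevalent; the date tie is read conservatively).  Survivors
are labeled incident or healthy.  The train/test split is stratified over
the seven ICD-10 subtypes (I20–I25, I50) plus a healthy stratum:
`round(n·frac)` subjects per stratum go to test, strata smaller than
`ceil(1/frac)` stay in train, and the split is seeded.

## Conditional VAE

The encoder maps the flattened 12×400 beat, concatenated with the
standardized condition vector, through two fully connected ELU layers
(defaults 256 and 128 units) to a 64-dimensional diagonal Gaussian
`(μ, log σ²)`; log-variances are clamped to ±10.  The decoder mirrors this,
consuming `[z, y]`.  Training minimizes `MSE(x, x̂) + KL(q‖N(0,I))` with
equal weights using Adam (lr 1e-3, batch 64), fully seeded and
deterministic.  The fully connected architecture is a deliberate compact
design for 1 CPU-scale training with hand-derived gradients; every gradient
path (ELBO terms, reparameterization, condition concatenation, Cox head) is
verified against central finite differences in the test suite.

Design points:

- **Condition standardization.** Conditions mix mm, degrees and years; each
  feature is z-scored with statistics frozen from the training set, stored in
  the checkpoint.  Constant features pass through unscaled.
- **Beat scale.** Beats are used in raw units by default.  With mean-per-entry
  MSE against a KL summed over 64 dimensions, the raw amplitude scale
  (R waves near 100 units) keeps reconstruction gradients dominant enough
  that the latent stays informative; per-lead standardization is available
  behind a flag but shifts the recon/KL balance toward posterior collapse.
- **Input-noise augmentation.** Optionally the encoder input can be freshly
  corrupted with white noise each step while the reconstruction target stays
  clean (denoising-autoencoder style).  On the synthetic cohorts this blurs
  exactly the fine amplitude information the survival head relies on and
  degrades risk ranking, so it defaults to off.
- **Generation** decodes `z ~ N(0, I)` with the requested condition, seeded.

## Survival model

The risk head is a single fully connected layer from the 64-d latent to a
scalar passed through a sigmoid, so scores live in (0, 1).  The survival loss
is the negative batch-averaged log partial likelihood

    L_surv = −(1/N) Σ_i δ_i ( r_i − log Σ_{j: t_j ≥ t_i} e^{r_j} ),

with Breslow handling of tied event times.  The negation makes minimizing
the equal-weighted total `L_recon + L_KL + L_surv` coherent — summing the
raw log-likelihood would reward poor survival fit.  The sigmoid caps the
exponents (numerical stability) at the cost of the partial likelihood's
shift invariance; ordering, which is what the C-index measures, is
preserved by monotonicity.  Three further choices matter in practice:

- **Risk on the posterior mean.**  The head scores μ rather than a sampled z
  during both training and evaluation.  Posterior σ is of the same order as
  the μ spread here, so a head fit on sampled z would be fit to a
  noise-diluted signal.
- **Zero initialization + ridge penalty.**  The Cox partial likelihood of a
  sigmoid-bounded score is maximized by saturating every score at 0 or 1,
  where its own gradient vanishes; a head that saturates early on minibatch
  noise freezes in a poor direction.  The head starts at exactly 0.5 for
  everyone, carries a small L2 penalty (1e-2) on its weights, and uses its
  own Adam (lr 2e-3, linearly decayed) separate from the network body.
- **Full-batch convergence pass.**  Minibatch risk sets make the survival
  gradient noisy, so after the joint epochs the head is refit from zero on
  the frozen training-set posterior means with full-batch, ridge-penalized
  Cox loss (800 Adam steps at lr 0.02) — same objective, deterministic,
  actually converged.

Evaluation: Harrell's C (own implementation; a pair (i, j) is comparable
when `t_i < t_j` and subject i had the event; risk ties count ½; 0.5 with a
warning when no pair is comparable), Kaplan–Meier with Greenwood log-log 95%
CIs via lifelines, and median-risk two-group stratification (scores exactly
at the median go to the low-risk group).

## Synthetic-data generator

Cardiac activity is a single time-varying current dipole whose trajectory in
the heart frame is a sum of five Gaussians shaping P, Q, R, S, T; wave
directions are defined anatomically (R pointing left–anterior–inferior) and
rotated into the tilted base frame.  The torso is an infinite homogeneous
conductor (σ = 0.2 S/m):

    φ = p·(r_e − r_s) / (4π σ ‖r_e − r_s‖³).

Limb and augmented leads derive from I and II exactly as clinical carts
derive them, which keeps `III = II − I` and `aVR + aVL + aVF = 0` exact in
floating point; V1–V6 are referenced to the Wilson central terminal; RL is
ground.  The overall gain is fixed so the default subject's lead-II R wave
sits near 100 raw units (1 mV).

The population scatters pose (position ±30 mm, rotations ±30° about the
base), electrodes (template torso ±20 mm, radially clamped to a
105–395 mm shell around the heart), demographics (age U[40, 80], sex
Bernoulli(½), BMI N(27, 4²) clipped), and per-subject wave amplitudes
(lognormal R-wave scale σ = 0.25, global scale σ = 0.15).  Survival times
are exponential with rate `h0·exp(Σβ·x_std)` over standardized features
{lead-II R amplitude of the noise-free beat, age, sex} with default log
hazard ratios {1.5, 0.3, 0.2} and `h0 = 1/(5·365)` per day; uniform
censoring is bisected to the requested censored fraction (default 0.7);
events carry a uniformly drawn ICD-10 subtype so stratified splitting sees
the label structure it expects.  The true log hazard is stored per subject.

What the simulator does *not* emulate: torso boundary effects and tissue
inhomogeneity (a single dipole in an infinite medium exaggerates precordial
amplitudes), beat-to-beat variability and rhythm (median beats only),
pathology-specific morphology, and any realistic correlation structure
between demographics and ECG shape.  Tests passing on this generator
demonstrate that the pipeline recovers structure the generator provably
contains; they do not certify performance on real cohort ECGs.

## Experiments and problem sizes

The desk-scale experiment suite uses 2,000-subject cohorts (80/20 stratified
split), 15–25 training epochs, and the sweep grids rotation {−40…40}° /
translation {−40…40} mm, sizes chosen so that each study runs in minutes on
one CPU while the quantities of interest (chance-level C ± 0.02, trend
signs, recovery gaps) are resolvable.  Conditional-generation fidelity is
scored as the per-lead sign of the least-squares slope of R-wave amplitude
(peak in the QRS window) against the sweep grid, compared between generated
mean beats (64 prior draws per grid point; weak-trend leads need the larger
draw count to average out prior-sampling noise) and the simulator's own
forward model over nine leads (I, II, III, V1–V6).  The survival comparison trains
four condition arms (baseline, +sex+age, +electrodes, +sex+age+electrodes)
on one shared cohort and split; with everything else equal, arm C-indices
are directly comparable (real studies would differ in subcohort sizes).

The joint-training recovery study uses 15 epochs: the encoder of this
compact dense model starts to overfit the 1,600-subject training set well
before the default 80-epoch budget, and the test-set hazard fidelity of the
latent peaks early.  The study trains three replicate joint models
(identical data and split, different training seeds) and scores each test
subject by the mean risk across replicates — replicate averaging cancels the
initialization- and shuffle-dependent component of the latent readout noise
and is consistently better than any single replicate.  Risk-ranking quality
is reported as Harrell's C of the ensemble on the test split next to the C
of the generator's true log hazard on the same subjects.

## Known limitations

- The fully connected encoder/decoder underfits fine waveform detail
  relative to a convolutional design at equal parameter count.
- The projection-angle orientation encoding is lossy by construction
  (arccos is even); identifiability holds only around a tilted base
  orientation, as discussed above.
- Cox modeling here ranks; no baseline hazard or absolute risk calibration
  is estimated.
- The C-index of the joint model on simulated cohorts sits a few points
  below the true-ranking ceiling — the equal-weight ELBO terms bound how
  precisely a 64-d latent can linearly encode any single feature, and the
  conditioning deliberately removes pose information from the latent that
  the pose-dependent hazard feature partially relies on.
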
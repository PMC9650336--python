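# Methods

This note documents the models, estimators and numerical conventions behind
`menet`, the choices that were genuinely open, and what the synthetic
validation does and does not establish about real EEG.

## Analysis model

The unit of analysis is one event-locked epoch (default 2 s). Preprocessing
applies a 4th-order Butterworth band-pass (0.5–60 Hz) forward and backward
(`sosfiltfilt`), giving zero phase distortion — essential, since every
downstream quantity is a phase statistic — then subtracts the instantaneous
channel mean (average reference). Global field power,
GFP(t) = √(Σᵢ(Vᵢ(t) − V̄(t))²/K), is reference-free and marks the moment of
strongest scalp field; the 1-s analysis block is centred on the GFP maximum
(earliest sample wins ties; blocks are shifted minimally inward when the
peak is within half a block of an edge). Block length is round(fs·dur)
samples; the midpoint uses the floor convention; intervals are half-open and
samples 0-based.

Instantaneous phase comes from a complex Morlet continuous wavelet transform
with 7 cycles, evaluated at 1-Hz steps across each band (alpha 8–12, beta
12–30, gamma 30–60 Hz), computed after an additional per-band Butterworth
pass (`filter_per_band`, on by default; the transform can also be applied to
the broadband block). Phase-locking between channels i, j at frequency f is

PLV = |(1/n) Σₜ exp(−i(φᵢ(f,t) − φⱼ(f,t)))|,

where n counts the time samples in the analysis window at the signal's
sampling rate. Per-bin PLV matrices are averaged arithmetically across the
band's bins. The PLV matrix is symmetric with unit diagonal by construction;
the diagonal is excluded from all graph edges.

Binary networks keep edges with PLV strictly above T (a tie at T gives no
edge), over the grid {0.64, 0.67, 0.70, 0.73, 0.76}. Distances are
unweighted hop counts from breadth-first search; a disconnected pair has
d = ∞ and contributes exactly 0 (never a large sentinel) to

E_global = 1/(N(N−1)) Σ_{j≠k} 1/d_{j,k},  E_nodal(j) = 1/(N−1) Σ_{k≠j} 1/d_{j,k}.

Isolated nodes stay in the node set, so E_global always equals the mean of
the nodal efficiencies. Regional efficiency is the unweighted mean of
E_nodal over each scalp region.

Group statistics use Welch's unequal-variance t-test (two-sided;
Welch–Satterthwaite df). Global efficiency is tested per (band, threshold)
uncorrected; the four regional efficiencies within one (band, threshold)
form a Benjamini–Hochberg family — the four-region partition is itself the
multiplicity-control device, and no correction is applied across bands or
thresholds, matching how per-cell p-values are conventionally tabulated.
Significance is p < α globally and monotone-adjusted q < α regionally; a
cell with both groups constant and equal is undefined and reported missing,
while constant-but-different groups report p = 0 with a warning.

Classification windows the 1-s block into 400-ms segments with 50 % overlap
(exactly four windows; window length floor(fs·0.4) samples). To avoid losing
most of a 400-ms window to wavelet edges, window PLV is sliced from the
parent block's transform. Each window × band is one sample; features are the
strict upper triangle of the PLV matrix in row-major node order
(N(N−1)/2 per band). The protocol is strictly leak-free: one stratified
80/20 split (optionally grouped by source epoch, since windows of one block
are correlated — the default sample-level split mirrors the common practice
but inherits that optimism), a 500-tree random forest fitted on the training
split ranks features by normalised Gini importance (ties broken by feature
index), and for each n ∈ {5,10,15,20,25,30} an RBF-kernel SVM on
training-standardised features reports 10-fold stratified CV accuracy
(training split) and accuracy/AUC/ROC on the test split, with ME as the
positive class. The 10-fold CV assesses the feature subset only; no
hyperparameters are tuned.

## Numerical choices

* **Morlet implementation.** The kernel exp(2πift)·exp(−t²/2σ_t²) with
  σ_t = n_cycles/(2πf) is truncated at ±3σ_t and applied by FFT convolution.
  Truncation matters: an untruncated 7-cycle, ±5σ wavelet at 8 Hz is longer
  than a 1-s block, which is why a stock TFR routine that refuses such
  signals cannot be used here. Only the coefficient's argument is used, so
  amplitude normalisation and the zero-mean correction are irrelevant;
  exact-zero coefficients get phase 0, so silent channels never yield NaNs.
* **Edge handling.** Whole-block PLV sums drop one σ_t (at the band's lowest
  frequency) from each block edge. Dropping the full truncated half-support
  (3σ_t) was rejected: at alpha it would leave ~0.16 s of a 1-s block, few
  enough samples that every pair's PLV saturates toward 1.
* **Estimator floor.** With 7 cycles, a 1-s block contains only a handful of
  independent phase samples at low frequencies, so the PLV of *independent*
  signals has a small-sample floor that grows toward slow bands (≈ 0.2 in
  gamma, ≈ 0.3 in beta, ≈ 0.45 in alpha). Group contrasts ride on top of
  this floor; it compresses dynamic range but affects both groups equally.
* **Determinism.** One pipeline seed feeds a `SeedSequence` whose children
  seed the simulation and the classifier; reruns with identical config are
  byte-identical across all CSV/JSON artifacts.

## Synthetic cohorts

Each channel is a sum of band-limited oscillators at the canonical carriers
(10, 20, 40 Hz) plus white (optionally 1/f) Gaussian noise (SD 0.5 at unit
oscillator amplitude). All channels of a region share a regional phase
random walk (SD 3 rad/√s), which (a) decorrelates regions within a 1-s block
and (b) adds realistic spectral width. Each channel adds von Mises phase
jitter around its regional phase, redrawn at 8 Hz and held between draws;
the concentration κ is the group contrast (default κ_ME = 8, κ_NE = 0.5) in
the coupled regions (default frontal, occipital, temporal — the regions
where such contrasts are reported for this paradigm) and κ = 1 elsewhere for
both groups. Expected pairwise PLV grows monotonically with κ
(≈ (I₁(κ)/I₀(κ))² for fast jitter, inflated by wavelet smoothing), so effect
sizes are calibrated by a single interpretable dial. The jitter refresh and
walk rates were chosen so the jitter survives wavelet smoothing: much faster
jitter is averaged away by the wavelet (both groups would look locked),
much slower jitter leaves too few independent draws per block (everything
saturates). The default geometry is 128 channels at 1024 Hz with contiguous
equal region blocks; `SimulationConfig.desk_scale()` gives the 32-channel /
256 Hz profile used throughout the tests, every algorithm being
scale-invariant in channel count. One seed spawns per-epoch substreams, so
growing a cohort never reshuffles existing epochs.

What the generator does *not* emulate: volume conduction and a forward head
model, 1/f-dominated background spectra (unless the pink-noise flag is on),
ocular/muscle artifacts, non-stationary band power, and participant-level
structure (epochs are i.i.d. within group; there is no participant random
effect). Consequently, passing tests demonstrate that the estimators recover
planted phase-coupling contrasts of realistic magnitude — not that real ME
recordings contain such contrasts, nor that the classifier's sample-level
split generalises across participants.

## Region maps

The four-region scalp partition is supplied as a channel→region CSV. For
BioSemi-named 128-channel montages a coarse ring-level default is shipped
(C→frontal, A→parietal, B→occipital, D→temporal); electrode-exact
assignments vary by lab, so this default is an explicit approximation meant
to be overridden. Synthetic cohorts carry their own balanced contiguous map.

## Validation scale and known limitations

Tests and the acceptance script run at desk scale: cohorts of 20–60 epochs
with 16–32 channels at 256 Hz, 20-replicate recovery/ranking studies, and a
200-cohort null-calibration study — sizes chosen so the whole suite runs in
a few minutes on one core while keeping Monte-Carlo error well inside the
asserted bounds. Known limitations: PLV is undirected and blind to lag
structure (no PLI/wPLI variants); thresholding is absolute, not
density-matched, so group differences in mean PLV and in topology are
entangled; the alpha band's small-sample PLV floor makes its absolute
efficiency values estimator-dependent (between-group *differences* remain
valid); and Welch tests treat epochs as independent observations — with
multiple epochs per participant a participant-level aggregation should be
used instead.
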
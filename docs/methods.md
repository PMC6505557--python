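# Methods

This note records the models, conventions and numerical choices behind
`vocalid`, in the order data flows through the pipeline.

## Data model

A dataset is a flat manifest (CSV: `path, individual, role, date, split,
provenance, mixed_with_individual`) of mono 44.1 kHz 16-bit PCM WAV clips.
Each clip is either *foreground* (the focal individual vocalizing over its
ambient background) or *background* (the same territory with the focal
individual silent).  `K` is the number of distinct foreground individuals.
Augmentation products record their provenance (`stratified_mix` /
`adversarial_mix`) and the donor individual, so every mixture is auditable.
The reserved label `__background__` names the optional explicit-background
("wastebasket") class.

Temporal splitting is half-open: `within_year` sends records dated strictly
before the boundary date to train and the rest to eval; `across_year` trains
on the boundary year and earlier.  The "only-N" restriction keeps each
individual's N chronologically earliest foreground training items (ties
broken by path) — matching the deployment framing of training on whatever
recordings exist first.  Chronological-earliest is this package's
deterministic convention; any fixed rule would do, but this one is
reproducible and order-independent.

## Audio and mixing

WAV I/O uses 16-bit PCM; decode divides by 32767 so full scale round-trips,
and encode/decode error is bounded by 2^-15.  Multichannel input is averaged
to mono; other rates are polyphase-resampled to 44.1 kHz with a logged
warning.

`mix_additive(fg, bg)` scales **both** inputs by 1/2 before summing, so the
output can never clip and both layers are treated symmetrically; this costs
6 dB of level on each layer, which is irrelevant downstream because the
features are gain-covariant and the classifier consumes per-clip summaries.
Output length equals the foreground length; a longer background contributes
a uniformly random contiguous crop (from the seeded augmentation stream), a
shorter one is tiled.  Crop/tile is this package's convention — length
handling is otherwise underdetermined.

## Spectral front end

Mel spectrogram: 1024-sample frames (~23 ms), Hamming window, hop 512 (50%
overlap), frames fully contained in the clip (no padding), magnitude
spectrum through a 40-filter triangular mel filterbank spanning 0 Hz to
Nyquist.  Dialect choices, since implementations differ: HTK mel scale
(`2595·log10(1+f/700)`), Slaney-style area normalization (filter scaled by
2/bandwidth), magnitude rather than power, no log compression (keeping the
median subtraction interpretable as removal of a stationary noise floor).
An optional rectified codebook projection exists behind a flag; log
compression is deliberately not applied by default.

Noise reduction subtracts each band's median over the whole clip and clamps
negatives to zero.  A global per-band median is the simplest robust
estimator of an unchanging noise floor; it removes steady tones and tilted
noise exactly and passes transients that occupy fewer than half the frames.

Per-clip summaries concatenate each feature dimension's mean and
*population* standard deviation (divisor T) over time.

## Codebook feature learning

Spherical k-means on spectrogram patches: all overlapping 4-frame windows
(band-major flattened, so one patch is 160-dimensional for 40 bands) are
mean-centred and ZCA-whitened (eigenvalue regularization 1e-8; the symmetric
whitening matrix is stored and invertible).  Patches are projected to the
unit sphere; assignment maximizes the dot product; each update renormalizes
the mean of assigned patches; empty clusters are reseeded from a random
patch; iteration stops when the summed-similarity objective changes by less
than 1e-6 relatively, or at 100 rounds.  Initialization takes k distinct
random whitened patches under the seed.  For tractability the patch pool is
capped at 100 000 patches (seeded subsample).

Projection maps each whitened patch to its k centroid dot products — a
linear map on whitened patch space — and the clip summary is the mean/SD of
those responses over time.  Defaults are k = 256, w = 4 (configurable); the
test suite and the acceptance runs use k = 64 (w = 4) as a desk-scale
setting with the same qualitative behaviour.  The codebook is always fit on
the (possibly augmented) training split only; a leakage-guard test asserts
evaluation audio never reaches it.

## Classifier

Random forest, 200 trees, unlimited depth, sqrt-of-features per split,
probabilities = fraction of tree votes, mandatory seed; training items are
canonically sorted by path so item order cannot perturb results.  With the
explicit-background flag, background training clips form one additional
class treated exactly like the individual classes.  When individual-only
scores are requested from such a model, the background column is dropped and
rows renormalized (a monotone per-row rescaling that preserves ranking).

## Evaluation

Pooled one-vs-rest AUC: every (item, class) probability is one binary
decision, positive iff the class is the item's true individual; the AUC is
the Mann–Whitney rank statistic over the pooled positives and negatives
(midranks, so ties count half).  One number per condition, interpretable as
P(random positive outranks random negative); a macro-averaged per-class AUC
would weight rare classes differently and is not the primary output.

Adversarial deviation is the RMS difference between the score matrices of
the adversarially mixed and unmodified evaluation sets, computed on the
probability scale, paired item by item (the mixtures are 1:1 and
order-preserving with their sources).

## Synthetic scenes

The generator emulates the statistical structure the experiments need, not
perceptual realism:

- **Vocal signatures**: each individual has a repertoire (default 5) of FM
  tone syllables — base frequency U(2, 7) kHz, sweep rate U(−40, 40) kHz/s,
  duration U(0.08, 0.18) s — rendered as Hann-windowed chirp sequences with
  random gaps.  `signature_strength` s linearly interpolates each
  individual's syllable parameters between one shared repertoire (s = 0, no
  vocal identity) and fully individual draws (s = 1).
- **Territory backgrounds**: spectrally tilted Gaussian noise (tilt exponent
  U(−0.8, 0.2) on amplitude vs (f/1 kHz)), three persistent habitat tones
  U(1, 8) kHz at low level, and Poisson-timed 50 ms transient chirps (rate
  U(2, 6)/s) centred near the habitat-tone frequencies.
  `confound_strength` c interpolates background parameters between shared
  (c = 0) and individual (c = 1) the same way.  The identity information is
  deliberately carried mainly by the *transient* chirps: steady tones and
  noise floors are erased by the median noise reduction, while sparse
  transients survive it, so the confound dial remains effective through the
  front end.
- **Assembly**: foreground = vocalization scaled to `snr_db` (default 10 dB,
  a good field recording) above the background RMS + the *same individual's*
  background at reference RMS 0.04 (ample 16-bit headroom); in the rare case
  the sum peaks above 0.99 both layers are scaled together, preserving the
  SNR.  Background clips are the background layer alone.  Dates spread
  clips over the configured years (successive season days from April 1
  within each year); `drift` resamples that fraction of the repertoire
  between years (default 0, i.e. stable calls).
- **Reproducibility**: every draw descends from one seed through spawned
  generator streams; identical configs yield byte-identical WAVs.

What passing tests on these scenes does and does not show: they demonstrate
that the pipeline transmits vocal identity when it exists, reports chance
when it does not, that the probes expose a planted background confound, and
that stratified augmentation plus learned features suppress it — i.e. the
*mechanism*.  They do not certify performance on real species, where
signatures are higher-dimensional, backgrounds non-stationary, SNR variable,
and repertoires drift in structured ways; real-data AUC levels cannot be
inferred from these numbers.

## Desk-scale study conditions

The acceptance runs use K = 8 individuals, 20 foreground + 20 background
clips of 2 s each per individual, split mid-season (boundary April 11, 10/10
per individual), codebook k = 64 — sizes chosen so a full two-condition
comparison (pure confound s = 0, c = 1; signal-plus-confound s = 1, c = 1)
completes in well under a minute while leaving dozens of evaluation items
per cell.  Generator defaults were fixed once to field-plausible values and
are not tuned per experiment.

## Known limitations

- No propagation/reverberation modelling, no overlapping singers, no
  multi-individual clips.
- Open-set recognition (rejecting unknown individuals) is out of scope; the
  wastebasket class is a closed-set device, not a universal background
  model.
- Automatic segmentation of long recordings into foreground/background
  clips is assumed done upstream.
- The equal-gain mixing convention changes the effective SNR of augmented
  items by construction; classifiers see this consistently in training and
  evaluation, but absolute SNRs of mixtures are not calibrated quantities.
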
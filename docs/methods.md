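# Methods

`hgstates` asks a single scientific question at several levels: which
statistical features of intracranial high-gamma activity (70–110 Hz amplitude
envelope, a proxy for local population firing) carry information about coarse,
naturalistic behavioral states labeled in 5-minute blocks?  Because no public
dataset of this kind exists, the package answers it on synthetic recordings
whose ground truth it controls, with every stage written so that real EDF
recordings plus a block-label table can be substituted directly.

## Signal model and conditioning

A raw recording is conditioned into a binned envelope in a fixed order:
channel rejection → referencing → (down-sampling for depth recordings) →
notch filtering → band-pass + Hilbert envelope + binning → despiking.

* **Channel rejection.** A channel is rejected when its mean squared value
  exceeds the across-channel mean by more than k standard deviations (k = 3
  for subdural grids, 1.5 for depth electrodes), or when it contains samples
  exactly equal to zero.  Grid channels are screened before entering the
  common average; depth-electrode bipolar pairs are screened after
  re-referencing (a flag switches this).
* **Referencing.** Common average for grids; adjacent-contact bipolar pairs
  (inferred from the "A1, A2, …" label convention) for depth electrodes.
* **Filters.** Notches are 2nd-order IIR with 1 Hz bandwidth at 60, 120, 180,
  240 Hz, applied forward–backward (zero phase); the high-gamma band-pass is a
  4th-order zero-phase Butterworth.  Depth recordings are decimated 2000 →
  500 Hz after an 8th-order low-pass at 0.8× the target Nyquist.  Filter
  realizations are this package's choice: standard, stable, and phase-free.
* **Envelope.** Magnitude of the analytic signal, averaged over non-
  overlapping 250 ms bins anchored at each contiguous segment's first sample;
  a trailing partial bin is dropped.  The binned amplitude estimates the
  square root of band power.
* **Despiking.** Bins exceeding 7× the channel median (per contiguous
  segment) are replaced by linear interpolation between the nearest unflagged
  neighbors (nearest value at edges).  Despiking operates on the binned
  envelope.
* **Z-scoring.** Where a feature family requires it, each channel is z-scored
  within consecutive 300 s windows (sample SD, ddof = 1), removing
  class-specific long-term mean and variance differences.

## Feature families and decoders

The decoding unit is a 30 s epoch (q channels × 120 bins) tiled within each
labeled 5-minute block; epochs crossing a recording gap are dropped.

| family     | envelope    | feature                        | decoder |
|------------|-------------|--------------------------------|---------|
| mean       | raw         | per-channel epoch mean         | linear SVM (one-vs-one) |
| variance   | raw         | per-channel epoch variance     | linear SVM |
| covariance | z-scored    | q×q epoch covariance           | MDM (Frobenius mean/distance) |
| slow       | z-scored    | mean analytic magnitude of the < 0.333 Hz band | linear SVM |
| fast       | z-scored    | mean analytic magnitude of the > 0.333 Hz band | linear SVM |
| gpfa       | z-scored    | latent trajectories (below)    | constrained QDA |

The SVM uses C = 1 (exposed in the config) with per-fold training-set
standardization.  MDM classifies a covariance to the class whose arithmetic
mean matrix is nearest in Frobenius distance; ties go deterministically to
the first class in sorted order and are logged.

**Cross-validation.** Time series are autocorrelated, so folds are seven
contiguous chronological blocks (sizes within one epoch of each other) and the
fold on each side of the test fold is excluded from training, keeping test and
training epochs at least one fold (≥ 5 min at the sizes used here) apart.
Training and test sets are class-balanced by seeded uniform subsampling
(balancing happens per train/test set, after fold assignment).  Every accuracy
is reported against the finite binomial chance level: the smallest accuracy
k*/n such that BinomCDF(k*; n, 1/n_classes) ≥ 1 − α, with α = 0.05 and n the
total balanced epoch count.  α = 0.05 reproduces the 29% (n = 320, 4 classes)
and 37% (n = 450, 3 classes) levels implied by the published per-class
durations.

**Welch PSDs** of the envelope use 120-bin (30 s) Hann windows with 75%
overlap sliding across each state's within-block data, zero-padded to 256
points at the 4 Hz envelope rate; the standard error is computed across the
individual periodograms before averaging.  Overlap is applied within each
contiguous labeled stretch (windows never span block or segment boundaries);
this is one of two defensible readings of "30-sec segments with 75% overlap"
and is the one that keeps every window label-pure.

## GPFA

Observation model: y_t | x_t ~ N(C x_t + d, R) with diagonal R; each latent
dimension across an epoch's T bins is a Gaussian process with squared-
exponential kernel K_i(t₁,t₂) = (1 − σₙ²) exp(−(t₁−t₂)²/2τ_i²) + σₙ²·1[t₁=t₂],
unit marginal variance, σₙ² = 10⁻³.  τ is the interpretable quantity: large τ
means a smooth, slowly drifting factor; τ near the bin width means an
effectively white factor.

* **E-step.** The posterior over all pT latents of an epoch is Gaussian with
  precision Λ = blockdiag(K_i⁻¹) + (CᵀR⁻¹C ⊗ structure over time); Λ is
  factorized once per iteration (it is shared by all equal-length epochs) and
  only the posterior mean is epoch-specific.  Nothing larger than pT × pT is
  ever built; the data log-likelihood uses the matrix-inversion lemma.
* **M-step.** C, d, R have the usual closed-form updates from the posterior
  moments.  Each τ_i is updated by numerically maximizing its expected
  log-likelihood term −½(E·log|K_i| + tr(K_i⁻¹ W_i)) over log τ (bounded
  Brent; bounds bin/2 to 100·T·bin ms), a generalized-EM step, so the
  recorded log-likelihood is monotone (tests assert this with 10⁻⁶ slack).
* **Initialization and stopping.** C, d, R start from a scikit-learn FA fit;
  τ starts on an octave ladder 500, 1000, 2000, … ms.  EM stops at a relative
  log-likelihood gain below tol (10⁻⁶ by default) or an iteration cap; the
  cap reached is recorded in a `converged` flag.  R is floored at 10⁻⁸× the
  channel variance.
* **Orthonormalization ("reduced GPFA").** C = U D Vᵀ; x̃ = D Vᵀ x satisfies
  U x̃ = C x exactly, and U's columns — orthonormal spatial factors ordered by
  covariance explained — make factors comparable and rankable.  Column signs
  are fixed so each column's largest-magnitude entry is positive.
* **Prediction error.** Leave-one-channel-out: latents are inferred from the
  other q − 1 channels and the held-out channel is predicted from them; RMSE
  is computed per behavioral class and summed ("class-balanced RMSE").
  Reduced GPFA predicts through the top-m orthonormalized factors of one
  larger fit.  Models are fit per fold on balanced training epochs and scored
  on the full test fold.
* **Decoding.** Vectorized latent epochs are classified by a Gaussian whose
  class mean is static in time (a tiled p-vector) and whose class covariance
  is block-diagonal with one shared p×p block per bin — equivalent to summing
  per-bin log-densities, which makes the (pT)-dimensional QDA tractable.
  Pooling one covariance across classes gives the LDA control.  Factors are
  refit per fold, sorted by fitted τ (slowest first), and evaluated
  incrementally from either end and one at a time (rank-aligned across
  folds).  Singular class covariances get a ridge of 10⁻⁶·trace/p.

## Synthetic data: what it emulates and what it does not

Each behavioral state plants, per 250 ms bin,
y_t = μ + diag(σ)(L(s·x_t) + ε_t) with GP latents x_t, i.i.d. unit-normal ε,
so channel means, variances, the covariance L diag(s²) Lᵀ + I, and the latent
timescales are all exactly known.  Latents are drawn independently per
5-minute block (one Cholesky per block rather than one over hours of bins);
epochs never span blocks, so within-epoch statistics are unaffected.  The
envelope is not clipped at zero by default, keeping the Gaussian ground truth
exact for oracle tests; raw synthesis (which needs a non-negative amplitude)
uses a clipping flag.

Raw recordings are built as envelope × band-limited unit-variance noise
carrier (white noise band-passed to 70–110 Hz), plus 1/f background noise,
line noise at 60 Hz and harmonics coherent across channels (one phase per
harmonic, as real mains pickup is — and so removable by a common average),
and sparse high-amplitude bursts.  Design choices that matter:

* The amplitude is held constant within each bin (zero-order hold), making
  the planted bin value exactly the within-bin mean amplitude.
* A stochastic 40 Hz-wide carrier has irreducible per-bin Rayleigh envelope
  noise of ~16% at 250 ms bins; the round-trip study conditions therefore
  plant a coefficient of variation of ~0.65 carried mostly by smooth factors,
  so recovery is limited by the additive noise, not the carrier construct.
* Bursts are lightly tapered in-band chirps (deterministic envelope) of
  exactly three bins, with onsets snapped to the bin grid and amplitude 10×
  the channel median envelope expressed on the raw envelope's own scale
  (× √(π/2) for a unit-variance carrier).  This guarantees each contaminated
  bin's averaged amplitude clearly exceeds the 7×-median despiking threshold,
  so the rule under test can both see and repair the artifact; a burst
  straddling a bin edge would dilute to ~4–6× the median — a large error
  invisible to the rule by construction.

What passing these tests shows: the chain, features, validation scheme, and
GPFA machinery are correct on data whose generating process matches the
models' assumptions.  What it does not show: robustness to non-Gaussian,
non-stationary physiology, movement artifacts, electrode drift, imperfect
behavioral labels, or volume conduction — none of which the generator
emulates.

## Study conditions (desk scale)

All canonical runs live in `hgstates.experiments` and are shared verbatim by
the analysis drivers, the test suite, and `scripts/acceptance.py`.

* **Feature families:** four states × six 5-minute blocks each (2 h, 240
  epochs, q = 12), all four differences planted; the shuffled-label null
  averages five independent permutations so its comparison to the chance
  level is stable.
* **Parameter recovery:** q = 12, p = 3, τ = {300, 1500, 8000} ms, 60 epochs
  of 120 bins, three independent datasets; pass = every τ within ±50% and
  loading subspace angle < 15° (observed: ≤ 7% and < 2°).
* **Model comparison:** two smooth-latent states (τ = 1–8 s), 100 epochs,
  dimensionalities 1–3, 7-fold buffered CV, EM capped at 60 iterations.
* **QDA/LDA control:** three covariance-only states, 180 epochs, q = 8,
  p = 4 factors refit per fold.
* **Round trip:** two deeply modulated states, 20 min at 512 Hz, q = 10,
  default noise, recovery through the no-reference chain (a common average
  deliberately removes the across-channel mean, so per-channel recovery is
  assessed without it).

Problem sizes and iteration caps are the package's desk-scale defaults; every
size is a keyword argument, and the same code runs at larger scale unchanged.

## Known limitations

* GPFA assumes equal epoch lengths within a fit (posterior covariance is
  shared); variable-length epochs would need per-length factorizations.
* The τ update fixes σₙ² rather than estimating it, following the reference
  convention for this kernel.
* The Welch overlap reading and the rejection-before/after-referencing order
  are documented choices among defensible alternatives, switchable by flags.
* EDF output is minimal (16-bit, 1 s records, one sampling rate); it reads
  back through mne but does not carry annotations or per-channel rates.
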
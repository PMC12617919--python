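# Methods

This package implements a computational chain that asks how the loss of
auditory-nerve fibers (ANFs) — cochlear nerve degeneration, CND — could
degrade word recognition under adverse listening conditions. The chain
has five stages: degraded-speech synthesis, an auditory-periphery
surrogate, population neurogram assembly under innervation profiles, a
spectro-temporal fidelity analysis, and neural-network word decoding,
plus a synthetic behavioral cohort that provides the human reference
statistics. This note records the model assumptions, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Stimuli

Real clinical word-recognition corpora are proprietary, so the package
synthesizes its own monosyllabic consonant-vowel-consonant (CVC) tokens:
a 50-entry lexicon combining 10 onsets, 10 two-formant vowels and 10
codas with coprime index strides, so words are spectrally distinct while
seeds of one word differ only in stochastic components (noise bursts,
aspiration). Durations are word-determined within 0.4–0.8 s. Tokens are
synthesized directly at 100 kHz, the input rate of the periphery model.

Each token is degraded the way difficult listening is emulated
clinically:

- **Time compression to 65%** of the original duration with a
  synchronized overlap-add algorithm. Implementation: 30-ms frames, 50%
  synthesis overlap with linear crossfade, and a ±10 ms *input-side*
  similarity search (the WSOLA formulation) — searching on the read
  position rather than the write position keeps the output duration
  exact while preserving pitch. Output is trimmed to
  `round(0.65 · n_samples)` samples.
- **Reverberation** by full linear convolution with a synthetic room
  impulse response: exponentially decaying white Gaussian noise whose
  backward-integrated energy falls 60 dB in T60 = 0.3 s; duration
  0.9 s, unit energy. One impulse response (per corpus seed) is shared
  by all words.
- **Noise**: zero-mean Gaussian noise at a prescribed SNR, one variant
  per SNR value — 11–30 dB in 1 dB steps for training (20 variants per
  word), −30–10 dB in 5 dB steps for testing (9 variants per word),
  which makes the train/test split 69%/31% by construction. Noise is
  added to the already-degraded token, and presentation level is set
  last, so the *mixture* is calibrated.
- **Level calibration** to 90 dB SPL: RMS = 20 µPa · 10^(90/20) =
  0.632 Pa.

The corpus object realizes items lazily (word base tokens are cached;
noise and level are applied on demand), and the item/partition/seed
table is a pure function of (spec, seed), so every CND condition reuses
exactly the same split.

## Auditory-periphery surrogate

The periphery is a phenomenological surrogate with a fixed contract:
given a calibrated waveform it returns instantaneous firing rate
(spikes/s) for any CF on a 71-channel logarithmic grid (125 Hz–16 kHz,
0.1 octave per step) and any of three spontaneous-rate (SR) classes,
sampled at 20 kHz (one sample per 50 µs neurogram bin). A published
full periphery implementation can be substituted behind the same
interface; all constants below are declared defaults of this surrogate,
not recovered values.

Stages:

1. **Middle ear**: 2nd-order Butterworth bandpass, 0.35–12 kHz.
2. **Cochlear filter**: 4th-order gammatone at human ERB bandwidth
   (Glasberg–Moore; b = 1.019·ERB(CF)), applied in the frequency
   domain — exact for this rational response and numerically stable at
   any CF/fs ratio, which time-domain IIR gammatones are not at
   100 kHz. Tuning is level-independent: outer-hair-cell function is
   normal (OHC = 1) in every condition here, so static tuning suffices;
   this is a deliberate simplification relative to level-dependent
   cochlear models.
3. **Inner hair cell**: arctangent nonlinearity with 3:1
   depolarizing/hyperpolarizing asymmetry, unit small-signal slope and
   zero resting output, followed by a 7th-order lowpass at 3 kHz (the
   phase-locking rolloff) and decimation to 20 kHz. Fine structure
   above the cutoff is removed; its envelope survives the rectifying
   asymmetry.
4. **Synapse**: the half-wave-rectified transduced drive u(t) is
   expressed as an instantaneous equivalent level
   l(t) = 20·log10(u(t)/(√2·20 µPa)), and the driven rate is
   R_class(l(t)), where R_class is a piecewise-linear rate-level
   function of that instantaneous level: threshold 0 dB SPL and 20 dB
   dynamic range with hard saturation (high-SR), 15/40 hard
   (medium-SR), 30/60 with sloping saturation of 0.5 spikes/s/dB
   beyond the dynamic range (low-SR); peak driven rate 300 spikes/s.
   Applying the saturating nonlinearity to the *instantaneous* drive —
   not to a smoothed envelope — matters: a fiber driven past its
   dynamic range is pegged at saturation for most of each cycle, so
   saturation destroys both envelope contrast and fine-structure
   contrast, which is precisely why saturated high-SR fibers are poor
   carriers of suprathreshold speech cues. (An earlier formulation that
   multiplied a saturating envelope gain onto a normalized
   fine-structure shape behaved like automatic gain control and made
   saturated fibers *more* noise-robust than unsaturated ones —
   qualitatively wrong.) The ladder produces the physiological
   crossover: high-SR fibers respond at low levels but saturate by
   ~60 dB SPL, low-SR fibers are silent below 30 dB but keep encoding
   level up to 90 dB.
5. **Adaptation**: two parallel exponential high-pass paths (fast
   τ = 10 ms, weight 0.5; slow τ = 1 s, weight 0.2) subtracted from the
   driven rate — an IIR approximation of power-law adaptation giving
   onset emphasis and offset suppression.
6. **Stochasticity**: fractional Gaussian noise (Hurst 0.9) added to
   spont + driven rate before half-wave rectification,
   rate = max(0, spont + driven + fGn). Spontaneous rates are the
   physiological class values (high 100, medium 5, low 0.1 spikes/s);
   fGn amplitudes (5, 1, 0.05 spikes/s) are scaled so the silence-rate
   coefficient of variation is largest for low-SR fibers while the mean
   silence rate recovers the nominal spont rate (rectification bias
   < 1%). fGn is generated by exact circulant embedding at 1 kHz and
   held to the 20-kHz grid — spont-rate variability is a slow process,
   and the held form lets the undriven window tail be evaluated at the
   slow rate with no approximation.

## Neurograms and CND profiles

A neurogram is the CF × time matrix of *summed* per-fiber rates — a sum
rather than a mean, so deafferentation reduces both pattern and
magnitude, matching the physical interpretation of synapse loss. The
innervation profiles are: normal = 2 low + 3 medium + 7 high-SR fibers
per CF (the classic distribution), high-SR-only = 0/0/7 (~42% loss),
severe = 0/0/3 (75% loss). Each fiber gets an independent fGn stream;
streams are drawn fiber-major from one per-class seeded generator, so a
profile with fewer fibers receives a prefix of the fuller profile's
draws and shared fibers are literally identical across conditions.

Decoder inputs use single presentations (no rep averaging) in a fixed
3.0-s window (60,000 bins of 50 µs; tokens onset-aligned, the remainder
of the window carrying spontaneous activity), then block-mean
time-downsampling by 100 (71 × 600 features). The downsampling factor
is a desk-scale choice: the full 71 × 60,000 input implies ~5·10⁸
weights for the wide decoder, which serves no scientific purpose here;
block-mean preserves the spectro-temporal envelope structure the
decoders exploit. The fidelity analysis instead uses rep-averaged
single-fiber-class neurograms over the token support only.

## Spectro-temporal fidelity

The acoustic reference is a continuous wavelet transform with
generalized Morse wavelets (symmetry γ = 3, time-bandwidth β = 20 —
standard near-symmetric analytic defaults), evaluated at the same 71
channel frequencies as the CF grid, real part half-wave rectified
(negative pressure has no firing-rate analogue), block-mean decimated
to the 50-µs grid.

Fidelity is the single 2D Pearson correlation between the wavelet
matrix W and the neurogram v over all (time, channel) cells, computed
*after* each CF row of the neurogram is shifted by the lag in
[0, 10 ms] that maximizes its normalized cross-correlation with the
corresponding wavelet row (compensation for the cochlear traveling-wave
delay; 10 ms covers the apical delay at 125 Hz). Ties resolve to the
smallest lag; constant rows are flagged degenerate and left unshifted;
a best lag at the search boundary raises a warning. After shifting,
both matrices are truncated to the common window and one global
correlation is taken — shifting-then-correlating (rather than averaging
per-channel correlations) keeps the printed 2D formula intact.

Group statistics: pairwise two-sample t-tests between SR classes at
each level, Benjamini–Hochberg adjusted across the whole table,
α = 0.05.

## Word decoders

Two fully connected architectures, fixed by design: NN1 = 5 hidden
layers × 128 ReLU units; NN2 = 16 × 32. Both use dropout 0.03 after
every hidden layer, a 25-way softmax output, Glorot-uniform
initialization, Adam at default settings (lr 10⁻³, β₁ 0.9, β₂ 0.999,
ε 10⁻⁷), sparse categorical cross-entropy, minibatch 32 with
reshuffling each epoch, and a fixed epoch budget (NN1 10, NN2 500) with
no early stopping. Features are z-scored per input dimension with
training-set statistics (zero-variance features pass through) — deep
narrow ReLU stacks do not train stably on raw rate units. The
implementation is plain numpy in float32 and is deterministic under a
fixed seed in single-threaded execution; per-epoch curves are recorded
by evaluating the full training set (and optionally the held-out set)
after each epoch with dropout off.

Evaluation reports percent correct, a true × predicted confusion
matrix, and accuracy within three SNR bins (10..0, −5..−15,
−20..−30 dB). The CND experiment trains one decoder per (architecture,
profile) on the identical split and compares profiles within
architecture.

## Synthetic cohort and behavioral bridge

The cohort generator emulates a cross-sectional sample of 395 adults:
ages uniform on [18, 80]; standard pure-tone average
PTA_St = 0.25·(age−18) + N(0, 7) dB HL; extended-high-frequency average
PTA_EHF = 5 + 0.80·(age−18) + N(0, 12) dB HL; word score
WRS_65% = 71.0 − 0.383·age − 0.10·PTA_St − 0.216·PTA_EHF + N(0, 12.9),
clipped to [0, 100] (the clip binds for well under 2% of listeners).
The coefficients were derived once, in closed form from the variance
budget, so that the population age-score correlation is ≈ −0.62 and
the adjusted R² of the three-predictor regression is ≈ 0.41 — the
published human values serve as calibration targets for the generator,
not as data; no real measurements enter the package.

The age → percent-ANF-survival map used for the model/human overlay is
a declared linear default (100% at age 0 to 25% at age 90),
configurable and never asserted as ground truth; model points sit at
the fiber-count survivals of the three profiles (100%, 58.3%, 25%).

## What the synthetic data do and do not show

The generator reproduces the *structure* of the study — spectrally
distinct CVC tokens, the degradation chain, SR-class physiology, the
correlation structure of the cohort — but not the content of real
speech or real listeners: no talker variability, coarticulation or
lexical statistics; formant vowels instead of natural voices; a
piecewise-linear rate-level ladder instead of fitted nonlinearities; no
efferent (medial olivocochlear) feedback, by design. Passing tests
therefore demonstrate that the pipeline's mechanics and its qualitative
predictions (level-dependent fidelity crossover, deafferentation-graded
decoding, architecture sensitivity) are implemented correctly — not
that the quantitative accuracies transfer to human materials.

## Numerical choices and problem sizes

- Periphery internals run in float32; fGn embedding lengths are padded
  to FFT-friendly sizes (the generated prefix is distributionally
  identical); neurogram assembly evaluates the undriven window tail at
  the fGn rate (exact, see above).
- Degenerate inputs: silent tokens raise on SNR/level operations;
  constant matrices raise on correlation; zero-variance features are
  passed through standardization unscaled.
- Desk-scale defaults used by the analysis scripts and tests: 10–25
  words, 20 fGn reps for fidelity (200 in the full protocol), NN2
  shortened to 200–300 epochs in the scaled deafferentation comparison
  (500 in the architecture-contrast run). These sizes are the package's
  own defaults for interactive use; all are parameters.

## Known limitations

- The periphery surrogate is calibrated qualitatively (orderings,
  saturation, spont rates), not against fiber-level datasets.
- The gammatone filterbank is level-independent; simulations involving
  hair-cell impairment would need a different backend (the config's
  OHC/IHC scalars exist but only the normal values are exercised).
- Circular FFT filtering can wrap a reverberation tail into the token
  onset; with the 0.9-s impulse response and padded windows the wrapped
  energy is ≥ 60 dB down and has no measurable effect.
- The fidelity analysis and the decoders share the periphery but not
  noise realizations; no attempt is made to model trial-by-trial human
  variability.
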
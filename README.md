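# cndspeech

Simulation pipeline linking **cochlear nerve degeneration (CND)** — the
loss of synapses between inner hair cells and auditory-nerve fibers
(ANFs) — to **word-recognition performance** under adverse listening
conditions. It is built for computational auditory neuroscientists and
audiology researchers who want a tested, desk-scale implementation of
the full chain:

1. **Degraded speech** — synthetic consonant-vowel-consonant word
   tokens, time-compressed to 65% of their duration (synchronized
   overlap-add), reverberated with a synthetic 0.3-s-decay room impulse
   response, mixed with Gaussian noise on SNR grids, calibrated in
   dB SPL.
2. **Auditory periphery** — a phenomenological surrogate producing
   instantaneous firing rate for fibers of the three spontaneous-rate
   (SR) classes (high 100, medium 5, low 0.1 spikes/s) at 71
   characteristic frequencies (125 Hz–16 kHz), with class-specific
   rate-level functions, power-law-style adaptation and fractional
   Gaussian noise.
3. **Neurograms** — CF × time firing-rate matrices (50-µs bins) under
   innervation profiles: normal (2 low + 3 medium + 7 high-SR fibers
   per CF), high-SR-only (0/0/7) and severe neural loss (0/0/3, ~75%
   fiber loss).
4. **Spectro-temporal fidelity** — the 2D Pearson correlation between a
   generalized-Morse-wavelet spectrogram W and the neurogram v,

       r = Σₘₙ (Wₘₙ − W̄)(vₘₙ − v̄) / √( Σₘₙ(Wₘₙ − W̄)² · Σₘₙ(vₘₙ − v̄)² ),

   after per-CF alignment for the cochlear traveling-wave delay.
5. **Word decoding** — two fully connected decoders on flattened
   neurograms (NN1: 5 × 128 ReLU; NN2: 16 × 32 ReLU; dropout 0.03,
   Adam, softmax over 25 words), evaluated per SNR bin and per CND
   profile.
6. **Behavioral bridge** — a synthetic listener cohort (age, standard
   and extended-high-frequency pure-tone averages, word scores) with
   the regression WRS₆₅% ~ Age + PTA_St + PTA_EHF, and an age →
   percent-ANF-survival mapping that places model and "human" scores on
   one axis.

The scientific claim the pipeline operationalizes: low- and medium-SR
fibers, though a minority, carry the suprathreshold speech cues that
survive noise and reverberation (high-SR fibers saturate at
conversational levels), so their selective loss — hidden from the
audiogram — degrades word recognition.

## Worked example

```python
import cndspeech as cs

# degrade one synthetic word and measure per-class encoding fidelity
df = cs.fidelity_experiment(cs.LEXICON[:4], levels_db_spl=(10.0, 90.0),
                            n_reps=8, seed=0)
print(df.groupby(["level_db_spl", "sr_class"]).r.mean().round(3))
```

prints (seed 0):

```
level_db_spl  sr_class
10.0          high        0.572
              low        -0.000
              medium      0.008
90.0          high        0.346
              low         0.682
              medium      0.497
```

At 10 dB SPL only the sensitive high-SR fibers encode the word (r 0.57;
low/medium-SR sit below threshold, r ≈ 0). At 90 dB SPL the ordering
reverses: high-SR fibers are saturated (r 0.35) while low-SR fibers
track the spectro-temporal structure best (r 0.68) — the level
crossover that motivates the CND hypothesis.

The numbered drivers under `analysis/` run the full chain at desk scale
and write tables to `results/`:

```bash
python analysis/01_build_corpus.py       # corpus manifest + calibrations
python analysis/02_fiber_fidelity.py     # fidelity x level x SR class
python analysis/03_train_decoders.py     # NN1/NN2 learning curves
python analysis/04_cnd_experiment.py     # accuracy x SNR bin x CND profile
python analysis/05_behavioral_overlay.py # cohort stats + survival overlay
```

## Layout

```
src/cndspeech/     audio, stimuli, fgn, periphery, neurogram,
                   fidelity, decoder, behavior
analysis/          numbered narrative drivers (write to results/)
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    model assumptions, parameters, design choices
```
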
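#!/usr/bin/env python
"""Assemble the degraded-speech corpus and verify its calibrations.

Builds the default 25-word synthetic CVC corpus (65% time compression,
0.3-s reverberation, noisy variants at 11-30 dB SNR for training and
-30..10 dB for testing, all presented at 90 dB SPL), writes the corpus
manifest, and reports the realized compression ratio, reverberation
decay and SNR accuracy of a few spot-checked items.
"""

from pathlib import Path

import numpy as np

from cndspeech.stimuli import CorpusSpec, build_corpus, schroeder_t60, synthesize_cvc_token, time_compress

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    corpus = build_corpus(CorpusSpec(), seed=0)
    manifest = corpus.manifest()
    manifest.to_csv(RESULTS / "corpus_manifest.csv", index=False)
    n_train, n_test = len(corpus.train_items), len(corpus.test_items)
    print(f"corpus: {n_train} train + {n_test} test items "
          f"({100 * n_train / (n_train + n_test):.0f}% / "
          f"{100 * n_test / (n_train + n_test):.0f}% split)")

    tok = synthesize_cvc_token(corpus.spec.lexicon[0], 100_000.0, seed=0)
    comp = time_compress(tok, corpus.spec.compress_ratio)
    print(f"compression: {100 * comp.duration / tok.duration:.1f}% of original duration")
    print(f"reverberation: Schroeder T60 = {schroeder_t60(corpus.rir):.3f} s (nominal 0.3)")

    for item in corpus.train_items[:3]:
        realized = corpus.realize(item)
        clean = corpus.base_token(item.word)
        scale = realized.rms / np.sqrt(np.mean((clean.samples / clean.rms) ** 2))  # noqa: F841
        noise = realized.samples - clean.samples * (
            np.dot(realized.samples, clean.samples) / np.dot(clean.samples, clean.samples))
        snr = 10 * np.log10(np.mean(realized.samples**2) / np.mean(noise**2) - 1)
        print(f"  {item.word} @ {item.snr_db:+.0f} dB nominal -> "
              f"{snr:+.1f} dB realized, level {realized.level_db_spl} dB SPL")
    print(f"manifest -> {RESULTS / 'corpus_manifest.csv'}")


if __name__ == "__main__":
    main()
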
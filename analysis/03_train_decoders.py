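#!/usr/bin/env python
"""Learning curves of the two word decoders on normal-innervation
neurograms.

Trains the shallow/wide network (NN1: 5 x 128 ReLU) and the deep/narrow
network (NN2: 16 x 32 ReLU) on flattened, time-downsampled neurograms of
the training grid and records per-epoch loss and accuracy. NN1 is
expected to converge within a few epochs; NN2 to learn slowly under its
capacity constraint.
"""

import time
from pathlib import Path

import pandas as pd

from cndspeech.decoder import DecoderConfig, neurogram_features, train_decoder
from cndspeech.neurogram import make_profile
from cndspeech.periphery import PeripheryConfig
from cndspeech.stimuli import CorpusSpec, build_corpus
from cndspeech.stimuli import LEXICON

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

N_WORDS = 10  # desk scale; the decoder experiment proper uses 25 words
EPOCHS = {"nn1": 10, "nn2": 200}


def main():
    t0 = time.time()
    corpus = build_corpus(CorpusSpec(lexicon=LEXICON[:N_WORDS]), seed=0)
    profile = make_profile("normal")
    X, y, _ = neurogram_features(corpus, corpus.train_items, [profile],
                                 PeripheryConfig(), seed=0, downsample=100)
    print(f"features: {X['normal'].shape} in {time.time() - t0:.0f} s")

    curves = []
    for arch in ("nn1", "nn2"):
        cfg = DecoderConfig(arch=arch, n_classes=N_WORDS, epochs=EPOCHS[arch], seed=0)
        trained = train_decoder(cfg, X["normal"], y)
        h = trained.history.assign(arch=arch)
        curves.append(h)
        print(f"{arch}: accuracy {100 * h.accuracy.iloc[0]:.0f}% (epoch 1) -> "
              f"{100 * h.accuracy.iloc[-1]:.0f}% (epoch {len(h)})")
    pd.concat(curves).to_csv(RESULTS / "learning_curves.csv", index=False)
    print(f"curves -> {RESULTS / 'learning_curves.csv'}")


if __name__ == "__main__":
    main()
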
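import numpy as np
import pytest

from cndspeech.audio import AudioToken
from cndspeech.stimuli import (
    LEXICON,
    Corpus,
    CorpusSpec,
    LexiconError,
    TruncationError,
    build_corpus,
    make_rir,
    reverberate,
    schroeder_t60,
    synthesize_cvc_token,
    time_compress,
)

FS = 20_000.0  # synthesis tests run at a light sampling rate


class TestSynthesis:
    def test_lexicon_has_50_distinct_words(self):
        assert len(LEXICON) == 50
        assert len(set(LEXICON)) == 50

    def test_deterministic_given_word_and_seed(self):
        a = synthesize_cvc_token(LEXICON[1], 100_000.0, seed=7)
        b = synthesize_cvc_token(LEXICON[1], 100_000.0, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_every_lexicon_token_duration_within_bounds(self):
        for word in LEXICON:
            tok = synthesize_cvc_token(word, FS, seed=0)
            assert 0.4 <= tok.duration <= 0.8

    def test_unknown_word_raises(self):
        with pytest.raises(LexiconError):
            synthesize_cvc_token("xyzzy", FS, seed=0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            synthesize_cvc_token(LEXICON[0], 8000.0, seed=0)

    def test_across_word_spectra_more_distinct_than_across_seeds(self):
        """Brute-force spectral oracle: mean pairwise log-spectrum L2 distance
        between different words must exceed the distance between seeds of one
        word, i.e. word identity dominates the stochastic components."""

        def log_spectrum(tok):
            n = int(0.4 * FS)
            spec = np.abs(np.fft.rfft(tok.samples[:n])) + 1e-9
            s = 20 * np.log10(spec)
            return s - s.mean()

        words = LEXICON[:25]
        specs = [log_spectrum(synthesize_cvc_token(w, FS, seed=0)) for w in words]
        across = [np.linalg.norm(specs[i] - specs[j])
                  for i in range(len(words)) for j in range(i + 1, len(words))]
        within = []
        for w in words[:8]:
            per_seed = [log_spectrum(synthesize_cvc_token(w, FS, seed=s)) for s in range(4)]
            within += [np.linalg.norm(per_seed[i] - per_seed[j])
                       for i in range(4) for j in range(i + 1, 4)]
        assert np.mean(across) > np.mean(within)


class TestTimeCompress:
    def test_65_percent_compression_duration(self):
        t = np.arange(int(1.0 * FS)) / FS
        tok = AudioToken(samples=np.sin(2 * np.pi * 150 * t) + 0.3 * np.sin(2 * np.pi * 450 * t), fs=FS)
        out = time_compress(tok, 0.65)
        assert out.duration == pytest.approx(0.650, abs=0.013)

    def test_ratio_one_is_identity(self):
        tok = synthesize_cvc_token(LEXICON[2], FS, seed=0)
        out = time_compress(tok, 1.0)
        assert np.array_equal(out.samples, tok.samples)

    def test_fundamental_preserved(self):
        """F0 via autocorrelation oracle: a 200 Hz vowel-like tone keeps its
        pitch under time-scale modification (it is not resampling)."""
        t = np.arange(int(0.8 * FS)) / FS
        x = sum(np.sin(2 * np.pi * 200 * k * t) / k for k in range(1, 5))
        out = time_compress(AudioToken(samples=x, fs=FS), 0.65)
        ac = np.correlate(out.samples, out.samples, mode="full")[len(out.samples) - 1:]
        lo, hi = int(FS / 300), int(FS / 120)  # plausible pitch lags
        f0 = FS / (lo + np.argmax(ac[lo:hi]))
        assert f0 == pytest.approx(200.0, rel=0.05)

    def test_invalid_ratio_raises(self):
        tok = synthesize_cvc_token(LEXICON[0], FS, seed=0)
        with pytest.raises(ValueError):
            time_compress(tok, 0.0)


class TestRoomImpulseResponse:
    def test_schroeder_t60_matches_nominal(self):
        rir = make_rir(0.3, FS, duration=0.9, seed=5)
        assert schroeder_t60(rir) == pytest.approx(0.3, rel=0.10)

    def test_tiny_decay_is_near_impulse(self):
        rir = make_rir(0.001, FS, duration=0.05, seed=5)
        e = rir.samples**2
        n5ms = int(0.005 * FS)
        assert e[:n5ms].sum() / e.sum() > 0.90

    def test_log_energy_slope_is_minus_60_over_t60(self):
        """Least-squares oracle on the smoothed log energy envelope."""
        t60 = 0.4
        rir = make_rir(t60, FS, duration=1.2, seed=2)
        win = int(0.01 * FS)
        e = np.convolve(rir.samples**2, np.ones(win) / win, mode="valid")
        t = np.arange(len(e)) / FS
        keep = slice(0, int(0.8 * len(e)))  # avoid the noisy tail
        slope = np.polyfit(t[keep], 10 * np.log10(e[keep] + 1e-30), 1)[0]
        assert slope == pytest.approx(-60.0 / t60, rel=0.10)

    def test_too_short_duration_raises(self):
        with pytest.raises(TruncationError):
            make_rir(0.3, FS, duration=0.4, seed=0)


class TestReverberate:
    def test_unit_impulse_identity(self):
        from cndspeech.stimuli import RoomImpulseResponse

        tok = synthesize_cvc_token(LEXICON[3], FS, seed=0)
        h = np.zeros(64)
        h[0] = 1.0
        rir = RoomImpulseResponse(samples=h, fs=FS, t60=0.0, seed=0)
        out = reverberate(tok, rir)
        assert np.allclose(out.samples[: len(tok.samples)], tok.samples, atol=1e-12)

    def test_full_convolution_length(self):
        from cndspeech.stimuli import RoomImpulseResponse

        tok = AudioToken(samples=np.random.default_rng(0).standard_normal(100), fs=FS)
        rir = RoomImpulseResponse(samples=np.random.default_rng(1).standard_normal(50), fs=FS, t60=0.1, seed=1)
        assert len(reverberate(tok, rir).samples) == 149

    def test_matches_naive_convolution_sum(self):
        from cndspeech.stimuli import RoomImpulseResponse

        rng = np.random.default_rng(7)
        x = rng.standard_normal(64)
        h = rng.standard_normal(64)
        out = reverberate(AudioToken(samples=x, fs=FS),
                          RoomImpulseResponse(samples=h, fs=FS, t60=0.1, seed=0)).samples
        naive = np.array([sum(x[j] * h[k - j] for j in range(max(0, k - 63), min(64, k + 1)))
                          for k in range(127)])
        assert np.max(np.abs(out - naive)) < 1e-9

    def test_rate_mismatch_raises(self):
        tok = synthesize_cvc_token(LEXICON[0], FS, seed=0)
        rir = make_rir(0.3, 2 * FS, seed=0)
        with pytest.raises(ValueError):
            reverberate(tok, rir)


class TestCorpus:
    def test_default_grid_counts_and_split_fraction(self):
        spec = CorpusSpec(fs=FS)
        corpus = build_corpus(spec, seed=0)
        assert len(corpus.train_items) == 25 * 20 == 500
        assert len(corpus.test_items) == 25 * 9 == 225
        frac = 100 * len(corpus.train_items) / len(corpus.items)
        assert frac == pytest.approx(69.0, abs=0.5)

    def test_two_word_corpus_scales_and_balances(self):
        spec = CorpusSpec(lexicon=LEXICON[:2], fs=FS)
        corpus = build_corpus(spec, seed=0)
        assert len(corpus.train_items) == 40 and len(corpus.test_items) == 18
        words = [it.word for it in corpus.train_items]
        assert words.count(LEXICON[0]) == words.count(LEXICON[1]) == 20

    def test_split_reproducible_across_builds(self):
        a = build_corpus(CorpusSpec(lexicon=LEXICON[:3], fs=FS), seed=4)
        b = build_corpus(CorpusSpec(lexicon=LEXICON[:3], fs=FS), seed=4)
        assert [(i.word, i.snr_db, i.partition, i.seed) for i in a.items] == \
               [(i.word, i.snr_db, i.partition, i.seed) for i in b.items]

    def test_train_and_test_grids_disjoint_else_warn(self):
        spec = CorpusSpec(lexicon=LEXICON[:2], train_snrs_db=(5, 10), test_snrs_db=(10, 20), fs=FS)
        with pytest.warns(UserWarning, match="overlap"):
            build_corpus(spec, seed=0)

    def test_realized_item_is_degraded_noisy_and_calibrated(self):
        spec = CorpusSpec(lexicon=LEXICON[:2], fs=FS)
        corpus = build_corpus(spec, seed=0)
        item = corpus.train_items[0]
        tok = corpus.realize(item)
        assert tok.level_db_spl == 90.0
        assert tok.rms == pytest.approx(20e-6 * 10**4.5, rel=1e-3)
        assert tok.snr_db == item.snr_db
        joined = " ".join(tok.lineage)
        for step in ["time_compress", "reverberate", "mix_noise", "set_level"]:
            assert step in joined

    def test_single_word_lexicon_rejected(self):
        with pytest.raises(ValueError):
            build_corpus(CorpusSpec(lexicon=LEXICON[:1], fs=FS), seed=0)
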
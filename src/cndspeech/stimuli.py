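"""Synthetic degraded-speech corpus: CVC tokens, SOLA time compression,
synthetic-room reverberation, noise mixing, and train/test organization.

The tokens are formant-synthesized consonant-vowel-consonant (CVC) words
standing in for a clinical monosyllabic corpus: a built-in 50-entry
lexicon combines a consonant inventory (plosive bursts, fricatives,
nasals) with a two-formant vowel inventory so that different words are
spectrally distinct while variants of one word (different seeds) differ
only in their stochastic noise components.

The degradation chain mirrors challenging-listening test conditions:
time compression to 65% of the original duration with a synchronous
overlap-add algorithm (duration changes, pitch does not), then
convolution with a synthetic room impulse response with a 0.3-s decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, fftconvolve, lfilter, sosfilt

from cndspeech.audio import AudioToken, SilentTokenError, mix_noise_at_snr, set_level


class LexiconError(KeyError):
    """Unknown word identifier."""


class TruncationError(ValueError):
    """Impulse-response duration too short for the requested decay."""


# --- synthetic CVC lexicon -------------------------------------------------

# consonant recipes: (kind, passband Hz, duration s, voiced)
_CONSONANTS = {
    "p": ("burst", (400, 1500), 0.035, False),
    "t": ("burst", (2500, 5000), 0.035, False),
    "k": ("burst", (1200, 2500), 0.040, False),
    "b": ("burst", (300, 1200), 0.045, True),
    "d": ("burst", (2000, 4000), 0.045, True),
    "g": ("burst", (1000, 2200), 0.050, True),
    "s": ("fric", (4000, 9000), 0.110, False),
    "sh": ("fric", (1800, 4500), 0.110, False),
    "f": ("fric", (1200, 8000), 0.090, False),
    "z": ("fric", (3500, 8000), 0.100, True),
    "m": ("nasal", (150, 450), 0.080, True),
    "n": ("nasal", (200, 600), 0.080, True),
}

# vowel formants (F1, F2) in Hz, loosely American-English monophthongs
_VOWELS = {
    "a": (730, 1090),
    "i": (270, 2290),
    "u": (300, 870),
    "e": (530, 1840),
    "ae": (660, 1720),
    "o": (570, 840),
    "ih": (390, 1990),
    "er": (490, 1350),
    "ow": (450, 1000),
    "uh": (640, 1190),
}

_ONSETS = ["p", "t", "k", "b", "d", "g", "s", "sh", "f", "m"]
_CODAS = ["t", "k", "s", "sh", "z", "n", "m", "d", "p", "f"]
_VORDER = list(_VOWELS)


def _build_lexicon(n: int = 50):
    """Deterministic 50-entry lexicon cycling through onsets/vowels/codas
    with coprime strides so consecutive entries share no segment."""
    words = []
    for k in range(n):
        c1, v, c2 = _segments(k)
        words.append(f"{c1}{v}{c2}")
    assert len(set(words)) == n
    return tuple(words)


def _segments(k: int):
    """Onset/vowel/coda for lexicon index k; the vowel index is shifted per
    block of ten so every (onset, vowel) pair in the lexicon is unique."""
    c1 = _ONSETS[k % 10]
    v = _VORDER[(k + k // 10) % 10]
    c2 = _CODAS[(7 * k + 2 + 3 * (k // 10)) % 10]
    return c1, v, c2


LEXICON = _build_lexicon()


def _word_spec(word: str):
    if word not in LEXICON:
        raise LexiconError(f"unknown word {word!r}; expected one of the built-in lexicon")
    k = LEXICON.index(word)
    c1, v, c2 = _segments(k)
    return k, c1, v, c2


def _resonator_sos(freq: float, bw: float, fs: float):
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * freq / fs
    # unity gain at the pole frequency
    b0 = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r) / np.sqrt(2 - 2 * np.cos(2 * theta)) if freq > 0 else (1 - r)
    return np.array([[b0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r]])


def _fade(x: np.ndarray, fs: float, t_fade: float = 0.005):
    n = min(int(t_fade * fs), len(x) // 2)
    if n > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, n)))
        x[:n] *= ramp
        x[-n:] *= ramp[::-1]
    return x


def _consonant(seg: str, fs: float, rng: np.random.Generator, f0: float):
    kind, band, dur, voiced = _CONSONANTS[seg]
    n = int(dur * fs)
    noise = rng.standard_normal(n)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, noise)
    if kind == "burst":
        env = np.exp(-np.arange(n) / (0.012 * fs))  # sharp transient
        x = x * env
    elif kind == "nasal":
        t = np.arange(n) / fs
        hum = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(4 * np.pi * f0 * t)
        x = 0.15 * x + hum
    if voiced and kind != "nasal":
        t = np.arange(n) / fs
        x = x * (0.75 + 0.25 * np.sign(np.sin(2 * np.pi * f0 * t)))
    x = x / (np.sqrt(np.mean(x**2)) + 1e-12)
    if kind == "burst":
        x *= 0.6
    return _fade(x, fs)


def _vowel(seg: str, fs: float, dur: float, f0: float, rng: np.random.Generator):
    f1, f2 = _VOWELS[seg]
    n = int(dur * fs)
    # glottal-like source: impulse train with decaying pulse shape + tiny jitter
    src = np.zeros(n)
    period = int(fs / f0)
    src[::period] = 1.0
    src = lfilter([1.0], [1.0, -0.985], src)  # integrate into decaying pulses
    src += 0.002 * rng.standard_normal(n)  # aspiration noise
    x = sosfilt(_resonator_sos(f1, 90.0, fs), src)
    x = x + 0.7 * sosfilt(_resonator_sos(f2, 120.0, fs), src)
    env = np.minimum(1.0, np.arange(n) / (0.03 * fs))
    env *= np.minimum(1.0, (n - np.arange(n)) / (0.05 * fs))
    x = x * env
    return x / (np.sqrt(np.mean(x**2)) + 1e-12)


def synthesize_cvc_token(word: str, fs: float = 100_000.0, seed: int = 0) -> AudioToken:
    """Synthesize one CVC token from the built-in lexicon.

    Deterministic given ``(word, seed)``; total duration lies in
    [0.4, 0.8] s and depends only on the word (so all seeds of one word
    align). Returns an RMS-normalized token (RMS = 1 Pa) ready for
    degradation and level calibration.
    """
    if fs < 16_000:
        raise ValueError("fs must be at least 16 kHz for CVC synthesis")
    k, c1, v, c2 = _word_spec(word)
    rng = np.random.default_rng(np.random.SeedSequence((seed, k)))
    f0 = 110.0 + 4.0 * (k % 7)  # per-word fundamental, 110-134 Hz
    vdur = 0.28 + 0.02 * (k % 9)  # 0.28-0.44 s vowel
    gap = int(0.015 * fs)
    parts = [
        _consonant(c1, fs, rng, f0),
        np.zeros(gap),
        _vowel(v, fs, vdur, f0, rng),
        np.zeros(gap),
        _consonant(c2, fs, rng, f0),
    ]
    lead = int(0.02 * fs)
    x = np.concatenate([np.zeros(lead)] + parts + [np.zeros(lead)])
    x = x / np.sqrt(np.mean(x**2))
    tok = AudioToken(samples=x, fs=fs, label=word, lineage=(f"synthesize(seed={seed})",))
    assert 0.4 <= tok.duration <= 0.8, f"token duration {tok.duration:.3f} s out of bounds"
    return tok


# --- SOLA time compression -------------------------------------------------

def time_compress(token: AudioToken, ratio: float) -> AudioToken:
    """Time-scale a token to ``ratio`` of its duration, preserving pitch.

    Synchronized overlap-add with an input-side similarity search
    (30-ms frames, 50% synthesis overlap, +/-10 ms cross-correlation
    window): each synthesis frame is read near its nominal analysis
    position at the offset that best continues the already-assembled
    output, then overlap-added with a linear crossfade. Output length is
    trimmed to round(ratio * input length) exactly.
    """
    if ratio <= 0:
        raise ValueError(f"compression ratio must be positive, got {ratio}")
    x = token.samples
    fs = token.fs
    if ratio == 1.0:
        return token.with_samples(x.copy(), "time_compress(1.0)")
    n_frame = int(0.030 * fs)
    ss = n_frame // 2  # synthesis hop, 50% overlap
    sa = ss / ratio  # analysis hop
    k_max = int(0.010 * fs)  # similarity search half-window
    out_len = int(round(len(x) * ratio))
    if len(x) < n_frame + sa + k_max:
        # too short for framewise processing; nothing to align
        return token.with_samples(x[:out_len].copy(), f"time_compress({ratio})")
    n_frames = int(np.ceil(out_len / ss)) + 1
    out = np.zeros(n_frames * ss + n_frame)
    wsum = np.zeros_like(out)
    ramp_in = np.linspace(0.0, 1.0, ss, endpoint=False)
    win = np.concatenate([ramp_in, ramp_in[::-1] + (1.0 / ss)])
    out[:n_frame] = x[:n_frame] * win
    wsum[:n_frame] = win
    for i in range(1, n_frames):
        pos = i * ss
        nominal = int(round(i * sa))
        lo = max(0, nominal - k_max)
        hi = min(len(x) - n_frame, nominal + k_max)
        if hi <= lo:
            break
        # natural continuation of the previous frame at this output hop
        prev = int(round((i - 1) * sa)) + ss
        ref = x[prev:prev + ss]
        if len(ref) < ss:
            break
        seg = x[lo:hi + ss]
        num = np.correlate(seg, ref, mode="valid")
        denom = np.sqrt(np.convolve(seg**2, np.ones(ss), mode="valid")[: len(num)] + 1e-12)
        best = lo + int(np.argmax(num / denom))
        frame = x[best:best + n_frame]
        out[pos:pos + n_frame] += frame * win
        wsum[pos:pos + n_frame] += win
    out = out[:out_len] / np.maximum(wsum[:out_len], 1e-8)
    return token.with_samples(out, f"time_compress({ratio})")


# --- reverberation ---------------------------------------------------------

@dataclass(frozen=True)
class RoomImpulseResponse:
    """Synthetic room impulse response: exponentially decaying Gaussian noise
    whose backward-integrated energy falls 60 dB in ``t60`` seconds."""

    samples: np.ndarray
    fs: float
    t60: float
    seed: int


def make_rir(t60: float, fs: float = 100_000.0, duration: float = 0.9, seed: int = 0) -> RoomImpulseResponse:
    if t60 <= 0:
        raise ValueError("t60 must be positive")
    if duration < 2 * t60:
        raise TruncationError(f"duration {duration} s < 2*t60 = {2 * t60} s")
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    # amplitude decay ln(1e3)/t60 per second == energy decay of 60 dB per t60
    h = rng.standard_normal(n) * np.exp(-(np.log(10.0 ** 3)) * t / t60)
    h /= np.sqrt(np.sum(h**2))
    return RoomImpulseResponse(samples=h, fs=float(fs), t60=float(t60), seed=int(seed))


def schroeder_t60(rir: RoomImpulseResponse, fit_db=(-5.0, -35.0)) -> float:
    """Estimate T60 by Schroeder backward integration: fit the decay curve
    on the ``fit_db`` segment and extrapolate to -60 dB."""
    e = np.cumsum(rir.samples[::-1] ** 2)[::-1]
    edb = 10 * np.log10(e / e[0] + 1e-300)
    t = np.arange(len(edb)) / rir.fs
    m = (edb <= fit_db[0]) & (edb >= fit_db[1])
    slope, _ = np.polyfit(t[m], edb[m], 1)
    return float(-60.0 / slope)


def reverberate(token: AudioToken, rir: RoomImpulseResponse) -> AudioToken:
    """Full linear convolution with the impulse response (len = n+m-1)."""
    if rir.fs != token.fs:
        raise ValueError(f"sample-rate mismatch: token {token.fs} Hz vs RIR {rir.fs} Hz")
    out = fftconvolve(token.samples, rir.samples, mode="full")
    return token.with_samples(out, f"reverberate(t60={rir.t60})")


# --- corpus ----------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Corpus layout: one noisy variant per SNR on each grid, so the default
    grids give 20 training and 9 test variants per word (a 69%/31% split)."""

    lexicon: tuple = LEXICON[:25]
    train_snrs_db: tuple = tuple(range(11, 31))  # 11..30 dB in 1 dB steps
    test_snrs_db: tuple = tuple(range(-30, 11, 5))  # -30..10 dB in 5 dB steps
    level_db_spl: float = 90.0
    compress_ratio: float = 0.65
    t60: float = 0.3
    fs: float = 100_000.0


@dataclass(frozen=True)
class CorpusItem:
    word: str
    snr_db: float
    partition: str  # "train" | "test"
    seed: int


class Corpus:
    """Lazily realized degraded-speech corpus.

    Each word is synthesized, time-compressed and reverberated once (the
    same impulse response for all words); noisy variants are realized on
    demand by adding seeded Gaussian noise and calibrating the mixture
    to the presentation level.
    """

    def __init__(self, spec: CorpusSpec, seed: int):
        if len(spec.lexicon) < 2:
            raise ValueError("lexicon must contain at least 2 words")
        overlap = set(spec.train_snrs_db) & set(spec.test_snrs_db)
        if overlap:
            warnings.warn(f"train/test SNR grids overlap at {sorted(overlap)} dB")
        self.spec = spec
        self.seed = int(seed)
        self.rir = make_rir(spec.t60, spec.fs, seed=seed + 1)
        self._base: dict[str, AudioToken] = {}
        items = []
        for wi, word in enumerate(spec.lexicon):
            for si, snr in enumerate(spec.train_snrs_db):
                items.append(CorpusItem(word, float(snr), "train", self._item_seed(0, wi, si)))
            for si, snr in enumerate(spec.test_snrs_db):
                items.append(CorpusItem(word, float(snr), "test", self._item_seed(1, wi, si)))
        self.items = tuple(items)

    def _item_seed(self, part: int, wi: int, si: int) -> int:
        return int(np.random.SeedSequence((self.seed, part, wi, si)).generate_state(1)[0] % (2**31))

    @property
    def train_items(self):
        return [it for it in self.items if it.partition == "train"]

    @property
    def test_items(self):
        return [it for it in self.items if it.partition == "test"]

    def base_token(self, word: str) -> AudioToken:
        """Clean degraded token (synthesized, compressed, reverberated)."""
        if word not in self._base:
            tok = synthesize_cvc_token(word, self.spec.fs, seed=self.seed)
            tok = time_compress(tok, self.spec.compress_ratio)
            tok = reverberate(tok, self.rir)
            self._base[word] = tok
        return self._base[word]

    def realize(self, item: CorpusItem) -> AudioToken:
        """Fully processed waveform for one corpus item (noise + level)."""
        tok = mix_noise_at_snr(self.base_token(item.word), item.snr_db, item.seed)
        return set_level(tok, self.spec.level_db_spl)

    def manifest(self):
        """Corpus manifest as a DataFrame (word, partition, SNR, seed)."""
        import pandas as pd

        return pd.DataFrame(
            [(it.word, it.partition, it.snr_db, it.seed) for it in self.items],
            columns=["word", "partition", "snr_db", "seed"],
        )


def build_corpus(spec: CorpusSpec, seed: int = 0) -> Corpus:
    """Assemble the corpus for a spec; the split (items and their seeds) is a
    pure function of (spec, seed) and is therefore identical across CND
    conditions that reuse the same corpus object or the same seed."""
    return Corpus(spec, seed)
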
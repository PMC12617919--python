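"""Acoustic-vs-neural spectro-temporal fidelity.

The acoustic reference is a generalized Morse wavelet spectrogram of the
calibrated waveform, computed on the same 71-channel logarithmic
frequency grid as the neurogram CFs, with the real part half-wave
rectified (negative-going pressure has no analogue in firing rate).
Fidelity is the single two-dimensional Pearson correlation

    r = sum_mn (W_mn - Wbar)(v_mn - vbar)
        / sqrt( sum_mn (W_mn - Wbar)^2 * sum_mn (v_mn - vbar)^2 )

computed after each CF row of the neurogram has been shifted by the lag
(within [0, max_lag]) that maximizes its normalized cross-correlation
with the corresponding wavelet row — compensating the cochlear
traveling-wave delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from cndspeech.audio import AudioToken, set_level
from cndspeech.neurogram import class_neurograms_multi
from cndspeech.periphery import SR_CLASSES, PeripheryConfig
from cndspeech.stimuli import make_rir, reverberate, synthesize_cvc_token, time_compress


class UndefinedCorrelationError(ValueError):
    """Correlation of a constant matrix is undefined."""


@dataclass(frozen=True)
class WaveletSpectrogram:
    """Half-wave-rectified real Morse-wavelet coefficients (Pa), one row
    per frequency channel on the neurogram grid."""

    W: np.ndarray
    channel_freqs: np.ndarray
    bin_s: float


def morse_wavelet_freq(freq_hz: np.ndarray, peak_hz: float,
                       gamma: float = 3.0, beta: float = 20.0) -> np.ndarray:
    """Frequency response of a generalized Morse wavelet with peak at
    ``peak_hz``, peak-normalized to 1 (analytic: zero at f <= 0)."""
    ratio = np.maximum(freq_hz, 0.0) / peak_hz
    with np.errstate(divide="ignore"):
        out = np.where(ratio > 0,
                       np.exp(beta * np.log(np.maximum(ratio, 1e-300))
                              + (beta / gamma) * (1.0 - ratio**gamma)),
                       0.0)
    return out


def morse_cwt(waveform: np.ndarray, fs: float, channel_freqs: np.ndarray,
              gamma: float = 3.0, beta: float = 20.0,
              out_fs: float = 20_000.0) -> WaveletSpectrogram:
    """Continuous wavelet transform with generalized Morse wavelets.

    One coefficient row per channel; the real part is half-wave
    rectified and block-mean decimated to the neurogram time grid.
    gamma = 3 (near-symmetric envelope) and beta = 20 are the defaults.
    """
    channel_freqs = np.asarray(channel_freqs, dtype=np.float64)
    if np.any(channel_freqs >= fs / 2) or np.any(channel_freqs <= 0):
        raise ValueError("channel frequencies must lie in (0, fs/2)")
    if fs % out_fs:
        raise ValueError("fs must be an integer multiple of out_fs")
    from scipy.fft import irfft, next_fast_len, rfft

    step = int(fs // out_fs)
    x = np.asarray(waveform, dtype=np.float64)
    n = len(x)
    n_out = n // step
    n_fast = next_fast_len(n, real=True)
    X = rfft(x, n=n_fast).astype(np.complex64)
    Psi = _wavelet_bank(n_fast, fs, tuple(channel_freqs), gamma, beta)
    rows = irfft(Psi * X, n=n_fast, axis=-1)[:, : n_out * step]
    np.maximum(rows, 0.0, out=rows)  # half-wave rectify the real part
    W = rows.reshape(len(channel_freqs), n_out, step).mean(axis=2, dtype=np.float64)
    return WaveletSpectrogram(W=W, channel_freqs=channel_freqs, bin_s=1.0 / out_fs)


_PSI_CACHE: dict = {}


def _wavelet_bank(n_fast: int, fs: float, freqs: tuple, gamma: float, beta: float):
    key = (n_fast, fs, freqs, gamma, beta)
    if _PSI_CACHE.get("key") != key:
        fgrid = np.fft.rfftfreq(n_fast, d=1.0 / fs)
        Psi = np.stack([morse_wavelet_freq(fgrid, fc, gamma, beta).astype(np.float32)
                        for fc in freqs])
        _PSI_CACHE.clear()
        _PSI_CACHE.update(key=key, Psi=Psi)
    return _PSI_CACHE["Psi"]


def align_lag(w_row: np.ndarray, v_row: np.ndarray, max_lag: float,
              fs: float) -> float:
    """Lag (s, in [0, max_lag]) maximizing the normalized cross-correlation
    of ``v_row`` (delayed, neural) against ``w_row`` (acoustic); ties go to
    the smallest lag, constant rows flag as degenerate with lag 0."""
    lags, _ = _align_rows(w_row[None, :], v_row[None, :], max_lag, fs)
    return float(lags[0] / fs)


def _align_rows(W: np.ndarray, V: np.ndarray, max_lag: float, fs: float):
    """Per-row best lags (in bins). Returns (lags, degenerate mask)."""
    if W.shape != V.shape:
        raise ValueError("matrices must share a shape")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    from scipy.signal import fftconvolve

    n = W.shape[1]
    L = min(int(round(max_lag * fs)), n - 1)
    m = n - L  # common comparison window
    W = np.asarray(W, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    w = W[:, :m] - W[:, :m].mean(axis=1, keepdims=True)
    wnorm = np.sqrt((w**2).sum(axis=1, keepdims=True))
    # numerator for every lag at once: since w is demeaned, the sliding-mean
    # term of the normalized cross-correlation vanishes
    cross = fftconvolve(V, w[:, ::-1], mode="full", axes=-1)[:, m - 1: m + L]
    # sliding second moments of the V windows via cumulative sums
    c1 = np.cumsum(np.concatenate([np.zeros((V.shape[0], 1)), V], axis=1), axis=1)
    c2 = np.cumsum(np.concatenate([np.zeros((V.shape[0], 1)), V**2], axis=1), axis=1)
    idx = np.arange(L + 1)
    s1 = c1[:, idx + m] - c1[:, idx]
    s2 = c2[:, idx + m] - c2[:, idx]
    vvar = np.maximum(s2 - s1**2 / m, 0.0)
    denom = wnorm * np.sqrt(vvar)
    c = np.where(denom > 1e-12, cross / np.where(denom > 1e-12, denom, 1.0), -np.inf)
    best = np.argmax(np.round(c, 12), axis=1)  # first max -> smallest lag on ties
    row_const = (np.ptp(W, axis=1) == 0) | (np.ptp(V, axis=1) == 0)
    best[row_const] = 0
    degenerate = row_const.copy()
    if L > 0 and np.any(best[~row_const] == L):
        warnings.warn("best alignment at the max_lag boundary; true delay may exceed range")
    return best, degenerate


def corr2d(W: np.ndarray, V: np.ndarray) -> float:
    """Two-dimensional Pearson correlation over all (time, channel) cells."""
    W = np.asarray(W, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if W.shape != V.shape:
        raise ValueError(f"shape mismatch: {W.shape} vs {V.shape}")
    dw = W - W.mean()
    dv = V - V.mean()
    den = np.sqrt((dw**2).sum() * (dv**2).sum())
    if den == 0:
        raise UndefinedCorrelationError("at least one matrix is constant")
    return float((dw * dv).sum() / den)


def align_and_correlate(W: np.ndarray, V: np.ndarray, max_lag: float,
                        fs: float):
    """Shift each neurogram row by its best lag, truncate both matrices to
    the common window, then take one global 2D correlation.

    Returns (r, lags_in_seconds).
    """
    lags, _ = _align_rows(W, V, max_lag, fs)
    n = W.shape[1]
    L = min(int(round(max_lag * fs)), n - 1)
    m = n - L
    Va = np.stack([V[i, lag:lag + m] for i, lag in enumerate(lags)])
    return corr2d(W[:, :m], Va), lags / fs


def fidelity_experiment(words, levels_db_spl=(10.0, 30.0, 50.0, 70.0, 90.0),
                        config: PeripheryConfig | None = None,
                        sr_classes=("low", "medium", "high"),
                        n_reps: int = 200, compress_ratio: float = 0.65,
                        t60: float = 0.3, max_lag: float = 0.010, seed: int = 0):
    """Fidelity analysis: per (word, presentation level, SR class), the 2D
    correlation between the degraded token's Morse spectrogram and the
    rep-averaged single-fiber-class neurogram, with per-CF lag alignment.

    Tokens are degraded (65% compression, 0.3-s reverberation; no added
    noise) and calibrated to each level before both the wavelet analysis
    and the periphery simulation. Returns a tidy DataFrame
    (word, level_db_spl, sr_class, r).
    """
    import pandas as pd

    if config is None:
        config = PeripheryConfig()
    rir = make_rir(t60, 100_000.0, seed=seed + 1)
    rows = []
    for wi, word in enumerate(words):
        tok = synthesize_cvc_token(word, 100_000.0, seed=seed)
        tok = reverberate(time_compress(tok, compress_ratio), rir)
        for level in levels_db_spl:
            tok_l = set_level(tok, level)
            Wsp = morse_cwt(tok_l.samples, tok_l.fs, config.cf_list, out_fs=config.fs_rate)
            word_seed = int(np.random.SeedSequence((seed, wi)).generate_state(1)[0] % 2**31)
            ngs = class_neurograms_multi(tok_l, sr_classes, config, n_reps=n_reps,
                                         seed=word_seed)
            for sr in sr_classes:
                ng = ngs[sr]
                n = min(Wsp.W.shape[1], ng.v.shape[1])
                r, _ = align_and_correlate(Wsp.W[:, :n], ng.v[:, :n], max_lag, config.fs_rate)
                rows.append((word, float(level), sr, r))
    return pd.DataFrame(rows, columns=["word", "level_db_spl", "sr_class", "r"])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def sr_group_stats(results) -> "pd.DataFrame":
    """Pairwise two-sample t-tests between SR classes at each level, with
    BH-adjusted p-values across the whole comparison table."""
    import pandas as pd

    classes = [c for c in SR_CLASSES if c in set(results["sr_class"])]
    if len(classes) < 2:
        raise ValueError("need at least two SR groups")
    rows = []
    for level, df_l in results.groupby("level_db_spl"):
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                ra = df_l.loc[df_l.sr_class == a, "r"].to_numpy()
                rb = df_l.loc[df_l.sr_class == b, "r"].to_numpy()
                if len(ra) < 3 or len(rb) < 3:
                    raise ValueError("need >= 3 words per group for the t-test")
                if np.ptp(ra) == 0 and np.ptp(rb) == 0 and np.allclose(ra.mean(), rb.mean()):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(ra, rb)
                rows.append((float(level), a, b, ra.mean() - rb.mean(), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["level_db_spl", "group_a", "group_b",
                                      "mean_diff", "t", "p"])
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p_adj"] < 0.05
    return out
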
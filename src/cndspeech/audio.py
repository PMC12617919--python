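"""Calibrated audio containers and level/noise utilities.

All waveforms are carried in Pascals.  Sound pressure level follows the
standard reference p0 = 20 uPa, so a token calibrated to L dB SPL has
RMS = 20e-6 * 10**(L/20) Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

P_REF = 20e-6  # Pa, reference pressure for dB SPL


class SilentTokenError(ValueError):
    """Raised when an operation needs a non-silent token (undefined SNR/level)."""


@dataclass(frozen=True)
class AudioToken:
    """A labelled mono waveform in Pascals.

    Parameters
    ----------
    samples : np.ndarray
        Mono pressure waveform, Pa.
    fs : float
        Sampling rate, Hz.
    label : str
        Word identifier.
    snr_db : float or None
        Nominal SNR of added noise, dB (None if no noise added).
    level_db_spl : float or None
        Calibrated presentation level, dB SPL (None before calibration).
    lineage : tuple of str
        Names of transforms applied so far, in order.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    snr_db: float | None = None
    level_db_spl: float | None = None
    lineage: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.fs

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples, transform: str, **meta) -> "AudioToken":
        return replace(
            self, samples=np.asarray(samples, dtype=np.float64),
            lineage=self.lineage + (transform,), **meta,
        )


def set_level(token: AudioToken, level_db_spl: float) -> AudioToken:
    """Scale a token so its RMS equals the target sound pressure level.

    Pure rescaling: waveform shape is preserved and the operation is
    idempotent for a fixed level.
    """
    rms = token.rms
    if rms == 0:
        raise SilentTokenError("cannot set the level of a silent token")
    target = P_REF * 10.0 ** (level_db_spl / 20.0)
    return token.with_samples(
        token.samples * (target / rms),
        f"set_level({level_db_spl})",
        level_db_spl=float(level_db_spl),
    )


def mix_noise_at_snr(token: AudioToken, snr_db: float, seed: int) -> AudioToken:
    """Add zero-mean Gaussian noise at a prescribed SNR.

    The noise RMS is set exactly from the signal RMS, so the realized
    10*log10(rms_signal^2 / rms_noise^2) equals ``snr_db`` up to the
    sampling fluctuation of the drawn noise (renormalized out here).
    """
    rms = token.rms
    if rms == 0:
        raise SilentTokenError("SNR is undefined for a silent token")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(token.samples))
    noise -= noise.mean()
    noise *= (rms / 10.0 ** (snr_db / 20.0)) / np.sqrt(np.mean(noise**2))
    return token.with_samples(
        token.samples + noise, f"mix_noise({snr_db} dB, seed={seed})", snr_db=float(snr_db)
    )


def resample_token(token: AudioToken, fs_new: float) -> AudioToken:
    """Resample by polyphase filtering (rational approximation of the ratio)."""
    if fs_new == token.fs:
        return token
    from fractions import Fraction

    frac = Fraction(int(round(fs_new)), int(round(token.fs))).limit_denominator(1000)
    out = resample_poly(token.samples, frac.numerator, frac.denominator)
    return replace(
        token, samples=out, fs=float(fs_new), lineage=token.lineage + (f"resample({fs_new})",)
    )


def write_wav(path, token: AudioToken) -> None:
    """Write a token as float32 WAV (values in Pa, not normalized)."""
    wavfile.write(path, int(round(token.fs)), token.samples.astype(np.float32))


def read_wav(path, label: str = "") -> AudioToken:
    """Read a mono WAV file; integer PCM is scaled to [-1, 1)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    return AudioToken(samples=np.asarray(data, dtype=np.float64), fs=float(fs), label=label,
                      lineage=(f"read_wav({path})",))
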
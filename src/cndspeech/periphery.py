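"""Phenomenological auditory-periphery surrogate.

Produces instantaneous firing rate (spikes/s) for an auditory-nerve
fiber of any characteristic frequency (CF) and spontaneous-rate (SR)
class. The processing chain is

    middle-ear bandpass -> gammatone cochlear filter -> inner-hair-cell
    transduction (asymmetric saturating nonlinearity + phase-locking
    lowpass) -> synapse (class-specific rate-level function, fast/slow
    adaptation, fractional Gaussian noise) -> rate

The three SR classes carry the physiological spontaneous rates
(high 100, medium 5, low 0.1 spikes/s) and a threshold / dynamic-range
ladder (high-SR fibers are the most sensitive but saturate first;
low-SR fibers have high thresholds, wide dynamic range and sloping
saturation). Outer- and inner-hair-cell scalars exist in the config but
are fixed at 1 (normal) in every analysis here: the experiments
manipulate neural survival, not hair-cell function.

The stage constants are declared surrogate defaults, not values
recovered from any published periphery implementation; the module's
contract (CF grid, SR classes, rate units, output sampling) is what the
downstream neurogram/fidelity/decoder stages rely on, so a full
published periphery model can be substituted behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import butter, lfilter, sosfilt

from cndspeech.audio import P_REF, AudioToken, resample_token
from cndspeech.fgn import sample_fgn


def cf_grid(n: int = 71, lo: float = 125.0, hi: float = 16_000.0) -> np.ndarray:
    """Geometric progression of characteristic frequencies from lo to hi
    inclusive (71 points over 125 Hz..16 kHz is a 0.1-octave grid)."""
    if n < 2:
        raise ValueError("need at least 2 characteristic frequencies")
    if not 0 < lo < hi:
        raise ValueError("require 0 < lo < hi")
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class SRClass:
    """One spontaneous-rate fiber class.

    threshold_db_spl and dynamic_range_db parameterize the rate-level
    function; ``saturation`` is "hard" (rate clamps at threshold + DR)
    or "sloping" (keeps growing slowly beyond DR). ``fgn_sigma`` scales
    the fGn so the silence-rate coefficient of variation is largest for
    low-SR fibers.
    """

    name: str
    spont_rate: float
    threshold_db_spl: float
    dynamic_range_db: float
    saturation: str = "hard"
    fgn_sigma: float = 1.0


SR_CLASSES = {
    "high": SRClass("high", 100.0, 0.0, 20.0, "hard", 5.0),
    "medium": SRClass("medium", 5.0, 15.0, 40.0, "hard", 1.0),
    "low": SRClass("low", 0.1, 30.0, 60.0, "sloping", 0.05),
}


@dataclass
class PeripheryConfig:
    cf_list: np.ndarray = field(default_factory=cf_grid)
    fs_in: float = 100_000.0  # model input rate, Hz
    fs_rate: float = 20_000.0  # rate-output rate (one sample per 50 us bin)
    ohc_scalar: float = 1.0
    ihc_scalar: float = 1.0
    lowpass_cutoff: float = 3_000.0  # phase-locking rolloff, Hz
    lowpass_order: int = 7
    ihc_scale: float = 0.5  # operating-point scale of the IHC nonlinearity (1/Pa)
    r_sat: float = 300.0  # peak driven rate at full dynamic range, spikes/s
    slope_ext: float = 0.5  # sp/s per dB beyond DR, sloping saturation only
    adapt_fast_tau: float = 0.010  # s
    adapt_slow_tau: float = 1.0  # s
    adapt_fast_frac: float = 0.5
    adapt_slow_frac: float = 0.2
    hurst: float = 0.9
    fgn_fs: float = 1_000.0  # fGn generation rate, Hz (held to fs_rate grid)
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self):
        cfs = np.asarray(self.cf_list, dtype=np.float64)
        if cfs.ndim != 1 or len(cfs) < 2 or np.any(np.diff(cfs) <= 0):
            raise ValueError("cf_list must be strictly increasing with >= 2 entries")
        self.cf_list = cfs
        if self.fs_in % self.fs_rate:
            raise ValueError("fs_in must be an integer multiple of fs_rate")
        if self.fs_rate % self.fgn_fs:
            raise ValueError("fs_rate must be an integer multiple of fgn_fs")

    @property
    def decim(self) -> int:
        return int(self.fs_in // self.fs_rate)

    @property
    def fgn_hold(self) -> int:
        return int(self.fs_rate // self.fgn_fs)


@dataclass(frozen=True)
class FiberResponse:
    """Instantaneous firing rate of one fiber (or rep-average thereof)."""

    rate: np.ndarray  # spikes/s, sampled at fs_rate
    cf: float
    sr_class: str
    seed: int
    fs: float = 20_000.0


# --- filter stages ---------------------------------------------------------

@lru_cache(maxsize=8)
def _middle_ear_sos(fs: float):
    return butter(2, [350.0, 12_000.0], btype="bandpass", fs=fs, output="sos")


def middle_ear(x: np.ndarray, fs: float) -> np.ndarray:
    """Minimal human middle-ear emphasis: 2nd-order bandpass 0.35-12 kHz."""
    return sosfilt(_middle_ear_sos(fs), x)


def erb_bandwidth(cf: float) -> float:
    """Glasberg-Moore equivalent rectangular bandwidth (Hz) at a CF."""
    return 24.7 * (4.37 * cf / 1000.0 + 1.0)


def gammatone_response(freq_hz: np.ndarray, cf: float, order: int = 4) -> np.ndarray:
    """One-sided frequency response of an order-4 gammatone filter at human
    ERB bandwidth, unit gain at CF."""
    b = 1.019 * erb_bandwidth(cf)
    return (1.0 + 1j * (freq_hz - cf) / b) ** (-order)


_H_CACHE: dict = {}


def _filterbank_matrix(n_fast: int, config: PeripheryConfig) -> np.ndarray:
    """Gammatone responses for the whole CF grid at one FFT length
    (complex64); cached because corpus variants of a word share a length."""
    key = (n_fast, config.cf_list.tobytes())
    if _H_CACHE.get("key") != key:
        f = np.fft.rfftfreq(n_fast, d=1.0 / config.fs_in).astype(np.float32)
        H = np.empty((len(config.cf_list), len(f)), dtype=np.complex64)
        for i, cf in enumerate(config.cf_list):
            b = np.float32(1.019 * erb_bandwidth(cf))
            t = 1.0 + 1j * (f - np.float32(cf)) / b
            t *= t  # t^2
            t *= t  # t^4
            H[i] = 1.0 / t
        _H_CACHE.clear()
        _H_CACHE.update(key=key, H=H)
    return _H_CACHE["H"]


def cochlear_channel(x: np.ndarray, cf: float, config: PeripheryConfig) -> np.ndarray:
    """Basilar-membrane surrogate: 4th-order gammatone at human ERB
    bandwidth, level-independent (hair-cell scalars are 1 throughout).
    Applied in the frequency domain, which is exact for these rational
    responses and numerically stable at any CF/fs ratio."""
    if not 20.0 <= cf < config.fs_in / 2:
        raise ValueError(f"cf {cf} Hz outside [20, fs/2) at fs={config.fs_in}")
    x = np.asarray(x, dtype=np.float64)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), d=1.0 / config.fs_in)
    return np.fft.irfft(X * gammatone_response(f, cf), n=len(x))


@lru_cache(maxsize=8)
def _ihc_lp_sos(order: int, cutoff: float, fs: float):
    return butter(order, cutoff, fs=fs, output="sos")


def ihc_stage(bm: np.ndarray, config: PeripheryConfig) -> np.ndarray:
    """Inner-hair-cell transduction.

    Asymmetric saturating nonlinearity (arctangent with a 3:1
    depolarizing/hyperpolarizing asymmetry, unit slope and zero output
    at rest) followed by a 7th-order lowpass at the phase-locking
    cutoff, then decimation to the rate sampling grid. Fine structure
    above the cutoff is removed while its envelope survives the
    nonlinearity.
    """
    bm = np.asarray(bm)
    if not np.all(np.isfinite(bm)):
        raise ValueError("non-finite basilar-membrane input")
    a = config.ihc_scale * config.ihc_scalar
    v = (2.0 / a) * (np.arctan(a * np.asarray(bm, dtype=np.float32) - 1.0) + np.float32(np.pi / 4))
    sos = _ihc_lp_sos(config.lowpass_order, config.lowpass_cutoff, config.fs_in)
    v = sosfilt(sos, v, axis=-1)
    return v[..., :: config.decim]


def _rate_level(level_db: np.ndarray, sr: SRClass, config: PeripheryConfig) -> np.ndarray:
    """Driven rate (spikes/s) as a function of equivalent drive level."""
    x = level_db - sr.threshold_db_spl
    driven = config.r_sat * np.clip(x / sr.dynamic_range_db, 0.0, 1.0)
    if sr.saturation == "sloping":
        driven = driven + config.slope_ext * np.maximum(x - sr.dynamic_range_db, 0.0)
    return driven


def _instantaneous_level(v: np.ndarray, config: PeripheryConfig) -> np.ndarray:
    """Instantaneous equivalent level (dB SPL) of the half-wave-rectified
    transduced drive.

    The rate-level nonlinearity is applied to this *instantaneous* level,
    so a fiber driven past its dynamic range is pegged at saturation for
    most of each cycle: saturation destroys both envelope contrast and
    fine-structure contrast, which is what makes saturated high-SR fibers
    poor carriers of suprathreshold speech cues.
    """
    u = np.maximum(np.asarray(v, dtype=np.float32), np.float32(1e-9))
    level = np.log10(u)
    level *= np.float32(20.0)
    level -= np.float32(20.0 * np.log10(np.sqrt(2.0) * P_REF))
    return level


def _adaptation(d: np.ndarray, config: PeripheryConfig) -> np.ndarray:
    """Two parallel exponential high-pass paths approximating power-law
    adaptation: onset gain 1, steady-state gain 1 - fast - slow."""
    out = d.copy()
    for tau, frac in ((config.adapt_fast_tau, config.adapt_fast_frac),
                      (config.adapt_slow_tau, config.adapt_slow_frac)):
        alpha = 1.0 - np.exp(-1.0 / (tau * config.fs_rate))
        out -= frac * lfilter([alpha], [1.0, -(1.0 - alpha)], d, axis=-1)
    return out


def driven_rate(v: np.ndarray, sr_class: str, config: PeripheryConfig) -> np.ndarray:
    """Deterministic adapted driven rate (no spont, no noise) from the
    transduced series; vectorized over leading axes."""
    sr = SR_CLASSES[sr_class] if isinstance(sr_class, str) else sr_class
    level = _instantaneous_level(v, config)
    return _adaptation(_rate_level(level, sr, config), config)


def driven_rates_multi(v: np.ndarray, sr_classes, config: PeripheryConfig) -> dict:
    """Adapted driven rates for several SR classes sharing one instantaneous
    drive-level computation (which is class-independent)."""
    level = _instantaneous_level(v, config)
    return {
        name: _adaptation(_rate_level(level, SR_CLASSES[name], config), config)
        for name in sr_classes
    }


def _fgn_on_rate_grid(n_bins: int, n_series: int, sigma: float,
                      config: PeripheryConfig, rng: np.random.Generator) -> np.ndarray:
    """fGn generated at the (slow) fgn rate and held to the rate grid."""
    hold = config.fgn_hold
    n_slow = -(-n_bins // hold)
    g = sample_fgn(n_slow, config.hurst, size=n_series, rng=rng)
    return np.repeat(sigma * g, hold, axis=-1)[:, :n_bins]


def synapse_stage(v: np.ndarray, sr_class: str, seed: int,
                  config: PeripheryConfig) -> np.ndarray:
    """Rate output of the synapse for one fiber:
    max(0, spont + adapted driven rate + fGn)."""
    sr = SR_CLASSES[sr_class] if isinstance(sr_class, str) else sr_class
    d = driven_rate(v, sr.name, config)
    rng = np.random.default_rng(seed)
    noise = _fgn_on_rate_grid(d.shape[-1], 1, sr.fgn_sigma, config, rng)[0]
    return np.maximum(0.0, sr.spont_rate + d + noise)


def fiber_response(token: AudioToken, cf: float, sr_class: str,
                   n_reps: int = 1, seed: int = 0,
                   config: PeripheryConfig | None = None) -> FiberResponse:
    """Full single-fiber chain, rate averaged over ``n_reps`` independent
    fGn seeds (the deterministic driven part is computed once)."""
    if config is None:
        config = PeripheryConfig()
    sr = SR_CLASSES[sr_class] if isinstance(sr_class, str) else sr_class
    if token.fs != config.fs_in:
        token = resample_token(token, config.fs_in)
    x = middle_ear(token.samples, config.fs_in)
    bm = cochlear_channel(x, cf, config)
    v = ihc_stage(bm, config)
    d = driven_rate(v, sr.name, config)
    class_id = list(SR_CLASSES).index(sr.name)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), class_id)))
    noise = _fgn_on_rate_grid(len(d), n_reps, sr.fgn_sigma, config, rng)
    rate = np.maximum(0.0, sr.spont_rate + d[None, :] + noise).mean(axis=0)
    return FiberResponse(rate=rate, cf=float(cf), sr_class=sr.name, seed=int(seed),
                         fs=config.fs_rate)


def transduced_channels(token: AudioToken, config: PeripheryConfig) -> np.ndarray:
    """Transduced (post-IHC) series for every CF in the grid, shape
    (n_cf, n_bins) at fs_rate; the shared front end for population
    neurograms."""
    if token.fs != config.fs_in:
        token = resample_token(token, config.fs_in)
    from scipy.fft import irfft, next_fast_len, rfft

    x = middle_ear(token.samples, config.fs_in)
    n = len(x)
    n_fast = next_fast_len(n, real=True)
    X = rfft(x, n=n_fast).astype(np.complex64)
    H = _filterbank_matrix(n_fast, config)
    bm = irfft(H * X, n=n_fast, axis=-1)[:, :n]
    return ihc_stage(bm, config)
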
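"""Population neurograms under cochlear-nerve-degeneration profiles.

A neurogram is a CF x time matrix of population firing rate: per CF, the
sum of the rates of the surviving fibers of each SR class (summing, not
averaging, so deafferentation reduces both pattern and magnitude). The
default window is 3.0 s at a 50-us bin width (60,000 bins): tokens are
onset-aligned at t = 0 and the remainder of the window carries the
model's spontaneous activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from cndspeech.audio import AudioToken
from cndspeech.fgn import sample_fgn
from cndspeech.periphery import (
    SR_CLASSES,
    PeripheryConfig,
    driven_rates_multi,
    transduced_channels,
)

NORMAL_COUNTS = (2, 3, 7)  # low, medium, high fibers per CF


@dataclass(frozen=True)
class CNDProfile:
    """Per-CF counts of surviving low-/medium-/high-SR fibers."""

    name: str
    n_low: int
    n_medium: int
    n_high: int

    def __post_init__(self):
        for c in (self.n_low, self.n_medium, self.n_high):
            if c < 0 or int(c) != c:
                raise ValueError(f"fiber counts must be non-negative integers, got {c}")

    @property
    def counts(self) -> dict:
        return {"low": self.n_low, "medium": self.n_medium, "high": self.n_high}

    @property
    def total(self) -> int:
        return self.n_low + self.n_medium + self.n_high

    @property
    def survival_percent(self) -> float:
        """Percent of the normal 12 fibers/CF that survive."""
        return 100.0 * self.total / sum(NORMAL_COUNTS)

    @property
    def loss_percent(self) -> float:
        return 100.0 - self.survival_percent


_PROFILES = {
    "normal": (2, 3, 7),
    "high_sr_only": (0, 0, 7),
    "severe": (0, 0, 3),
}


def make_profile(name: str, counts: tuple | None = None) -> CNDProfile:
    """Named innervation profile, or a custom one from explicit counts.

    normal = (2, 3, 7) low/medium/high fibers per CF; high_sr_only keeps
    only the 7 high-SR fibers; severe keeps 3 high-SR fibers (~75% loss).
    """
    if counts is None:
        if name not in _PROFILES:
            raise KeyError(f"unknown profile {name!r}; known: {sorted(_PROFILES)}")
        counts = _PROFILES[name]
    return CNDProfile(name, *counts)


@dataclass(frozen=True)
class Neurogram:
    """Firing-rate matrix: rows = CF channels, columns = 50-us time bins."""

    v: np.ndarray  # spikes/s, shape (n_cf, n_bins)
    cf_list: np.ndarray
    bin_s: float
    label: str = ""
    snr_db: float | None = None
    profile: str = ""

    @property
    def n_bins(self) -> int:
        return self.v.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_s


def _fiber_noise_slow(n_slow: int, config: PeripheryConfig,
                      rng: np.random.Generator, sigma: float, n_reps: int) -> np.ndarray:
    """fGn draws at the slow rate for one fiber, shape (n_reps, n_cf, n_slow)."""
    n_cf = len(config.cf_list)
    g = sample_fgn(n_slow, config.hurst, size=n_reps * n_cf, rng=rng)
    return sigma * g.reshape(n_reps, n_cf, n_slow)


def _class_rate_sum(d_active: np.ndarray, spont: float, g_slow: np.ndarray,
                    hold: int, n_bins: int) -> np.ndarray:
    """Summed rectified rate of a batch of fibers (axis 0 of ``g_slow``)
    sharing one driven rate; exact per-fiber rectification.

    The driven region is evaluated at the full rate; the undriven tail is
    evaluated at the slow fGn rate and held, which is identical to
    full-rate evaluation because the held noise is constant within each
    slow bin and the drive there is zero.
    """
    k, n_cf, _ = g_slow.shape
    n_act = d_active.shape[1]
    k_act = n_act // hold
    out = np.empty((n_cf, n_bins), dtype=np.float32)
    # broadcast the held (slow) noise against the full-rate drive without
    # materializing a repeated copy
    da = d_active.reshape(n_cf, k_act, hold)
    acc = np.maximum(np.float32(spont) + da + g_slow[0, :, :k_act, None], np.float32(0.0))
    for j in range(1, k):
        acc += np.maximum(np.float32(spont) + da + g_slow[j, :, :k_act, None], np.float32(0.0))
    out[:, :n_act] = acc.reshape(n_cf, n_act)
    if n_bins > n_act:
        tail = np.maximum(0.0, spont + g_slow[:, :, k_act:]).sum(axis=0)
        out[:, n_act:] = np.repeat(tail, hold, axis=-1)[:, : n_bins - n_act]
    return out


def _assemble(driven: dict, profile: CNDProfile, config: PeripheryConfig,
              seed: int, n_bins: int, n_reps: int) -> np.ndarray:
    hold = config.fgn_hold
    n_slow = -(-n_bins // hold)
    v = np.zeros((len(config.cf_list), n_bins), dtype=np.float32)
    for class_id, (name, sr) in enumerate(SR_CLASSES.items()):
        count = profile.counts[name]
        if count == 0:
            continue
        d = driven[name]
        n_act = min(-(-d.shape[1] // hold) * hold, n_bins)
        d_active = np.zeros((d.shape[0], n_act), dtype=np.float32)
        d_active[:, : min(d.shape[1], n_act)] = d[:, :n_act]
        # one seeded stream per class, fibers drawn fiber-major: a profile
        # with fewer fibers of a class receives a prefix of the draws a
        # fuller profile receives, so shared fibers get identical noise
        n_cf = len(config.cf_list)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), class_id)))
        g = sample_fgn(n_slow, config.hurst, size=count * n_reps * n_cf, rng=rng,
                       dtype=np.float32)
        g = (np.float32(sr.fgn_sigma) * g).reshape(count, n_reps, n_cf, n_slow)
        if n_reps == 1:
            v += _class_rate_sum(d_active, sr.spont_rate, g[:, 0], hold, n_bins)
        else:
            acc = np.zeros((n_cf, n_bins), dtype=np.float32)
            for rep in range(n_reps):
                acc += _class_rate_sum(d_active, sr.spont_rate, g[:, rep], hold, n_bins)
            v += acc / n_reps
    return v


def build_neurogram(token: AudioToken, profile: CNDProfile,
                    config: PeripheryConfig | None = None, seed: int = 0,
                    duration: float = 3.0, n_reps: int = 1) -> Neurogram:
    """Population neurogram for one token under one innervation profile.

    Per-fiber fGn seeds are derived by counter from (seed, class, fiber
    index), so fibers shared between two profiles (e.g. the 3 high-SR
    fibers of the severe profile and the first 3 of normal) receive
    identical noise, and the build is bit-reproducible.
    """
    return build_neurograms_multi(token, [profile], config, seed, duration, n_reps)[profile.name]


def build_neurograms_multi(token: AudioToken, profiles,
                           config: PeripheryConfig | None = None, seed: int = 0,
                           duration: float = 3.0, n_reps: int = 1) -> dict:
    """Neurograms for several profiles sharing one front-end computation
    (the deterministic driven rates are profile-independent)."""
    if config is None:
        config = PeripheryConfig()
    n_bins = int(round(duration * config.fs_rate))
    needed = {name for p in profiles for name, c in p.counts.items() if c > 0}
    driven: dict[str, np.ndarray] = {}
    if needed:
        v_t = transduced_channels(token, config)
        if v_t.shape[1] > n_bins:
            warnings.warn(
                f"token ({v_t.shape[1]} bins) longer than the {n_bins}-bin window; truncating"
            )
            v_t = v_t[:, :n_bins]
        driven = driven_rates_multi(v_t, needed, config)
    out = {}
    for profile in profiles:
        v = _assemble(driven, profile, config, seed, n_bins, n_reps)
        out[profile.name] = Neurogram(
            v=v, cf_list=config.cf_list, bin_s=1.0 / config.fs_rate,
            label=token.label, snr_db=token.snr_db, profile=profile.name,
        )
    return out


def class_neurogram(token: AudioToken, sr_class: str,
                    config: PeripheryConfig | None = None,
                    n_reps: int = 200, seed: int = 0) -> Neurogram:
    """Mean single-fiber neurogram for one SR class (rep-averaged over
    independent fGn seeds), covering the token duration only — the unit
    of the spectro-temporal fidelity analysis."""
    return class_neurograms_multi(token, [sr_class], config, n_reps, seed)[sr_class]


def class_neurograms_multi(token: AudioToken, sr_classes,
                           config: PeripheryConfig | None = None,
                           n_reps: int = 200, seed: int = 0) -> dict:
    """Mean single-fiber neurograms for several SR classes sharing the
    cochlear/IHC front end and envelope decomposition."""
    if config is None:
        config = PeripheryConfig()
    v_t = transduced_channels(token, config)
    driven = driven_rates_multi(v_t, sr_classes, config)
    hold = config.fgn_hold
    out = {}
    for sr_class in sr_classes:
        sr = SR_CLASSES[sr_class]
        d = driven[sr_class]
        n_bins = d.shape[1]
        n_act = -(-n_bins // hold) * hold
        d32 = np.zeros((d.shape[0], n_act), dtype=np.float32)
        d32[:, :n_bins] = d
        class_id = list(SR_CLASSES).index(sr_class)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), class_id)))
        acc = np.zeros((d.shape[0], n_bins))
        done = 0
        while done < n_reps:  # rep chunks bound transient memory
            chunk = min(16, n_reps - done)
            g = _fiber_noise_slow(n_act // hold, config, rng, sr.fgn_sigma, chunk)
            acc += _class_rate_sum(d32, sr.spont_rate, g.astype(np.float32),
                                   hold, n_act)[:, :n_bins]
            done += chunk
        out[sr_class] = Neurogram(
            v=acc / n_reps, cf_list=config.cf_list, bin_s=1.0 / config.fs_rate,
            label=token.label, snr_db=token.snr_db, profile=f"single_{sr_class}")
    return out


def downsample_neurogram(ng: Neurogram, factor: int) -> Neurogram:
    """Block-mean over time by an integer factor that divides the bin count;
    rate units (spikes/s) and the global mean are preserved exactly."""
    if factor == 1:
        return ng
    if factor <= 0 or ng.n_bins % factor:
        raise ValueError(f"factor {factor} must be a positive divisor of {ng.n_bins} bins")
    v = ng.v.reshape(ng.v.shape[0], ng.n_bins // factor, factor).mean(axis=-1)
    return replace(ng, v=v, bin_s=ng.bin_s * factor)
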
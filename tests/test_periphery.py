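import numpy as np
import pytest

from cndspeech.audio import AudioToken, set_level
from cndspeech.periphery import (
    SR_CLASSES,
    PeripheryConfig,
    cf_grid,
    cochlear_channel,
    fiber_response,
    ihc_stage,
    middle_ear,
    synapse_stage,
    driven_rate,
)

from conftest import tone_token


class TestCFGrid:
    def test_printed_grid_71_channels_125_to_16k(self):
        g = cf_grid(71, 125.0, 16_000.0)
        assert len(g) == 71
        assert g[0] == pytest.approx(125.0)
        assert g[-1] == pytest.approx(16_000.0)

    def test_two_point_grid_is_endpoints(self):
        assert np.allclose(cf_grid(2, 125.0, 16_000.0), [125.0, 16_000.0])

    def test_consecutive_ratio_is_tenth_octave(self):
        # 16000/125 = 2^7 over 70 steps -> constant ratio 2^0.1
        g = cf_grid(71, 125.0, 16_000.0)
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, 2**0.1, rtol=1e-12)

    def test_bad_arguments_raise(self):
        with pytest.raises(ValueError):
            cf_grid(1, 125.0, 16_000.0)
        with pytest.raises(ValueError):
            cf_grid(5, 1000.0, 100.0)


class TestCochlearChannel:
    def test_on_cf_channel_has_maximal_rms(self, default_config):
        cfs = default_config.cf_list
        tok = tone_token(cfs[30])
        rms = [np.sqrt(np.mean(cochlear_channel(tok.samples, cf, default_config)[2000:] ** 2))
               for cf in cfs]
        assert int(np.argmax(rms)) == 30

    def test_silence_gives_zero(self, default_config):
        out = cochlear_channel(np.zeros(1000), 1000.0, default_config)
        assert np.allclose(out, 0.0)

    def test_octave_below_rejected_by_20_db(self, default_config):
        cf = float(default_config.cf_list[30])
        on = cochlear_channel(tone_token(cf).samples, cf, default_config)
        off = cochlear_channel(tone_token(cf / 2).samples, cf, default_config)
        # steady-state portion, away from onset transients
        ratio = np.sqrt(np.mean(on[5000:-5000] ** 2) / np.mean(off[5000:-5000] ** 2))
        assert 20 * np.log10(ratio) > 20.0

    def test_cf_out_of_range_raises(self, default_config):
        with pytest.raises(ValueError):
            cochlear_channel(np.zeros(100), 10.0, default_config)
        with pytest.raises(ValueError):
            cochlear_channel(np.zeros(100), 60_000.0, default_config)


class TestIHCStage:
    def test_zero_input_constant_resting_output(self, default_config):
        out = ihc_stage(np.zeros(5000), default_config)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_asymmetric_transduction(self, default_config):
        x = 0.5 * np.ones(2000)
        up = ihc_stage(x, default_config)[-10:]
        down = ihc_stage(-x, default_config)[-10:]
        assert not np.allclose(np.abs(up), np.abs(down), rtol=0.05)

    def test_am_envelope_passes_carrier_blocked(self, default_config):
        """8 kHz carrier with 100 Hz AM: the modulation survives transduction
        while the carrier falls by far more than 20 dB (phase-locking rolloff)."""
        fs = default_config.fs_in
        t = np.arange(int(0.5 * fs)) / fs
        x = (1 + 0.8 * np.sin(2 * np.pi * 100 * t)) * np.sin(2 * np.pi * 8000 * t)
        v = ihc_stage(x, default_config)
        fs_out = default_config.fs_rate
        spec = np.abs(np.fft.rfft(v - v.mean()))
        f = np.fft.rfftfreq(len(v), 1 / fs_out)
        in_spec = np.abs(np.fft.rfft(x - x.mean()))
        fin = np.fft.rfftfreq(len(x), 1 / fs)

        def band(freqs, spectrum, f0):
            return spectrum[(freqs > f0 * 0.95) & (freqs < f0 * 1.05)].max()

        out_ratio = band(f, spec, 8000.0) / band(f, spec, 100.0)
        in_ratio = band(fin, in_spec, 8000.0) / band(fin, in_spec, 100.0)
        assert band(f, spec, 100.0) > 0
        assert 20 * np.log10(in_ratio / out_ratio) > 20.0


class TestSynapse:
    def test_silence_recovers_nominal_spont_rates(self, silence_1s, default_config):
        """The three printed spontaneous rates re-emerge as the mean model
        output in quiet (rep-averaged over independent fGn seeds)."""
        means = {}
        for name, tol in [("high", 0.10), ("medium", 0.20)]:
            rates = [fiber_response(silence_1s, 1000.0, name, n_reps=1, seed=s).rate.mean()
                     for s in range(20)]
            means[name] = np.mean(rates)
            nominal = SR_CLASSES[name].spont_rate
            assert means[name] == pytest.approx(nominal, rel=tol)
        low = np.mean([fiber_response(silence_1s, 1000.0, "low", n_reps=1, seed=s).rate.mean()
                       for s in range(20)])
        assert low == pytest.approx(SR_CLASSES["low"].spont_rate, abs=0.1)

    def test_threshold_and_dynamic_range_ladder(self):
        th = {n: c.threshold_db_spl for n, c in SR_CLASSES.items()}
        dr = {n: c.dynamic_range_db for n, c in SR_CLASSES.items()}
        assert th["high"] < th["medium"] < th["low"]
        assert dr["low"] > dr["high"]
        sp = {n: c.spont_rate for n, c in SR_CLASSES.items()}
        assert sp["high"] == 100.0 > sp["medium"] == 5.0 > sp["low"] == 0.1

    def test_onset_adaptation(self, default_config):
        tok = set_level(tone_token(1000.0, dur=0.4, fade=0.001), 60.0)
        fr = fiber_response(tok, 1000.0, "high", n_reps=8, seed=0)
        fs = default_config.fs_rate
        onset = fr.rate[: int(0.010 * fs)].mean()
        steady = fr.rate[-int(0.110 * fs):-int(0.010 * fs)].mean()
        assert onset > steady

    def test_rate_level_saturation_and_growth(self, default_config):
        """High-SR fibers saturate by 60 dB SPL (mean driven rate changes
        < 5% from 60 to 90 dB); low-SR fibers keep growing from 30 to 90 dB."""
        def mean_rate(cls, level):
            tok = set_level(tone_token(1000.0, dur=0.3), level)
            fr = fiber_response(tok, 1000.0, cls, n_reps=4, seed=1)
            return fr.rate[2000:].mean()

        h60, h90 = mean_rate("high", 60.0), mean_rate("high", 90.0)
        assert abs(h90 - h60) / h60 < 0.05
        lows = [mean_rate("low", L) for L in (30.0, 45.0, 60.0, 75.0, 90.0)]
        assert all(b > a for a, b in zip(lows, lows[1:]))

    def test_rates_nonnegative_and_finite(self, default_config):
        tok = set_level(tone_token(500.0, dur=0.2), 100.0)
        for cls in SR_CLASSES:
            fr = fiber_response(tok, 500.0, cls, n_reps=1, seed=2)
            assert np.all(np.isfinite(fr.rate))
            assert np.all(fr.rate >= 0)

    def test_rep_averaging_reduces_variance(self, silence_1s):
        """Across seed batches the variance of the rep-averaged rate shrinks
        roughly like 1/n_reps."""
        def batch_var(n_reps):
            means = [fiber_response(silence_1s, 1000.0, "high", n_reps=n_reps,
                                    seed=100 + s).rate[:2000].mean() for s in range(12)]
            return np.var(means)

        v1, v16 = batch_var(1), batch_var(16)
        assert v16 < v1 / 4

    def test_unknown_class_raises(self, default_config):
        with pytest.raises(KeyError):
            synapse_stage(np.zeros(100), "ultra", seed=0, config=default_config)

    def test_deterministic_given_seed(self, silence_1s):
        a = fiber_response(silence_1s, 2000.0, "medium", n_reps=2, seed=5)
        b = fiber_response(silence_1s, 2000.0, "medium", n_reps=2, seed=5)
        assert np.array_equal(a.rate, b.rate)


def test_middle_ear_band_emphasis(default_config):
    fs = default_config.fs_in
    def gain(freq):
        x = tone_token(freq, dur=0.2).samples
        return np.sqrt(np.mean(middle_ear(x, fs)[5000:] ** 2))
    assert gain(2000.0) > gain(100.0)
    assert gain(2000.0) > gain(30_000.0)


def test_config_validation():
    with pytest.raises(ValueError):
        PeripheryConfig(cf_list=np.array([500.0, 400.0]))
    with pytest.raises(ValueError):
        PeripheryConfig(fs_in=100_000.0, fs_rate=30_000.0)
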
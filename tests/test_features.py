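"""Feature extraction: gammatone descriptors, temporal stats, MFCCs."""

import numpy as np
import pytest

from clipsim import features, synth
from conftest import make_tone


class TestGammatone:
    def test_silence_gives_zero_energy(self):
        clip = synth.AudioClip(np.zeros(int(0.4 * synth.RATE_HZ)), synth.RATE_HZ, "s")
        e, cf = features.gammatone_decompose(clip)
        assert np.allclose(e, 0.0)
        assert cf[0] == pytest.approx(26.0, rel=1e-6)

    def test_tone_peaks_in_nearest_band(self):
        e, cf = features.gammatone_decompose(make_tone(1000.0))
        peak_cf = cf[np.argmax(e.mean(axis=1))]
        nearest = cf[np.argmin(np.abs(cf - 1000.0))]
        assert peak_cf == nearest

    def test_frame_count_follows_framing_arithmetic(self):
        clip = make_tone(440.0, duration_s=0.8)
        e, _ = features.gammatone_decompose(clip)
        w, h = 1102, 551
        assert e.shape[1] == (len(clip.samples) - w) // h + 1

    def test_too_short_clip_rejected(self):
        clip = synth.AudioClip(np.zeros(500), synth.RATE_HZ, "tiny")
        with pytest.raises(ValueError, match="frame"):
            features.gammatone_decompose(clip)


class TestSpectralDescriptors:
    def test_flat_spectrum_flatness_and_crest_one(self):
        e = np.ones((16, 5))
        d = features.spectral_descriptors(e, np.linspace(100, 8000, 16))
        assert np.allclose(d["flatness"], 1.0)
        assert np.allclose(d["crest"], 1.0)

    def test_single_band_zero_spread_centroid_at_band(self):
        e = np.zeros((16, 4))
        e[5] = 2.0
        cf = np.linspace(100, 8000, 16)
        d = features.spectral_descriptors(e, cf)
        assert np.allclose(d["spread"], 0.0)
        assert np.allclose(d["centroid"], cf[5])

    def test_identical_consecutive_frames_zero_variation(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0.1, 1, 16)
        e = np.tile(col[:, None], (1, 6))
        d = features.spectral_descriptors(e, np.linspace(100, 8000, 16))
        assert np.allclose(d["variation"][1:], 0.0, atol=1e-12)

    def test_zero_frames_flagged_undefined(self):
        e = np.ones((16, 4))
        e[:, 2] = 0.0
        d = features.spectral_descriptors(e, np.linspace(100, 8000, 16))
        assert np.isnan(d["centroid"][2])
        assert np.isnan(d["variation"][2]) and np.isnan(d["variation"][3])


class TestTemporalDescriptors:
    def test_am_tone_modulation_frequency(self):
        spec = synth.ClipSpec("am", "x", 2000, 0.8, (1000.0,), (1.0,),
                              am_rate=4.0, am_depth=0.9)
        clip = synth.generate_clip(spec, seed=3)
        d = features.temporal_descriptors(clip)
        assert d["mod_freq"] == pytest.approx(4.0, abs=0.5)
        assert d["mod_amp"] > 0

    def test_pure_tone_zero_crossing_rate(self):
        d = features.temporal_descriptors(make_tone(1000.0))
        assert d["zcr_median"] == pytest.approx(2000.0, rel=0.01)

    def test_constant_signal_zero_crossings(self):
        clip = synth.AudioClip(np.full(int(0.8 * synth.RATE_HZ), 0.5),
                               synth.RATE_HZ, "c")
        d = features.temporal_descriptors(clip)
        assert d["zcr_median"] == 0.0 and d["zcr_iqr"] == 0.0

    def test_silence_maps_to_zeros(self):
        clip = synth.AudioClip(np.zeros(int(0.4 * synth.RATE_HZ)), synth.RATE_HZ, "s")
        d = features.temporal_descriptors(clip)
        assert d == {"mod_freq": 0.0, "mod_amp": 0.0,
                     "zcr_median": 0.0, "zcr_iqr": 0.0}


class TestExtractTT:
    def test_exactly_24_finite_entries(self, stimulus_set):
        vec = features.extract_tt(stimulus_set.clips[0])
        assert len(vec.values) == 24
        assert list(vec.values) == list(features.TT_FEATURE_NAMES)
        assert all(np.isfinite(v) for v in vec.values.values())

    def test_stationary_tone_has_near_zero_spectral_iqrs(self):
        vec = features.extract_tt(make_tone(440.0))
        for name in ("centroid", "spread", "flatness", "crest"):
            med = abs(vec.values[f"tt.{name}.median"])
            assert vec.values[f"tt.{name}.iqr"] <= 0.05 * med + 1e-6

    def test_gain_invariance_of_normalized_descriptors(self):
        tone = make_tone(440.0)
        half = synth.AudioClip(tone.samples * 0.5, tone.rate_hz, "half")
        a = features.extract_tt(tone).values
        b = features.extract_tt(half).values
        for name in ("tt.centroid.median", "tt.flatness.median", "tt.crest.median"):
            assert a[name] == pytest.approx(b[name], rel=1e-6)

    def test_iqr_nonnegative_flatness_crest_ranges(self, feature_table):
        iqr_cols = [c for c in feature_table.columns if c.endswith(".iqr")]
        assert (feature_table[iqr_cols] >= 0).all().all()
        assert feature_table["tt.flatness.median"].between(0, 1, inclusive="right").all()
        assert (feature_table["tt.crest.median"] >= 1).all()


class TestExtractMFCC:
    def test_exactly_24_entries(self, stimulus_set):
        vec = features.extract_mfcc(stimulus_set.clips[0])
        assert len(vec.values) == 24
        assert list(vec.values) == list(features.MFCC_FEATURE_NAMES)

    def test_stationary_tone_deltas_near_zero(self):
        vec = features.extract_mfcc(make_tone(440.0))
        deltas = [v for k, v in vec.values.items() if k.startswith("mfcc.d")]
        assert max(abs(v) for v in deltas) < 0.05

    def test_noise_and_tone_have_distinct_first_coefficients(self):
        rng = np.random.default_rng(0)
        noise = synth.AudioClip(0.5 * rng.standard_normal(int(0.8 * synth.RATE_HZ)),
                                synth.RATE_HZ, "noise")
        tone = make_tone(200.0)
        c_noise = features.extract_mfcc(noise).values["mfcc.c01.median"]
        c_tone = features.extract_mfcc(tone).values["mfcc.c01.median"]
        assert abs(c_noise - c_tone) > 1.0

    def test_too_few_frames_rejected(self):
        clip = synth.AudioClip(np.ones(1200), synth.RATE_HZ, "short")
        with pytest.raises(ValueError, match="3 frames"):
            features.extract_mfcc(clip)

    def test_matches_independent_implementation(self, stimulus_set):
        """Rank correlation > 0.95 against a from-scratch MFCC oracle."""
        from scipy.stats import spearmanr

        def oracle_mfcc_medians(clip):
            x = clip.samples
            w, h = 1102, 551
            win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(w) / w)
            nfr = (len(x) - w) // h + 1
            frames = np.stack([x[i * h:i * h + w] * win for i in range(nfr)])
            power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
            nyq = clip.rate_hz / 2
            mel = lambda f: 2595 * np.log10(1 + f / 700)
            imel = lambda m: 700 * (10 ** (m / 2595) - 1)
            edges = imel(np.linspace(0, mel(nyq), 42))
            bins = np.fft.rfftfreq(w, 1 / clip.rate_hz)
            logmel = np.empty((nfr, 40))
            for m in range(40):
                lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
                wgt = np.maximum(0, np.minimum((bins - lo) / (mid - lo),
                                               (hi - bins) / (hi - mid)))
                logmel[:, m] = np.log(power @ wgt + 1e-10)
            # orthonormal DCT-II by explicit summation
            kk = np.arange(1, 13)
            basis = np.cos(np.pi * kk[:, None] * (2 * np.arange(40) + 1) / (2 * 40))
            coefs = logmel @ basis.T * np.sqrt(2 / 40)
            return np.median(coefs, axis=0)

        ours, ref = [], []
        for clip in stimulus_set.clips:
            vec = features.extract_mfcc(clip).values
            ours.extend(vec[f"mfcc.c{i:02d}.median"] for i in range(1, 13))
            ref.extend(oracle_mfcc_medians(clip))
        rho = spearmanr(ours, ref).statistic
        assert rho > 0.95


class TestBuildFeatureTable:
    def test_combined_table_is_16_by_48(self, feature_table):
        assert feature_table.shape == (16, 48)

    def test_single_set_has_24_columns(self, stimulus_set):
        table = features.build_feature_table(stimulus_set.clips[:4], sets=("tt",))
        assert table.shape == (4, 24)
        assert all(c.startswith("tt.") for c in table.columns)

    def test_column_order_and_values_stable(self, stimulus_set, feature_table):
        again = features.build_feature_table(stimulus_set.clips)
        assert again.equals(feature_table)

    def test_failing_clip_named_in_error(self, stimulus_set):
        bad = synth.AudioClip(np.zeros(100), synth.RATE_HZ, "broken_clip")
        with pytest.raises(RuntimeError, match="broken_clip"):
            features.build_feature_table([stimulus_set.clips[0], bad])
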
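import numpy as np
import pytest

from clipsim import features, synth


def make_tone(freq_hz: float = 440.0, duration_s: float = 0.8,
              amp: float = 0.5) -> synth.AudioClip:
    """Plain sinusoid without fades — a stationary reference signal."""
    n = int(round(duration_s * synth.RATE_HZ))
    t = np.arange(n) / synth.RATE_HZ
    return synth.AudioClip(amp * np.sin(2 * np.pi * freq_hz * t),
                           synth.RATE_HZ, f"tone{freq_hz:.0f}")


@pytest.fixture(scope="session")
def stimulus_set() -> synth.StimulusSet:
    return synth.generate_stimulus_set(seed=1)


@pytest.fixture(scope="session")
def feature_table(stimulus_set):
    return features.build_feature_table(stimulus_set.clips)


@pytest.fixture(scope="session")
def sorted_similarity(stimulus_set, feature_table):
    """Similarity matrix aggregated from 40 simulated participants."""
    from clipsim.normalization import normalize

    normed = normalize(feature_table, "n4")
    latent = synth.LatentModel(
        true_weights={f: 1.0 for f in ("tt.centroid.median", "tt.mod_freq",
                                       "mfcc.c03.median")},
        noise_sd=0.3,
    )
    dist = synth.true_distances(normed, latent)
    rng = np.random.default_rng(77)
    parts = [
        synth.simulate_participant(dist, latent, int(rng.integers(0, 2**31 - 1)))
        for _ in range(40)
    ]
    return synth.aggregate_similarity(parts, n_items=16)
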
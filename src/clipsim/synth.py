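"""Synthetic stimuli and sorting-behaviour simulation.

The experiments this package models used short excerpts (400 ms and 800 ms)
of commercial recordings from four popular-music genres, sorted by
participants into four groups of four by perceived similarity in sound.
Neither the audio nor the raw behavioural data can be redistributed, so this
module synthesises stand-ins with the statistical structure the downstream
analysis assumes:

* parametric audio clips (sums of harmonic partials + band-limited noise,
  amplitude-modulated, faded in/out) whose genre "templates" separate on
  spectral centroid, flatness and modulation rate;
* a reference corpus of clips (default: 4 genres x 110 songs x 10 clips)
  used for corpus-based rank normalization;
* noisy participants who partition 16 clips into 4 groups of 4 by local
  search on perturbed ground-truth distances, aggregated into a pairwise
  similarity matrix (fraction of participants co-grouping a pair).

Everything is deterministic given its seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

RATE_HZ = 44_100
NYQUIST_HZ = RATE_HZ / 2
FADE_S = 0.020
PEAK = 0.9

__all__ = [
    "RATE_HZ",
    "ClipSpec",
    "AudioClip",
    "Partition",
    "LatentModel",
    "StimulusSet",
    "GenreTemplate",
    "DEFAULT_TEMPLATES",
    "SetConfig",
    "CorpusConfig",
    "generate_clip",
    "generate_stimulus_set",
    "corpus_clip_specs",
    "generate_corpus",
    "simulate_participant",
    "aggregate_similarity",
    "true_distances",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClipSpec:
    """Parametric recipe for one synthetic clip."""

    clip_id: str
    genre: str
    release_year: int
    duration_s: float
    partial_freqs: tuple[float, ...]
    partial_amps: tuple[float, ...]
    noise_band: tuple[float, float] | None = None
    noise_gain: float = 0.0
    am_rate: float = 0.0
    am_depth: float = 0.0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"{self.clip_id}: duration_s must be positive")
        if len(self.partial_freqs) != len(self.partial_amps):
            raise ValueError(f"{self.clip_id}: partial freqs/amps length mismatch")
        for f in self.partial_freqs:
            if f >= NYQUIST_HZ:
                raise ValueError(
                    f"{self.clip_id}: partial frequency {f:.1f} Hz is at or above "
                    f"the Nyquist frequency ({NYQUIST_HZ:.0f} Hz)"
                )
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError(f"{self.clip_id}: am_depth must lie in [0, 1]")


@dataclass
class AudioClip:
    """A sampled mono waveform with its clip identifier."""

    samples: np.ndarray
    rate_hz: int = RATE_HZ
    clip_id: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz


@dataclass(frozen=True)
class Partition:
    """One participant's sorting of clips into equal-size groups."""

    groups: tuple[frozenset[int], ...]

    def validate(self, n_items: int = 16, n_groups: int = 4) -> None:
        if len(self.groups) != n_groups:
            raise ValueError(f"expected {n_groups} groups, got {len(self.groups)}")
        size = n_items // n_groups
        seen: set[int] = set()
        for g in self.groups:
            if len(g) != size:
                raise ValueError(f"group size {len(g)} != {size}")
            seen |= g
        if seen != set(range(n_items)):
            raise ValueError("groups do not partition the item set")

    def co_grouped(self, i: int, j: int) -> bool:
        return any(i in g and j in g for g in self.groups)


@dataclass(frozen=True)
class LatentModel:
    """Ground truth behind simulated sorting behaviour.

    ``true_weights`` maps feature names to nonnegative weights; the
    ground-truth distance between two clips is the weighted sum of absolute
    feature differences, plus ``genre_bonus`` for cross-genre pairs.
    ``noise_sd`` is the standard deviation of the symmetric Gaussian
    perturbation each participant applies to the distances before sorting.
    """

    true_weights: dict[str, float]
    genre_bonus: float = 0.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not any(w > 0 for w in self.true_weights.values()):
            raise ValueError("at least one true weight must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(f for f, w in self.true_weights.items() if w > 0)


@dataclass
class StimulusSet:
    """16 clips plus their metadata table (clip_id, genre, release_year)."""

    clips: list[AudioClip]
    metadata: pd.DataFrame
    specs: list[ClipSpec] = field(default_factory=list)

    @property
    def clip_ids(self) -> list[str]:
        return [c.clip_id for c in self.clips]


# ---------------------------------------------------------------------------
# genre templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenreTemplate:
    """Parameter ranges from which clips of one genre are drawn.

    The four defaults are tuned so that the genres separate on spectral
    centroid (fundamental register and spectral tilt), spectral flatness
    (noise level) and amplitude-modulation rate/depth, and carry the
    genre-decade coupling of the original stimulus selection
    (jazz 1960-70s, rock 1970-80s, pop and hip-hop 1990-2000).
    """

    name: str
    f0_range: tuple[float, float]
    n_partials: int
    tilt: float                       # amplitude of partial k is k**-tilt
    noise_band: tuple[float, float]
    noise_gain_range: tuple[float, float]
    am_rate_range: tuple[float, float]
    am_depth_range: tuple[float, float]
    year_range: tuple[int, int]


DEFAULT_TEMPLATES: tuple[GenreTemplate, ...] = (
    GenreTemplate("jazz", (180.0, 260.0), 8, 1.5, (2000.0, 6000.0),
                  (0.005, 0.03), (1.5, 3.0), (0.15, 0.40), (1960, 1979)),
    GenreTemplate("rock", (90.0, 130.0), 14, 0.5, (1500.0, 9000.0),
                  (0.10, 0.30), (3.0, 6.0), (0.30, 0.55), (1970, 1989)),
    GenreTemplate("pop", (240.0, 330.0), 10, 1.0, (4000.0, 12000.0),
                  (0.04, 0.12), (1.0, 2.5), (0.10, 0.30), (1990, 2000)),
    GenreTemplate("hiphop", (55.0, 80.0), 6, 2.0, (200.0, 2500.0),
                  (0.06, 0.18), (7.0, 11.0), (0.60, 0.90), (1990, 2000)),
)


@dataclass(frozen=True)
class SetConfig:
    """Configuration of one 16-clip stimulus set."""

    duration_s: float = 0.8
    templates: tuple[GenreTemplate, ...] = DEFAULT_TEMPLATES
    clips_per_genre: int = 4
    freq_jitter: float = 0.12     # relative jitter on partial frequencies
    amp_jitter: float = 0.25      # relative jitter on partial amplitudes


@dataclass(frozen=True)
class CorpusConfig:
    """Recipe for the reference corpus used by corpus-rank normalization.

    Defaults mirror the reference-corpus construction: 110 songs per genre,
    10 clips of 800 ms per song, for 4 x 110 x 10 = 4,400 clips.
    """

    templates: tuple[GenreTemplate, ...] = DEFAULT_TEMPLATES
    songs_per_genre: int = 110
    clips_per_song: int = 10
    duration_s: float = 0.8

    @property
    def n_clips(self) -> int:
        return len(self.templates) * self.songs_per_genre * self.clips_per_song


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------

def generate_clip(spec: ClipSpec, seed: int) -> AudioClip:
    """Synthesise one clip from its spec, deterministically given the seed.

    The waveform is a sum of sinusoidal partials (random phases) plus
    band-limited Gaussian noise, amplitude-modulated at ``am_rate`` with
    depth ``am_depth``, peak-normalised to 0.9, with 20 ms raised-cosine
    fades applied at both ends.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * RATE_HZ))
    t = np.arange(n) / RATE_HZ
    x = np.zeros(n)
    for f, a in zip(spec.partial_freqs, spec.partial_amps):
        if a != 0.0:
            x += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if spec.noise_band is not None and spec.noise_gain > 0:
        lo, hi = spec.noise_band
        hi = min(hi, NYQUIST_HZ * 0.999)
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=RATE_HZ, output="sos")
        x += spec.noise_gain * signal.sosfilt(sos, rng.standard_normal(n))
    if spec.am_rate > 0 and spec.am_depth > 0:
        x *= 1.0 + spec.am_depth * np.sin(2 * np.pi * spec.am_rate * t)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= PEAK / peak
    _apply_fades(x)
    return AudioClip(samples=x, rate_hz=RATE_HZ, clip_id=spec.clip_id)


def _apply_fades(x: np.ndarray, fade_s: float = FADE_S, rate_hz: int = RATE_HZ) -> None:
    n_fade = min(int(round(fade_s * rate_hz)), len(x) // 2)
    if n_fade == 0:
        return
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
    x[:n_fade] *= ramp
    x[-n_fade:] *= ramp[::-1]


def _draw_spec(
    rng: np.random.Generator,
    template: GenreTemplate,
    clip_id: str,
    duration_s: float,
    freq_jitter: float,
    amp_jitter: float,
    f0: float | None = None,
    release_year: int | None = None,
) -> ClipSpec:
    """Draw one clip spec from a genre template with within-genre jitter."""
    if f0 is None:
        f0 = rng.uniform(*template.f0_range)
    harmonics = np.arange(1, template.n_partials + 1)
    freqs = f0 * harmonics * (1 + rng.uniform(-freq_jitter, freq_jitter, len(harmonics)))
    amps = harmonics ** (-template.tilt) * (
        1 + rng.uniform(-amp_jitter, amp_jitter, len(harmonics))
    )
    keep = freqs < NYQUIST_HZ * 0.95
    if release_year is None:
        release_year = int(rng.integers(template.year_range[0], template.year_range[1] + 1))
    return ClipSpec(
        clip_id=clip_id,
        genre=template.name,
        release_year=release_year,
        duration_s=duration_s,
        partial_freqs=tuple(float(f) for f in freqs[keep]),
        partial_amps=tuple(float(a) for a in amps[keep]),
        noise_band=template.noise_band,
        noise_gain=float(rng.uniform(*template.noise_gain_range)),
        am_rate=float(rng.uniform(*template.am_rate_range)),
        am_depth=float(rng.uniform(*template.am_depth_range)),
    )


def generate_stimulus_set(config: SetConfig | None = None, seed: int = 0) -> StimulusSet:
    """Generate one experiment's stimulus set: 4 genres x 4 clips.

    Raises a ValueError if the configuration does not name exactly 4 genre
    templates (the sorting paradigm requires 16 = 4 x 4 clips).
    """
    config = config or SetConfig()
    if len(config.templates) != 4:
        raise ValueError(
            f"stimulus set requires exactly 4 genre templates, got {len(config.templates)}"
        )
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    specs: list[ClipSpec] = []
    rows = []
    for template in config.templates:
        for i in range(config.clips_per_genre):
            clip_id = f"{template.name}{i + 1:02d}"
            spec = _draw_spec(rng, template, clip_id, config.duration_s,
                              config.freq_jitter, config.amp_jitter)
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clips.append(generate_clip(spec, clip_seed))
            specs.append(spec)
            rows.append({
                "clip_id": clip_id,
                "genre": template.name,
                "release_year": spec.release_year,
                "duration_s": config.duration_s,
                "seed": clip_seed,
            })
    metadata = pd.DataFrame(rows).set_index("clip_id")
    return StimulusSet(clips=clips, metadata=metadata, specs=specs)


def corpus_clip_specs(config: CorpusConfig | None = None, seed: int = 0) -> list[ClipSpec]:
    """Enumerate the clip specs of the reference corpus.

    Clips from the same song share a fundamental and release year; clip-level
    jitter is applied on top, emulating several excerpts per recording.
    """
    config = config or CorpusConfig()
    rng = np.random.default_rng(seed)
    specs: list[ClipSpec] = []
    for template in config.templates:
        for s in range(config.songs_per_genre):
            f0 = float(rng.uniform(*template.f0_range))
            year = int(rng.integers(template.year_range[0], template.year_range[1] + 1))
            for c in range(config.clips_per_song):
                clip_id = f"{template.name}_s{s + 1:03d}_c{c + 1:02d}"
                specs.append(_draw_spec(rng, template, clip_id, config.duration_s,
                                        freq_jitter=0.06, amp_jitter=0.15,
                                        f0=f0, release_year=year))
    return specs


def generate_corpus(config: CorpusConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Synthesise the reference corpus and return its full feature table.

    The returned table (clips x 48 features) is the reference used by
    corpus-based rank normalization. At the default size (4,400 clips of
    800 ms) this takes a few minutes on one CPU; pass a smaller
    :class:`CorpusConfig` for quick runs.
    """
    from .features import build_feature_table  # deferred: features imports AudioClip

    config = config or CorpusConfig()
    specs = corpus_clip_specs(config, seed)
    rng = np.random.default_rng(seed + 1)
    clips = [generate_clip(spec, int(rng.integers(0, 2**31 - 1))) for spec in specs]
    return build_feature_table(clips)


# ---------------------------------------------------------------------------
# sorting-behaviour simulation
# ---------------------------------------------------------------------------

def true_distances(
    features: pd.DataFrame,
    latent: LatentModel,
    metadata: pd.DataFrame | None = None,
) -> np.ndarray:
    """Ground-truth pairwise distance matrix implied by a latent model.

    d(i, j) = sum_f w_f |x_if - x_jf| (+ genre_bonus for cross-genre pairs,
    if metadata with a ``genre`` column is given).
    """
    missing = [f for f in latent.true_weights if f not in features.columns]
    if missing:
        raise KeyError(f"latent-model features absent from table: {missing}")
    n = len(features)
    d = np.zeros((n, n))
    for feat, w in latent.true_weights.items():
        if w == 0:
            continue
        col = features[feat].to_numpy(float)
        d += w * np.abs(col[:, None] - col[None, :])
    if latent.genre_bonus != 0 and metadata is not None:
        genres = metadata.loc[features.index, "genre"].to_numpy()
        d += latent.genre_bonus * (genres[:, None] != genres[None, :])
    np.fill_diagonal(d, 0.0)
    return d


def simulate_participant(
    true_dist: np.ndarray,
    latent: LatentModel,
    seed: int,
    n_groups: int = 4,
) -> Partition:
    """Simulate one participant's constrained sort.

    The participant perceives the ground-truth distances perturbed by
    symmetric additive Gaussian noise (sd = ``latent.noise_sd``), then sorts
    the items into ``n_groups`` equal groups by local search: a random
    equal-size initial assignment followed by best-improving cross-group
    item swaps until no swap lowers the total within-group perceived
    distance. Ties between equally improving swaps are broken toward the
    lexicographically lowest item-index pair. Deterministic given the seed.
    """
    d = np.asarray(true_dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distance matrix must have zero diagonal and be nonnegative")
    if n % n_groups != 0:
        raise ValueError(f"{n} items cannot form {n_groups} equal groups")
    size = n // n_groups

    rng = np.random.default_rng(seed)
    if latent.noise_sd > 0:
        noise = rng.normal(0.0, latent.noise_sd, size=(n, n))
        noise = np.triu(noise, 1)
        d = d + noise + noise.T

    assign = np.empty(n, dtype=int)
    assign[rng.permutation(n)] = np.repeat(np.arange(n_groups), size)

    # W[i, g] = summed perceived distance from item i to the members of group g
    onehot = np.eye(n_groups)[assign]
    W = d @ onehot

    while True:
        best_delta = -1e-9
        best_pair: tuple[int, int] | None = None
        for i, j in itertools.combinations(range(n), 2):
            gi, gj = assign[i], assign[j]
            if gi == gj:
                continue
            # after swapping, i joins gj (without j) and j joins gi (without i)
            delta = (W[i, gj] - d[i, j]) + (W[j, gi] - d[i, j]) - W[i, gi] - W[j, gj]
            if delta < best_delta:  # strict: ties keep the lowest (i, j) pair
                best_delta = delta
                best_pair = (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        gi, gj = assign[i], assign[j]
        assign[i], assign[j] = gj, gi
        W[:, gi] += d[:, j] - d[:, i]
        W[:, gj] += d[:, i] - d[:, j]

    groups = tuple(frozenset(np.flatnonzero(assign == g).tolist()) for g in range(n_groups))
    return Partition(groups=groups)


def aggregate_similarity(partitions: list[Partition], n_items: int = 16) -> np.ndarray:
    """Aggregate sorts into a similarity matrix.

    s(i, j) is the fraction of participants who placed clips i and j in the
    same group. The diagonal is stored as 1 by construction but carries no
    behavioural information and is excluded from all modelling downstream.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    counts = np.zeros((n_items, n_items))
    for p in partitions:
        for g in p.groups:
            idx = sorted(g)
            for a, b in itertools.combinations(idx, 2):
                counts[a, b] += 1
                counts[b, a] += 1
    s = counts / len(partitions)
    np.fill_diagonal(s, 1.0)
    return s
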
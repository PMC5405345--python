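"""Acoustic feature extraction: timbre descriptors and MFCCs.

Two 24-dimensional feature sets are computed per clip, mirroring the common
practice of describing the timbre of dense musical textures by frame-wise
spectral statistics:

* **TT set** (24 entries): ten spectral-shape descriptors computed on an
  ERB-spaced gammatone filterbank decomposition (centroid, spread,
  skewness, kurtosis, slope, decrease, rolloff, flatness, crest, and
  spectral variation a.k.a. flux), each summarised over frames by its
  median and interquartile range (20 values), plus four time-domain
  descriptors: energy-modulation frequency and amplitude, and the median
  and IQR of the zero-crossing rate.
* **MFCC set** (24 entries): the medians over frames of the first 12
  Mel-frequency cepstral coefficients (0th/energy coefficient excluded)
  and of their 12 frame-to-frame first differences (ΔMFCCs).

All frame-wise analyses share the same framing: 25 ms frames with 1/2
overlap (1,102 samples and a 551-sample hop at 44.1 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal
from scipy.stats import iqr as _iqr

from .synth import AudioClip

__all__ = [
    "FrameSpec",
    "FeatureVector",
    "TT_FEATURE_NAMES",
    "MFCC_FEATURE_NAMES",
    "erb_space",
    "gammatone_decompose",
    "spectral_descriptors",
    "temporal_descriptors",
    "extract_tt",
    "extract_mfcc",
    "build_feature_table",
]


@dataclass(frozen=True)
class FrameSpec:
    """Frame length 25 ms, 1/2 overlap; frame size rounded to an even count."""

    frame_s: float = 0.025
    overlap: float = 0.5
    window: str = "hann"

    def frame_samples(self, rate_hz: int) -> int:
        return int(round(self.frame_s * rate_hz))

    def hop_samples(self, rate_hz: int) -> int:
        return int(round(self.frame_samples(rate_hz) * (1 - self.overlap)))

    def n_frames(self, n_samples: int, rate_hz: int) -> int:
        w = self.frame_samples(rate_hz)
        h = self.hop_samples(rate_hz)
        if n_samples < w:
            raise ValueError(
                f"clip of {n_samples} samples is shorter than one analysis frame "
                f"({w} samples, {self.frame_s * 1000:.0f} ms)"
            )
        return (n_samples - w) // h + 1


DEFAULT_FRAMES = FrameSpec()


@dataclass
class FeatureVector:
    """Named scalar descriptors for one clip; set_tag is 'TT' or 'MFCC'."""

    values: dict[str, float]
    set_tag: str

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")


_SPECTRAL = ("centroid", "spread", "skewness", "kurtosis", "slope",
             "decrease", "rolloff", "flatness", "crest", "variation")
TT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"tt.{d}.{s}" for d in _SPECTRAL for s in ("median", "iqr")
) + ("tt.mod_freq", "tt.mod_amp", "tt.zcr.median", "tt.zcr.iqr")
MFCC_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"mfcc.c{i:02d}.median" for i in range(1, 13)
) + tuple(f"mfcc.d{i:02d}.median" for i in range(1, 13))


def _frame(x: np.ndarray, w: int, h: int) -> np.ndarray:
    """Return (n_frames, w) view-like framing of a 1-D signal."""
    n_frames = (len(x) - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    return x[idx]


# ---------------------------------------------------------------------------
# gammatone filterbank
# ---------------------------------------------------------------------------

def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """Center frequencies uniformly spaced on the ERB-number scale."""
    def erb_num(f):
        return 21.4 * np.log10(1 + 0.00437 * np.asarray(f))

    def inv_erb_num(e):
        return (10 ** (e / 21.4) - 1) / 0.00437

    return inv_erb_num(np.linspace(erb_num(fmin), erb_num(fmax), n))


def _gammatone_band(x: np.ndarray, cf: float, fs: int) -> np.ndarray:
    """4th-order gammatone filter as a cascade of four 2nd-order stages.

    The cascade form stays numerically stable down to the lowest ERB bands,
    unlike the expanded 8th-order transfer function.
    """
    T = 1.0 / fs
    erb = 24.7 * (4.37e-3 * cf + 1.0)
    B = 1.019 * 2 * np.pi * erb
    wc = 2 * np.pi * cf * T
    cos_wc, sin_wc = np.cos(wc), np.sin(wc)
    decay = np.exp(-B * T)
    a = [0, 0, 0, 0]
    for idx, sign_sq in enumerate((("+", np.sqrt(3 + 2**1.5)),
                                   ("-", np.sqrt(3 + 2**1.5)),
                                   ("+", np.sqrt(3 - 2**1.5)),
                                   ("-", np.sqrt(3 - 2**1.5)))):
        s = sign_sq[1] if sign_sq[0] == "+" else -sign_sq[1]
        a[idx] = -(2 * T * cos_wc * decay + 2 * s * T * sin_wc * decay) / 2
    b_denom = [1.0, -2 * cos_wc * decay, decay**2]

    z = np.exp(2j * wc)
    num = 1.0
    for s in (np.sqrt(3 - 2**1.5), -np.sqrt(3 - 2**1.5),
              np.sqrt(3 + 2**1.5), -np.sqrt(3 + 2**1.5)):
        num *= -2 * z * T + 2 * decay * np.exp(1j * wc) * T * (cos_wc - s * sin_wc)
    den = (-2 / decay**2 - 2 * z + 2 * (1 + z) / decay) ** 4
    gain = abs(num / den)

    y = signal.lfilter([T / gain, a[0] / gain, 0.0], b_denom, x)
    for idx in (1, 2, 3):
        y = signal.lfilter([T, a[idx], 0.0], b_denom, y)
    return y


def gammatone_decompose(
    clip: AudioClip,
    n_bands: int = 64,
    fmin: float = 26.0,
    frames: FrameSpec = DEFAULT_FRAMES,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-energy time-frequency decomposition via a gammatone filterbank.

    Returns ``(energies, center_freqs)`` where ``energies`` has shape
    (n_bands, n_frames): the per-frame energy (sum of squares) of the signal
    filtered by each 4th-order gammatone filter. Center frequencies are
    ERB-spaced from ``fmin`` up to just below the Nyquist frequency.
    """
    x = np.asarray(clip.samples, dtype=float)
    w = frames.frame_samples(clip.rate_hz)
    h = frames.hop_samples(clip.rate_hz)
    n_frames = frames.n_frames(len(x), clip.rate_hz)  # raises if too short
    centers = erb_space(fmin, clip.rate_hz / 2 * 0.95, n_bands)
    energies = np.empty((n_bands, n_frames))
    for b, fc in enumerate(centers):
        band = _gammatone_band(x, fc, clip.rate_hz)
        energies[b] = (_frame(band, w, h) ** 2).sum(axis=1)
    return energies, centers


# ---------------------------------------------------------------------------
# spectral-shape descriptors
# ---------------------------------------------------------------------------

def spectral_descriptors(
    energies: np.ndarray, center_freqs: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-frame spectral-shape descriptors of a band-energy matrix.

    Frames with zero total energy yield NaN (undefined) and are excluded
    from downstream summaries. ``variation`` (spectral flux, 1 minus the
    normalised correlation of consecutive frame spectra) is undefined for
    the first frame.
    """
    e = np.asarray(energies, dtype=float)
    if np.any(e < 0):
        raise ValueError("band energies must be nonnegative")
    f = np.asarray(center_freqs, dtype=float)
    n_bands, n_frames = e.shape
    total = e.sum(axis=0)
    live = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(live, e / np.where(live, total, 1.0), np.nan)

        centroid = (f[:, None] * p).sum(axis=0)
        dev = f[:, None] - centroid[None, :]
        spread = np.sqrt((dev**2 * p).sum(axis=0))
        m3 = (dev**3 * p).sum(axis=0)
        m4 = (dev**4 * p).sum(axis=0)
        skewness = np.where(spread > 0, m3 / spread**3, 0.0)
        kurtosis = np.where(spread > 0, m4 / spread**4, 0.0)

        # least-squares slope of normalised energy against frequency
        fbar = f.mean()
        denom = ((f - fbar) ** 2).sum()
        slope = ((f - fbar)[:, None] * p).sum(axis=0) / denom

        # low-frequency-emphasised slope: mean gradient relative to band 1
        rest = p[1:, :]
        dec_w = 1.0 / np.arange(1, n_bands)
        decrease = (dec_w[:, None] * (rest - p[0:1, :])).sum(axis=0) / np.where(
            rest.sum(axis=0) > 0, rest.sum(axis=0), 1.0
        )

        cum = np.cumsum(e, axis=0)
        thresh = 0.95 * total
        roll_idx = np.argmax(cum >= thresh[None, :], axis=0)
        rolloff = f[roll_idx]

        geo = np.exp(np.mean(np.log(np.where(e > 0, e, np.nan)), axis=0))
        arith = e.mean(axis=0)
        flatness = np.where(arith > 0, geo / arith, np.nan)
        # frames containing exactly-zero bands have geometric mean 0
        flatness = np.where(np.any(e == 0, axis=0) & live, 0.0, flatness)
        crest = np.where(arith > 0, e.max(axis=0) / arith, np.nan)

        norms = np.sqrt((e**2).sum(axis=0))
        dots = (e[:, 1:] * e[:, :-1]).sum(axis=0)
        corr = dots / (norms[1:] * norms[:-1])
        variation = np.full(n_frames, np.nan)
        variation[1:] = 1.0 - corr

    dead = ~live
    out = {
        "centroid": centroid, "spread": spread, "skewness": skewness,
        "kurtosis": kurtosis, "slope": slope, "decrease": decrease,
        "rolloff": rolloff, "flatness": flatness, "crest": crest,
        "variation": variation,
    }
    for name, series in out.items():
        series[dead] = np.nan
        if name == "variation":
            series[np.concatenate([[True], dead[:-1]])] = np.nan
    return out


# ---------------------------------------------------------------------------
# time-domain descriptors
# ---------------------------------------------------------------------------

def temporal_descriptors(
    clip: AudioClip, frames: FrameSpec = DEFAULT_FRAMES
) -> dict[str, float]:
    """Energy-modulation and zero-crossing descriptors.

    The energy envelope is obtained by full-wave rectification followed by a
    4th-order Butterworth low-pass at 50 Hz; its DC component is removed and
    the modulation frequency/amplitude are read off the maximal peak of a
    zero-padded FFT of the envelope. The zero-crossing rate (crossings per
    second) is computed per frame and summarised by median and IQR. Silence
    maps every descriptor to 0.
    """
    x = np.asarray(clip.samples, dtype=float)
    w = frames.frame_samples(clip.rate_hz)
    h = frames.hop_samples(clip.rate_hz)
    frames.n_frames(len(x), clip.rate_hz)

    if np.max(np.abs(x)) == 0:
        return {"mod_freq": 0.0, "mod_amp": 0.0, "zcr_median": 0.0, "zcr_iqr": 0.0}

    sos = signal.butter(4, 50.0, btype="lowpass", fs=clip.rate_hz, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(x))
    env = env - env.mean()
    nfft = int(2 ** np.ceil(np.log2(8 * len(env))))
    spec = np.abs(np.fft.rfft(env, nfft)) * 2.0 / len(env)
    freqs = np.fft.rfftfreq(nfft, 1.0 / clip.rate_hz)
    spec[0] = 0.0
    peak = int(np.argmax(spec))
    mod_amp = float(spec[peak])
    mod_freq = float(freqs[peak]) if mod_amp > 1e-9 else 0.0
    if mod_amp <= 1e-9:
        mod_amp = 0.0

    pos = (x >= 0).astype(np.int8)
    crossings = np.abs(np.diff(pos)).astype(float)
    # a crossing between samples t and t+1 is attributed to frame position t
    per_frame = _frame(np.append(crossings, 0.0), w, h).sum(axis=1)
    rate = per_frame / (w / clip.rate_hz)
    return {
        "mod_freq": mod_freq,
        "mod_amp": mod_amp,
        "zcr_median": float(np.median(rate)),
        "zcr_iqr": float(_iqr(rate)),
    }


# ---------------------------------------------------------------------------
# feature-set extraction
# ---------------------------------------------------------------------------

def _summarise(series: np.ndarray) -> tuple[float, float]:
    valid = series[np.isfinite(series)]
    if valid.size == 0:
        raise ValueError("descriptor undefined for every frame (silent clip?)")
    return float(np.median(valid)), float(_iqr(valid))


def extract_tt(
    clip: AudioClip,
    n_bands: int = 64,
    frames: FrameSpec = DEFAULT_FRAMES,
) -> FeatureVector:
    """The 24-entry timbre-descriptor vector of one clip."""
    energies, centers = gammatone_decompose(clip, n_bands=n_bands, frames=frames)
    per_frame = spectral_descriptors(energies, centers)
    values: dict[str, float] = {}
    for name in _SPECTRAL:
        med, spread = _summarise(per_frame[name])
        values[f"tt.{name}.median"] = med
        values[f"tt.{name}.iqr"] = spread
    temp = temporal_descriptors(clip, frames=frames)
    values["tt.mod_freq"] = temp["mod_freq"]
    values["tt.mod_amp"] = temp["mod_amp"]
    values["tt.zcr.median"] = temp["zcr_median"]
    values["tt.zcr.iqr"] = temp["zcr_iqr"]
    return FeatureVector(values=values, set_tag="TT")


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_mels: int, nfft: int, rate_hz: int) -> np.ndarray:
    """Triangular mel filters (unit peak) from 0 Hz to Nyquist."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate_hz / 2), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(nfft, 1.0 / rate_hz)
    fb = np.zeros((n_mels, len(bins)))
    for m in range(n_mels):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bins - lo) / (mid - lo)
        down = (hi - bins) / (hi - mid)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def extract_mfcc(
    clip: AudioClip,
    n_mels: int = 40,
    n_coefs: int = 12,
    frames: FrameSpec = DEFAULT_FRAMES,
) -> FeatureVector:
    """Medians of the first 12 MFCCs and of their frame-to-frame deltas.

    Pipeline: Hann-windowed frames -> power spectrum -> 40-band triangular
    mel filterbank (0 Hz to Nyquist) -> log power -> orthonormal DCT-II ->
    coefficients 1..12 (the 0th, overall-energy coefficient is dropped).
    Deltas are first differences of consecutive frames, so at least 3 frames
    are required.
    """
    x = np.asarray(clip.samples, dtype=float)
    w = frames.frame_samples(clip.rate_hz)
    h = frames.hop_samples(clip.rate_hz)
    n_frames = frames.n_frames(len(x), clip.rate_hz)
    if n_frames < 3:
        raise ValueError(
            f"MFCC deltas need at least 3 frames; clip yields {n_frames}"
        )
    win = signal.get_window(frames.window, w, fftbins=True)
    framed = _frame(x, w, h) * win
    power = np.abs(np.fft.rfft(framed, axis=1)) ** 2  # (frames, bins)
    fb = _mel_filterbank(n_mels, w, clip.rate_hz)
    mel_power = power @ fb.T
    log_mel = np.log(mel_power + 1e-10)
    cepstra = sp_fft.dct(log_mel, type=2, norm="ortho", axis=1)
    coefs = cepstra[:, 1:n_coefs + 1]  # (frames, 12)
    deltas = np.diff(coefs, axis=0)
    values = {
        f"mfcc.c{i + 1:02d}.median": float(np.median(coefs[:, i]))
        for i in range(n_coefs)
    }
    values.update({
        f"mfcc.d{i + 1:02d}.median": float(np.median(deltas[:, i]))
        for i in range(n_coefs)
    })
    return FeatureVector(values=values, set_tag="MFCC")


def build_feature_table(
    clips: list[AudioClip],
    sets: tuple[str, ...] = ("tt", "mfcc"),
    n_bands: int = 64,
    frames: FrameSpec = DEFAULT_FRAMES,
) -> pd.DataFrame:
    """Extract the requested feature sets for a list of clips.

    Returns a DataFrame indexed by clip_id, with 24 columns per requested
    set (48 for the combined TT+MFCC table). Extraction failures abort and
    name the offending clip.
    """
    if len(clips) < 2:
        raise ValueError("feature table requires at least 2 clips")
    known = {"tt", "mfcc"}
    req = tuple(s.lower() for s in sets)
    if not req or any(s not in known for s in req):
        raise ValueError(f"sets must be a nonempty subset of {sorted(known)}")
    rows = []
    for clip in clips:
        try:
            values: dict[str, float] = {}
            if "tt" in req:
                values.update(extract_tt(clip, n_bands=n_bands, frames=frames).values)
            if "mfcc" in req:
                values.update(extract_mfcc(clip, frames=frames).values)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for clip "
                               f"{clip.clip_id!r}: {exc}") from exc
        rows.append(pd.Series(values, name=clip.clip_id))
    order = [n for n in TT_FEATURE_NAMES if "tt" in req]
    order += [n for n in MFCC_FEATURE_NAMES if "mfcc" in req]
    table = pd.DataFrame(rows)[order]
    table.index.name = "clip_id"
    return table
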
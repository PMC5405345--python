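"""File I/O: WAV clips, feature/partition/similarity CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synth import AudioClip, Partition

__all__ = [
    "write_wav", "read_wav", "write_feature_table", "read_feature_table",
    "write_partitions", "read_partitions", "write_similarity",
    "read_similarity",
]


def write_wav(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM RIFF WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.rate_hz, (x * 32767.0).astype(np.int16))


def read_wav(path: str | Path, clip_id: str | None = None) -> AudioClip:
    """Read a WAV file; stereo is downmixed to mono by summing channels."""
    rate, data = wavfile.read(str(path))
    x = data.astype(float)
    if np.issubdtype(data.dtype, np.integer):
        x /= float(np.iinfo(data.dtype).max)
    if x.ndim == 2:
        x = x.sum(axis=1)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x /= peak
    return AudioClip(samples=x, rate_hz=int(rate),
                     clip_id=clip_id or Path(path).stem)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="clip_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="clip_id")


def write_partitions(
    partitions: list[Partition], clip_ids: list[str], path: str | Path
) -> None:
    rows = []
    for pid, part in enumerate(partitions):
        for g_idx, group in enumerate(part.groups):
            for item in sorted(group):
                rows.append({"participant_id": pid, "clip_id": clip_ids[item],
                             "group_index": g_idx})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_partitions(path: str | Path, clip_ids: list[str]) -> list[Partition]:
    df = pd.read_csv(path)
    pos = {c: i for i, c in enumerate(clip_ids)}
    parts = []
    for _, sub in df.groupby("participant_id", sort=True):
        groups = [
            frozenset(pos[c] for c in grp["clip_id"])
            for _, grp in sub.groupby("group_index", sort=True)
        ]
        parts.append(Partition(groups=tuple(groups)))
    return parts


def write_similarity(sim: np.ndarray, clip_ids: list[str], path: str | Path) -> None:
    pd.DataFrame(sim, index=clip_ids, columns=clip_ids).to_csv(
        path, index_label="clip_id"
    )


def read_similarity(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col="clip_id")
    return df.to_numpy(float), [str(c) for c in df.index]
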
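"""Pairwise design matrix, meta predictors, and the similarity response.

For L clips, every non-identical unordered pair contributes one row: with
L = 16 that is m = 16*15/2 = 120 pairs. The predictor for pair (i, j) and
feature f is the absolute difference |x_if - x_jf| of the clips'
(normalized) feature values. Meta predictors are the binary genre
indicator G (0 = same genre, 1 = different) and the absolute release-year
difference. The response y is the lower triangle of the similarity matrix,
diagonal excluded, in the same fixed pair order.

Pair order is the column-major lower triangle: (2,1), (3,1), ..., (L,1),
(3,2), ... — arbitrary but fixed, and shared by construction between X,
the meta columns, and y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DesignMatrix", "pair_order", "pairwise_distances", "meta_columns",
           "response_vector"]


def pair_order(n_clips: int) -> list[tuple[int, int]]:
    """Positional (i, j) pairs with i > j, column-major over the lower triangle."""
    return [(i, j) for j in range(n_clips) for i in range(j + 1, n_clips)]


@dataclass
class DesignMatrix:
    """Pairs x features distance matrix with its pair bookkeeping."""

    X: pd.DataFrame                 # index: "id_i|id_j" labels
    pairs: list[tuple[int, int]]    # positional indices into clip_ids
    clip_ids: list[str]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(float)

    @property
    def m(self) -> int:
        return len(self.pairs)


def _pair_labels(clip_ids: list[str], pairs: list[tuple[int, int]]) -> list[str]:
    return [f"{clip_ids[i]}|{clip_ids[j]}" for i, j in pairs]


def pairwise_distances(table: pd.DataFrame) -> DesignMatrix:
    """Absolute-difference design matrix over all non-identical pairs."""
    if len(table) < 2:
        raise ValueError("need at least 2 clips to form pairs")
    vals = table.to_numpy(float)
    if not np.isfinite(vals).all():
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite value for clip {table.index[bad[0]]!r}, "
            f"feature {table.columns[bad[1]]!r}"
        )
    clip_ids = [str(c) for c in table.index]
    pairs = pair_order(len(clip_ids))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    X = pd.DataFrame(
        np.abs(vals[ii] - vals[jj]),
        index=_pair_labels(clip_ids, pairs),
        columns=table.columns,
    )
    return DesignMatrix(X=X, pairs=pairs, clip_ids=clip_ids)


def meta_columns(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-pair meta predictors: genre indicator G and |Δ release year|.

    ``metadata`` must be indexed by clip_id, in the same clip order used for
    the distance matrix, with ``genre`` and ``release_year`` columns.
    """
    for col in ("genre", "release_year"):
        if col not in metadata.columns or metadata[col].isna().any():
            raise ValueError(f"metadata must provide {col!r} for every clip")
    clip_ids = [str(c) for c in metadata.index]
    genres = metadata["genre"].to_numpy()
    years = metadata["release_year"].to_numpy(float)
    pairs = pair_order(len(clip_ids))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    return pd.DataFrame(
        {
            "meta.genre": (genres[ii] != genres[jj]).astype(float),
            "meta.date": np.abs(years[ii] - years[jj]),
        },
        index=_pair_labels(clip_ids, pairs),
    )


def response_vector(
    similarity: np.ndarray,
    clip_ids: list[str] | None = None,
    atol: float = 1e-8,
) -> pd.Series:
    """Lower-triangle similarity response, diagonal excluded.

    The entries follow the shared pair order, so y aligns row-for-row with
    :func:`pairwise_distances` and :func:`meta_columns` for the same clip
    ordering.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(s, s.T, atol=atol):
        raise ValueError("similarity matrix is asymmetric beyond tolerance")
    n = s.shape[0]
    ids = [str(c) for c in clip_ids] if clip_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("clip_ids length does not match matrix size")
    pairs = pair_order(n)
    y = np.array([s[i, j] for i, j in pairs])
    return pd.Series(y, index=_pair_labels(ids, pairs), name="similarity")
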
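"""Feature normalization schemes N1-N5.

Raw audio descriptors have idiosyncratic, heavy-tailed distributions; five
schemes regularise them before pairwise distances are taken. Each scheme is
applied per feature column, independently, and normalized features from
different schemes are never pooled into one design matrix:

* **N1** none (raw values),
* **N2** range normalization to [0, 1],
* **N3** z-scores (sample sd, denominator L-1),
* **N4** rank transformation within the test set: x -> rank(x)/L with
  midranks for ties (L = number of clips),
* **N5** rank transformation against a reference corpus: x -> l'/L' where
  l' is the insertion rank of x in the corpus column (count of corpus
  values <= x) and L' the corpus size.

All schemes are monotone within a column, so value ordering is preserved;
N4 depends only on the within-set ordering of values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SCHEMES = ("n1", "n2", "n3", "n4", "n5")

__all__ = ["SCHEMES", "normalize"]


def normalize(
    table: pd.DataFrame,
    scheme: str,
    corpus: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply one of the five normalization schemes to a feature table.

    Parameters
    ----------
    table:
        Clips x features table of raw descriptor values.
    scheme:
        One of ``"n1" .. "n5"`` (case-insensitive).
    corpus:
        Reference feature table, required for N5; it must contain every
        column of ``table``.
    """
    s = scheme.lower()
    if s not in SCHEMES:
        raise ValueError(f"unknown normalization scheme {scheme!r}; expected one of {SCHEMES}")
    if not np.isfinite(table.to_numpy(float)).all():
        raise ValueError("feature table contains non-finite values")

    if s == "n1":
        return table.copy()

    out = {}
    L = len(table)
    for name in table.columns:
        col = table[name].to_numpy(float)
        if s == "n2":
            lo, hi = col.min(), col.max()
            if hi == lo:
                raise ValueError(f"feature {name!r} is constant; range normalization undefined")
            out[name] = (col - lo) / (hi - lo)
        elif s == "n3":
            sd = col.std(ddof=1)
            if sd == 0:
                raise ValueError(f"feature {name!r} is constant; z-scoring undefined")
            out[name] = (col - col.mean()) / sd
        elif s == "n4":
            out[name] = rankdata(col, method="average") / L
        else:  # n5
            if corpus is None:
                raise ValueError("scheme N5 requires a corpus feature table")
            if name not in corpus.columns:
                raise ValueError(f"corpus table lacks feature {name!r}")
            ref = np.sort(corpus[name].to_numpy(float))
            if ref.size == 0:
                raise ValueError(f"corpus column {name!r} is empty")
            out[name] = np.searchsorted(ref, col, side="right") / ref.size
    return pd.DataFrame(out, index=table.index)[table.columns]
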
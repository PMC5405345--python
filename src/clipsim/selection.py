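"""Bootstrap percentile CIs on PLSR coefficients and sparse refits.

Predictor relevance is assessed by a clip-level bootstrap: per replicate,
four clip ids are drawn *with replacement* from the 16 (so 1-4 distinct
clips are hit) and every pair touching a drawn clip is deleted — on
average about 59% of the 120 pairs survive, since a pair survives iff none
of the four independent draws hits either endpoint: ((L-2)/L)^4 =
(14/16)^4 ≈ 0.586. The model is refit on the surviving pairs and the
coefficients recorded; over B replicates the 0.025/0.975 percentiles give
a per-feature confidence interval, and features whose interval excludes
zero form the sparse model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .plsr import PLSRModel, fit_simpls

__all__ = [
    "BootstrapResult",
    "bootstrap_coefficients",
    "fit_sparse",
    "expected_retained_fraction",
    "retained_fraction_mc",
]


@dataclass
class BootstrapResult:
    coefficient_samples: np.ndarray   # (B, n)
    ci_low: np.ndarray
    ci_high: np.ndarray
    selected: list[str]
    feature_names: list[str]
    B: int
    n_drop: int
    seed: int
    reduced_k_replicates: list[int] = field(default_factory=list)

    def ci_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ci_low": self.ci_low, "ci_high": self.ci_high,
             "selected": [f in self.selected for f in self.feature_names]},
            index=self.feature_names,
        )


def expected_retained_fraction(n_clips: int = 16, n_drop: int = 4) -> float:
    """Closed form: a pair survives iff no draw hits either endpoint."""
    return ((n_clips - 2) / n_clips) ** n_drop


def retained_fraction_mc(
    n_clips: int = 16,
    n_drop: int = 4,
    reps: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo retained-pair fractions under the deletion scheme."""
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for j in range(n_clips) for i in range(j + 1, n_clips)]
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    out = np.empty(reps)
    for r in range(reps):
        drawn = rng.integers(0, n_clips, n_drop)
        keep = ~(np.isin(ii, drawn) | np.isin(jj, drawn))
        out[r] = keep.mean()
    return out


def bootstrap_coefficients(
    design: DesignMatrix,
    y,
    B: int = 1000,
    n_drop: int = 4,
    k: int = 2,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> BootstrapResult:
    """Clip-deletion bootstrap of the PLSR coefficients.

    Replicates whose surviving design matrix cannot support ``k``
    components are refit with the largest attainable component count and
    listed in ``reduced_k_replicates`` (B stays fixed).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    Xm = design.values
    yv = np.asarray(y, dtype=float).ravel()
    if yv.shape[0] != Xm.shape[0]:
        raise ValueError("y length does not match the design matrix")
    n_clips = len(design.clip_ids)
    ii = np.array([p[0] for p in design.pairs])
    jj = np.array([p[1] for p in design.pairs])

    rng = np.random.default_rng(seed)
    samples = np.empty((B, Xm.shape[1]))
    reduced: list[int] = []
    for b in range(B):
        drawn = rng.integers(0, n_clips, n_drop)
        keep = ~(np.isin(ii, drawn) | np.isin(jj, drawn))
        kb = k
        while True:
            try:
                model = fit_simpls(Xm[keep], yv[keep], kb)
                break
            except ValueError:
                kb -= 1
                if kb < 1:
                    raise
        if kb < k:
            reduced.append(b)
        samples[b] = model.beta
    lo, hi = np.percentile(samples, ci, axis=0)
    names = design.feature_names
    selected = [f for f, l, h in zip(names, lo, hi) if l > 0 or h < 0]
    return BootstrapResult(
        coefficient_samples=samples, ci_low=lo, ci_high=hi, selected=selected,
        feature_names=names, B=B, n_drop=n_drop, seed=seed,
        reduced_k_replicates=reduced,
    )


def fit_sparse(design: DesignMatrix, y, selected: list[str], k: int = 2) -> PLSRModel:
    """Refit on the selected columns only (all pairs); k is capped at |selected|."""
    if not selected:
        raise ValueError(
            "empty feature selection; fall back to the full model instead"
        )
    missing = [f for f in selected if f not in design.X.columns]
    if missing:
        raise ValueError(f"selected features absent from design matrix: {missing}")
    Xs = design.X[selected]
    return fit_simpls(Xs, y, min(k, len(selected)))
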
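"""Loading-matrix comparison: Tucker congruence and alignment.

Tucker's congruence coefficient is the cosine between vectorized loading
matrices, so it measures pattern similarity irrespective of scale — the
property that makes it usable across network loadings and factor loadings,
which live on different magnitudes.  Bands follow the usual convention:
fair similarity for 0.85 <= phi < 0.95, good for phi >= 0.95.

Before comparison, an estimated loading matrix must be aligned to the
target: its columns may be permuted and sign-flipped relative to the
simulated factors.  :func:`align_loadings` picks the column permutation and
per-column signs maximizing total matched absolute congruence via optimal
assignment, and applies the same permutation/signs congruently to an
estimated factor-correlation matrix.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "tucker_congruence",
    "align_loadings",
    "AlignmentResult",
    "congruence_band",
]


def tucker_congruence(estimated, simulated) -> float:
    """Cosine between vectorized loading matrices, in [-1, 1]."""
    x = np.asarray(estimated, dtype=float).ravel()
    y = np.asarray(simulated, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("loading matrices must have equal shape")
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0:
        raise ValueError("congruence undefined for zero-norm input")
    return float(np.sum(x * y) / denom)


def congruence_band(phi: float) -> str:
    """Qualitative similarity band for a congruence value."""
    if phi >= 0.95:
        return "good"
    if phi >= 0.85:
        return "fair"
    return "poor"


@dataclasses.dataclass
class AlignmentResult:
    permutation: np.ndarray          # estimated column j matches target permutation[j]
    column_signs: np.ndarray         # sign applied to each *target-position* column
    aligned_loadings: np.ndarray
    aligned_correlations: np.ndarray | None


def _column_congruences(estimated: np.ndarray, target: np.ndarray) -> np.ndarray:
    """m x m matrix of column congruences; zero-norm columns give 0 + warning."""
    m = estimated.shape[1]
    out = np.zeros((m, m))
    t_norms = np.linalg.norm(target, axis=0)
    for j in range(m):
        e = estimated[:, j]
        e_norm = np.linalg.norm(e)
        if e_norm == 0:
            warnings.warn(
                f"estimated column {j} is all zero; assigned arbitrarily "
                "with sign +1",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            out[j, :] = (e @ target) / (e_norm * t_norms)
        out[j, t_norms == 0] = 0.0
    return out


def align_loadings(
    estimated,
    target,
    estimated_correlations=None,
) -> AlignmentResult:
    """Match estimated columns (and signs) to target columns.

    Hungarian assignment on the absolute column-congruence matrix; each
    matched column's sign is the sign of its congruence with the target (+1
    on ties/zeros).  Never decreases whole-matrix congruence relative to the
    unaligned comparison.
    """
    est = np.asarray(estimated, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if est.shape != tgt.shape:
        raise ValueError("estimated and target loadings must have equal shape")
    congruences = _column_congruences(est, tgt)
    rows, cols = linear_sum_assignment(-np.abs(congruences))
    permutation = np.empty(est.shape[1], dtype=int)
    permutation[rows] = cols

    order = np.argsort(permutation)      # source column for each target slot
    signs = np.sign(congruences[order, np.arange(est.shape[1])])
    signs[signs == 0] = 1.0
    aligned = est[:, order] * signs
    aligned_corr = None
    if estimated_correlations is not None:
        corr = np.asarray(estimated_correlations, dtype=float)
        aligned_corr = corr[np.ix_(order, order)] * np.outer(signs, signs)
    return AlignmentResult(
        permutation=permutation,
        column_signs=signs,
        aligned_loadings=aligned,
        aligned_correlations=aligned_corr,
    )
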
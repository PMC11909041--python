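"""Network scores and factor-correlation estimation.

Scores are computed like component scores: the data are z-scored column-wise
(denominator ``n - 1``) and pre-multiplied by the standardized loading
matrix.  The Pearson correlations between score columns serve as estimates
of the correlations between factors — no rotation is involved, since a
partial-correlation network's between-community edges already embed the
factor correlations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .loadings_original import LoadingMatrix

__all__ = ["ScoreMatrix", "network_scores", "factor_correlation_mae"]


@dataclasses.dataclass
class ScoreMatrix:
    values: np.ndarray                 # n x m network scores
    loading_method: str
    factor_correlations: np.ndarray    # m x m score correlations

    @property
    def n_communities(self) -> int:
        return self.values.shape[1]


def network_scores(data, loadings) -> ScoreMatrix:
    """Score each observation on each community: ``z(X) @ O``.

    Raises on zero-variance data columns (naming them) and on degenerate
    zero-variance score columns (e.g. an all-zero loading column), for which
    a correlation between factors is undefined.
    """
    if isinstance(data, pd.DataFrame):
        names = [str(c) for c in data.columns]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        names = [f"V{i + 1:02d}" for i in range(x.shape[1])]
    if isinstance(loadings, LoadingMatrix):
        values = loadings.values
        method = loadings.method
    else:
        values = np.asarray(loadings, dtype=float)
        method = "unknown"
    if x.shape[1] != values.shape[0]:
        raise ValueError(
            f"data has {x.shape[1]} variables but loadings have "
            f"{values.shape[0]} rows"
        )
    sds = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(f"zero-variance column(s): {[names[i] for i in dead]}")
    z = (x - x.mean(axis=0)) / sds
    scores = z @ values
    score_sds = scores.std(axis=0, ddof=1)
    if np.any(score_sds == 0):
        raise ValueError(
            "score correlations undefined: zero-variance score column "
            f"{list(np.flatnonzero(score_sds == 0))} (all-zero loadings?)"
        )
    if scores.shape[1] == 1:
        corr = np.ones((1, 1))
    else:
        corr = np.corrcoef(scores, rowvar=False)
    return ScoreMatrix(values=scores, loading_method=method,
                       factor_correlations=corr)


def factor_correlation_mae(estimated: np.ndarray, simulated: np.ndarray) -> float:
    """Mean absolute error over the unique off-diagonal factor correlations."""
    est = np.asarray(estimated, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if est.shape != sim.shape:
        raise ValueError("correlation matrices must have equal shape")
    m = est.shape[0]
    if est.ndim != 2 or est.shape[1] != m or m < 2:
        raise ValueError("need square matrices with at least 2 factors")
    iu = np.triu_indices(m, 1)
    return float(np.mean(np.abs(est[iu] - sim[iu])))
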
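"""Revised network loadings.

Three changes relative to the original community-split strength:

1. **Signs first.**  Per community, nodes whose within-community connection
   sum is negative are iteratively flipped (updating the sub-network each
   time) until every node's sum is nonnegative, yielding a +-1 sign vector
   ``v``; a community whose sign sum is negative is recoded wholesale.  The
   whole network is then conjugated by ``v`` before any sums are taken, so
   reverse-keyed variables no longer cancel against the rest of their
   community.

2. **Count-adjusted within sums.**  The diagonal of a partial-correlation
   matrix is zero, so a node's within-community sum has one fewer potential
   nonzero term than a cross-loading sum over the same community.  The
   within loading is therefore the adjusted average times the community
   size, ``l_ic = p_c * (sum_j t_ij) / (p_c - 1)``; between-community
   loadings stay plain signed sums ``l_ik = sum_{j in k} w_ij``.

3. **Log-root standardization.**  Partial correlations shrink roughly like
   ``1 / log(p)`` as variables are added, so each column ``c`` is divided by

       (sum of |within l| over community c's assigned nodes) ** (1 / log(zeta * p_c))

   with scaling factor ``zeta = 2`` by default, removing the dependence of
   loading size on the number of variables per community.  Logs are natural.

Rows are finally multiplied by ``v`` to restore each variable's original
orientation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .ggm import Network, as_membership
from .loadings_original import LoadingMatrix, _weights

__all__ = [
    "RevisedConfig",
    "community_sign_vector",
    "within_loadings",
    "between_loadings",
    "standardize_revised",
    "revised_loadings",
]


@dataclasses.dataclass
class RevisedConfig:
    """Tunables for the revised loadings.

    zeta : loading-magnitude scaling factor in the root exponent
        ``1 / log(zeta * p_c)``; must satisfy ``zeta * p_c > 1`` for every
        community so the exponent stays positive.
    max_sign_iterations : cap on sign-loop flips per community
        (default ``100 * p``); hitting it warns and keeps the current state.
    """

    zeta: float = 2.0
    max_sign_iterations: int | None = None

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")


def community_sign_vector(
    network, membership, max_iterations: int | None = None
) -> np.ndarray:
    """Per-node +-1 signs orienting each community positively.

    Within each community, the lowest-index node whose within-community
    connection sum is negative is flipped (negating its row and column in
    the sub-network) and the sums are recomputed; the loop ends when no sum
    is negative.  A community whose resulting sign sum is negative is
    recoded (``v -> -v``) toward a positive orientation; ties keep the
    current signs.
    """
    w = _weights(network)
    p = w.shape[0]
    memb = as_membership(membership, p)
    cap = max_iterations if max_iterations is not None else 100 * p
    v = np.ones(p)
    for community in np.unique(memb):
        idx = np.flatnonzero(memb == community)
        target = w[np.ix_(idx, idx)].copy()
        iterations = 0
        while True:
            sums = target.sum(axis=1)
            negative = np.flatnonzero(sums < 0)
            if negative.size == 0:
                break
            if iterations >= cap:
                warnings.warn(
                    f"sign loop for community {community} did not settle "
                    f"in {cap} flips; keeping current signs",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
            a = int(negative[0])
            target[a, :] *= -1.0
            target[:, a] *= -1.0
            v[idx[a]] *= -1.0
            iterations += 1
        if v[idx].sum() < 0:
            v[idx] *= -1.0
    return v


def within_loadings(signed_network, membership) -> np.ndarray:
    """Count-adjusted within-community sums (length ``p``).

    Expects the network already conjugated by the sign vector
    (``diag(v) W diag(v)``).  Singleton communities yield 0 with a warning
    rather than a division error.
    """
    w = _weights(signed_network)
    memb = as_membership(membership, w.shape[0])
    out = np.zeros(w.shape[0])
    for community in np.unique(memb):
        idx = np.flatnonzero(memb == community)
        p_c = idx.size
        if p_c == 1:
            warnings.warn(
                f"community {community} is a singleton; its within "
                "loading is set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        block = w[np.ix_(idx, idx)]
        out[idx] = p_c * block.sum(axis=1) / (p_c - 1)
    return out


def between_loadings(signed_network, membership) -> np.ndarray:
    """Signed cross-community sums, ``p x m`` with zeros in assigned cells."""
    w = _weights(signed_network)
    memb = as_membership(membership, w.shape[0])
    communities = np.unique(memb)
    out = np.zeros((w.shape[0], communities.size))
    for col, k in enumerate(communities):
        jdx = np.flatnonzero(memb == k)
        out[:, col] = w[:, jdx].sum(axis=1)
        out[jdx, col] = 0.0  # assigned cells are filled by within_loadings
    return out


def standardize_revised(
    unstandardized: np.ndarray,
    within: np.ndarray,
    membership,
    config: RevisedConfig | None = None,
    node_signs: np.ndarray | None = None,
) -> np.ndarray:
    """Divide each column by its community's log-root denominator.

    Column ``c`` is divided by ``(sum_{i in c} |within_i|) ** (1 /
    log(zeta * p_c))``; an edgeless community (zero sum) maps to a zero
    column.  Rows are then multiplied by ``node_signs`` to restore the
    original variable orientation.
    """
    config = config or RevisedConfig()
    loadings = np.asarray(unstandardized, dtype=float)
    within = np.asarray(within, dtype=float)
    memb = as_membership(membership, loadings.shape[0])
    communities = np.unique(memb)
    out = np.zeros_like(loadings)
    for col, community in enumerate(communities):
        idx = np.flatnonzero(memb == community)
        exponent = np.log(config.zeta * idx.size)
        if exponent <= 0:
            raise ValueError(
                f"zeta * p_c = {config.zeta * idx.size:.3g} <= 1 leaves the "
                "root exponent undefined; increase zeta"
            )
        base = np.abs(within[idx]).sum()
        if base > 0:
            out[:, col] = loadings[:, col] / base ** (1.0 / exponent)
    if node_signs is not None:
        out = out * np.asarray(node_signs, dtype=float)[:, None]
    return out


def revised_loadings(
    network, membership, config: RevisedConfig | None = None
) -> LoadingMatrix:
    """Full revised pipeline: signs, adjusted sums, log-root standardization."""
    config = config or RevisedConfig()
    w = _weights(network)
    memb = as_membership(membership, w.shape[0])
    v = community_sign_vector(w, memb, config.max_sign_iterations)
    signed = w * np.outer(v, v)
    within = within_loadings(signed, memb)
    loadings = between_loadings(signed, memb)
    communities = np.unique(memb)
    for col, community in enumerate(communities):
        idx = np.flatnonzero(memb == community)
        loadings[idx, col] = within[idx]
    values = standardize_revised(loadings, within, memb, config, node_signs=v)
    names = (
        network.node_names
        if isinstance(network, Network)
        else [f"V{i + 1:02d}" for i in range(w.shape[0])]
    )
    return LoadingMatrix(
        values=values,
        method="revised",
        standardized=True,
        node_names=list(names),
        community_labels=[int(c) for c in communities],
    )
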
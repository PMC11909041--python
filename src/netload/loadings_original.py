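"""Original network loadings: community-split node strength.

A node's strength (sum of absolute edge weights) is split by community:
``l_ic = sum_{j in c} |w_ij|`` for every node and every community, then
standardized column-wise by the square root of the column sum,
``o_ic = l_ic / sqrt(sum_i l_ic)``.

Signs are then restored by a two-stage heuristic.  Stage 1 inspects each
within-community sub-network: for every node it asks whether negating that
node's row/column in the matrix of edge signs would raise the total sign
sum, and if so flips the sign of the node's assigned loading.  Stage 2
repeats the test on each rectangular between-community sub-network, flipping
cross-loading signs.  Each decision is evaluated against the sub-network's
*initial* sign matrix — flips do not feed back into later decisions.  When a
community contains an (even) mix of positively and negatively keyed
variables this makes every node's flip look favourable, all loadings in the
community flip together, and the mixed keying is lost: the known failure
mode of this formulation, preserved here deliberately (see the revised
formulation for the fix).  Finally each column is wholly negated unless its
sum is positive, orienting columns toward positive loadings.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ggm import Network, as_membership

__all__ = [
    "LoadingMatrix",
    "SignState",
    "strength_split",
    "standardize_original",
    "apply_signs_original",
    "original_loadings",
    "write_loadings",
    "read_loadings",
]


@dataclasses.dataclass
class LoadingMatrix:
    """``p x m`` network loadings with one column per community."""

    values: np.ndarray
    method: str  # "original" | "revised"
    standardized: bool
    node_names: list[str]
    community_labels: list[int]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_communities(self) -> int:
        return self.values.shape[1]

    def assigned(self, membership) -> np.ndarray:
        """Each node's loading on its own community (length ``p``)."""
        memb = as_membership(membership, self.n_nodes)
        return self.values[np.arange(self.n_nodes), memb - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.node_names, columns=self.community_labels
        )


@dataclasses.dataclass
class SignState:
    """Bookkeeping for one sign-assignment step (diagnostic output)."""

    target: np.ndarray        # sub-network the decision was made on
    sign_matrix: np.ndarray   # signs of the target (+1/-1, 0 for zero edges)
    sign_sum: float           # total of sign_matrix before any flip
    flipped: np.ndarray       # node indices (within target rows) flipped


def _weights(network) -> np.ndarray:
    if isinstance(network, Network):
        return network.weights
    w = np.asarray(network, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("network weights must be a square matrix")
    return w


def strength_split(network, membership) -> np.ndarray:
    """Unstandardized loadings: node strength split by community.

    Row sums over the columns equal node strength exactly.
    """
    w = _weights(network)
    memb = as_membership(membership, w.shape[0])
    communities = np.unique(memb)
    loadings = np.zeros((w.shape[0], communities.size))
    for col, community in enumerate(communities):
        loadings[:, col] = np.abs(w[:, memb == community]).sum(axis=1)
    return loadings


def standardize_original(unstandardized: np.ndarray) -> np.ndarray:
    """Column-wise square-root-sum standardization.

    ``o_ic = l_ic / sqrt(sum_i l_ic)`` with the sum over all ``p`` rows of
    the column (assigned and cross entries alike).  All-zero columns map to
    zero rather than erroring.
    """
    loadings = np.asarray(unstandardized, dtype=float)
    if np.any(loadings < 0):
        raise ValueError(
            "unstandardized loadings must be nonnegative (signs come later)"
        )
    sums = loadings.sum(axis=0)
    out = np.zeros_like(loadings)
    nonzero = sums > 0
    out[:, nonzero] = loadings[:, nonzero] / np.sqrt(sums[nonzero])
    return out


def _stage_flips(sign_matrix: np.ndarray, symmetric: bool) -> np.ndarray:
    """Rows whose (no-feedback) flip would raise the total sign sum.

    For row ``a`` the candidate flip negates row ``a`` (and column ``a``
    when the target is a symmetric within-community block); every decision
    compares against the initial sign sum, so the gain test reduces to the
    row's sign sum being negative.
    """
    base = sign_matrix.sum()
    flipped = []
    for a in range(sign_matrix.shape[0]):
        candidate = sign_matrix.copy()
        candidate[a, :] *= -1
        if symmetric:
            candidate[:, a] *= -1
        if candidate.sum() > base:
            flipped.append(a)
    return np.asarray(flipped, dtype=int)


def apply_signs_original(
    standardized: np.ndarray, network, membership
) -> tuple[np.ndarray, list[SignState]]:
    """Two-stage sign assignment plus final column orientation.

    Returns the signed loading matrix and the per-stage :class:`SignState`
    trace (one entry per within block, one per ordered community pair).
    """
    w = _weights(network)
    out = np.asarray(standardized, dtype=float).copy()
    if np.any(out < 0):
        raise ValueError("standardized loadings must be nonnegative on entry")
    memb = as_membership(membership, w.shape[0])
    communities = np.unique(memb)
    trace: list[SignState] = []

    # stage 1: within-community blocks
    for col, community in enumerate(communities):
        idx = np.flatnonzero(memb == community)
        target = w[np.ix_(idx, idx)]
        signs = np.sign(target)
        flips = _stage_flips(signs, symmetric=True)
        out[idx[flips], col] *= -1.0
        trace.append(SignState(target, signs, float(signs.sum()), flips))

    # stage 2: between-community blocks (rows: community c, cols: k)
    for col_c, community in enumerate(communities):
        idx = np.flatnonzero(memb == community)
        for col_k, other in enumerate(communities):
            if other == community:
                continue
            jdx = np.flatnonzero(memb == other)
            target = w[np.ix_(idx, jdx)]
            signs = np.sign(target)
            flips = _stage_flips(signs, symmetric=False)
            out[idx[flips], col_k] *= -1.0
            trace.append(SignState(target, signs, float(signs.sum()), flips))

    # final orientation: keep a column only if its sum is strictly positive
    for col in range(out.shape[1]):
        if not out[:, col].sum() > -out[:, col].sum():
            out[:, col] *= -1.0
    return out, trace


def original_loadings(network, membership) -> LoadingMatrix:
    """Full original pipeline: split, standardize, sign."""
    w = _weights(network)
    memb = as_membership(membership, w.shape[0])
    unstd = strength_split(w, memb)
    signed, _ = apply_signs_original(standardize_original(unstd), w, memb)
    names = (
        network.node_names
        if isinstance(network, Network)
        else [f"V{i + 1:02d}" for i in range(w.shape[0])]
    )
    return LoadingMatrix(
        values=signed,
        method="original",
        standardized=True,
        node_names=list(names),
        community_labels=[int(c) for c in np.unique(memb)],
    )


# ---------------------------------------------------------------------------
# text interfaces


def write_loadings(path, loadings: LoadingMatrix) -> None:
    """CSV of nodes x communities plus a YAML metadata sidecar."""
    loadings.to_frame().to_csv(path)
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(
            {"method": loadings.method, "standardized": loadings.standardized},
            fh,
        )


def read_loadings(path) -> LoadingMatrix:
    frame = pd.read_csv(path, index_col=0)
    try:
        with open(f"{path}.meta.yaml") as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError:
        meta = {"method": "unknown", "standardized": True}
    return LoadingMatrix(
        values=frame.to_numpy(dtype=float),
        method=meta["method"],
        standardized=bool(meta["standardized"]),
        node_names=[str(i) for i in frame.index],
        community_labels=[int(c) for c in frame.columns],
    )
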
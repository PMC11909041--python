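"""Factor-model population structures and multivariate-normal samples.

This module generates the data every other part of the package is validated
against: a common-factor model with loading matrix ``Lambda`` (one dominant
loading per variable plus small Gaussian cross-loadings), factor-correlation
matrix ``Phi``, and uniquenesses ``Psi`` chosen so that every indicator has
unit variance.  The population correlation matrix is

    R_P = Lambda @ Phi @ Lambda' + Psi,   Psi = 1 - diag(Lambda @ Phi @ Lambda')

and samples are drawn as ``X = Z U`` where ``U`` is the upper-triangular
Cholesky factor of ``R_P`` and ``Z`` is i.i.d. standard normal.

A candidate model is rejected (and redrawn by :func:`build_model`) when
``R_P`` is not positive definite or any communality exceeds 0.90.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FactorModelSpec",
    "GeneratedSample",
    "ModelValidityError",
    "generate_loading_matrix",
    "population_correlation",
    "sample_data",
    "build_model",
    "generate_sample",
    "constant_phi",
    "write_sample",
    "read_sample",
    "save_condition",
    "load_condition",
]

#: Maximum communality accepted before a model is rejected as degenerate.
MAX_COMMUNALITY = 0.90

SIGN_PATTERNS = ("all_positive", "half_negative")


class ModelValidityError(Exception):
    """Candidate population model failed a validity check (retriable).

    Distinct from ``ValueError`` so callers can redraw the loading matrix
    instead of aborting: a non-positive-definite ``R_P`` or a communality
    above 0.90 is a property of the random draw, not a usage error.
    """


@dataclasses.dataclass
class FactorModelSpec:
    """A fully realized population factor model.

    Attributes
    ----------
    n_factors : int
        Number of factors ``m``.
    variables_per_factor : np.ndarray
        Number of indicators assigned to each factor (length ``m``).
    loading_matrix : np.ndarray
        ``p x m`` matrix ``Lambda`` with one dominant loading per variable.
    factor_correlations : np.ndarray
        ``m x m`` symmetric matrix ``Phi`` with unit diagonal.
    uniqueness : np.ndarray
        Length-``p`` diagonal of ``Psi``; complements the communalities so
        that all indicator variances equal one.
    sign_pattern : str
        ``"all_positive"`` or ``"half_negative"``.
    cross_loading_sd : float
        Standard deviation of the Gaussian cross-loadings.
    """

    n_factors: int
    variables_per_factor: np.ndarray
    loading_matrix: np.ndarray
    factor_correlations: np.ndarray
    uniqueness: np.ndarray
    sign_pattern: str = "all_positive"
    cross_loading_sd: float = 0.0

    @property
    def n_variables(self) -> int:
        return int(np.sum(self.variables_per_factor))

    @property
    def membership(self) -> np.ndarray:
        """True community assignment (1-based, factor of each variable)."""
        return np.repeat(
            np.arange(1, self.n_factors + 1), self.variables_per_factor
        )

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniqueness

    @property
    def assigned_loadings(self) -> np.ndarray:
        """Each variable's loading on its own factor (length ``p``)."""
        return self.loading_matrix[
            np.arange(self.n_variables), self.membership - 1
        ]


@dataclasses.dataclass
class GeneratedSample:
    """A multivariate-normal sample plus the population objects behind it."""

    data: np.ndarray
    population_correlation: np.ndarray
    cholesky_factor: np.ndarray
    seed: int | None
    spec: FactorModelSpec

    @property
    def node_names(self) -> list[str]:
        return _default_names(self.data.shape[1])


def _default_names(p: int) -> list[str]:
    width = max(2, len(str(p)))
    return [f"V{i:0{width}d}" for i in range(1, p + 1)]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_loading_matrix(
    n_factors: int,
    variables_per_factor: Sequence[int],
    dominant_range: tuple[float, float] = (0.40, 0.70),
    cross_sd: float = 0.0,
    sign_pattern: str = "all_positive",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw a ``p x m`` loading matrix with dominant and cross-loadings.

    Dominant loadings are uniform on ``dominant_range``; every off-block
    entry is Normal(0, ``cross_sd``).  Under ``"half_negative"`` the first
    ``floor(p_c / 2)`` variables of each factor are negated (exactly one
    variable when ``p_c == 3``), emulating reverse-keyed indicators.
    """
    rng = _as_rng(rng)
    vpf = np.asarray(variables_per_factor, dtype=int)
    lo, hi = float(dominant_range[0]), float(dominant_range[1])
    if n_factors < 1 or vpf.shape != (n_factors,) or np.any(vpf < 1):
        raise ValueError(
            "variables_per_factor must list a positive count per factor"
        )
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("dominant_range must satisfy 0 < low < high < 1")
    if cross_sd < 0:
        raise ValueError("cross_sd must be nonnegative")
    if sign_pattern not in SIGN_PATTERNS:
        raise ValueError(f"sign_pattern must be one of {SIGN_PATTERNS}")

    p = int(vpf.sum())
    if cross_sd > 0:
        loadings = rng.normal(0.0, cross_sd, size=(p, n_factors))
    else:
        loadings = np.zeros((p, n_factors))
    start = 0
    for f, size in enumerate(vpf):
        block = slice(start, start + size)
        loadings[block, f] = rng.uniform(lo, hi, size=size)
        if sign_pattern == "half_negative":
            n_neg = 1 if size == 3 else size // 2
            # whole-row negation: the variable itself is reverse keyed
            loadings[start : start + n_neg, :] *= -1.0
        start += size
    return loadings


def population_correlation(
    loading_matrix: np.ndarray, factor_correlations: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied correlation matrix ``R_P`` and uniquenesses.

    Raises
    ------
    ValueError
        On dimension mismatch between ``Lambda`` and ``Phi``.
    ModelValidityError
        When any communality exceeds 0.90 or ``R_P`` has an eigenvalue
        <= 0; callers should redraw the loading matrix.
    """
    lam = np.asarray(loading_matrix, dtype=float)
    phi = np.asarray(factor_correlations, dtype=float)
    if lam.ndim != 2 or phi.shape != (lam.shape[1], lam.shape[1]):
        raise ValueError(
            f"factor_correlations must be {lam.shape[1]}x{lam.shape[1]} "
            f"to match the loading matrix, got {phi.shape}"
        )
    common = lam @ phi @ lam.T
    communality = np.diag(common).copy()
    if np.any(communality > MAX_COMMUNALITY):
        raise ModelValidityError(
            f"communality {communality.max():.4f} exceeds {MAX_COMMUNALITY}"
        )
    uniqueness = 1.0 - communality
    r_pop = common + np.diag(uniqueness)
    if np.linalg.eigvalsh(r_pop).min() <= 0:
        raise ModelValidityError("population correlation not positive definite")
    return r_pop, uniqueness


def sample_data(
    population_correlation: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` multivariate-normal rows with correlation ``R_P``.

    Uses the upper-triangular Cholesky factor ``U`` (``R_P = U'U``) so that
    ``X = Z U`` with ``Z`` i.i.d. standard normal.
    """
    if n < 2:
        raise ValueError("need at least n = 2 observations")
    r_pop = np.asarray(population_correlation, dtype=float)
    upper = np.linalg.cholesky(r_pop).T  # raises LinAlgError when not PD
    z = _as_rng(rng).standard_normal((n, r_pop.shape[0]))
    return z @ upper


def constant_phi(n_factors: int, rho: float) -> np.ndarray:
    """Equicorrelated ``Phi`` with off-diagonal ``rho``."""
    phi = np.full((n_factors, n_factors), float(rho))
    np.fill_diagonal(phi, 1.0)
    return phi


def build_model(
    n_factors: int,
    variables_per_factor: Sequence[int],
    dominant_range: tuple[float, float] = (0.40, 0.70),
    cross_sd: float = 0.0,
    sign_pattern: str = "all_positive",
    factor_correlations: np.ndarray | float = 0.0,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 1000,
) -> FactorModelSpec:
    """Draw loading matrices until the implied ``R_P`` passes validity.

    The redraw loop is capped at ``max_attempts`` (the degenerate-model
    region is tiny for the ranges used here, so the cap is a safety net
    against misconfigured inputs, not an expected exit).
    """
    rng = _as_rng(rng)
    if np.isscalar(factor_correlations):
        phi = constant_phi(n_factors, float(factor_correlations))
    else:
        phi = np.asarray(factor_correlations, dtype=float)
    for _ in range(max_attempts):
        lam = generate_loading_matrix(
            n_factors, variables_per_factor, dominant_range, cross_sd,
            sign_pattern, rng,
        )
        try:
            _, uniqueness = population_correlation(lam, phi)
        except ModelValidityError:
            continue
        return FactorModelSpec(
            n_factors=n_factors,
            variables_per_factor=np.asarray(variables_per_factor, dtype=int),
            loading_matrix=lam,
            factor_correlations=phi,
            uniqueness=uniqueness,
            sign_pattern=sign_pattern,
            cross_loading_sd=float(cross_sd),
        )
    raise RuntimeError(
        f"no valid population model in {max_attempts} attempts; "
        "check loading ranges and factor correlations"
    )


def generate_sample(
    spec: FactorModelSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> GeneratedSample:
    """Sample ``n`` observations from a realized factor model."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    r_pop, _ = population_correlation(
        spec.loading_matrix, spec.factor_correlations
    )
    upper = np.linalg.cholesky(r_pop).T
    z = _as_rng(rng).standard_normal((int(n), r_pop.shape[0]))
    return GeneratedSample(
        data=z @ upper,
        population_correlation=r_pop,
        cholesky_factor=upper,
        seed=None if seed is None else int(seed),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# text interfaces


def write_sample(path, data: np.ndarray, node_names: Sequence[str] | None = None) -> None:
    """Write a samples-by-variables matrix as CSV with a V01..Vp header."""
    data = np.asarray(data)
    names = list(node_names) if node_names else _default_names(data.shape[1])
    pd.DataFrame(data, columns=names).to_csv(path, index=False)


def read_sample(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_condition(path, **condition) -> None:
    """Serialize a generating condition (not a realized ``Lambda``) to YAML.

    Recognized keys: factors, variables_per_factor, loading_range, cross_sd,
    phi, sign_pattern, n, seed.
    """
    clean = {}
    for key, value in condition.items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, (np.integer, np.floating)):
            value = value.item()
        elif isinstance(value, tuple):
            value = list(value)
        clean[key] = value
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=False)


def load_condition(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
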
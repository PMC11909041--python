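"""Reproductions of the validation experiments at desk scale.

Wires the pieces together: factor-model simulation -> network estimation ->
original/revised loadings (with *true* memberships supplied, isolating
loading quality from community detection) -> network scores -> alignment ->
congruence and factor-correlation error.

Three named examples plus two simulation designs are provided:

* ``table1`` — two factors x six variables, half of each factor's variables
  reverse keyed, orthogonal factors, n = 100,000: the sign-recovery example.
* ``table2`` — three variables on factor 1, nine on factor 2 with one
  variable loading 0.40 on both, factor correlation 0.30, n = 100,000: the
  cross-loading example.
* ``small_sim`` — four factors with 3/6/12/24 variables: demonstrates the
  original loadings' dependence on community size and the revised
  standardization breaking it.
* ``mapping_sim`` — broad parameter sweep mapping revised network loadings
  onto factor-loading effect-size guidelines (n = 1000 per replicate; the
  full-scale version uses 500 replicates per condition, the default here is
  a desk-scale 5).
* the main factorial design (via :func:`main_design` + :func:`run_design`).

Replicate seeds are spawned deterministically from one master seed, so runs
are reproducible and independent of execution order.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import factor_sim, ggm
from .evaluation import align_loadings, tucker_congruence
from .factor_sim import FactorModelSpec, build_model, constant_phi
from .loadings_original import original_loadings, write_loadings
from .loadings_revised import revised_loadings
from .scores import factor_correlation_mae, network_scores

__all__ = [
    "SimulationCondition",
    "main_design",
    "run_design",
    "aggregate_results",
    "run_example",
    "table1_example",
    "table2_example",
    "small_simulation",
    "mapping_simulation",
    "TABLE1_LOADINGS",
    "TABLE2_LOADINGS",
]

logger = logging.getLogger("netload")

EXAMPLE_NAMES = ("table1", "table2", "small_sim", "mapping_sim")
METHODS = ("original", "revised")
CROSS_LOADING_SD = 0.05


# ---------------------------------------------------------------------------
# named example designs (printed loading matrices used as inputs)

def _table1_lambda() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lam = np.zeros((12, 2))
    lam[:6, 0] = [-0.63, -0.64, -0.51, 0.62, 0.58, 0.55]
    lam[6:, 1] = [-0.60, -0.48, -0.58, 0.59, 0.54, 0.59]
    membership = np.repeat([1, 2], 6)
    return lam, np.eye(2), membership


def _table2_lambda() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lam = np.zeros((12, 2))
    lam[:3, 0] = [0.63, 0.64, 0.51]
    lam[3, :] = [0.40, 0.40]  # V04: equal dual loading, assigned to factor 2
    lam[4:, 1] = [0.58, 0.55, 0.60, 0.48, 0.58, 0.59, 0.54, 0.59]
    membership = np.array([1] * 3 + [2] * 9)
    return lam, constant_phi(2, 0.30), membership


TABLE1_LOADINGS, _, TABLE1_MEMBERSHIP = _table1_lambda()
TABLE2_LOADINGS, TABLE2_PHI, TABLE2_MEMBERSHIP = _table2_lambda()


# ---------------------------------------------------------------------------
# condition grid

@dataclasses.dataclass
class SimulationCondition:
    """One cell of the factorial design.

    ``variables_per_factor``, ``loading_level`` and ``factor_correlation``
    accept the string ``"varying"``: the value is then redrawn uniformly per
    replicate (3-12 variables, loadings 0.30-0.80, correlations 0.00-0.70,
    independently across factors/pairs).  A numeric loading level ``L``
    means dominant loadings drawn uniformly from ``L +- 0.10``.
    """

    n_factors: int
    variables_per_factor: int | str
    loading_level: float | str
    sign_pattern: str
    factor_correlation: float | str
    n: int

    def label(self) -> str:
        return (
            f"m={self.n_factors}|vpf={self.variables_per_factor}"
            f"|load={self.loading_level}|sign={self.sign_pattern}"
            f"|phi={self.factor_correlation}|n={self.n}"
        )

    def realize(self, rng: np.random.Generator) -> FactorModelSpec:
        """Draw one replicate's population model for this cell."""
        if self.variables_per_factor == "varying":
            vpf = rng.integers(3, 13, size=self.n_factors)
        else:
            vpf = np.full(self.n_factors, int(self.variables_per_factor))
        if self.loading_level == "varying":
            dominant = (0.30, 0.80)
        else:
            level = float(self.loading_level)
            dominant = (level - 0.10, level + 0.10)
        for _ in range(100):
            if self.factor_correlation == "varying":
                phi = np.eye(self.n_factors)
                iu = np.triu_indices(self.n_factors, 1)
                draws = rng.uniform(0.0, 0.70, size=len(iu[0]))
                phi[iu] = draws
                phi = phi + phi.T - np.eye(self.n_factors)
                if np.linalg.eigvalsh(phi).min() <= 0:
                    continue  # redraw a non-PD factor-correlation matrix
            else:
                phi = constant_phi(self.n_factors, float(self.factor_correlation))
            try:
                return build_model(
                    self.n_factors, vpf, dominant, CROSS_LOADING_SD,
                    self.sign_pattern, phi, rng,
                )
            except RuntimeError:
                continue
        raise RuntimeError(f"could not realize condition {self.label()}")


def main_design(
    n_factors: Sequence[int] = (2, 3, 4),
    variables_per_factor: Sequence = (3, 6, 12, "varying"),
    loading_levels: Sequence = (0.40, 0.55, 0.70, "varying"),
    sign_patterns: Sequence[str] = ("all_positive", "half_negative"),
    factor_correlations: Sequence = (0.00, 0.30, 0.50, 0.70, "varying"),
    sample_sizes: Sequence[int] = (500, 1000),
) -> list[SimulationCondition]:
    """The factorial grid (full defaults: 960 cells); pass subsets to scale."""
    return [
        SimulationCondition(m, vpf, load, sign, phi, n)
        for m in n_factors
        for vpf in variables_per_factor
        for load in loading_levels
        for sign in sign_patterns
        for phi in factor_correlations
        for n in sample_sizes
    ]


# ---------------------------------------------------------------------------
# runners

def _loadings_for(method: str, network: ggm.Network, membership: np.ndarray):
    if method == "original":
        return original_loadings(network, membership)
    if method == "revised":
        return revised_loadings(network, membership)
    raise ValueError(f"unknown loading method: {method}")


def _evaluate_replicate(
    spec: FactorModelSpec,
    sample: np.ndarray,
    methods: Sequence[str],
) -> tuple[ggm.Network, dict[str, dict]]:
    """Estimate the network once, then score every loading method on it."""
    network = ggm.estimate_network(sample)
    membership = spec.membership
    out: dict[str, dict] = {}
    for method in methods:
        loading = _loadings_for(method, network, membership)
        score = network_scores(sample, loading)
        aligned = align_loadings(
            loading.values, spec.loading_matrix, score.factor_correlations
        )
        phi_t = tucker_congruence(aligned.aligned_loadings, spec.loading_matrix)
        if spec.n_factors >= 2:
            mae = factor_correlation_mae(
                aligned.aligned_correlations, spec.factor_correlations
            )
        else:
            mae = np.nan
        out[method] = {
            "congruence": phi_t,
            "mae": mae,
            "loading": loading,
            "aligned": aligned,
        }
    return network, out


def run_design(
    conditions: Iterable[SimulationCondition],
    replicates: int = 20,
    seed: int = 0,
    methods: Sequence[str] = METHODS,
) -> pd.DataFrame:
    """Run a condition grid; one record per replicate x method.

    Replicate-level estimation failures are logged and recorded with NaN
    outcomes; the run continues.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("empty condition grid")
    master = np.random.SeedSequence(seed)
    children = iter(master.spawn(len(conditions) * replicates))
    records = []
    for cond in conditions:
        logger.info("condition %s", cond.label())
        for rep in range(replicates):
            rng = np.random.default_rng(next(children))
            started = time.perf_counter()
            base = dataclasses.asdict(cond) | {
                "condition": cond.label(), "replicate": rep,
            }
            try:
                spec = cond.realize(rng)
                sample = factor_sim.generate_sample(spec, cond.n, rng).data
                network, results = _evaluate_replicate(spec, sample, methods)
            except Exception:  # noqa: BLE001 - replicate-level resilience
                logger.exception(
                    "replicate %d of %s failed", rep, cond.label()
                )
                elapsed = time.perf_counter() - started
                for method in methods:
                    records.append(base | {
                        "method": method, "congruence": np.nan,
                        "mae": np.nan, "gamma_used": np.nan,
                        "elapsed": elapsed,
                    })
                continue
            elapsed = time.perf_counter() - started
            for method in methods:
                records.append(base | {
                    "method": method,
                    "congruence": results[method]["congruence"],
                    "mae": results[method]["mae"],
                    "gamma_used": network.gamma_used,
                    "elapsed": elapsed,
                })
    return pd.DataFrame.from_records(records)


def aggregate_results(results: pd.DataFrame) -> pd.DataFrame:
    """Mean congruence/MAE per method x sign pattern (Table-3 style).

    Failed replicates (NaN) are excluded listwise; ``n_missing`` reports how
    many were dropped per cell.
    """
    def _agg(group: pd.DataFrame) -> pd.Series:
        ok = group.dropna(subset=["congruence"])
        return pd.Series({
            "congruence": ok["congruence"].mean(),
            "mae": ok["mae"].mean(),
            "n_replicates": len(ok),
            "n_missing": len(group) - len(ok),
        })

    grouped = results.groupby(["method", "sign_pattern"])
    return grouped.apply(_agg, include_groups=False).reset_index()


# ---------------------------------------------------------------------------
# worked examples

def _fixed_example(
    lam: np.ndarray,
    phi: np.ndarray,
    membership: np.ndarray,
    seed: int,
    n: int = 100_000,
) -> dict:
    """Generate, estimate and load a design with a fixed printed Lambda."""
    r_pop, uniqueness = factor_sim.population_correlation(lam, phi)
    spec = FactorModelSpec(
        n_factors=lam.shape[1],
        variables_per_factor=np.bincount(membership)[1:],
        loading_matrix=lam,
        factor_correlations=phi,
        uniqueness=uniqueness,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    data = factor_sim.sample_data(r_pop, n, rng)
    network, results = _evaluate_replicate(spec, data, METHODS)
    tables = {"simulated": pd.DataFrame(lam, index=network.node_names)}
    for method in METHODS:
        aligned = results[method]["aligned"].aligned_loadings
        tables[method] = pd.DataFrame(aligned, index=network.node_names)
    return {
        "spec": spec,
        "network": network,
        "results": results,
        "loading_tables": tables,
        "membership": membership,
    }


def table1_example(seed: int = 0, n: int = 100_000) -> dict:
    """Mixed-sign example: 2 factors x 6 variables, 3 reverse keyed each."""
    lam, phi, membership = _table1_lambda()
    return _fixed_example(lam, phi, membership, seed, n)


def table2_example(seed: int = 0, n: int = 100_000) -> dict:
    """Cross-loading example: 3 + 9 variables, one equal dual loading."""
    lam, phi, membership = _table2_lambda()
    return _fixed_example(lam, phi, membership, seed, n)


SMALL_SIM_SIZES = (3, 6, 12, 24)
SMALL_SIM_SAMPLE_SIZES = (250, 1000, 10_000, 100_000)


def small_simulation(
    seed: int = 0,
    replicates: int = 25,
    sample_sizes: Sequence[int] = SMALL_SIM_SAMPLE_SIZES,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Community-size dependence study (full-scale original: 100 replicates).

    Four factors with 3, 6, 12 and 24 variables, dominant loadings
    U(0.40, 0.70), cross-loadings N(0, 0.05), factor correlations 0.30.
    Returns per-variable records (assigned loading per method) pooled over
    replicates and sample sizes, plus the four pooled Pearson correlations:
    each method's assigned loadings vs. community size and vs. the simulated
    loadings.
    """
    sizes = np.array(SMALL_SIM_SIZES)
    membership = np.repeat(np.arange(1, 5), sizes)
    vpf_per_variable = np.repeat(sizes, sizes)
    children = iter(np.random.SeedSequence(seed).spawn(replicates))
    rows = []
    for rep in range(replicates):
        rng = np.random.default_rng(next(children))
        spec = build_model(
            4, sizes, (0.40, 0.70), CROSS_LOADING_SD, "all_positive",
            constant_phi(4, 0.30), rng,
        )
        simulated = spec.assigned_loadings
        for n in sample_sizes:
            data = factor_sim.generate_sample(spec, n, rng).data
            _, results = _evaluate_replicate(spec, data, METHODS)
            assigned = {
                method: results[method]["aligned"].aligned_loadings[
                    np.arange(membership.size), membership - 1
                ]
                for method in METHODS
            }
            for i in range(membership.size):
                rows.append({
                    "replicate": rep, "n": n, "node": i,
                    "variables_per_factor": int(vpf_per_variable[i]),
                    "simulated": float(simulated[i]),
                    "original": float(assigned["original"][i]),
                    "revised": float(assigned["revised"][i]),
                })
        logger.info("small_sim replicate %d/%d done", rep + 1, replicates)
    records = pd.DataFrame.from_records(rows)

    def _r(a: str, b: str) -> float:
        return float(np.corrcoef(records[a], records[b])[0, 1])

    summary = {
        "r_original_vs_vpf": _r("original", "variables_per_factor"),
        "r_revised_vs_vpf": _r("revised", "variables_per_factor"),
        "r_original_vs_simulated": _r("original", "simulated"),
        "r_revised_vs_simulated": _r("revised", "simulated"),
    }
    return records, summary


MAPPING_FACTORS = (2, 3, 4, 5)
MAPPING_VPF = (3, 6, 9, 12, 24)


def mapping_simulation(
    seed: int = 0,
    replicates: int = 5,
    n: int = 1000,
    factors: Sequence[int] = MAPPING_FACTORS,
    variables_per_factor: Sequence[int] = MAPPING_VPF,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Map revised network loadings onto factor-loading effect sizes.

    Broad sweep: loadings U(0.30, 0.80), pairwise factor correlations
    U(0.00, 0.50), n = 1000 per replicate (the design leaves the sample size
    open; 1000 is the upper end of the main grid).  Returns pooled
    (simulated, revised) assigned-loading pairs with simulated >= 0.30,
    the regression R^2 and pooled congruence, and 2-digit bin counts for a
    heatmap export.
    """
    conditions = [
        SimulationCondition(m, vpf, "varying", "all_positive", np.nan, n)
        for m in factors
        for vpf in variables_per_factor
    ]
    children = iter(
        np.random.SeedSequence(seed).spawn(len(conditions) * replicates)
    )
    rows = []
    for cond in conditions:
        for rep in range(replicates):
            rng = np.random.default_rng(next(children))
            vpf = np.full(cond.n_factors, int(cond.variables_per_factor))
            phi = np.eye(cond.n_factors)
            iu = np.triu_indices(cond.n_factors, 1)
            while True:
                phi[iu] = rng.uniform(0.0, 0.50, size=len(iu[0]))
                phi = np.triu(phi) + np.triu(phi, 1).T
                if np.linalg.eigvalsh(phi).min() > 0:
                    break
            spec = build_model(
                cond.n_factors, vpf, (0.30, 0.80), CROSS_LOADING_SD,
                "all_positive", phi, rng,
            )
            data = factor_sim.generate_sample(spec, n, rng).data
            network = ggm.estimate_network(data)
            loading = revised_loadings(network, spec.membership)
            assigned = loading.assigned(spec.membership)
            simulated = spec.assigned_loadings
            for sim, rev in zip(simulated, assigned):
                rows.append({
                    "n_factors": cond.n_factors,
                    "variables_per_factor": int(cond.variables_per_factor),
                    "replicate": rep,
                    "simulated": float(sim),
                    "revised": float(rev),
                })
        logger.info("mapping condition %s done", cond.label())
    records = pd.DataFrame.from_records(rows)
    kept = records[records["simulated"] >= 0.30]
    slope_r = np.corrcoef(kept["revised"], kept["simulated"])[0, 1]
    stats = {
        "r_squared": float(slope_r**2),
        "congruence": tucker_congruence(
            kept["revised"].to_numpy(), kept["simulated"].to_numpy()
        ),
    }
    return records, stats


def mapping_heatmap_bins(records: pd.DataFrame) -> pd.DataFrame:
    """Two-digit bin counts of (simulated, revised) pairs, simulated >= 0.30."""
    kept = records[records["simulated"] >= 0.30].copy()
    kept["simulated_bin"] = kept["simulated"].round(2)
    kept["revised_bin"] = kept["revised"].round(2)
    return (
        kept.groupby(["simulated_bin", "revised_bin"])
        .size()
        .rename("count")
        .reset_index()
    )


def run_example(
    name: str,
    seed: int = 0,
    scale_factor: float = 1.0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run a named example; optionally write its tables as CSV.

    ``scale_factor`` scales replicate counts of the simulation examples
    relative to full scale (100 for ``small_sim``, 500 per condition for
    ``mapping_sim``); the fixed-seed examples ignore it.
    """
    if name not in EXAMPLE_NAMES:
        raise ValueError(f"unknown example {name!r}; choose from {EXAMPLE_NAMES}")
    out: dict
    if name in ("table1", "table2"):
        example = table1_example(seed) if name == "table1" else table2_example(seed)
        out = example | {
            "tables": {
                f"loadings_{k}": v for k, v in example["loading_tables"].items()
            }
        }
    elif name == "small_sim":
        replicates = max(1, round(100 * scale_factor))
        records, summary = small_simulation(seed, replicates)
        out = {
            "records": records,
            "summary": summary,
            "tables": {
                "records": records,
                "summary": pd.DataFrame([summary]),
            },
        }
    else:  # mapping_sim
        replicates = max(1, round(500 * scale_factor / 100))
        records, stats = mapping_simulation(seed, replicates)
        out = {
            "records": records,
            "summary": stats,
            "tables": {
                "records": records,
                "summary": pd.DataFrame([stats]),
                "heatmap_bins": mapping_heatmap_bins(records),
            },
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for table_name, frame in out["tables"].items():
            frame.to_csv(out_dir / f"{name}_{table_name}.csv")
        if "network" in out:
            ggm.write_network(out_dir / f"{name}_network.csv", out["network"])
            for method in METHODS:
                write_loadings(
                    out_dir / f"{name}_{method}_loadings.csv",
                    out["results"][method]["loading"],
                )
    return out
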
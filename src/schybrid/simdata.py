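"""Synthetic branching-differentiation data with known per-cell fate mixtures.

The simulator emulates a lineage-negative bone-marrow differentiation
continuum: a stem-like root, branch intermediates, and committed endpoint
progenitors. Every cell sits on one edge of the branch topology with a
latent *fate-mixture weight* ``w`` — the weight of the downstream (child)
type versus the upstream (parent) type. Cells with ``w`` inside the hybrid
window [0.4, 0.6] are ground-truth hybrid cells; the fraction of such cells
per edge is a planted, recoverable parameter.

Generative model
----------------
Each cell type owns a disjoint gene *program*. A cell's log mean expression
blends the two flanking programs with weights ``(1 - w, w)`` on top of a
per-gene baseline; counts are negative binomial (gamma–Poisson) with
per-dataset dispersion, and library sizes are lognormal. Program activation
rises along pseudotime through a logistic switch; pseudotime is placed so
that activation equals the fate-mixture weight, which keeps expression
log-linear in ``w``.

Committed (non-hybrid) cells draw ``w`` from a U-shaped Beta(0.2, 0.2)
truncated outside a guard band around the hybrid window: committed states
behave as metastable attractors near the trajectory endpoints, and the gap
keeps "truth-committed" and "truth-hybrid" distinguishable under
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse, stats

from . import dataio
from .dataio import CellTable, DataValidationError, ExpressionMatrix

#: closed window of fate-mixture weights defining ground-truth hybrid cells.
TRUTH_HYBRID_WINDOW = (0.4, 0.6)
#: committed cells keep their mixture weight outside this guard band.
COMMITTED_EXCLUSION = (0.35, 0.65)
#: shape of the U-shaped committed-weight distribution.
_COMMITTED_BETA = 0.2
#: steepness of the pseudotime -> activation logistic switch.
_SIGMOID_K = 8.0


class SimulationError(ValueError):
    """Invalid topology or configuration."""


@dataclass(frozen=True)
class BranchTopology:
    """Directed differentiation tree: single root, acyclic, all reachable."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        nodes = set(self.nodes)
        if len(nodes) != len(self.nodes):
            raise SimulationError("duplicate node labels")
        for parent, child in self.edges:
            if parent not in nodes or child not in nodes:
                raise SimulationError(f"edge ({parent}, {child}) uses unknown node")
        children = [c for _, c in self.edges]
        if len(set(children)) != len(children):
            raise SimulationError("a node has two parents (not a tree)")
        roots = nodes - set(children)
        if len(roots) != 1:
            raise SimulationError(f"expected a single root, found {sorted(roots)}")
        # reachability from the root implies acyclicity for a tree
        reached = set(roots)
        frontier = list(roots)
        adj: dict[str, list[str]] = {}
        for p, c in self.edges:
            adj.setdefault(p, []).append(c)
        while frontier:
            for c in adj.get(frontier.pop(), []):
                if c in reached:
                    raise SimulationError("topology contains a cycle")
                reached.add(c)
                frontier.append(c)
        if reached != nodes:
            raise SimulationError(
                f"nodes {sorted(nodes - reached)} unreachable from the root"
            )

    @property
    def root(self) -> str:
        return (set(self.nodes) - {c for _, c in self.edges}).pop()


def default_topology() -> BranchTopology:
    """Five-type hematopoietic caricature.

    HSC-like root, GMP/MEP-like branch intermediates, and Pro_NE/Pro_Mast-like
    endpoint progenitors — the subset of the lineage-negative compartment on
    which the plasticity statistics are usually read out.
    """
    return BranchTopology(
        nodes=("HSC", "GMP", "MEP", "Pro_NE", "Pro_Mast"),
        edges=(("HSC", "GMP"), ("HSC", "MEP"),
               ("GMP", "Pro_NE"), ("MEP", "Pro_Mast")),
    )


@dataclass
class SimConfig:
    """Simulator knobs.

    ``program_effect_size`` is the log-fold step height of a fully active
    program over baseline; ``nb_dispersion`` is the negative-binomial size
    parameter (smaller = noisier); ``hybrid_fraction_target`` is the expected
    per-edge fraction of truth-hybrid cells.
    """

    n_cells: int = 2000
    n_genes: int = 250
    genes_per_program: int = 40
    program_effect_size: float = 2.0
    nb_dispersion: float = 8.0
    library_size_mean: float = 8000.0
    library_size_sigma: float = 0.35
    hybrid_fraction_target: float = 0.10
    group: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "genes_per_program"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        for name in ("program_effect_size", "nb_dispersion",
                     "library_size_mean", "library_size_sigma"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not 0.0 <= self.hybrid_fraction_target <= 1.0:
            raise SimulationError("hybrid_fraction_target must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth per cell: edge, pseudotime and fate-mixture weight.

    ``weight_child`` is the mixture weight of the downstream (child) type;
    the parent's weight is its complement.
    """

    df: pd.DataFrame

    COLUMNS = ("cell_id", "edge_parent", "edge_child", "true_type",
               "pseudotime", "weight_child")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise DataValidationError(f"truth table missing columns {missing}")
        w = self.df["weight_child"].to_numpy(float)
        if w.size and (w.min() < 0 or w.max() > 1):
            raise DataValidationError("fate-mixture weights outside [0, 1]")

    def edge_mask(self, edge: tuple[str, str]) -> np.ndarray:
        parent, child = edge
        return ((self.df["edge_parent"] == parent)
                & (self.df["edge_child"] == child)).to_numpy()


def _sigmoid(t: np.ndarray) -> np.ndarray:
    """Logistic program switch rescaled to hit exactly 0 and 1 at t = 0, 1."""
    lo = 1.0 / (1.0 + np.exp(_SIGMOID_K / 2.0))
    hi = 1.0 / (1.0 + np.exp(-_SIGMOID_K / 2.0))
    return (1.0 / (1.0 + np.exp(-_SIGMOID_K * (t - 0.5))) - lo) / (hi - lo)


def _inverse_sigmoid(w: np.ndarray) -> np.ndarray:
    lo = 1.0 / (1.0 + np.exp(_SIGMOID_K / 2.0))
    hi = 1.0 / (1.0 + np.exp(-_SIGMOID_K / 2.0))
    s = lo + np.asarray(w, float) * (hi - lo)
    return 0.5 + np.log(s / (1.0 - s)) / _SIGMOID_K


def _draw_committed_weights(rng: np.random.Generator, n: int) -> np.ndarray:
    """U-shaped committed weights avoiding the guard band around the window."""
    a = _COMMITTED_BETA
    lo, hi = COMMITTED_EXCLUSION
    cdf_lo = stats.beta.cdf(lo, a, a)
    u = rng.random(n) * cdf_lo
    w = stats.beta.ppf(u, a, a)
    upper = rng.random(n) < 0.5
    w = np.where(upper, 1.0 - w, w)
    return np.clip(w, 0.0, 1.0)


def simulate_branching(
    topology: BranchTopology | None = None,
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, CellTable, SyntheticTruth]:
    """Draw a synthetic branching dataset; bitwise reproducible under a seed.

    Reference labels follow the truth with the tie rule that a mixture
    weight >= 0.5 assigns the downstream type.
    """
    topology = topology or default_topology()
    config = config or SimConfig()
    n_programs = len(topology.nodes)
    if config.n_genes < n_programs * config.genes_per_program:
        raise SimulationError(
            f"n_genes={config.n_genes} cannot hold {n_programs} programs of "
            f"{config.genes_per_program} genes"
        )
    rng = np.random.default_rng(config.seed)

    gene_ids = np.array([f"g{i:05d}" for i in range(config.n_genes)], dtype=object)
    program_genes = {
        node: np.arange(i * config.genes_per_program, (i + 1) * config.genes_per_program)
        for i, node in enumerate(topology.nodes)
    }

    # per-gene baseline rates (lognormal, arbitrary units; normalized per cell)
    log_base = rng.normal(loc=0.0, scale=0.5, size=config.n_genes)

    edges = list(topology.edges)
    n_edges = len(edges)
    counts_per_edge = np.full(n_edges, config.n_cells // n_edges, dtype=int)
    counts_per_edge[: config.n_cells % n_edges] += 1

    edge_parent, edge_child, weights, hybrids = [], [], [], []
    for (parent, child), n_edge in zip(edges, counts_per_edge):
        is_hybrid = rng.random(n_edge) < config.hybrid_fraction_target
        w = np.empty(n_edge)
        n_h = int(is_hybrid.sum())
        lo, hi = TRUTH_HYBRID_WINDOW
        w[is_hybrid] = lo + rng.random(n_h) * (hi - lo)
        w[~is_hybrid] = _draw_committed_weights(rng, n_edge - n_h)
        edge_parent.extend([parent] * n_edge)
        edge_child.extend([child] * n_edge)
        weights.append(w)
        hybrids.append(is_hybrid)

    w = np.concatenate(weights)
    edge_parent = np.asarray(edge_parent, dtype=object)
    edge_child = np.asarray(edge_child, dtype=object)
    pseudotime = _inverse_sigmoid(w)
    true_type = np.where(w >= 0.5, edge_child, edge_parent)
    cell_ids = np.array([f"cell{i:06d}" for i in range(len(w))], dtype=object)

    # log mean: baseline + effect * (parent program * (1-w) + child program * w)
    log_mu = np.tile(log_base, (len(w), 1))
    for i in range(len(w)):
        log_mu[i, program_genes[edge_parent[i]]] += config.program_effect_size * (1.0 - w[i])
        log_mu[i, program_genes[edge_child[i]]] += config.program_effect_size * w[i]
    mu = np.exp(log_mu)
    mu /= mu.sum(axis=1, keepdims=True)

    lib = rng.lognormal(
        mean=np.log(config.library_size_mean) - config.library_size_sigma ** 2 / 2.0,
        sigma=config.library_size_sigma, size=len(w),
    )
    lam = mu * lib[:, None]
    shape = config.nb_dispersion
    counts = rng.poisson(rng.gamma(shape, lam / shape))

    expr = ExpressionMatrix(sparse.csr_matrix(counts), cell_ids, gene_ids,
                            dataio.RAW_COUNTS)
    cells = CellTable(pd.DataFrame({
        "cell_id": cell_ids,
        "reference_label": true_type,
        "group": config.group,
    }), vocabulary=tuple(sorted(topology.nodes)))
    truth = SyntheticTruth(pd.DataFrame({
        "cell_id": cell_ids,
        "edge_parent": edge_parent,
        "edge_child": edge_child,
        "true_type": true_type,
        "pseudotime": pseudotime,
        "weight_child": w,
        "is_hybrid": np.concatenate(hybrids),
    }))
    return expr, cells, truth


def truth_hybrid_fraction(truth: SyntheticTruth, edge: tuple[str, str],
                          window: tuple[float, float] = TRUTH_HYBRID_WINDOW) -> float:
    """Fraction of an edge's cells with mixture weight in the closed window."""
    mask = truth.edge_mask(edge)
    if not mask.any():
        raise SimulationError(f"no cells on edge {edge}")
    w = truth.df.loc[mask, "weight_child"].to_numpy(float)
    lo, hi = window
    return float(np.mean((w >= lo) & (w <= hi)))


def write_fixture(expr: ExpressionMatrix, cells: CellTable, truth: SyntheticTruth,
                  directory: str | Path, config: SimConfig | None = None,
                  overwrite: bool = False) -> Path:
    """Write a simulated dataset in the standard on-disk formats."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    dataio.write_expression(expr, directory)
    dataio.write_cell_table(cells, directory / "cells_annotation.tsv")
    from ._utils import atomic_write_text
    atomic_write_text(directory / "truth.tsv", truth.df.to_csv(sep="\t", index=False))
    meta = {"config": config.to_dict() if config else None}
    files = [directory / "matrix.mtx", directory / "cells.tsv",
             directory / "genes.tsv", directory / "cells_annotation.tsv",
             directory / "truth.tsv"]
    from ._utils import write_manifest
    return write_manifest(directory, files, meta=meta, name="fixture_manifest.json")
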
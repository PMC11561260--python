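"""End-to-end orchestration helpers: simulate -> train -> predict -> score.

These drive the same library calls the CLI exposes, and are what the
recovery experiments use: simulate a branching dataset with a planted
hybrid fraction, train the classifier on the reference labels, predict
probabilities for every cell, and measure P_hc on a planted edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifier, plasticity, simdata
from .classifier import ClassifierModel
from .dataio import CellTable, ExpressionMatrix, GeneSetCollection, ProbMatrix
from .simdata import BranchTopology, SimConfig, SyntheticTruth


@dataclass
class PipelineRun:
    expr: ExpressionMatrix
    cells: CellTable
    truth: SyntheticTruth
    model: ClassifierModel
    prob: ProbMatrix
    topology: BranchTopology
    config: SimConfig


def simulate_fit_predict(
    config: SimConfig | None = None,
    topology: BranchTopology | None = None,
    gene_sets: GeneSetCollection | None = None,
    backend: str = "centroid",
    hyperparams: dict | None = None,
) -> PipelineRun:
    """Simulate a dataset, train on its reference labels, predict all cells."""
    topology = topology or simdata.default_topology()
    config = config or SimConfig()
    expr, cells, truth = simdata.simulate_branching(topology, config)
    model = classifier.fit_classifier(expr, cells, gene_sets=gene_sets,
                                      hyperparams=hyperparams,
                                      seed=config.seed, backend=backend)
    prob = classifier.predict_proba(model, expr)
    return PipelineRun(expr, cells, truth, model, prob, topology, config)


def edge_phc(run: PipelineRun, edge: tuple[str, str],
             window: tuple[float, float] = plasticity.HYBRID_WINDOW,
             restrict_to_edge: bool = True) -> float:
    """Pipeline P_hc for the (parent, child) pair of one trajectory edge.

    With ``restrict_to_edge`` the eligible population M is exactly the
    cells planted on that edge (matching the ground-truth denominator);
    otherwise M is every cell whose reference label is one of the pair,
    which for shared labels (e.g. a root feeding two branches) includes
    cells from neighboring edges.
    """
    parent, child = edge
    if restrict_to_edge:
        mask = run.truth.edge_mask(edge)
        eligible = run.truth.df.loc[mask, "cell_id"].tolist()
        res = plasticity.fate_bias(run.prob, child, parent, eligibility=eligible)
    else:
        res = plasticity.fate_bias(run.prob, child, parent, eligibility=run.cells)
    return plasticity.phc(res, window)


def recovery_curve(fractions, seeds, n_cells: int = 2000,
                   edge: tuple[str, str] = ("HSC", "GMP"),
                   window: tuple[float, float] = plasticity.HYBRID_WINDOW,
                   **config_kwargs) -> dict[float, float]:
    """Mean pipeline P_hc per planted hybrid fraction across seeds."""
    out = {}
    for f in fractions:
        values = []
        for seed in seeds:
            cfg = SimConfig(n_cells=n_cells, hybrid_fraction_target=float(f),
                            seed=int(seed), **config_kwargs)
            run = simulate_fit_predict(cfg)
            values.append(edge_phc(run, edge, window))
        out[float(f)] = float(np.mean(values))
    return out
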
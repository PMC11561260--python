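"""Probabilistic cell-type annotation with reference transfer.

Downstream plasticity statistics consume only a per-cell probability simplex
over cell types, so the annotator is a pluggable contract: anything that
turns expression into calibrated class probabilities can stand here
(genuine external annotator output is ingested through
:func:`schybrid.dataio.read_probability_table`).

Two built-in backends share the same feature pipeline (log-normalization,
then gene-set score features or top-variance genes, then standardization):

``centroid`` (default)
    Constrained least-squares mixture deconvolution: each cell's feature
    vector is decomposed as a convex combination of robust (per-feature
    median) class centroids, solved with non-negativity and sum-to-one
    constraints. The weights are the class probabilities. A cell lying
    between two types receives intermediate weight on both — exactly the
    hybrid signal the fate-bias statistic measures. This is the same family
    of annotator as quadratic-programming identity deconvolution tools used
    for hybrid-state detection.

``multinomial``
    L2-regularized multinomial logistic regression on the same features.
    Its probabilities are posterior class memberships; on well-separated
    references they saturate near 0/1, which makes it a faithful hard
    annotator but a poor hybrid meter.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.optimize import nnls
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from . import dataio
from .dataio import (CellTable, DataValidationError, ExpressionMatrix,
                     GeneSetCollection, ProbMatrix)

DEFAULT_TARGET_SUM = 1e4
DEFAULT_HYPERPARAMS = {
    "n_top_genes": 200,      # feature genes when no gene sets are given
    "C": 1.0,                # inverse L2 strength (multinomial backend)
    "target_sum": DEFAULT_TARGET_SUM,
    "case_insensitive": False,
}
#: warn when more than this fraction of model genes is absent from a query.
COVERAGE_WARN_FRACTION = 0.2
#: minimum mixture weight for a cell to count as a committed archetype member
#: during centroid purification.
CENTROID_CONFIDENCE = 0.9
MIN_CONFIDENT_CELLS = 20


class ClassifierError(ValueError):
    """Invalid training or prediction inputs."""


def normalize(expr: ExpressionMatrix, target_sum: float = DEFAULT_TARGET_SUM) -> ExpressionMatrix:
    """Scale each cell to a fixed library size, then log1p.

    All-zero cells cannot be normalized; they are dropped with a warning.
    Re-normalizing an already log-normalized matrix is a usage error.
    """
    if expr.layer_tag != dataio.RAW_COUNTS:
        raise ClassifierError("normalize() expects a raw_counts matrix")
    vals = expr.values
    totals = np.asarray(vals.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        dropped = expr.cell_ids[~keep]
        warnings.warn(f"dropping {len(dropped)} all-zero cell(s): "
                      f"{list(dropped[:5])}{'...' if len(dropped) > 5 else ''}")
        vals = vals[keep]
        totals = totals[keep]
    scale = target_sum / totals
    if sparse.issparse(vals):
        out = sparse.diags(scale) @ vals.tocsr()
        out.data = np.log1p(out.data)
        out = out.tocsr()
    else:
        out = np.log1p(np.asarray(vals, dtype=float) * scale[:, None])
    return ExpressionMatrix(out, expr.cell_ids[keep], expr.gene_ids, dataio.LOGNORM)


@dataclass
class FeatureSpec:
    """How expression becomes the classifier's feature matrix.

    ``kind`` is ``"gene_sets"`` (one mean-expression score per set) or
    ``"genes"`` (selected genes used directly). ``gene_lists`` holds the
    training-time resolved gene ids per feature; query genes absent from a
    later matrix contribute zero.
    """

    kind: str
    names: list[str]
    gene_lists: list[list[str]]

    def all_genes(self) -> set[str]:
        return {g for genes in self.gene_lists for g in genes}


@dataclass
class ClassifierModel:
    backend: str
    feature_spec: FeatureSpec
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    class_labels: np.ndarray
    norm_target: float
    seed: int
    centroids: np.ndarray | None = None          # classes x features
    estimator: object | None = None              # fitted sklearn model
    training_log: dict = field(default_factory=dict)


def _feature_matrix(expr: ExpressionMatrix, spec: FeatureSpec,
                    check_coverage: bool = False) -> np.ndarray:
    """Assemble the n_cells x n_features score matrix.

    Missing genes contribute zero; each gene-set score divides by the
    training-time set size so absence lowers the score rather than hiding it.
    """
    index = expr.gene_index()
    if check_coverage:
        model_genes = spec.all_genes()
        missing = {g for g in model_genes if g not in index}
        if model_genes and len(missing) == len(model_genes):
            raise ClassifierError("query shares no genes with the model")
        if model_genes and len(missing) / len(model_genes) > COVERAGE_WARN_FRACTION:
            warnings.warn(
                f"{len(missing)}/{len(model_genes)} model genes missing from "
                "the query; missing genes are treated as zero"
            )
    dense = expr.to_dense()
    out = np.zeros((expr.n_cells, len(spec.names)), dtype=float)
    for j, genes in enumerate(spec.gene_lists):
        cols = [index[g] for g in genes if g in index]
        if cols:
            out[:, j] = dense[:, cols].sum(axis=1) / len(genes)
    return out


def _build_feature_spec(expr: ExpressionMatrix, gene_sets: GeneSetCollection | None,
                        hyperparams: dict) -> FeatureSpec:
    if gene_sets is not None:
        names, lists = [], []
        for name in gene_sets.names():
            hit, _missing = gene_sets.match(name, expr.gene_ids,
                                            hyperparams["case_insensitive"])
            if not hit:
                warnings.warn(f"gene set {name!r} matches no genes in the matrix; skipped")
                continue
            names.append(name)
            lists.append(hit)
        if not names:
            raise ClassifierError("gene sets match zero genes in the reference matrix")
        return FeatureSpec("gene_sets", names, lists)
    dense = expr.to_dense()
    variances = dense.var(axis=0)
    n_top = min(int(hyperparams["n_top_genes"]), expr.n_genes)
    # stable selection: sort by (-variance, gene order)
    order = np.lexsort((np.arange(expr.n_genes), -variances))[:n_top]
    order = np.sort(order)
    genes = [str(g) for g in expr.gene_ids[order]]
    return FeatureSpec("genes", genes, [[g] for g in genes])


def _standardize(F: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (F - mean) / scale


def _fit_backend(backend: str, Z: np.ndarray, y: np.ndarray,
                 classes: np.ndarray, hyperparams: dict, seed: int,
                 scale: np.ndarray | None = None):
    """Return (centroids, estimator) for the requested backend."""
    if backend == "centroid":
        centroids = np.vstack([np.median(Z[y == c], axis=0) for c in classes])
        # One purification pass: labeled populations on a differentiation
        # continuum contain partially committed members that drag the class
        # centroid toward neighboring types, which flattens the probability
        # scale. Re-estimating each centroid from its confidently assigned
        # members (weight >= CENTROID_CONFIDENCE) anchors it near the
        # committed archetype. Falls back to the plain median for classes
        # with too few confident members.
        probs = _simplex_deconvolve(centroids, Z, scale)
        for k, c in enumerate(classes):
            confident = (y == c) & (probs[:, k] >= CENTROID_CONFIDENCE)
            if confident.sum() >= MIN_CONFIDENT_CELLS:
                centroids[k] = np.median(Z[confident], axis=0)
        return centroids, None
    if backend == "multinomial":
        est = LogisticRegression(C=float(hyperparams["C"]), max_iter=2000,
                                 random_state=seed)
        est.fit(Z, y)
        return None, est
    raise ClassifierError(f"unknown backend {backend!r}")


def _predict_backend(model: ClassifierModel, Z: np.ndarray) -> np.ndarray:
    if model.backend == "centroid":
        return _simplex_deconvolve(model.centroids, Z, model.scaler_scale)
    est = model.estimator
    probs = np.asarray(est.predict_proba(Z))
    # estimator classes_ are sorted, matching model.class_labels order
    return probs


def _simplex_deconvolve(centroids: np.ndarray, Z: np.ndarray,
                        scale: np.ndarray | None = None,
                        penalty: float = 1e3) -> np.ndarray:
    """Per-cell NNLS fit of feature vectors to convex centroid mixtures.

    The sum-to-one constraint is imposed through a heavily weighted extra
    equation, then enforced exactly by renormalization. NNLS returns exact
    zeros for inactive classes, so irrelevant types drop out of fate-bias
    denominators instead of collecting float dust.

    When the feature scaler is given, the design gains a free (signed,
    simplex-exempt) component along the standardized image of a uniform
    log-expression shift. Compositional normalization moves every
    log-feature of a cell by a common offset that depends on how much of
    the library its active programs absorb; this nuisance direction is not
    spanned by the centroids, and absorbing it keeps mixture weights from
    soaking up library-composition effects.
    """
    k = centroids.shape[0]
    cols = [centroids.T]
    if scale is not None:
        u = 1.0 / np.asarray(scale, dtype=float)
        norm = np.linalg.norm(u)
        if norm > 0:
            u = u / norm
            cols.extend([u[:, None], -u[:, None]])
    design = np.hstack(cols)
    constraint = np.zeros(design.shape[1])
    constraint[:k] = penalty
    A = np.vstack([design, constraint])
    out = np.empty((Z.shape[0], k), dtype=float)
    for i in range(Z.shape[0]):
        b = np.concatenate([Z[i], [penalty]])
        p, _ = nnls(A, b)
        p = p[:k]
        s = p.sum()
        out[i] = p / s if s > 0 else np.full(k, 1.0 / k)
    return out


def fit_classifier(
    ref: ExpressionMatrix,
    cells: CellTable,
    gene_sets: GeneSetCollection | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
    backend: str = "centroid",
) -> ClassifierModel:
    """Train a probability-emitting annotator on a labeled reference.

    A stratified 80/20 split provides a held-out hard-label accuracy for the
    training log; the returned model is refit on the full reference.
    Deterministic under a fixed seed.
    """
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})

    labels = cells.labels_for(ref.cell_ids)
    classes = np.asarray(sorted(set(labels)), dtype=object)
    if len(classes) < 2:
        raise ClassifierError("reference has a single class; need at least 2")
    if ref.n_cells < 1000:
        warnings.warn(
            f"reference has {ref.n_cells} cells; at least 1,000 are "
            "recommended for stable probabilities"
        )

    lognorm = ref if ref.layer_tag == dataio.LOGNORM else normalize(ref, hp["target_sum"])
    if lognorm.n_cells != ref.n_cells:
        labels = cells.labels_for(lognorm.cell_ids)

    spec = _build_feature_spec(lognorm, gene_sets, hp)
    F = _feature_matrix(lognorm, spec)
    mean = F.mean(axis=0)
    scale = F.std(axis=0)
    scale[scale < 1e-8] = 1.0
    Z = _standardize(F, mean, scale)

    # held-out diagnostic (skipped when a class is too small to stratify)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    heldout_accuracy = None
    if min(counts.values()) >= 5:
        idx_train, idx_test = train_test_split(
            np.arange(len(labels)), test_size=0.2, stratify=labels,
            random_state=seed)
        cent, est = _fit_backend(backend, Z[idx_train], labels[idx_train],
                                 classes, hp, seed, scale)
        probe = ClassifierModel(backend, spec, mean, scale, classes,
                                hp["target_sum"], seed, cent, est)
        probs = _predict_backend(probe, Z[idx_test])
        pred = classes[np.argmax(probs, axis=1)]
        heldout_accuracy = float(np.mean(pred == labels[idx_test]))

    centroids, estimator = _fit_backend(backend, Z, labels, classes, hp, seed, scale)
    log = {
        "backend": backend,
        "n_cells": int(len(labels)),
        "n_features": int(Z.shape[1]),
        "class_counts": counts,
        "heldout_accuracy": heldout_accuracy,
        "seed": int(seed),
        "hyperparams": {k: hp[k] for k in sorted(hp)},
    }
    return ClassifierModel(backend, spec, mean, scale, classes,
                           hp["target_sum"], seed, centroids, estimator, log)


def predict_proba(model: ClassifierModel, query: ExpressionMatrix) -> ProbMatrix:
    """Per-cell class probabilities for a query matrix.

    Raw queries are normalized with the model's recipe; genes absent from
    the query count as zero (with a coverage warning past 20% missing).
    """
    lognorm = (query if query.layer_tag == dataio.LOGNORM
               else normalize(query, model.norm_target))
    F = _feature_matrix(lognorm, model.feature_spec, check_coverage=True)
    Z = _standardize(F, model.scaler_mean, model.scaler_scale)
    probs = _predict_backend(model, Z)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return ProbMatrix(probs, lognorm.cell_ids, model.class_labels)


def assign_labels(prob: ProbMatrix) -> np.ndarray:
    """Hard labels: per-row argmax; ties go to the first label in vocabulary order."""
    return prob.class_labels[np.argmax(prob.probs, axis=1)]


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Serialize to a single archive file (deterministic bytes for equal models)."""
    from ._utils import atomic_write_bytes
    atomic_write_bytes(path, pickle.dumps(model, protocol=5))


def load_model(path: str | Path) -> ClassifierModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, ClassifierModel):
        raise ClassifierError(f"{path} does not contain a classifier model")
    return model
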
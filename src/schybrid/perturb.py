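"""In-silico gene-set knockouts with re-prediction by a fixed classifier.

A knockout zeroes the raw counts of every gene in a pathway/gene set, then
the *unchanged* trained classifier re-predicts cell identities on the
perturbed matrix. The knockout acts on raw counts, before normalization, so
per-cell library-size factors are recomputed from the post-knockout totals.
Comparing baseline vs perturbed cell-type fractions, P_hc values and ECDF
levels quantifies what the pathway contributes to identity and plasticity;
comparing a perturbed P_hc against a control and a disease condition yields
a reversed / partially-reversed / not-reversed call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import dataio
from .classifier import ClassifierModel, assign_labels, predict_proba
from .dataio import CellTable, ExpressionMatrix, GeneSetCollection, ProbMatrix
from .plasticity import DEFAULT_WINDOWS, HYBRID_WINDOW, fate_bias, phc

logger = logging.getLogger(__name__)

REVERSED = "reversed"
PARTIALLY_REVERSED = "partially_reversed"
NOT_REVERSED = "not_reversed"


class PerturbationError(ValueError):
    """Invalid knockout request or reversal inputs."""


@dataclass
class PerturbationResult:
    gene_set: str
    genes_hit: list[str]
    genes_missing: list[str]
    baseline: ProbMatrix
    perturbed: ProbMatrix
    fractions: pd.DataFrame                  # index class, columns baseline/perturbed
    phc: pd.DataFrame | None = None          # long: pair, window, baseline, perturbed
    reversal_calls: dict = field(default_factory=dict)


def knockout_gene_set(expr: ExpressionMatrix, genes: Iterable[str],
                      case_insensitive: bool = False,
                      name: str = "gene_set") -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Zero the columns of every matched gene in a raw-count matrix.

    Returns the perturbed matrix plus the genes hit and missing. Matching no
    gene at all is fatal — there would be nothing to knock out. Idempotent.
    """
    if expr.layer_tag != dataio.RAW_COUNTS:
        raise PerturbationError("knockout acts on raw counts, before normalization")
    genes = list(dict.fromkeys(genes))
    collection = GeneSetCollection({name: genes})
    hit, missing = collection.match(name, expr.gene_ids, case_insensitive)
    if not hit:
        raise PerturbationError(
            f"gene set {name!r}: none of {len(genes)} genes are in the matrix; "
            "nothing to knock out"
        )
    if missing:
        logger.info("gene set %s: %d gene(s) absent from the matrix: %s",
                    name, len(missing), missing[:5])
    index = expr.gene_index()
    cols = np.array([index[g] for g in hit], dtype=int)
    vals = expr.values
    if sparse.issparse(vals):
        out = vals.tocsc(copy=True)
        for c in cols:
            out.data[out.indptr[c]:out.indptr[c + 1]] = 0
        out.eliminate_zeros()
        out = out.tocsr()
    else:
        out = np.array(vals, copy=True)
        out[:, cols] = 0
    perturbed = ExpressionMatrix(out, expr.cell_ids.copy(), expr.gene_ids.copy(),
                                 expr.layer_tag)
    return perturbed, hit, missing


def _fraction_table(model_labels: np.ndarray, baseline: np.ndarray,
                    perturbed: np.ndarray) -> pd.DataFrame:
    classes = list(model_labels)
    def frac(labels: np.ndarray) -> pd.Series:
        s = pd.Series(labels).value_counts(normalize=True)
        return s.reindex(classes).fillna(0.0)
    return pd.DataFrame({"baseline": frac(baseline), "perturbed": frac(perturbed)})


def perturb_and_repredict(
    model: ClassifierModel,
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    set_name: str,
    pairs: Sequence[tuple[str, str]] = (),
    windows: Sequence[Sequence[float]] = (HYBRID_WINDOW,),
    eligibility: CellTable | None = None,
    case_insensitive: bool = False,
) -> PerturbationResult:
    """Knock out one gene set and re-predict with the same trained model.

    The model parameters are never refit on perturbed data; only the query
    matrix changes. P_hc columns are computed when fate pairs are given,
    with eligibility taken from the (unperturbed) reference annotation.
    """
    if set_name not in gene_sets:
        raise PerturbationError(f"unknown gene set {set_name!r}")
    baseline_prob = predict_proba(model, expr)
    knocked, hit, missing = knockout_gene_set(
        expr, gene_sets.sets[set_name], case_insensitive, name=set_name)
    perturbed_prob = predict_proba(model, knocked)

    fractions = _fraction_table(model.class_labels,
                                assign_labels(baseline_prob),
                                assign_labels(perturbed_prob))

    phc_rows = None
    if pairs:
        rows = []
        for pair in pairs:
            res_b = fate_bias(baseline_prob, *pair, eligibility=eligibility)
            res_p = fate_bias(perturbed_prob, *pair, eligibility=eligibility)
            for window in windows:
                rows.append({
                    "gene_set": set_name,
                    "pair": f"{pair[0]}_vs_{pair[1]}",
                    "window": f"[{window[0]:g}, {window[1]:g}]",
                    "baseline": phc(res_b, window),
                    "perturbed": phc(res_p, window),
                })
        phc_rows = pd.DataFrame(rows)
    return PerturbationResult(set_name, hit, missing, baseline_prob,
                              perturbed_prob, fractions, phc_rows)


def classify_reversal(control_phc: float, disease_phc: float,
                      perturbed_phc: float) -> str:
    """Three-way call for a perturbation's P_hc against control and disease.

    ``partially_reversed`` when the perturbed value lies in the closed band
    between the control and disease values (boundary equality counts as
    partial, to keep calls stable under float noise); ``reversed`` when it
    overshoots past the control value; ``not_reversed`` otherwise.
    """
    for name, v in (("control", control_phc), ("disease", disease_phc),
                    ("perturbed", perturbed_phc)):
        if not 0.0 <= v <= 1.0:
            raise PerturbationError(f"{name} P_hc {v!r} outside [0, 1]")
    lo, hi = sorted((control_phc, disease_phc))
    if lo <= perturbed_phc <= hi:
        return PARTIALLY_REVERSED
    if (control_phc <= disease_phc and perturbed_phc < control_phc) or (
            control_phc > disease_phc and perturbed_phc > control_phc):
        return REVERSED
    return NOT_REVERSED


def add_reversal_calls(result: PerturbationResult,
                       control: dict[tuple[str, str], float],
                       disease: dict[tuple[str, str], float]) -> PerturbationResult:
    """Attach reversal calls using the result's perturbed P_hc values.

    ``control`` and ``disease`` map ``(pair_name, window_name)`` to the
    reference-condition P_hc values.
    """
    if result.phc is None:
        raise PerturbationError("result has no P_hc values; pass fate pairs first")
    for _, row in result.phc.iterrows():
        key = (row["pair"], row["window"])
        if key in control and key in disease:
            result.reversal_calls[key] = classify_reversal(
                control[key], disease[key], row["perturbed"])
    return result


def perturbation_report(results: Sequence[PerturbationResult],
                        ecdf_threshold: float = 0.5) -> dict[str, pd.DataFrame]:
    """Long-format tables across perturbations.

    ``fractions``: gene_set x class fractions (baseline and perturbed sum to
    1 within each gene set and arm); ``phc``: gene_set x pair x window;
    ``ecdf``: fraction of cells whose probability for each class sits
    strictly below the threshold, baseline vs perturbed.
    """
    if not results:
        raise PerturbationError("no perturbation results to report")
    frac_rows, phc_frames, ecdf_rows = [], [], []
    for res in results:
        for cls, row in res.fractions.iterrows():
            frac_rows.append({"gene_set": res.gene_set, "class": cls,
                              "baseline": row["baseline"],
                              "perturbed": row["perturbed"]})
        if res.phc is not None:
            df = res.phc.copy()
            if res.reversal_calls:
                df["reversal"] = [
                    res.reversal_calls.get((r["pair"], r["window"]))
                    for _, r in df.iterrows()
                ]
            phc_frames.append(df)
        for cls in res.baseline.class_labels:
            ecdf_rows.append({
                "gene_set": res.gene_set, "class": cls,
                "baseline": float(np.mean(res.baseline.column(cls) < ecdf_threshold)),
                "perturbed": float(np.mean(res.perturbed.column(cls) < ecdf_threshold)),
            })
    report = {
        "fractions": pd.DataFrame(frac_rows),
        "ecdf": pd.DataFrame(ecdf_rows),
    }
    if phc_frames:
        report["phc"] = pd.concat(phc_frames, ignore_index=True)
    return report


def write_report(report: dict[str, pd.DataFrame], directory: str | Path) -> list[Path]:
    from ._utils import atomic_write_text
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.items():
        path = directory / f"perturbation_{name}.tsv"
        atomic_write_text(path, df.to_csv(sep="\t", index=False))
        written.append(path)
    return written
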
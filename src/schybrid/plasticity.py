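"""Fate bias, proportion of hybrid cells (P_hc), ECDF ambiguity curves, and
the reference-vs-prediction overlap matrix.

The central statistic: for an ordered fate pair (A, B), each eligible cell's
*fate bias* is

    bias = Prob.A / (Prob.A + Prob.B)

so 1 means definite commitment to A, 0 definite commitment to B, and 0.5 an
equal ("hybrid") state. The proportion of hybrid cells on that transition,

    P_hc = N / M,

counts the N eligible cells whose bias falls in a closed window (default
[0.4, 0.6], centered on the hybrid point) out of the M cells eligible for
the pair. A signed variant (Prob.A − Prob.B)/(Prob.A + Prob.B), which puts
the hybrid point at 0 instead of 0.5, is available for audit via
``formula="signed"``.

Eligibility (the M population) defaults to cells whose reference label is A
or B; an explicit cell list may be supplied instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataio import CellTable, ProbMatrix

logger = logging.getLogger(__name__)

HYBRID_WINDOW = (0.4, 0.6)
#: the window triplet reported in multi-window P_hc tables.
DEFAULT_WINDOWS = ((0.35, 0.65), (0.4, 0.6), (0.45, 0.55))


class PlasticityError(ValueError):
    """Invalid fate pair, window or eligible population."""


@dataclass
class FateBiasResult:
    """Per-cell bias values for an ordered fate pair.

    ``cell_ids`` are the M eligible cells retained; cells with
    Prob.A + Prob.B = 0 are excluded from M and listed in
    ``excluded_cells``.
    """

    type_a: str
    type_b: str
    cell_ids: np.ndarray
    bias: np.ndarray
    excluded_cells: np.ndarray
    formula: str = "ratio"

    @property
    def m(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "type_a": self.type_a,
            "type_b": self.type_b,
            "bias": self.bias,
        })


@dataclass
class ECDFCurve:
    """Empirical CDF of one type's predicted probability, per reference group."""

    target_type: str
    threshold: float
    values: dict[str, np.ndarray]            # group -> sorted probabilities
    cumulative: dict[str, np.ndarray]        # group -> fractions in (0, 1]
    threshold_fraction: dict[str, float]     # group -> frac strictly below threshold

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"group": g, "probability": self.values[g],
                          "cumulative": self.cumulative[g]})
            for g in self.values
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class OverlapMatrix:
    """Row-normalized reference-label x predicted-label proportions."""

    matrix: pd.DataFrame
    flag_threshold: float
    flagged_types: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.matrix


def _resolve_eligible(prob: ProbMatrix, type_a: str, type_b: str,
                      eligibility: CellTable | Iterable[str] | None) -> np.ndarray:
    if eligibility is None:
        return prob.cell_ids
    if isinstance(eligibility, CellTable):
        mask = eligibility.df["reference_label"].isin([type_a, type_b])
        wanted = set(eligibility.df.loc[mask, "cell_id"])
        return np.array([c for c in prob.cell_ids if c in wanted], dtype=object)
    wanted = list(dict.fromkeys(eligibility))
    have = set(map(str, prob.cell_ids))
    missing = [c for c in wanted if str(c) not in have]
    if missing:
        raise PlasticityError(f"eligible cells absent from probabilities: {missing[:5]}")
    return np.asarray(wanted, dtype=object)


def fate_bias(prob: ProbMatrix, type_a: str, type_b: str,
              eligibility: CellTable | Iterable[str] | None = None,
              formula: str = "ratio") -> FateBiasResult:
    """Per-cell fate bias of A against B over the eligible population."""
    if type_a == type_b:
        raise PlasticityError("fate pair must use two distinct types")
    for t in (type_a, type_b):
        if t not in set(prob.class_labels):
            raise PlasticityError(f"unknown class label {t!r}")
    if formula not in ("ratio", "signed"):
        raise PlasticityError(f"unknown bias formula {formula!r}")

    eligible = _resolve_eligible(prob, type_a, type_b, eligibility)
    if len(eligible) == 0:
        raise PlasticityError(f"no eligible cells for pair ({type_a}, {type_b})")
    sub = prob.subset(eligible)
    pa = sub.column(type_a)
    pb = sub.column(type_b)
    denom = pa + pb
    keep = denom > 0
    excluded = sub.cell_ids[~keep]
    if excluded.size:
        logger.info("pair (%s, %s): %d cell(s) with Prob.A+Prob.B=0 excluded from M",
                    type_a, type_b, excluded.size)
    if not keep.any():
        raise PlasticityError(
            f"all eligible cells have zero probability mass on ({type_a}, {type_b})"
        )
    if formula == "ratio":
        bias = pa[keep] / denom[keep]
    else:
        bias = (pa[keep] - pb[keep]) / denom[keep]
    return FateBiasResult(type_a, type_b, sub.cell_ids[keep], bias, excluded, formula)


def _check_window(window: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(window[0]), float(window[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise PlasticityError(f"window {window} must satisfy 0 <= lo <= hi <= 1")
    return lo, hi


def phc(result: FateBiasResult, window: Sequence[float] = HYBRID_WINDOW) -> float:
    """Proportion of eligible cells whose bias lies in the closed window."""
    lo, hi = _check_window(window)
    if result.m == 0:
        raise PlasticityError("empty eligible population (M = 0)")
    n = int(np.sum((result.bias >= lo) & (result.bias <= hi)))
    return n / result.m


def phc_table(prob: ProbMatrix, pairs: Sequence[tuple[str, str]],
              windows: Sequence[Sequence[float]] = DEFAULT_WINDOWS,
              eligibility: CellTable | None = None,
              as_percent: bool = True) -> pd.DataFrame:
    """P_hc per (group, window) row and fate-pair column.

    With a cell table, rows are produced per annotation group; without one,
    a single ``all`` group covers every cell. Percentages are rounded to two
    decimals.
    """
    if eligibility is not None:
        groups = list(dict.fromkeys(eligibility.df["group"]))
    else:
        groups = ["all"]
    rows = []
    index = []
    for group in groups:
        if eligibility is not None:
            sub_table = CellTable(
                eligibility.df[eligibility.df["group"] == group].copy(),
                vocabulary=eligibility.vocabulary)
        else:
            sub_table = None
        results = {
            pair: fate_bias(prob, pair[0], pair[1], eligibility=sub_table)
            for pair in pairs
        }
        for window in windows:
            lo, hi = _check_window(window)
            row = {}
            for pair, res in results.items():
                value = phc(res, (lo, hi))
                row[f"{pair[0]}_vs_{pair[1]}"] = (
                    round(100.0 * value, 2) if as_percent else value)
            rows.append(row)
            index.append((group, f"[{lo:g}, {hi:g}]"))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["group", "bias_range"]))
    return table


def ecdf_curve(prob: ProbMatrix, target_type: str, groups: CellTable,
               threshold: float = 0.5) -> ECDFCurve:
    """Per-group empirical CDF of the target type's probability column.

    ``threshold_fraction`` is the fraction of each group's cells with a
    probability strictly below the threshold. Empty groups are omitted with
    a warning.
    """
    if target_type not in set(prob.class_labels):
        raise PlasticityError(f"unknown class label {target_type!r}")
    col = dict(zip(prob.cell_ids, prob.column(target_type)))
    values: dict[str, np.ndarray] = {}
    cumulative: dict[str, np.ndarray] = {}
    frac: dict[str, float] = {}
    for label in dict.fromkeys(groups.df["reference_label"]):
        ids = groups.df.loc[groups.df["reference_label"] == label, "cell_id"]
        vals = np.sort([col[c] for c in ids if c in col])
        if vals.size == 0:
            warnings.warn(f"group {label!r} has no cells with probabilities; omitted")
            continue
        values[label] = vals
        cumulative[label] = np.arange(1, vals.size + 1) / vals.size
        frac[label] = float(np.mean(vals < threshold))
    return ECDFCurve(target_type, threshold, values, cumulative, frac)


def overlap_matrix(reference: CellTable, predicted, flag_threshold: float = 0.8) -> OverlapMatrix:
    """Row-normalized confusion of reference labels against predicted labels.

    ``predicted`` is a mapping / pandas Series keyed by cell id, or an array
    aligned with the reference table's row order. Every row sums to 1; rows
    whose diagonal entry falls below ``flag_threshold`` are flagged as
    high-plasticity ("flexible") identities.
    """
    ref_labels = reference.df["reference_label"].to_numpy(object)
    ids = reference.cell_ids
    if isinstance(predicted, pd.Series):
        pred = predicted.reindex(ids).to_numpy(object)
    elif isinstance(predicted, dict):
        pred = np.array([predicted.get(c) for c in ids], dtype=object)
    else:
        pred = np.asarray(predicted, dtype=object)
        if len(pred) != len(ids):
            raise PlasticityError(
                f"{len(pred)} predictions for {len(ids)} reference cells")
    if any(p is None for p in pred):
        raise PlasticityError("some reference cells have no prediction")
    if not set(ref_labels) & set(pred):
        raise PlasticityError("reference and predicted label sets are disjoint")

    counts = pd.crosstab(pd.Series(ref_labels, name="reference"),
                         pd.Series(pred, name="predicted"))
    counts = counts.reindex(sorted(counts.index), axis=0)
    counts = counts.reindex(sorted(counts.columns), axis=1)
    matrix = counts.div(counts.sum(axis=1), axis=0)
    flagged = [r for r in matrix.index
               if (matrix.loc[r, r] if r in matrix.columns else 0.0) < flag_threshold]
    return OverlapMatrix(matrix, flag_threshold, flagged)
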
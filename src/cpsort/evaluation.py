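"""Multi-class evaluation: reference-set preparation, confusion matrices,
the Gorodkin K-category correlation coefficient R_K, and per-class
precision / recall / F1.

R_K generalises the binary Matthews correlation to a K x K confusion matrix
C with N = sum(C), trace c, truth (row) totals t_k and prediction (column)
totals p_k::

    R_K = (c*N - sum_k p_k t_k) / sqrt((N^2 - sum_k p_k^2) * (N^2 - sum_k t_k^2))

R_K ranges over [-1, 1]; 1 is a perfect prediction and 0 indicates random
assignment.  Degenerate denominators (a constant truth or prediction
vector) return 0 by convention, as does precision with no positive calls;
both events are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledSet:
    """Per-protein (truth, predicted) labels over an ordered category universe."""

    ids: tuple[str, ...]
    truth: tuple[str, ...]
    predicted: tuple[str, ...]
    universe: tuple[str, ...]

    def __post_init__(self):
        if not (len(self.ids) == len(self.truth) == len(self.predicted)):
            raise ValueError("ids/truth/predicted must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in labeled set")
        u = set(self.universe)
        stray = (set(self.truth) | set(self.predicted)) - u
        if stray:
            raise ValueError(f"labels outside the category universe: {sorted(stray)}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]], universe: Sequence[str] | None = None
    ) -> "LabeledSet":
        ids, truth, pred = zip(*records) if records else ((), (), ())
        if universe is None:
            universe = sorted(set(truth) | set(pred))
        return cls(tuple(ids), tuple(truth), tuple(pred), tuple(universe))


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


def dedupe_nterm(records: Sequence, k: int = 60) -> list:
    """Collapse proteins sharing an identical N-terminus (first ``k`` residues).

    Among records whose first ``min(k, len)`` residues are identical, only
    the first is kept; merges are logged.  Operates on any objects with
    ``id`` and ``sequence`` attributes.
    """
    seen: dict[str, str] = {}
    out = []
    for rec in records:
        key = rec.sequence[:k]
        if key in seen:
            log.info("dedupe: %s shares first %d residues with %s; dropped", rec.id, k, seen[key])
            continue
        seen[key] = rec.id
        out.append(rec)
    return out


def aggregate_categories(labels: Sequence[str], mapping: Mapping[str, str]) -> list[str]:
    """Relabel categories through a total mapping (e.g. fold PPC into a
    secretory super-class).  Unmapped labels are an error naming the label."""
    out = []
    for lab in labels:
        if lab not in mapping:
            raise KeyError(f"label {lab!r} missing from aggregation mapping")
        out.append(mapping[lab])
    return out


def aggregate_labeled_set(
    labeled: LabeledSet,
    mapping: Mapping[str, str],
    axis: str = "both",
) -> LabeledSet:
    """Apply a category aggregation to truth, prediction, or both axes.

    Published per-class tables sometimes aggregate only one side (e.g. a
    truth-side super-class scored against raw predictions); ``axis`` selects
    "truth", "predicted", or "both".
    """
    if axis not in {"truth", "predicted", "both"}:
        raise ValueError(f"axis must be truth/predicted/both, got {axis!r}")
    truth = aggregate_categories(labeled.truth, mapping) if axis in {"truth", "both"} else list(labeled.truth)
    pred = aggregate_categories(labeled.predicted, mapping) if axis in {"predicted", "both"} else list(labeled.predicted)
    universe = sorted(set(truth) | set(pred))
    return LabeledSet(labeled.ids, tuple(truth), tuple(pred), tuple(universe))


def confusion(labeled: LabeledSet) -> pd.DataFrame:
    """K x K confusion counts, truth on rows and prediction on columns."""
    k = len(labeled.universe)
    idx = {c: i for i, c in enumerate(labeled.universe)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(labeled.truth, labeled.predicted):
        counts[idx[t], idx[p]] += 1
    return pd.DataFrame(counts, index=list(labeled.universe), columns=list(labeled.universe))


def gorodkin_rk(cm: pd.DataFrame | np.ndarray) -> float:
    """K-category correlation coefficient from a square confusion matrix."""
    c = np.asarray(cm, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    trace = np.trace(c)
    t = c.sum(axis=1)  # truth (row) totals
    p = c.sum(axis=0)  # prediction (column) totals
    num = trace * n - float(p @ t)
    den = math.sqrt(max(n * n - float(p @ p), 0.0)) * math.sqrt(max(n * n - float(t @ t), 0.0))
    if den == 0.0:
        log.info("gorodkin_rk: degenerate denominator (constant labels); returning 0")
        return 0.0
    return num / den


def per_class_metrics(labeled: LabeledSet, positive_class: str) -> ClassMetrics:
    """One-vs-rest precision / recall / F1 and support for one category."""
    if positive_class not in labeled.universe:
        raise ValueError(f"unknown class {positive_class!r}")
    tp = sum(1 for t, p in zip(labeled.truth, labeled.predicted) if t == positive_class and p == positive_class)
    fp = sum(1 for t, p in zip(labeled.truth, labeled.predicted) if t != positive_class and p == positive_class)
    fn = sum(1 for t, p in zip(labeled.truth, labeled.predicted) if t == positive_class and p != positive_class)
    if tp + fp == 0:
        log.info("per_class_metrics: no positive predictions for %r; precision := 0", positive_class)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    return ClassMetrics(
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        support=tp + fn,
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when P+R == 0."""
    return 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0


def pos_neg_ratio(labeled_or_truth, positive_class: str) -> float:
    """positives / (N - positives) over the truth labels."""
    truth = labeled_or_truth.truth if isinstance(labeled_or_truth, LabeledSet) else tuple(labeled_or_truth)
    pos = sum(1 for t in truth if t == positive_class)
    neg = len(truth) - pos
    if pos == 0:
        return 0.0
    if neg == 0:
        raise ZeroDivisionError("all records are positive; ratio undefined")
    return pos / neg


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report-table rounding: 2 decimals, ties away from zero."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_labeled_tsv(path: str | Path) -> LabeledSet:
    """Read a classification table: TSV of id, truth, predicted (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    for needed in ("id", "truth", "predicted"):
        if needed not in cols:
            raise ValueError(f"classification table must have column {needed!r}")
    df.columns = cols
    return LabeledSet.from_records(list(zip(df["id"], df["truth"], df["predicted"])))


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read an aggregation mapping file: TSV/whitespace pairs 'from<TAB>to'."""
    mapping: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"bad mapping line: {raw!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def classification_report(labeled: LabeledSet) -> pd.DataFrame:
    """Per-class precision/recall/F1/support table plus overall R_K."""
    rows = []
    for cat in labeled.universe:
        m = per_class_metrics(labeled, cat)
        rows.append(
            {
                "category": cat,
                "precision": round_half_up(m.precision),
                "recall": round_half_up(m.recall),
                "f1": round_half_up(m.f1),
                "support": m.support,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["rk"] = gorodkin_rk(confusion(labeled))
    df.attrs["n"] = len(labeled.ids)
    return df
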
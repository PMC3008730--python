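"""Expression classes and enrichment of integration targets for active genes.

Normalized per-gene expression values (averaged over array replicates,
with a present/absent detection call) are divided into four classes:
absent (not detected), low (< 25th percentile of detected values),
intermediate (25th-75th), high (> 75th).  Integration target genes are
then compared to random-control target genes for their fraction of active
(detected) and highly expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from retromap.genome_annotation import round_pct

__all__ = [
    "ExpressionTable",
    "ExpressionClassing",
    "classify_expression",
    "class_distribution",
]

CLASSES = ("absent", "low", "intermediate", "high")


@dataclass
class ExpressionTable:
    """gene_id -> (normalized expression value, detection call)."""

    values: dict[str, float]
    detected: dict[str, bool]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionTable":
        return cls(
            values=dict(zip(df["gene_id"], df["value"].astype(float))),
            detected=dict(zip(df["gene_id"], df["detected"].astype(bool))),
        )

    def genes(self) -> list[str]:
        return list(self.values)


@dataclass
class ExpressionClassing:
    classes: dict[str, str]
    q25: float
    q75: float

    def __getitem__(self, gene_id: str) -> str:
        return self.classes[gene_id]


def classify_expression(table: ExpressionTable) -> ExpressionClassing:
    """Assign absent/low/intermediate/high classes.

    Percentiles are computed over detected genes only (linear
    interpolation); values exactly at a percentile boundary fall in the
    intermediate class.  Undetected genes are absent regardless of value.
    """
    detected_vals = np.array(
        [v for g, v in table.values.items() if table.detected.get(g, False)],
        dtype=float,
    )
    if len(detected_vals) == 0:
        raise ValueError("no detected genes: cannot compute expression classes")
    if not np.all(np.isfinite(detected_vals)):
        raise ValueError("non-finite expression value among detected genes")
    if len(detected_vals) < 4:
        raise ValueError("need at least 4 detected genes for quartiles")
    q25, q75 = np.percentile(detected_vals, [25, 75])
    classes: dict[str, str] = {}
    for gene, value in table.values.items():
        if not table.detected.get(gene, False):
            classes[gene] = "absent"
        elif value < q25:
            classes[gene] = "low"
        elif value > q75:
            classes[gene] = "high"
        else:
            classes[gene] = "intermediate"
    return ExpressionClassing(classes=classes, q25=float(q25), q75=float(q75))


def class_distribution(
    target_genes: Iterable[str],
    classing: ExpressionClassing,
    background_target_genes: Iterable[str],
) -> dict:
    """Class proportions of targets vs background, with enrichment tests.

    Gene ids absent from the classing are counted as unmapped and excluded
    from denominators.  Reports per-class percentages for both sets and
    continuity-corrected two-proportion tests for the active fraction
    (any detected class) and for the high class.
    """
    t_counts, t_unmapped = _count_classes(target_genes, classing)
    b_counts, b_unmapped = _count_classes(background_target_genes, classing)
    n_t = sum(t_counts.values())
    n_b = sum(b_counts.values())
    if n_t == 0 or n_b == 0:
        raise ValueError("no mapped genes in target or background list")

    def pcts(counts: dict[str, int], n: int) -> dict[str, float]:
        return {c: round_pct(counts[c], n) for c in CLASSES}

    t_active = n_t - t_counts["absent"]
    b_active = n_b - b_counts["absent"]
    active_test = _two_prop(t_active, n_t, b_active, n_b)
    high_test = _two_prop(t_counts["high"], n_t, b_counts["high"], n_b)
    return {
        "target_counts": t_counts,
        "target_pct": pcts(t_counts, n_t),
        "background_counts": b_counts,
        "background_pct": pcts(b_counts, n_b),
        "n_target": n_t,
        "n_background": n_b,
        "unmapped_target": t_unmapped,
        "unmapped_background": b_unmapped,
        "active_fraction_target": t_active / n_t,
        "active_fraction_background": b_active / n_b,
        "active_test": active_test,
        "high_test": high_test,
    }


def _count_classes(
    genes: Iterable[str], classing: ExpressionClassing
) -> tuple[dict[str, int], int]:
    counts = {c: 0 for c in CLASSES}
    unmapped = 0
    for g in set(genes):
        cls = classing.classes.get(g)
        if cls is None:
            unmapped += 1
        else:
            counts[cls] += 1
    return counts, unmapped


def _two_prop(x1: int, n1: int, x2: int, n2: int) -> dict:
    """Two-sample proportion test as a 2x2 chi-square with Yates correction."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if (table.sum(axis=1) == 0).any():
        raise ValueError("zero denominator in proportion test")
    if (table.sum(axis=0) == 0).any():
        # degenerate margins (all genes in one class): no test possible
        return {"chi2": float("nan"), "pvalue": 1.0}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return {"chi2": float(chi2), "pvalue": float(p)}
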
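"""Evaluation statistics over per-complex binding energies.

Summaries over a benchmark of protein-ligand complexes: the spread
("energy range", max minus min over complexes) of each scoring column, its
Pearson correlation with the experimental binding free energies, and a
consistency check of the additive binding-energy decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .thermo import BindingBreakdown

__all__ = [
    "ComplexRecord",
    "EvaluationSummary",
    "energy_range",
    "pearson",
    "summarize",
    "breakdown_consistency",
]


@dataclass
class ComplexRecord:
    """One complex: experimental dG plus per-target-function energies."""

    pdb_id: str
    dG_exp: float
    per_function_energies: dict[str, float]


@dataclass
class EvaluationSummary:
    ranges: dict[str, float]
    correlations: dict[str, float]


def energy_range(values) -> float:
    """Max minus min; needs at least two values."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("energy_range needs at least 2 values")
    return float(v.max() - v.min())


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs equal-length inputs of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


def summarize(records: list[ComplexRecord]) -> EvaluationSummary:
    """Energy range of every column (experimental included) and Pearson
    correlation of every scoring column against the experimental values."""
    if not records:
        raise ValueError("no records")
    labels = list(records[0].per_function_energies)
    for rec in records:
        missing = set(labels) - set(rec.per_function_energies)
        if missing:
            raise ValueError(f"record {rec.pdb_id}: missing columns {sorted(missing)}")
    exp = [r.dG_exp for r in records]
    ranges = {"dG_exp": energy_range(exp)}
    correlations: dict[str, float] = {}
    for label in labels:
        col = [r.per_function_energies[label] for r in records]
        ranges[label] = energy_range(col)
        correlations[label] = pearson(exp, col)
    return EvaluationSummary(ranges=ranges, correlations=correlations)


def breakdown_consistency(rows: list[BindingBreakdown]) -> float:
    """Max over rows of |dG_bind - (dE + dG_v + dG_t + dG_r + dG_all)|."""
    if not rows:
        raise ValueError("no rows")
    residuals = [
        abs(r.dG_bind - (r.dE + r.dG_v + r.dG_t + r.dG_r + r.dG_all)) for r in rows
    ]
    return float(max(residuals))


def summary_frame(summary: EvaluationSummary) -> pd.DataFrame:
    """Two-row frame mirroring the benchmark-table footer."""
    cols = list(summary.ranges)
    return pd.DataFrame(
        {
            c: [summary.ranges.get(c, np.nan), summary.correlations.get(c, np.nan)]
            for c in cols
        },
        index=["energy_range", "energy_correlation"],
    )
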
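"""RPKM-based differential expression between the two culture states.

The test for equal read proportions between libraries follows a binomial
sampling model: an exact two-sided binomial test for low-count genes and a
normal approximation on the proportion otherwise.  Multiple testing is
controlled with Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ParameterError, RunConfig


@dataclass
class ExpressionRecord:
    unigene_id: str
    length_bp: int
    count_MY: int
    count_FB: int
    rpkm_MY: float = 0.0
    rpkm_FB: float = 0.0
    fold_change: float = float("nan")
    p_value: float = 1.0
    fdr: float = 1.0
    deg_class: str = "not_DE"


def rpkm(count: int, gene_len_bp: int, lib_total: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_len_bp <= 0:
        raise ParameterError("gene length must be positive")
    if lib_total <= 0:
        raise ParameterError("library total must be positive")
    return count * 1e9 / (lib_total * gene_len_bp)


def deg_test(
    count_MY: int,
    count_FB: int,
    total_MY: int,
    total_FB: int,
    exact_below: int = 30,
) -> float:
    """Two-sided p-value for equal read proportions between libraries.

    Under the null the gene's MY count is Binomial(n, p0) with
    ``n = count_MY + count_FB`` and ``p0 = total_MY / (total_MY + total_FB)``.
    Exact binomial when ``n < exact_below``, normal approximation otherwise.
    """
    if total_MY <= 0 or total_FB <= 0:
        raise ParameterError("library totals must be positive")
    n = count_MY + count_FB
    if n == 0:
        return 1.0
    p0 = total_MY / (total_MY + total_FB)
    if n < exact_below:
        return float(stats.binomtest(count_MY, n, p0).pvalue)
    z = (count_MY - n * p0) / math.sqrt(n * p0 * (1.0 - p0))
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downward
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adjusted
    return out.tolist()


def _classify_one(rec: ExpressionRecord, config: RunConfig) -> str:
    if rec.count_FB == 0 and rec.count_MY >= config.min_specific:
        return "MY_specific"
    if rec.count_MY == 0 and rec.count_FB >= config.min_specific:
        return "FB_specific"
    if rec.fdr < config.fdr_threshold:
        if rec.fold_change >= config.fc_up:
            return "up_FB"
        if rec.fold_change <= config.fc_down:
            return "up_MY"
    return "not_DE"


def analyze_counts(
    table: pd.DataFrame, config: RunConfig | None = None
) -> list[ExpressionRecord]:
    """Full expression analysis of a count table.

    ``table`` needs columns unigene_id, length_bp, count_MY, count_FB.
    Library totals are the column sums.  Specific classes are assigned before
    the fold-change ratio, so zero-denominator ratios never arise for them.
    """
    config = config or RunConfig()
    required = {"unigene_id", "length_bp", "count_MY", "count_FB"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"count table missing columns: {sorted(missing)}")
    total_MY = int(table["count_MY"].sum())
    total_FB = int(table["count_FB"].sum())
    records: list[ExpressionRecord] = []
    for row in table.itertuples(index=False):
        rec = ExpressionRecord(
            unigene_id=str(row.unigene_id),
            length_bp=int(row.length_bp),
            count_MY=int(row.count_MY),
            count_FB=int(row.count_FB),
        )
        rec.rpkm_MY = rpkm(rec.count_MY, rec.length_bp, total_MY)
        rec.rpkm_FB = rpkm(rec.count_FB, rec.length_bp, total_FB)
        if rec.rpkm_MY > 0:
            rec.fold_change = rec.rpkm_FB / rec.rpkm_MY
        elif rec.rpkm_FB > 0:
            rec.fold_change = float("inf")
        rec.p_value = deg_test(
            rec.count_MY, rec.count_FB, total_MY, total_FB, config.exact_test_below
        )
        records.append(rec)
    for rec, fdr in zip(records, bh_adjust([r.p_value for r in records])):
        rec.fdr = fdr
        rec.deg_class = _classify_one(rec, config)
    return records


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unigene_id": [r.unigene_id for r in records],
            "length_bp": [r.length_bp for r in records],
            "count_MY": [r.count_MY for r in records],
            "count_FB": [r.count_FB for r in records],
            "rpkm_MY": [r.rpkm_MY for r in records],
            "rpkm_FB": [r.rpkm_FB for r in records],
            "fold_change": [r.fold_change for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "deg_class": [r.deg_class for r in records],
        }
    )
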
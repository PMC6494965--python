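"""Univariate substructure enrichment statistics.

For each retained MACCS key, a 2x2 contingency table cross-tabulates key
presence against ABC-16 sensitivity. Association is assessed with a
two-sided Fisher exact test computed directly from the hypergeometric
distribution (point-probability summation over the full support), effect
size with the natural-log odds ratio (Haldane-Anscombe +0.5 correction when
a cell is zero), and multiplicity with Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprints import FingerprintMatrix

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "contingency_for_key",
    "fisher_exact_two_sided",
    "log_odds",
    "bh_fdr",
    "enrich_all",
    "enrichment_frame",
    "write_enrichment_tsv",
]

#: relative tolerance when comparing point probabilities for the two-sided sum
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: key presence (rows) x ABC-16 sensitivity (columns).

    a = present & sensitive, b = present & not, c = absent & sensitive,
    d = absent & not.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"contingency counts must be non-negative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-key enrichment summary: counts, log-odds ratio, exact p, FDR q."""

    key_id: int
    table: ContingencyTable
    log_odds: float
    p_value: float
    q_value: float

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if self.q_value < self.p_value - 1e-12 or self.q_value > 1.0:
            raise ValueError(f"q_value {self.q_value} inconsistent with p {self.p_value}")


def contingency_for_key(
    matrix: FingerprintMatrix, labels: pd.Series, key_id: int
) -> ContingencyTable:
    """Exact cross-tabulation of one key's presence against the labels."""
    if key_id not in matrix.key_ids:
        raise ValueError(f"key_id {key_id} not in matrix (retained keys: {len(matrix.key_ids)})")
    missing = [d for d in matrix.drug_ids if d not in labels.index]
    if missing:
        raise ValueError(f"labels missing for drugs: {missing}")
    y = labels.loc[matrix.drug_ids].to_numpy().astype(int)
    col = matrix.bits[:, matrix.key_ids.index(key_id)].astype(int)
    a = int(np.sum((col == 1) & (y == 1)))
    b = int(np.sum((col == 1) & (y == 0)))
    c = int(np.sum((col == 0) & (y == 1)))
    d = int(np.sum((col == 0) & (y == 0)))
    return ContingencyTable(a, b, c, d)


def _log_hypergeom_pmf(k: int, n: int, r1: int, c1: int) -> float:
    """log P[X = k] for X ~ Hypergeom(n, r1, c1) via log-gamma."""
    r2 = n - r1

    def lchoose(m, j):
        return math.lgamma(m + 1) - math.lgamma(j + 1) - math.lgamma(m - j + 1)

    return lchoose(r1, k) + lchoose(r2, c1 - k) - lchoose(n, c1)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by hypergeometric point-probability summation.

    Conditioning on both margins, every table with the same margins whose
    point probability does not exceed the observed one (within relative
    tolerance 1e-7, the usual tie convention) contributes to p. A table with
    a zero margin is degenerate: the observed outcome is the only possible
    one, so p = 1 (with a warning).
    """
    n = table.n
    r1 = table.a + table.b  # key present
    c1 = table.a + table.c  # sensitive
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn(
            f"degenerate contingency table (zero margin): {table}; p = 1", stacklevel=2
        )
        return 1.0
    k_lo = max(0, c1 - (n - r1))
    k_hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(table.a, n, r1, c1)
    threshold = log_obs + math.log1p(_TIE_RTOL)
    p = 0.0
    for k in range(k_lo, k_hi + 1):
        lp = _log_hypergeom_pmf(k, n, r1, c1)
        if lp <= threshold:
            p += math.exp(lp)
    return min(p, 1.0)


def log_odds(table: ContingencyTable) -> float:
    """Natural-log odds ratio ln(ad/bc), Haldane-Anscombe corrected.

    When any cell is zero, 0.5 is added to every cell before the ratio. The
    correction applies to the effect size only, never to the p-value.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a * d) / (b * c))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)]
        raise ValueError(f"p-values outside (0, 1]: {bad.tolist()}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q.tolist()


def enrich_all(
    matrix: FingerprintMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    m_total: int | None = None,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Enrichment of every retained key, with FDR across the whole panel.

    ``m_total`` optionally inflates the BH denominator beyond the number of
    tested keys (e.g. 166 when constant keys were filtered out beforehand);
    by default m = number of retained keys. Returns (all results in key
    order, significant subset with q < alpha sorted by q then |log-odds|
    descending).
    """
    tables = [contingency_for_key(matrix, labels, k) for k in matrix.key_ids]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate tables are reported as p = 1
        p_values = [fisher_exact_two_sided(t) for t in tables]
    if m_total is None:
        q_values = bh_fdr(p_values)
    else:
        if m_total < len(p_values):
            raise ValueError(f"m_total {m_total} smaller than number of tested keys {len(p_values)}")
        scale = m_total / len(p_values)
        q_values = [min(q * scale, 1.0) for q in bh_fdr(p_values)]
    results = [
        EnrichmentResult(k, t, log_odds(t), p, q)
        for k, t, p, q in zip(matrix.key_ids, tables, p_values, q_values)
    ]
    significant = sorted(
        (r for r in results if r.q_value < alpha),
        key=lambda r: (r.q_value, -abs(r.log_odds)),
    )
    return results, significant


def enrichment_frame(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "key_id": [r.key_id for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "log_odds": [r.log_odds for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.q_value < alpha for r in results],
        }
    )


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], path: str | Path, alpha: float = 0.05
) -> None:
    """TSV with counts and 6-decimal log_odds / p / q per key."""
    frame = enrichment_frame(results, alpha=alpha)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
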
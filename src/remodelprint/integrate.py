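"""Joint gene integration, gene-set enrichment and expression cross-reference.

The enrichment statistic follows the observed/expected convention:
``strength = log10(observed / expected)`` with ``expected = |query| x
|term| / |background|``, and a hypergeometric upper-tail p-value
P(X >= observed) corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Set

import numpy as np
from scipy.stats import hypergeom, ttest_rel

from .io import ExpressionMatrix, Group
from .stats import bh_fdr, round_half_up, two_sample_t

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "ExpressionResult",
    "joint_genes",
    "enrich",
    "list_overlap",
    "expression_crossref",
]

_P_FLOOR = 5e-324  # smallest positive double; keeps p in (0, 1] for BH


@dataclass
class EnrichmentResult:
    term: str
    observed: int
    expected: float
    strength: float
    p: float
    fdr: float


@dataclass
class ExpressionResult:
    gene: str
    log2fc: float  # COPD minus non-COPD, log2 scale
    p: float
    fdr: float
    deregulated: bool  # FDR < threshold


def joint_genes(variant_goi_genes: Set[str], cna_goi_genes: Set[str]) -> tuple:
    """Exact intersection and union of the two gene-of-interest sets."""
    a, b = set(variant_goi_genes), set(cna_goi_genes)
    return a & b, a | b


def enrich(
    query_genes: Set[str],
    annotations: Mapping[str, Set[str]],
    background: Set[str],
) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of ``query_genes`` in each term.

    Query genes outside the background are dropped with a warning, term
    gene sets are intersected with the background, and terms with zero
    observed overlap are omitted.  Results are sorted by FDR.
    """
    background = set(background)
    if not background:
        raise ValueError("enrich: empty background")
    query = set(query_genes)
    outside = query - background
    if outside:
        log.warning("enrich: %d query genes outside background dropped", len(outside))
        query &= background
    raw = []
    for term in sorted(annotations):
        term_genes = set(annotations[term]) & background
        observed = len(query & term_genes)
        if observed == 0:
            continue
        expected = len(query) * len(term_genes) / len(background)
        strength = math.log10(observed / expected)
        p = float(hypergeom.sf(observed - 1, len(background), len(term_genes), len(query)))
        p = min(max(p, _P_FLOOR), 1.0)
        raw.append((term, observed, expected, strength, p))
    fdrs = bh_fdr([r[4] for r in raw])
    results = [
        EnrichmentResult(term=t, observed=o, expected=e, strength=s, p=p, fdr=q)
        for (t, o, e, s, p), q in zip(raw, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.term))
    return results


def list_overlap(query_genes: Set[str], reference_list: Set[str]) -> tuple:
    """Overlap set and its percentage of the query (one decimal)."""
    query = set(query_genes)
    if not query:
        raise ValueError("list_overlap: empty query")
    overlap = query & set(reference_list)
    return overlap, round_half_up(100.0 * len(overlap) / len(query), 1)


def expression_crossref(
    goi_genes: Set[str],
    matrix: ExpressionMatrix,
    test_mode: str = "welch",
    fdr_threshold: float = 0.05,
) -> tuple:
    """Differential expression (COPD vs non-COPD) of the genes of interest.

    Returns ``(results, n_detected, n_deregulated)``.  ``log2fc`` is
    mean(COPD) - mean(non-COPD) on the (already log2) matrix; the
    p-value comes from the chosen two-sample t-test (``welch`` default,
    ``student`` pooled, ``paired``); FDR is BH over the detected genes.
    Genes absent from the matrix count as not detected.
    """
    if test_mode not in ("welch", "student", "paired"):
        raise ValueError(f"unknown test_mode {test_mode!r}")
    copd_cols = [j for j, s in enumerate(matrix.samples) if matrix.group_map[s] == Group.COPD]
    ctrl_cols = [j for j, s in enumerate(matrix.samples) if matrix.group_map[s] == Group.NON_COPD]
    if len(copd_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("expression_crossref: each group needs at least 2 samples")
    if test_mode == "paired" and len(copd_cols) != len(ctrl_cols):
        raise ValueError("expression_crossref: paired test requires equal group sizes")
    gene_row = {g: i for i, g in enumerate(matrix.genes)}
    detected = sorted(g for g in goi_genes if g in gene_row)
    log2fcs, pvals = [], []
    for gene in detected:
        row = matrix.values[gene_row[gene]]
        x = row[copd_cols]
        y = row[ctrl_cols]
        lfc = float(x.mean() - y.mean())
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0 and x.mean() == y.mean():
            p = 1.0  # no signal, no spread
        elif test_mode == "paired":
            p = float(ttest_rel(x, y).pvalue)
        else:
            p = two_sample_t(x, y, equal_var=(test_mode == "student")).p
        if not np.isfinite(p):
            p = 1.0
        log2fcs.append(lfc)
        pvals.append(min(max(p, 5e-324), 1.0))
    fdrs = bh_fdr(pvals)
    results = [
        ExpressionResult(gene=g, log2fc=l, p=p, fdr=q, deregulated=q < fdr_threshold)
        for g, l, p, q in zip(detected, log2fcs, pvals, fdrs)
    ]
    n_deregulated = sum(r.deregulated for r in results)
    return results, len(detected), n_deregulated
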
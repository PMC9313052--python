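"""Group summaries, t-tests, fold changes and BH FDR correction.

Conventions match the reporting style of the analysis: histogram
summaries are mean +/- SEM (sample sd, n-1 denominator), group contrasts
use Student's t-test (pooled variance by default, Welch optional), fold
changes are printed to one decimal (half-up), and multiple testing is
corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "TestResult",
    "mean_sem",
    "two_sample_t",
    "fold_change",
    "round_half_up",
    "bh_fdr",
    "significance_star",
    "stratum_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- SEM of one metric in one stratum (group x morphology)."""

    group: str
    morphology: str
    metric: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class TestResult:
    contrast: str
    t: float
    p: float
    significant: bool
    df: Optional[float] = None
    note: str = ""


def mean_sem(values: Sequence[float]) -> tuple:
    """Mean and standard error of the mean (sd / sqrt(n), sd with n-1).

    A singleton gets SEM 0 by convention (no spread estimable).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem: empty input")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
    contrast: str = "",
    alpha: float = 0.05,
) -> TestResult:
    """Two-sample t-test (pooled-variance Student by default; Welch optional).

    Degenerate zero-variance inputs are handled explicitly: equal means
    give t=0, p=1; unequal means with zero variance give the p -> 0
    limit and are flagged in ``note``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t: each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(contrast, 0.0, 1.0, False, df=float(a.size + b.size - 2))
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TestResult(
            contrast, sign * math.inf, 0.0, True,
            df=float(a.size + b.size - 2), note="zero variance, unequal means",
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(a.size + b.size - 2) if equal_var else float(res.df)
    p = float(res.pvalue)
    return TestResult(contrast, float(res.statistic), p, p < alpha, df=df)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (2.35 -> 2.4 at one decimal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fold_change(mean_target: float, mean_reference: float, ndigits: int = 1) -> float:
    """Ratio of group means, reported half-up at ``ndigits`` decimals."""
    if mean_reference <= 0:
        raise ValueError("fold_change: reference mean must be > 0")
    return round_half_up(mean_target / mean_reference, ndigits)


def bh_fdr(p_values: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up FDR; input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("bh_fdr: p-values must lie in (0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return [float(q) for q in fdr]


def significance_star(p: float) -> str:
    """Report stars: ``**`` for p < 0.01, ``*`` for p < 0.05, else empty."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def stratum_summary(per_sample: pd.DataFrame, value_cols: Iterable[str]) -> pd.DataFrame:
    """Tidy mean +/- SEM per (group, morphology) stratum for each metric.

    ``per_sample`` needs ``group`` and ``morphology`` columns plus the
    metric columns.  Raises if any stratum of a represented group is
    empty (paired design assumed).
    """
    rows = []
    groups = list(dict.fromkeys(per_sample["group"]))
    morphs = list(dict.fromkeys(per_sample["morphology"]))
    for g in groups:
        for m in morphs:
            sub = per_sample[(per_sample["group"] == g) & (per_sample["morphology"] == m)]
            if sub.empty:
                raise ValueError(f"stratum_summary: empty stratum ({g}, {m})")
            for col in value_cols:
                mean, sem = mean_sem(sub[col].to_numpy())
                rows.append(
                    GroupSummary(group=g, morphology=m, metric=col,
                                 n=len(sub), mean=mean, sem=sem)
                )
    return pd.DataFrame([r.__dict__ for r in rows])
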
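"""Marker-phenotype association and 1:1 segregation tests for the F1.

A derived DNA (or expression) marker scored presence/absence across the
population is validated two ways: a two-sided Fisher exact test of the
marker x phenotype 2x2 table, and a chi-square test of the marker's
segregation ratio against the 1:1 expectation of a pseudo-testcross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    continuity_corrected: bool  # 0.5 added to every cell for the odds ratio
    degenerate: bool  # a margin summed to 0; p fixed at 1


@dataclass
class SegregationResult:
    chi_square: float
    p_value: float
    n_present: int
    n_absent: int


def marker_counts(table: pd.DataFrame) -> np.ndarray:
    """2x2 counts from a per-tree table (marker_present x phenotype).

    ``table`` needs columns ``marker_present`` (0/1 or bool) and
    ``phenotype`` (two labels); rows with missing values are rejected.
    Row 0/1 = marker absent/present, columns in sorted phenotype order.
    """
    df = pd.DataFrame(table)
    for col in ("marker_present", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"marker table missing column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"marker table has missing values in {col!r}")
    present = df["marker_present"].astype(int)
    if not present.isin([0, 1]).all():
        raise ValueError("marker_present must be binary (0/1)")
    levels = sorted(df["phenotype"].astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"expected <= 2 phenotype labels, got {levels}")
    counts = np.zeros((2, 2), dtype=np.int64)
    for j, level in enumerate(levels):
        sub = present[df["phenotype"].astype(str) == level]
        counts[0, j] = int((sub == 0).sum())
        counts[1, j] = int((sub == 1).sum())
    return counts


def fisher_marker_association(table: np.ndarray | pd.DataFrame) -> FisherResult:
    """Two-sided Fisher exact test of a 2x2 marker/phenotype table.

    The two-sided p sums hypergeometric probabilities of tables (at the
    observed margins) no more probable than the observed one.  The odds
    ratio is the sample (a d)/(b c); when any cell is 0, 0.5 is added to
    every cell (flagged).  A zero row or column margin makes the test
    undefined: p = 1, flagged degenerate.
    """
    counts = np.asarray(table, dtype=np.int64)
    if isinstance(table, pd.DataFrame) and "marker_present" in table.columns:
        counts = marker_counts(table)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if counts.sum() < 1:
        raise ValueError("table total must be >= 1")
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        odds = _odds_ratio(counts)
        return FisherResult(
            odds_ratio=odds[0],
            p_value=1.0,
            continuity_corrected=odds[1],
            degenerate=True,
        )
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    odds, corrected = _odds_ratio(counts)
    return FisherResult(
        odds_ratio=odds, p_value=float(p), continuity_corrected=corrected,
        degenerate=False,
    )


def _odds_ratio(counts: np.ndarray) -> tuple[float, bool]:
    a, b = counts[0]
    c, d = counts[1]
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        return float(a * d / (b * c)), True
    return float(a * d / (b * c)), False


def segregation_ratio_test(
    presence_count: int, absence_count: int
) -> SegregationResult:
    """Chi-square goodness of fit against 1:1 segregation (df = 1)."""
    a, b = int(presence_count), int(absence_count)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise ValueError("total count must be >= 1")
    chi2 = (a - b) ** 2 / n  # = sum (obs - n/2)^2 / (n/2)
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(chi_square=float(chi2), p_value=p,
                             n_present=a, n_absent=b)
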
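"""Gene expression markers (GEMs).

A GEM is a transcript whose expression level splits a segregating
population into two roughly equal groups differing by at least a stated
fold change — i.e. it is inherited like a Mendelian marker.  Detection
splits each gene's sorted expression values at the largest gap between
consecutive values (the split that maximizes the separation between the
resulting high and low groups), excluding degenerate splits that would
isolate fewer than ``min_group`` samples — a gap created by one or two
outlying trees is a technical artifact, not a segregation pattern.  The
gene is a GEM when the groups' mean log2 difference reaches
log2(min_fold) and neither group is smaller than balance_min of the
population.  For unimodal noise the largest admissible gap still falls
near the extremes most of the time, so the balance constraint rejects
such genes; a genuinely bimodal gene splits between its modes with
near-1:1 balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PhenotypeTable

DEFAULT_MIN_FOLD = 1.5
DEFAULT_BALANCE_MIN = 1.0 / 3.0
DEFAULT_MIN_GROUP = 3
MIN_SAMPLES = 6


@dataclass
class GEMCall:
    """Per-gene bimodal split and marker call."""

    gene_id: str
    is_gem: bool
    split_index: int  # samples with the split_index smallest values form "low"
    group_of_sample: np.ndarray  # "high"/"low" per sample, input order
    fold_diff_log2: float  # mean(high) - mean(low), log2 units
    balance: float  # min(group sizes) / n
    divergence: np.ndarray  # per-sample deviation from the gene's mean


def detect_gem(
    values: np.ndarray,
    gene_id: str = "",
    min_fold: float = DEFAULT_MIN_FOLD,
    balance_min: float = DEFAULT_BALANCE_MIN,
    min_group: int = DEFAULT_MIN_GROUP,
) -> GEMCall:
    """Split one gene's expression at the largest admissible gap.

    Candidate splits leave at least ``min_group`` samples on each side
    (capped at n//2 so at least one split is always admissible); among
    them the one with the largest gap between the adjacent sorted
    values — equivalently, the largest separation min(high) - max(low)
    — is chosen.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < MIN_SAMPLES:
        raise ValueError(
            f"need >= {MIN_SAMPLES} samples with finite expression, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    n = x.size
    lo_k = min(max(int(min_group), 1), n // 2)
    order = np.argsort(x, kind="stable")
    sorted_x = x[order]
    gaps = np.diff(sorted_x)
    ks = np.arange(1, n)
    admissible = np.minimum(ks, n - ks) >= lo_k
    masked = np.where(admissible, gaps, -np.inf)
    split = int(np.argmax(masked)) + 1  # low group = split smallest values
    low_mask = np.zeros(n, dtype=bool)
    low_mask[order[:split]] = True
    fold = float(x[~low_mask].mean() - x[low_mask].mean()) if gaps.max() > 0 else 0.0
    balance = min(split, n - split) / n
    # 1e-9 absolute slack so means computed in floating point do not miss
    # an exactly-at-threshold fold
    is_gem = fold >= np.log2(min_fold) - 1e-9 and balance >= balance_min
    groups = np.where(low_mask, "low", "high")
    return GEMCall(
        gene_id=gene_id,
        is_gem=bool(is_gem),
        split_index=split,
        group_of_sample=groups,
        fold_diff_log2=fold,
        balance=balance,
        divergence=x - x.mean(),
    )


def scan_gems(
    expr: ExpressionMatrix,
    min_fold: float = DEFAULT_MIN_FOLD,
    balance_min: float = DEFAULT_BALANCE_MIN,
    min_group: int = DEFAULT_MIN_GROUP,
) -> tuple[list[GEMCall], PhenotypeTable | None]:
    """Call every gene; emit a phenotype table of the GEM-derived traits.

    Each detected GEM contributes a trait ``GEM:<gene_id>`` with
    group_A = high-expression samples and group_B = low — directly
    usable as a phenotype grouping for differential expression.
    Returns (calls, phenotype table or None when no GEM was found).
    """
    calls = [
        detect_gem(expr.values[i], expr.gene_ids[i], min_fold, balance_min, min_group)
        for i in range(expr.n_genes)
    ]
    frames = []
    for call in calls:
        if not call.is_gem:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": expr.sample_ids,
                    "trait": f"GEM:{call.gene_id}",
                    "label": np.where(
                        call.group_of_sample == "high", "group_A", "group_B"
                    ),
                }
            )
        )
    phenotypes = (
        PhenotypeTable(pd.concat(frames, ignore_index=True)) if frames else None
    )
    return calls, phenotypes


def gem_summary(calls: list[GEMCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "is_gem": [c.is_gem for c in calls],
            "split_index": [c.split_index for c in calls],
            "fold_diff_log2": [c.fold_diff_log2 for c in calls],
            "balance": [c.balance for c in calls],
        }
    )
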
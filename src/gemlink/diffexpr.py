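"""Two-group differential expression with an empirical-Bayes moderated t.

The trait splits samples into group_A and group_B.  Per gene, the
M-value is the difference in mean log2 expression between the groups;
the pooled residual variance s^2 (df = n_A + n_B - 2) is shrunk toward a
prior (d0, s0^2) estimated across genes by moment matching of log s^2
against a scaled-F distribution (digamma/trigamma inversion):

    s~^2  = (d0 s0^2 + df s^2) / (d0 + df)
    t_mod = M / sqrt(s~^2 (1/n_A + 1/n_B)),   df_total = d0 + df

With d0 = 0 this reduces exactly to the pooled two-sample t-test; with
d0 unbounded every gene shares the variance s0^2.  P-values are
converted to q-values (FDR) with the pi0-estimating step-up procedure;
pi0 is read off a cubic smooth of pi0(lambda) at the largest lambda, and
for fewer than 100 genes the procedure falls back to pi0 = 1
(Benjamini-Hochberg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix, PhenotypeTable

DEFAULT_Q_THRESHOLD = 0.05
_PI0_LAMBDA_GRID = np.arange(0.05, 0.9001, 0.05)
_BH_FALLBACK_MIN_GENES = 100


class GroupSizeError(ValueError):
    """A phenotype group has too few samples for the analysis."""


@dataclass
class PriorEstimate:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0^2 scale."""

    d0: float
    s0_squared: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if self.d0 > 0 and not self.s0_squared > 0:
            raise ValueError("s0_squared must be positive when d0 > 0")


@dataclass
class StoreyResult:
    pi0: float
    lambda_grid: np.ndarray
    q_values: np.ndarray  # aligned to the input p order
    method: str = "storey-smooth"


def compute_m_values(
    expr: ExpressionMatrix, phenotypes: PhenotypeTable, trait: str
) -> pd.DataFrame:
    """Per-gene group means, M-value, and pooled residual variance.

    Returns a DataFrame indexed by gene_id with columns mean_A, mean_B,
    M (= mean_A - mean_B), s2, df_residual, and attrs n_A / n_B.
    Samples labelled ``unassigned`` are excluded.
    """
    samples_a, samples_b = phenotypes.groups(trait)
    for name, samples in (("group_A", samples_a), ("group_B", samples_b)):
        if len(samples) < 2:
            raise GroupSizeError(
                f"trait {trait!r}: {name} has {len(samples)} sample(s); need >= 2"
            )
    xa = expr.sample_columns(samples_a)
    xb = expr.sample_columns(samples_b)
    n_a, n_b = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + (
        (xb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    df_residual = n_a + n_b - 2
    out = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "M": mean_a - mean_b,
            "s2": ss / df_residual,
            "df_residual": df_residual,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    out.attrs["n_A"] = n_a
    out.attrs["n_B"] = n_b
    return out


def fit_variance_prior(s2: np.ndarray, df_residual: float) -> PriorEstimate:
    """Moment-match (d0, s0^2) from per-gene variances at a shared df.

    Works on log s^2: under the scaled-F model the adjusted log
    variances e = log s^2 - digamma(df/2) + log(df/2) have variance
    trigamma(df/2) + trigamma(d0/2), so the excess spread over
    trigamma(df/2) identifies d0 via trigamma inversion and the mean of
    e identifies s0^2.  If the spread does not exceed trigamma(df/2),
    d0 is reported unbounded and s0^2 = exp(mean(e)).
    """
    s2 = np.asarray(s2, dtype=float)
    usable = s2[np.isfinite(s2) & (s2 > 0)]
    if usable.size < 2:
        warnings.warn(
            "fewer than 2 genes with positive variance; variance prior disabled "
            "(d0 = 0)",
            stacklevel=2,
        )
        return PriorEstimate(d0=0.0, s0_squared=float(usable[0]) if usable.size else 1.0)
    df1 = float(df_residual)
    z = np.log(usable)
    e = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    if e_var < 1e-15:
        # degenerate spread: the empirical prior is a point mass, so no
        # sampling-noise adjustment applies
        return PriorEstimate(d0=np.inf, s0_squared=float(np.exp(np.mean(z))))
    excess = e_var - float(special.polygamma(1, df1 / 2.0))
    if excess <= 0:
        return PriorEstimate(d0=np.inf, s0_squared=float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return PriorEstimate(d0=d0, s0_squared=s0_sq)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-10:
            break
    return y


def moderated_t_test(
    gene_stats: pd.DataFrame, prior: PriorEstimate, n_a: int, n_b: int
) -> pd.DataFrame:
    """Shrink variances toward the prior and test M = 0 per gene.

    Adds columns s2_post, t_mod, df_total, p_value, degenerate to a copy
    of ``gene_stats`` (from :func:`compute_m_values`).
    """
    out = gene_stats.copy()
    s2 = out["s2"].to_numpy(dtype=float)
    df = out["df_residual"].to_numpy(dtype=float)
    m = out["M"].to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_squared)
        df_total = np.full_like(df, np.inf)
    elif prior.d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (prior.d0 * prior.s0_squared + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    scale = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(scale > 0, m / np.where(scale > 0, scale, 1.0), 0.0)
        t_mod = np.where((scale == 0) & (m != 0), np.sign(m) * np.inf, t_mod)
    p = _t_sf_two_sided(t_mod, df_total)
    degenerate = scale == 0
    p = np.where(degenerate & (m != 0), 0.0, p)
    p = np.where(degenerate & (m == 0), 1.0, p)
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["df_total"] = df_total
    out["p_value"] = p
    out["degenerate"] = degenerate
    return out


def _t_sf_two_sided(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    finite_df = np.where(np.isinf(df), 1.0, df)
    p_t = 2.0 * stats.t.sf(np.abs(t), finite_df)
    p_norm = 2.0 * stats.norm.sf(np.abs(t))
    return np.where(np.isinf(df), p_norm, p_t)


def storey_qvalues(
    p_values: np.ndarray,
    pi0: float | None = None,
    lambda_grid: np.ndarray = _PI0_LAMBDA_GRID,
) -> StoreyResult:
    """FDR q-values with a smoothed pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the lambda grid; a
    cubic least-squares smooth is evaluated at the largest lambda and
    clipped to (0, 1].  q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the
    sorted p-values.  With fewer than 100 p-values (or ``pi0`` given)
    the estimate is replaced by the fixed value / 1.0.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    method = "storey-smooth"
    if pi0 is not None:
        pi0_hat = float(pi0)
        method = "fixed-pi0"
    elif m < _BH_FALLBACK_MIN_GENES:
        pi0_hat = 1.0
        method = "bh-fallback"
    else:
        pi0_lambda = np.array(
            [(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid]
        )
        coeffs = np.polynomial.polynomial.polyfit(lambda_grid, pi0_lambda, deg=3)
        pi0_hat = float(np.polynomial.polynomial.polyval(lambda_grid[-1], coeffs))
        pi0_hat = min(1.0, max(pi0_hat, 1.0 / m))
    if not 0.0 < pi0_hat <= 1.0:
        raise ValueError(f"pi0 must lie in (0, 1]; got {pi0_hat}")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0_hat * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return StoreyResult(pi0=pi0_hat, lambda_grid=np.asarray(lambda_grid), q_values=q,
                        method=method)


def de_analysis(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    use_ebayes: bool = True,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Full per-gene DE table: means, M, moderated t, p and q values."""
    gene_stats = compute_m_values(expr, phenotypes, trait)
    n_a, n_b = gene_stats.attrs["n_A"], gene_stats.attrs["n_B"]
    if use_ebayes:
        prior = fit_variance_prior(
            gene_stats["s2"].to_numpy(), float(gene_stats["df_residual"].iloc[0])
        )
    else:
        prior = PriorEstimate(d0=0.0, s0_squared=1.0)
    result = moderated_t_test(gene_stats, prior, n_a, n_b)
    storey = storey_qvalues(result["p_value"].to_numpy(), pi0=pi0)
    result["q_value"] = storey.q_values
    result.attrs.update(gene_stats.attrs)
    result.attrs["pi0"] = storey.pi0
    result.attrs["pi0_method"] = storey.method
    result.attrs["prior_d0"] = prior.d0
    result.attrs["prior_s0_squared"] = prior.s0_squared
    return result


def call_de(results: pd.DataFrame, q_threshold: float = DEFAULT_Q_THRESHOLD) -> set[str]:
    """Gene ids with q below the threshold, regardless of |M|."""
    mask = results["q_value"] < q_threshold
    return set(results.index[mask])


@dataclass
class Dendrogram:
    """Complete-linkage tree over samples on 1 - Pearson correlation."""

    sample_ids: list[str]
    merge_matrix: np.ndarray  # scipy linkage format
    distances: np.ndarray = field(repr=False)  # condensed


def sample_dendrogram(expr: ExpressionMatrix) -> Dendrogram:
    """Agglomerate samples by expression-profile similarity.

    Distance is 1 - Pearson correlation between sample profiles;
    agglomeration is complete linkage.  Samples are pre-sorted by id so
    tie-breaking is deterministic.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    order = np.argsort(np.asarray(expr.sample_ids, dtype=object), kind="stable")
    sample_ids = [expr.sample_ids[i] for i in order]
    x = expr.values[:, order]
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = sample_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has a constant expression profile")
    corr = np.corrcoef(x.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    merge = linkage(condensed, method="complete")
    return Dendrogram(sample_ids=sample_ids, merge_matrix=merge, distances=condensed)
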
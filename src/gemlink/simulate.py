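"""Synthetic F1 pseudo-testcross generator.

Emulates the study design the pipeline targets: 48 F1 trees from a cross
of two fully heterozygous parents, a single dominant resistance locus
(QTL) carried on one haplotype of one parent, and a subset of genes with
cis-linked heritable expression differences that co-segregate with the
local haplotype.  Recombination follows the Haldane map function (no
interference).  Expression is additive on the log2 scale:

    expr(gene, tree) = baseline(gene)
                       + effect(gene) * [tree inherited the effect haplotype]
                       + Normal(0, noise_sd^2)

By default effects and the resistance allele ride on haplotype 1 of the
second ("R5-like") parent, mirroring single-parent inheritance of the
resistance traits; every locus then segregates 1:1 among the offspring.

Two placement scenarios are exposed: ``linked`` draws cis-gene positions
within a window around the QTL (so cis expression co-segregates with the
trait), ``unlinked`` draws them on non-QTL chromosomes (a null in which
expression heritability exists but is unrelated to the trait).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .io import AnnotationTable, ExpressionMatrix, PhenotypeTable

Scenario = Literal["linked", "unlinked"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cross.

    Defaults match the target study's scale: a 17-chromosome, ~748 Mb
    genome, 2,000 assayed genes, 48 offspring, 2.5 cM/Mb, 5% of genes
    carrying a 1.0 log2-unit cis effect over i.i.d. Gaussian log2 noise
    of SD 0.5.
    """

    seed: int
    n_chromosomes: int = 17
    chrom_length_bp: int = 44_000_000
    n_genes: int = 2_000
    n_trees: int = 48
    cm_per_mb: float = 2.5
    qtl: tuple[str, int] = ("12", 30_000_000)
    cis_fraction: float = 0.05
    effect_size_log2: float = 1.0
    noise_sd_log2: float = 0.5
    scenario: Scenario = "linked"
    cis_window_bp: int = 5_000_000  # linked scenario: cis genes within +-window of QTL
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_genes, self.n_trees) < 1:
            raise ValueError("counts and lengths must all be >= 1")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError(f"cis_fraction {self.cis_fraction} outside [0, 1]")
        if self.noise_sd_log2 < 0 or self.cm_per_mb < 0:
            raise ValueError("noise_sd_log2 and cm_per_mb must be non-negative")
        chrom, pos = self.qtl
        labels = [str(i + 1) for i in range(self.n_chromosomes)]
        if str(chrom) not in labels:
            raise ValueError(f"QTL chromosome {chrom!r} not among {labels}")
        if not 1 <= pos <= self.chrom_length_bp:
            raise ValueError(f"QTL position {pos} outside chromosome of length "
                             f"{self.chrom_length_bp}")
        if self.scenario not in ("linked", "unlinked"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "unlinked" and self.n_chromosomes < 2:
            raise ValueError("unlinked scenario needs >= 2 chromosomes")

    @property
    def chromosome_labels(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosome_labels}


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated data."""

    qtl: tuple[str, int]
    cis_effect: pd.Series  # gene_id -> log2 effect (0 for non-cis genes)
    # inherited haplotype index (0/1) per tree at every gene locus, one
    # matrix per parent; shape (n_trees, n_genes), gene order as in the
    # expression matrix
    haplotype_parent1: np.ndarray
    haplotype_parent2: np.ndarray
    qtl_haplotype_parent2: np.ndarray  # (n_trees,) 0/1; 1 = resistant allele
    phenotype: pd.Series  # tree_id -> group_A (resistant) / group_B

    @property
    def cis_gene_ids(self) -> list[str]:
        return self.cis_effect.index[self.cis_effect != 0].tolist()


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    annotation: AnnotationTable
    truth: SimTruth
    config: SimConfig


def build_genetic_map(positions_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Adjacent recombination fractions along one chromosome (Haldane).

    For adjacent loci separated by ``d`` Morgans (d = dbp * cM/Mb / 1e8),
    r = 0.5 * (1 - exp(-2 d)); r = 0 at zero distance and tends to 0.5.
    """
    pos = np.asarray(positions_bp, dtype=np.int64)
    if pos.ndim != 1:
        raise ValueError("positions must be a 1-D sequence")
    if pos.size >= 2 and not np.all(np.diff(pos) > 0):
        raise ValueError("locus positions must be strictly increasing")
    d_morgan = np.diff(pos) * (cm_per_mb / 1e8)
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgan))


def simulate_meiosis(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    recomb_fractions: np.ndarray,
    rng: np.random.Generator,
    n_gametes: int = 1,
) -> np.ndarray:
    """Draw gametes from one parent over an ordered set of linked loci.

    Each gamete starts on a fair random haplotype and switches between
    the two parental haplotypes independently in each interval with its
    recombination fraction.  Returns allele sequences, shape
    (n_gametes, n_loci).
    """
    hap0, hap1 = (np.asarray(h) for h in parent_haplotypes)
    if hap0.shape != hap1.shape or hap0.ndim != 1:
        raise ValueError("parent haplotypes must be 1-D and of equal length")
    r = np.asarray(recomb_fractions, dtype=float)
    if r.shape != (hap0.size - 1,):
        raise ValueError(
            f"expected {hap0.size - 1} recombination fractions, got {r.size}"
        )
    idx = _gamete_haplotype_indices(rng, n_gametes, r)
    stacked = np.stack([hap0, hap1])  # (2, n_loci)
    return stacked[idx, np.arange(hap0.size)[None, :]]


def _gamete_haplotype_indices(
    rng: np.random.Generator, n_gametes: int, r: np.ndarray
) -> np.ndarray:
    """Haplotype index (0/1) at each locus for n_gametes independent meioses."""
    start = rng.integers(0, 2, size=(n_gametes, 1))
    if r.size == 0:
        return start.astype(np.int8)
    switches = rng.random((n_gametes, r.size)) < r[None, :]
    idx = (start + np.concatenate(
        [np.zeros((n_gametes, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )) % 2
    return idx.astype(np.int8)


def simulate_cross(config: SimConfig) -> SimulatedDataset:
    """Simulate one F1 population; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    qtl_chrom, qtl_pos = str(config.qtl[0]), int(config.qtl[1])

    n_cis = int(round(config.cis_fraction * config.n_genes))
    chroms, positions, is_cis = _place_genes(config, rng, n_cis)

    # genomic order; gene ids reflect it
    order = np.lexsort((positions, chroms))
    chroms, positions, is_cis = chroms[order], positions[order], is_cis[order]
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    tree_ids = [f"tree{t + 1:02d}" for t in range(config.n_trees)]

    effects = np.where(is_cis, config.effect_size_log2, 0.0)

    hap1 = np.empty((config.n_trees, config.n_genes), dtype=np.int8)
    hap2 = np.empty((config.n_trees, config.n_genes), dtype=np.int8)
    qtl_hap2 = np.zeros(config.n_trees, dtype=np.int8)

    for chrom in config.chromosome_labels:
        mask = chroms == chrom
        loci = positions[mask]
        has_qtl = chrom == qtl_chrom
        if has_qtl:
            insert_at = int(np.searchsorted(loci, qtl_pos))
            loci_full = np.insert(loci, insert_at, qtl_pos)
        else:
            loci_full = loci
        if loci_full.size == 0:
            continue
        r = build_genetic_map(loci_full, config.cm_per_mb)
        # one gamete per parent per tree on this chromosome
        g1 = _gamete_haplotype_indices(rng, config.n_trees, r)
        g2 = _gamete_haplotype_indices(rng, config.n_trees, r)
        if has_qtl:
            qtl_hap2[:] = g2[:, insert_at]
            keep = np.ones(loci_full.size, dtype=bool)
            keep[insert_at] = False
            g1, g2 = g1[:, keep], g2[:, keep]
        hap1[:, mask] = g1
        hap2[:, mask] = g2

    baseline = rng.normal(
        config.baseline_mean_log2, config.baseline_sd_log2, size=config.n_genes
    )
    noise = rng.normal(0.0, config.noise_sd_log2, size=(config.n_genes, config.n_trees))
    # effects ride on haplotype 1 of parent 2
    values = baseline[:, None] + effects[:, None] * (hap2.T == 1) + noise

    phenotype_labels = np.where(qtl_hap2 == 1, "group_A", "group_B")
    phenotypes = PhenotypeTable.from_assignments(tree_ids, phenotype_labels, "trait")
    expression = ExpressionMatrix(gene_ids, tree_ids, values)
    annotation = AnnotationTable(
        pd.DataFrame(
            {"gene_id": gene_ids, "chromosome": chroms, "position_bp": positions}
        ),
        chrom_lengths=config.lengths(),
    )
    truth = SimTruth(
        qtl=(qtl_chrom, qtl_pos),
        cis_effect=pd.Series(effects, index=gene_ids, name="cis_effect_log2"),
        haplotype_parent1=hap1,
        haplotype_parent2=hap2,
        qtl_haplotype_parent2=qtl_hap2,
        phenotype=pd.Series(phenotype_labels, index=tree_ids, name="phenotype"),
    )
    return SimulatedDataset(expression, phenotypes, annotation, truth, config)


def _place_genes(
    config: SimConfig, rng: np.random.Generator, n_cis: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw gene locations; cis genes near (linked) or away from (unlinked) the QTL."""
    qtl_chrom, qtl_pos = str(config.qtl[0]), int(config.qtl[1])
    labels = np.array(config.chromosome_labels)

    n_bg = config.n_genes - n_cis
    bg_chroms = labels[rng.integers(0, labels.size, size=n_bg)]
    bg_pos = rng.integers(1, config.chrom_length_bp + 1, size=n_bg)

    if config.scenario == "linked":
        lo = max(1, qtl_pos - config.cis_window_bp)
        hi = min(config.chrom_length_bp, qtl_pos + config.cis_window_bp)
        cis_chroms = np.full(n_cis, qtl_chrom, dtype=labels.dtype)
        cis_pos = rng.integers(lo, hi + 1, size=n_cis)
    else:
        other = labels[labels != qtl_chrom]
        cis_chroms = other[rng.integers(0, other.size, size=n_cis)]
        cis_pos = rng.integers(1, config.chrom_length_bp + 1, size=n_cis)

    chroms = np.concatenate([cis_chroms, bg_chroms])
    positions = np.concatenate([cis_pos, bg_pos]).astype(np.int64)
    is_cis = np.zeros(config.n_genes, dtype=bool)
    is_cis[:n_cis] = True

    # loci must be distinct (strictly increasing per chromosome) and must not
    # collide with the QTL point; redraw the rare collisions
    for _ in range(100):
        key = chroms.astype(object) + ":" + positions.astype(str).astype(object)
        _, first = np.unique(key, return_index=True)
        dup = np.ones(config.n_genes, dtype=bool)
        dup[first] = False
        dup |= (chroms == qtl_chrom) & (positions == qtl_pos)
        if not dup.any():
            break
        positions[dup] = rng.integers(1, config.chrom_length_bp + 1, size=int(dup.sum()))
    else:  # pragma: no cover - 44 Mb chromosomes make this unreachable
        raise RuntimeError("could not place genes at distinct positions")
    return chroms, positions, is_cis


def truth_frame(dataset: SimulatedDataset) -> pd.DataFrame:
    """Flat per-gene truth table (for the CLI's truth.tsv)."""
    t = dataset.truth
    ann = dataset.annotation.table.set_index("gene_id")
    return pd.DataFrame(
        {
            "gene_id": t.cis_effect.index,
            "chromosome": ann["chromosome"].reindex(t.cis_effect.index).to_numpy(),
            "position_bp": ann["position_bp"].reindex(t.cis_effect.index).to_numpy(),
            "cis_effect_log2": t.cis_effect.to_numpy(),
        }
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=int(seed))
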
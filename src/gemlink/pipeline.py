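"""End-to-end orchestration: trait mode and GEM-trait mode.

Trait mode runs differential expression between the two phenotype
groups, calls DE genes at the q threshold, and quantifies their physical
clustering (per-chromosome summary, 10-Mb window scan, permutation test
of the peak).  GEM mode first detects gene expression markers, turns
each into a high/low molecular trait, and runs trait mode per GEM,
reporting whether the resulting DE peak window contains the GEM gene's
own locus (cis-clustered) or lies elsewhere (trans-clustered).

All randomness (the permutation null) is governed by one mandatory
seed; every output file starts with a comment header recording the seed
and a hash of the configuration, so re-running a config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import diffexpr as _diffexpr
from . import gem as _gem
from .io import AnnotationTable, ExpressionMatrix, PhenotypeTable

logger = logging.getLogger("gemlink")


@dataclass
class RunConfig:
    trait: str | None = None  # None => GEM mode
    q_threshold: float = _diffexpr.DEFAULT_Q_THRESHOLD
    window_bp: int = _cluster.DEFAULT_WINDOW_BP
    step_bp: int = _cluster.DEFAULT_STEP_BP
    n_perm: int = _cluster.DEFAULT_N_PERM
    seed: int = 0
    use_ebayes: bool = True
    min_fold: float = _gem.DEFAULT_MIN_FOLD
    balance_min: float = _gem.DEFAULT_BALANCE_MIN

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"seed={self.seed} config_hash={self.hash()}"


@dataclass
class TraitReport:
    trait: str
    de_table: pd.DataFrame
    de_genes: set[str]
    chromosomes: _cluster.ChromosomeSummary | None
    windows: _cluster.WindowScan | None
    peak_permutation_p: float | None
    notes: list[str] = field(default_factory=list)

    @property
    def peak(self) -> pd.Series | None:
        return self.windows.peak if self.windows is not None else None


@dataclass
class GEMReport:
    calls: list[_gem.GEMCall]
    trait_reports: dict[str, TraitReport]
    localization: pd.DataFrame  # gem_id, n_de, peak window, cis/trans call
    notes: list[str] = field(default_factory=list)


def run_trait_analysis(
    expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    annotation: AnnotationTable,
    config: RunConfig,
    trait: str | None = None,
) -> TraitReport:
    """DE analysis followed by physical clustering for one trait."""
    trait = trait if trait is not None else config.trait
    if trait is None:
        raise ValueError("no trait specified")
    if trait not in phenotypes.traits:
        raise KeyError(
            f"trait {trait!r} not in phenotype table; available: {phenotypes.traits}"
        )
    logger.info("DE analysis for trait %r", trait)
    de_table = _diffexpr.de_analysis(
        expr, phenotypes, trait, use_ebayes=config.use_ebayes
    )
    de_genes = _diffexpr.call_de(de_table, config.q_threshold)
    notes: list[str] = []
    if not de_genes:
        notes.append(f"no genes at q < {config.q_threshold}; clustering skipped")
        logger.info("trait %r: %s", trait, notes[-1])
        return TraitReport(trait, de_table, de_genes, None, None, None, notes)
    mapped = set(annotation.table["gene_id"]) & de_genes
    if not mapped:
        notes.append("no DE gene is mapped in the annotation; clustering skipped")
        return TraitReport(trait, de_table, de_genes, None, None, None, notes)
    chroms = _cluster.chromosome_summary(de_genes, annotation)
    windows = _cluster.window_scan(
        de_genes, annotation, width=config.window_bp, step=config.step_bp
    )
    perm_p = _cluster.permutation_window_test(
        int(windows.peak["de_count"]),
        windows.n_de_mapped,
        annotation,
        width=config.window_bp,
        step=config.step_bp,
        n_perm=config.n_perm,
        seed=np.random.default_rng([config.seed, _stable_offset(trait)]),
    )
    logger.info(
        "trait %r: %d DE genes, peak %s:%d-%d (count %d, perm p %.4g)",
        trait, len(de_genes), windows.peak["chromosome"],
        windows.peak["start_bp"], windows.peak["end_bp"],
        windows.peak["de_count"], perm_p,
    )
    return TraitReport(trait, de_table, de_genes, chroms, windows, perm_p, notes)


def run_gem_analysis(
    expr: ExpressionMatrix,
    annotation: AnnotationTable,
    config: RunConfig,
) -> GEMReport:
    """Detect GEMs and run a trait analysis per GEM-derived trait."""
    calls, gem_phenotypes = _gem.scan_gems(
        expr, min_fold=config.min_fold, balance_min=config.balance_min
    )
    if gem_phenotypes is None:
        return GEMReport(
            calls=calls,
            trait_reports={},
            localization=pd.DataFrame(
                columns=["gem_id", "n_de", "peak_chromosome", "peak_start_bp",
                         "peak_end_bp", "peak_permutation_p", "localization"]
            ),
            notes=["no GEMs detected"],
        )
    reports: dict[str, TraitReport] = {}
    rows = []
    for trait in gem_phenotypes.traits:
        gem_id = trait.removeprefix("GEM:")
        report = run_trait_analysis(expr, gem_phenotypes, annotation, config, trait)
        reports[trait] = report
        row = {
            "gem_id": gem_id,
            "n_de": len(report.de_genes),
            "peak_chromosome": None,
            "peak_start_bp": None,
            "peak_end_bp": None,
            "peak_permutation_p": report.peak_permutation_p,
            "localization": "no-peak",
        }
        if report.peak is not None:
            row["peak_chromosome"] = report.peak["chromosome"]
            row["peak_start_bp"] = int(report.peak["start_bp"])
            row["peak_end_bp"] = int(report.peak["end_bp"])
            row["localization"] = _classify_localization(
                report.peak, gem_id, annotation
            )
        rows.append(row)
    return GEMReport(calls=calls, trait_reports=reports,
                     localization=pd.DataFrame(rows))


def _classify_localization(
    peak: pd.Series, gem_id: str, annotation: AnnotationTable
) -> str:
    """cis-clustered if the DE peak window contains the GEM gene's own locus."""
    loc = annotation.position_of(gem_id)
    if loc is None:
        return "gem-unmapped"
    chrom, pos = loc
    if chrom == peak["chromosome"] and peak["start_bp"] <= pos < peak["end_bp"]:
        return "cis-clustered"
    return "trans-clustered"


def write_trait_report(report: TraitReport, outdir: str | Path,
                       config: RunConfig) -> None:
    """Write DE table, chromosome summary, windows, peak BED, and run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()
    de = report.de_table.reset_index()
    de["de_call"] = de["gene_id"].isin(report.de_genes)
    _write_tsv(de[["gene_id", "mean_A", "mean_B", "M", "t_mod", "df_total",
                   "p_value", "q_value", "de_call"]],
               outdir / "de_results.tsv", header)
    if report.chromosomes is not None:
        _write_tsv(report.chromosomes.table, outdir / "chromosome_summary.tsv", header)
    if report.windows is not None:
        _write_tsv(report.windows.windows, outdir / "windows.tsv", header)
        with open(outdir / "peak.bed", "w") as fh:
            fh.write(f"# {header}\n")
            fh.write(_cluster.peak_to_bed(report.windows.peak) + "\n")
    log = {
        "trait": report.trait,
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_de": len(report.de_genes),
        "pi0": report.de_table.attrs.get("pi0"),
        "prior_d0": _jsonable(report.de_table.attrs.get("prior_d0")),
        "peak_permutation_p": report.peak_permutation_p,
        "notes": report.notes,
    }
    with open(outdir / "run_log.jsonl", "w") as fh:
        fh.write(json.dumps(log, sort_keys=True, default=str) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _jsonable(x):
    if isinstance(x, float) and np.isinf(x):
        return "inf"
    return x


def _stable_offset(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")
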
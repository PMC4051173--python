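"""Data model and tabular I/O for the expression-linkage pipeline.

All pipeline inputs are plain TSV: a log2 expression matrix (genes x
samples), a phenotype table assigning samples to two trait groups, and a
gene annotation giving each gene a representative genomic point (1-based
bp).  Lines starting with ``#`` are header comments (used to record seeds
and config hashes) and are ignored on read.

Also ships the reference table of trait-associated transcripts from the
published apple O3 x R5 rootstock study (powdery-mildew and woolly-apple-
aphid resistance sections), used as a worked example and test fixture.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

PHENOTYPE_LABELS = ("group_A", "group_B", "unassigned")

_FIXTURE_NAME = "apple_f1_de_genes.tsv"


class FormatError(ValueError):
    """A file or table violates the pipeline's format contract."""


@dataclass
class ExpressionMatrix:
    """Log2-normalized expression, genes in rows, samples in columns."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), log2 units

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value for gene {self.gene_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def sample_columns(self, samples: Iterable[str]) -> np.ndarray:
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [idx[s] for s in samples]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in expression matrix") from None
        return self.values[:, cols]


@dataclass
class PhenotypeTable:
    """Sample-to-group assignments, one row per (sample, trait)."""

    table: pd.DataFrame  # columns: sample_id, trait, label

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = ["sample_id", "trait", "label"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns {missing}")
        df = df[required].astype(str).reset_index(drop=True)
        dup = df.duplicated(subset=["sample_id", "trait"])
        if dup.any():
            row = df[dup].iloc[0]
            raise FormatError(
                f"duplicate phenotype row for sample {row.sample_id!r}, "
                f"trait {row.trait!r}"
            )
        bad = ~df["label"].isin(PHENOTYPE_LABELS)
        if bad.any():
            raise FormatError(
                f"unknown phenotype label {df.loc[bad, 'label'].iloc[0]!r}; "
                f"allowed: {PHENOTYPE_LABELS}"
            )
        self.table = df

    @property
    def traits(self) -> list[str]:
        return sorted(self.table["trait"].unique())

    def groups(self, trait: str) -> tuple[list[str], list[str]]:
        """Samples in group_A and group_B for one trait (unassigned dropped)."""
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(
                f"trait {trait!r} not in phenotype table; available: {self.traits}"
            )
        a = sub.loc[sub["label"] == "group_A", "sample_id"].tolist()
        b = sub.loc[sub["label"] == "group_B", "sample_id"].tolist()
        return a, b

    @classmethod
    def from_assignments(
        cls, sample_ids: Iterable[str], labels: Iterable[str], trait: str
    ) -> "PhenotypeTable":
        return cls(
            pd.DataFrame(
                {"sample_id": list(sample_ids), "trait": trait, "label": list(labels)}
            )
        )


@dataclass
class AnnotationTable:
    """Gene -> (chromosome, 1-based bp position) map.

    A gene's position is a single representative point; genes absent from
    the table are treated as unmapped downstream.
    """

    table: pd.DataFrame  # columns: gene_id, chromosome, position_bp
    chrom_lengths: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        required = ["gene_id", "chromosome", "position_bp"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing columns {missing}")
        df = df[required].reset_index(drop=True)
        df["gene_id"] = df["gene_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_bp"] = pd.to_numeric(df["position_bp"], errors="raise").astype(
            np.int64
        )
        dup = df["gene_id"].duplicated()
        if dup.any():
            raise FormatError(f"duplicate gene id {df.loc[dup, 'gene_id'].iloc[0]!r}")
        if (df["position_bp"] < 1).any():
            g = df.loc[df["position_bp"] < 1, "gene_id"].iloc[0]
            raise FormatError(f"position_bp < 1 for gene {g!r} (positions are 1-based)")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.table["chromosome"].unique())

    def position_of(self, gene_id: str) -> tuple[str, int] | None:
        sub = self.table[self.table["gene_id"] == gene_id]
        if sub.empty:
            return None
        row = sub.iloc[0]
        return str(row["chromosome"]), int(row["position_bp"])

    def lengths(self) -> dict[str, int]:
        """Chromosome extents: declared lengths if given, else max gene position."""
        if self.chrom_lengths is not None:
            return dict(self.chrom_lengths)
        return (
            self.table.groupby("chromosome")["position_bp"].max().astype(int).to_dict()
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV (first column gene ids)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene id column plus >=1 sample column")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    _check_unique(gene_ids, "gene id", where=str(path))
    _check_unique(sample_ids, "sample id", where=str(path))
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any() or body[col].isna().any():
            i = int(np.argmax((converted.isna()).to_numpy()))
            raise FormatError(
                f"{path}: non-numeric or missing value at gene {gene_ids[i]!r}, "
                f"sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            _write_comment(fh, header_comment)
        frame = matrix.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(fh, sep="\t", lineterminator="\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path)
    df = df.rename(columns={"trait_name": "trait"})
    return PhenotypeTable(df)


def write_phenotypes(
    phenotypes: PhenotypeTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            _write_comment(fh, header_comment)
        phenotypes.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_gene_annotation(path: str | Path) -> AnnotationTable:
    df = _read_tsv(path)
    return AnnotationTable(df)


def write_gene_annotation(
    annotation: AnnotationTable, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            _write_comment(fh, header_comment)
        annotation.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# packaged reference table

FIXTURE_SECTIONS = ("PM", "WAA")


def load_reference_de_genes(trait_section: str) -> pd.DataFrame:
    """Published trait-associated transcript table, one section at a time.

    ``trait_section`` is ``"PM"`` (powdery mildew resistance, 30 rows) or
    ``"WAA"`` (woolly apple aphid resistance, 7 rows).  Columns: seq_id,
    delta_expression (log2, resistant minus susceptible), q_value,
    chromosome, position_mb (as printed, one decimal).
    """
    if trait_section not in FIXTURE_SECTIONS:
        raise KeyError(
            f"unknown trait section {trait_section!r}; expected one of "
            f"{FIXTURE_SECTIONS}"
        )
    raw = resources.files("gemlink.fixtures").joinpath(_FIXTURE_NAME).read_text()
    df = pd.read_csv(
        _io.StringIO(raw),
        sep="\t",
        dtype={"chromosome": str},
    )
    out = df[df["trait_section"] == trait_section].reset_index(drop=True)
    return out[["seq_id", "delta_expression", "q_value", "chromosome", "position_mb"]]


def reference_annotation(trait_section: str) -> AnnotationTable:
    """Annotation table for a reference section, Mb converted to 1-based bp."""
    df = load_reference_de_genes(trait_section)
    return AnnotationTable(
        pd.DataFrame(
            {
                "gene_id": df["seq_id"],
                "chromosome": df["chromosome"],
                "position_bp": np.round(df["position_mb"] * 1e6).astype(np.int64),
            }
        )
    )


# ---------------------------------------------------------------------------


def _check_unique(ids: list[str], what: str, where: str | None = None) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            prefix = f"{where}: " if where else ""
            raise FormatError(f"{prefix}duplicate {what} {x!r}")
        seen.add(x)


def _write_comment(fh, comment: str) -> None:
    for line in comment.splitlines():
        fh.write(f"# {line}\n")
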
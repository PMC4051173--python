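import numpy as np
import pandas as pd
import pytest

from gemlink import ExpressionMatrix, PhenotypeTable, SimConfig, simulate_cross
from gemlink.io import AnnotationTable


@pytest.fixture(scope="session")
def linked_dataset():
    """One default linked-scenario cross, shared across tests."""
    return simulate_cross(SimConfig(seed=12345))


@pytest.fixture()
def small_expr():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(40)]
    samples = [f"s{j:02d}" for j in range(12)]
    return ExpressionMatrix(genes, samples, rng.normal(8, 1, size=(40, 12)))


@pytest.fixture()
def two_group_phenotypes(small_expr):
    labels = ["group_A"] * 6 + ["group_B"] * 6
    return PhenotypeTable.from_assignments(small_expr.sample_ids, labels, "trait")


@pytest.fixture()
def toy_annotation():
    """12 genes on 2 chromosomes, 4 of them clustered tightly on chr 1."""
    rows = []
    for i, pos in enumerate([10, 1_000_000, 1_200_000, 1_400_000, 1_600_000,
                             9_000_000, 20_000_000, 33_000_000]):
        rows.append((f"a{i}", "1", pos))
    for i, pos in enumerate([5_000_000, 15_000_000, 25_000_000, 40_000_000]):
        rows.append((f"b{i}", "2", pos))
    return AnnotationTable(
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "position_bp"]),
        chrom_lengths={"1": 44_000_000, "2": 44_000_000},
    )
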
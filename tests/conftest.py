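import numpy as np
import pandas as pd
import pytest

from driverscope.io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    PositionWeightMatrix,
    SurvivalTable,
)
from driverscope.simulate import (
    BulkSimConfig,
    ScSimConfig,
    simulate_bulk_cohort,
    simulate_sc_dataset,
)


@pytest.fixture(scope="session")
def bulk_cohort():
    """A planted-signal bulk cohort: one strongly prognostic pathway."""
    cfg = BulkSimConfig(
        n_samples=300,
        n_genes=500,
        n_pathways=10,
        genes_per_pathway=20,
        planted_pathways={0: 0.8},
        seed=11,
    )
    return simulate_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def sc_dataset():
    """Single-cell dataset with a 2x CNV gain block and a planted driver loss."""
    cfg = ScSimConfig(
        cell_types={"Malignant": 250, "Immune": 250, "Stromal": 150},
        reference_types=("Immune", "Stromal"),
        malignant_type="Malignant",
        n_genes=1000,
        n_chromosomes=5,
        cnv_blocks=[(250, 550, 2.0), (700, 760, 0.35)],
        de_genes={"G00050": 2.0, "G00051": 2.5},
        pseudotime_genes={"G00100": "late-up", "G00101": "down", "G00102": "early-peak"},
        lr_pairs=[("G00200", "G00201", "Immune", "Malignant", 8.0)],
        seed=7,
    )
    return simulate_sc_dataset(cfg)


@pytest.fixture
def tiny_expr():
    """5 genes x 2 samples with distinct values and no ties."""
    df = pd.DataFrame(
        {
            "S1": [5.0, 4.0, 3.0, 2.0, 1.0],
            "S2": [1.0, 3.0, 5.0, 2.0, 4.0],
        },
        index=["GA", "GB", "GC", "GD", "GE"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def tiny_sets():
    return GeneSetCollection(
        {
            "set1": GeneSet("set1", "d", ("GA", "GC")),
            "set2": GeneSet("set2", "d", ("GB", "GD", "GE")),
        }
    )


@pytest.fixture
def strong_pwm():
    """A sharply peaked 8-mer motif (ACGTACGT consensus)."""
    probs = np.full((4, 8), 0.03)
    consensus = "ACGTACGT"
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        probs[idx[b], j] = 0.91
    return PositionWeightMatrix("MA_TEST", probs)


def make_survival(times, events, ids=None):
    ids = ids or [f"P{i}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame(
            {"time": times, "event": events},
            index=pd.Index(ids, name="subject_id"),
        )
    )
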
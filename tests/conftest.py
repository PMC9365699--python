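import numpy as np
import pandas as pd
import pytest

from sicnv.genome_io import CountMatrix, GenePositionTable
from sicnv.simulator import SimulationConfig


@pytest.fixture
def gene_position_file(tmp_path):
    """Headerless 4-column TSV with shuffled starts and a chrM gene."""
    rows = [
        ("geneC", "chr1", 300, 400),
        ("geneA", "chr1", 100, 150),
        ("geneB", "chr1", 200, 260),
        ("geneD", "chr2", 50, 90),
        ("geneM", "chrM", 1, 500),
    ]
    path = tmp_path / "genes.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    return path


@pytest.fixture
def small_counts():
    """2 spots x 3 genes with 4 nonzero cells."""
    return CountMatrix(
        barcodes=["AAAC-1", "AAAG-1"],
        gene_ids=["geneA", "geneB", "geneC"],
        counts=np.array([[5, 0, 2], [0, 7, 1]]),
    )


def make_gene_table(n_genes, chromosome="chr_sim"):
    return GenePositionTable(
        pd.DataFrame(
            {
                "gene_id": [f"g{j:04d}" for j in range(n_genes)],
                "chromosome": chromosome,
                "start": np.arange(n_genes) * 1000 + 1,
                "stop": np.arange(n_genes) * 1000 + 1000,
                "genome_rank": np.arange(n_genes),
            }
        ),
        (chromosome,),
    )


@pytest.fixture
def tiny_sim_config():
    """Fast simulator settings for structural tests (sub-second)."""
    return SimulationConfig(
        domain_size=(20.0, 20.0),
        n_founders=3,
        n_steps=16,
        n_genes=60,
        segment_length_genes=(10, 25),
        mean_spot_depth=800.0,
        max_cells=800,
        seed=0,
    )
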
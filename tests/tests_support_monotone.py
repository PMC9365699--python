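"""Shared builder for the copy-number ladder used in monotonicity checks."""

import numpy as np
import pandas as pd

from conftest import make_gene_table
from sicnv.genome_io import CountMatrix
from sicnv.simulator import SimulationConfig, SyntheticTissue, bin_cells_to_spots, sample_expression


def build_copy_ladder_counts(seed=0, n_genes=600, spots_per_group=12,
                             segment=slice(180, 350), depth=5000.0):
    """Counts for groups of pure spots at segment copy 2 (reference), 3 and 4.

    Uses the simulator's expression model on hand-placed cells so the
    ladder inherits the exact intensity-proportional-to-copy generative
    process. Returns (counts, gene_table, {copy: barcodes}, reference_barcodes).
    """
    config = SimulationConfig(
        domain_size=(200.0, 20.0),
        n_genes=n_genes,
        mean_spot_depth=depth,
        seed=seed,
    )
    genotypes = []
    for copy in (2, 3, 4):
        g = np.full(n_genes, 2, dtype=np.int16)
        g[segment] = copy
        genotypes.append(g)

    cells = {"cell_id": [], "parent_id": [], "x": [], "y": [],
             "genotype_id": [], "birth_step": [], "alive": []}
    cid = 0
    spot_of_group: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for gi in range(3):
        for s in range(spots_per_group):
            col = gi * spots_per_group + s
            x = (col + 0.5) * config.spot_pitch
            y = 1.0
            spot_of_group[gi].append(f"spot_0x{col}")
            for _ in range(5):  # 5 cells per spot
                cells["cell_id"].append(cid)
                cells["parent_id"].append(-1)
                cells["x"].append(x)
                cells["y"].append(y)
                cells["genotype_id"].append(gi)
                cells["birth_step"].append(0)
                cells["alive"].append(True)
                cid += 1

    tissue = SyntheticTissue(pd.DataFrame(cells), np.array(genotypes), config)
    tissue = bin_cells_to_spots(tissue)
    counts = sample_expression(tissue, rng=np.random.default_rng(seed))
    genes = make_gene_table(n_genes)
    carriers_by_copy = {2: spot_of_group[0], 3: spot_of_group[1], 4: spot_of_group[2]}
    reference = spot_of_group[0]
    return counts, genes, carriers_by_copy, reference
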
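"""Generative tissue simulator with ground-truth copy numbers.

Virtual cells populate a rectangular domain: at every step each cell
moves, divides, dies or stays stagnant. Divisions occasionally mutate a
contiguous gene segment by +-1 copy, producing spatially structured
clones. Cells are binned into a Visium-like spot grid and per-spot UMI
counts are sampled with expression intensity proportional to copy number,
so every downstream inference stage can be scored against known truth.
"""

from __future__ import annotations

import logging
import os
import tomllib
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from sicnv.genome_io import CountMatrix

logger = logging.getLogger(__name__)

SIM_CHROMOSOME = "chr_sim"  # single artificial chromosome


class ExtinctionError(RuntimeError):
    """Population died out before the simulation finished."""

    def __init__(self, step: int):
        super().__init__(f"population extinct at step {step}")
        self.step = step


@dataclass
class SimulationConfig:
    """Parameters of the generative process.

    ``p_move + p_divide + p_die + p_stagnate`` must sum to 1. Mutations
    occur at division with probability ``p_mutation_at_division``;
    restricting them to early steps (``mutation_last_step``) yields large,
    spatially coherent clones.
    """

    domain_size: tuple[float, float] = (60.0, 60.0)
    n_founders: int = 5
    n_steps: int = 48
    p_move: float = 0.05
    p_divide: float = 0.20
    p_die: float = 0.01
    p_stagnate: float = 0.74
    p_mutation_at_division: float = 0.30
    mutation_last_step: Optional[int] = 8
    n_genes: int = 600
    max_copy_number: int = 6
    segment_length_genes: tuple[int, int] = (60, 150)
    spot_diameter: float = 1.8
    spot_pitch: float = 2.0
    baseline_expression: Optional[np.ndarray] = None
    mean_spot_depth: float = 5000.0
    depth_dispersion: float = 20.0
    move_step: float = 0.5
    division_offset: float = 1.0
    site_capacity: int = 2
    max_cells: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([self.p_move, self.p_divide, self.p_die, self.p_stagnate])
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("action probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"p_move+p_divide+p_die+p_stagnate must sum to 1, got {probs.sum()}"
            )
        if not 0 <= self.p_mutation_at_division <= 1:
            raise ValueError("p_mutation_at_division must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.max_copy_number < 0:
            raise ValueError("max_copy_number must be >= 0")
        lo, hi = self.segment_length_genes
        if not (1 <= lo <= hi):
            raise ValueError("segment_length_genes must satisfy 1 <= min <= max")

    def baselines(self) -> np.ndarray:
        if self.baseline_expression is not None:
            b = np.asarray(self.baseline_expression, dtype=float)
            if b.shape != (self.n_genes,) or (b <= 0).any():
                raise ValueError("baseline_expression must be positive, length n_genes")
            return b
        return np.ones(self.n_genes)

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw = raw.get("simulation", raw)
        kwargs = {}
        for key, value in raw.items():
            if key in ("domain_size", "segment_length_genes"):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SyntheticTissue:
    """Simulated cells with lineage, genotypes and (optional) spot binning.

    ``cells`` columns: cell_id, parent_id (-1 for founders), x, y,
    genotype_id, birth_step, alive. ``genotypes`` is a
    (n_genotypes, n_genes) absolute-copy integer matrix (diploid = 2).
    Spot columns (``spot``) are added by :func:`bin_cells_to_spots`.
    """

    cells: pd.DataFrame
    genotypes: np.ndarray
    config: SimulationConfig
    spots: Optional[pd.DataFrame] = None  # barcode, x, y, n_cells

    @property
    def alive(self) -> pd.DataFrame:
        return self.cells[self.cells["alive"]]

    def clone_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Collapse genotypes of living cells into clone labels.

        Cells with identical copy-number vectors share a clone; labels
        ``clone_00, clone_01, ...`` are ordered by decreasing clone size
        (ties by genotype content). Returns ``(labels_per_alive_cell,
        clone_genotypes)`` where row ``k`` of the matrix is the genotype of
        ``clone_k``.
        """
        alive = self.alive
        vecs = self.genotypes[alive["genotype_id"].to_numpy()]
        uniq, inverse, counts = np.unique(
            vecs, axis=0, return_inverse=True, return_counts=True
        )
        order = np.argsort(-counts, kind="stable")
        rank = np.empty(len(order), dtype=int)
        rank[order] = np.arange(len(order))
        labels = np.array([f"clone_{rank[i]:02d}" for i in inverse])
        return labels, uniq[order]


def simulate_tissue(config: SimulationConfig) -> SyntheticTissue:
    """Run the agent-based growth process. Deterministic given the seed.

    Local crowding limits each unit site to ``site_capacity`` cells, so
    divisions succeed only where space remains; growth concentrates at the
    tissue frontier and early mutations expand into contiguous sectors.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.domain_size

    xs: list[float] = []
    ys: list[float] = []
    parent: list[int] = []
    genotype_id: list[int] = []
    birth_step: list[int] = []
    alive: list[bool] = []
    genotypes: list[np.ndarray] = [np.full(config.n_genes, 2, dtype=np.int16)]
    occupancy: dict[tuple[int, int], int] = {}

    def site(x: float, y: float) -> tuple[int, int]:
        return (int(x), int(y))

    def has_room(x: float, y: float) -> bool:
        return occupancy.get(site(x, y), 0) < config.site_capacity

    for _ in range(config.n_founders):
        x = float(rng.uniform(0, width))
        y = float(rng.uniform(0, height))
        xs.append(x)
        ys.append(y)
        parent.append(-1)
        genotype_id.append(0)
        birth_step.append(0)
        alive.append(True)
        occupancy[site(x, y)] = occupancy.get(site(x, y), 0) + 1

    living = list(range(config.n_founders))
    probs = [config.p_move, config.p_divide, config.p_die, config.p_stagnate]

    for step in range(1, config.n_steps + 1):
        if not living:
            raise ExtinctionError(step - 1)
        actions = rng.choice(4, size=len(living), p=probs)
        can_mutate = (
            config.mutation_last_step is None or step <= config.mutation_last_step
        )
        next_living: list[int] = []
        for cell, action in zip(living, actions):
            if action == 0:  # move (bounded step; blocked by crowded sites)
                dx, dy = rng.normal(0.0, config.move_step, size=2)
                nx = float(np.clip(xs[cell] + dx, 0, width))
                ny = float(np.clip(ys[cell] + dy, 0, height))
                old = site(xs[cell], ys[cell])
                if site(nx, ny) == old or has_room(nx, ny):
                    occupancy[old] -= 1
                    occupancy[site(nx, ny)] = occupancy.get(site(nx, ny), 0) + 1
                    xs[cell], ys[cell] = nx, ny
                next_living.append(cell)
            elif action == 1:  # divide into a nearby free site
                next_living.append(cell)
                if len(xs) >= config.max_cells:
                    continue
                placed = None
                for _attempt in range(6):
                    dx, dy = rng.normal(0.0, config.division_offset, size=2)
                    nx = float(np.clip(xs[cell] + dx, 0, width))
                    ny = float(np.clip(ys[cell] + dy, 0, height))
                    if has_room(nx, ny):
                        placed = (nx, ny)
                        break
                if placed is None:
                    continue  # no room: division fails
                gid = genotype_id[cell]
                if can_mutate and rng.random() < config.p_mutation_at_division:
                    gid = _mutate(genotypes, gid, config, rng)
                xs.append(placed[0])
                ys.append(placed[1])
                occupancy[site(*placed)] = occupancy.get(site(*placed), 0) + 1
                parent.append(cell)
                genotype_id.append(gid)
                birth_step.append(step)
                alive.append(True)
                next_living.append(len(xs) - 1)
            elif action == 2:  # die
                alive[cell] = False
                occupancy[site(xs[cell], ys[cell])] -= 1
            else:  # stagnate
                next_living.append(cell)
        living = next_living
        if not living:
            raise ExtinctionError(step)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(xs)),
            "parent_id": parent,
            "x": xs,
            "y": ys,
            "genotype_id": genotype_id,
            "birth_step": birth_step,
            "alive": alive,
        }
    )
    logger.info(
        "simulate_tissue: %d cells (%d alive), %d genotypes",
        len(cells), int(cells["alive"].sum()), len(genotypes),
    )
    return SyntheticTissue(cells, np.array(genotypes), config)


def _mutate(
    genotypes: list[np.ndarray],
    gid: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> int:
    """Apply a +-1 copy change to one contiguous segment; returns new gid."""
    lo, hi = config.segment_length_genes
    length = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, config.n_genes))
    stop = min(start + length, config.n_genes)
    direction = 1 if rng.random() < 0.5 else -1
    new = genotypes[gid].copy()
    new[start:stop] = np.clip(
        new[start:stop] + direction, 0, config.max_copy_number
    )
    genotypes.append(new)
    return len(genotypes) - 1


# ---------------------------------------------------------------------------
# Spot binning and expression sampling
# ---------------------------------------------------------------------------


def bin_cells_to_spots(
    tissue: SyntheticTissue, config: Optional[SimulationConfig] = None
) -> SyntheticTissue:
    """Assign living cells to a regular grid of circular capture spots.

    A cell joins the spot whose centre lies within ``spot_diameter / 2``;
    cells in the inter-spot gaps stay unassigned; empty spots are dropped.
    """
    config = config or tissue.config
    if config.spot_diameter > config.spot_pitch:
        raise ValueError("spot_diameter > spot_pitch: overlapping capture areas")
    pitch = config.spot_pitch
    radius = config.spot_diameter / 2.0

    cells = tissue.cells.copy()
    x = cells["x"].to_numpy()
    y = cells["y"].to_numpy()
    col = np.floor(x / pitch).astype(int)
    row = np.floor(y / pitch).astype(int)
    cx = (col + 0.5) * pitch
    cy = (row + 0.5) * pitch
    dist = np.hypot(x - cx, y - cy)
    inside = (dist <= radius) & cells["alive"].to_numpy()

    spot_names = np.array([f"spot_{r}x{c}" for r, c in zip(row, col)], dtype=object)
    spot = np.where(inside, spot_names, None)
    cells["spot"] = spot

    assigned = cells[inside]
    spots = (
        assigned.groupby("spot", sort=True)
        .agg(n_cells=("cell_id", "size"))
        .reset_index()
        .rename(columns={"spot": "barcode"})
    )
    rc = spots["barcode"].str.extract(r"spot_(-?\d+)x(-?\d+)").astype(int)
    spots["x"] = (rc[1] + 0.5) * pitch
    spots["y"] = (rc[0] + 0.5) * pitch
    logger.info(
        "bin_cells_to_spots: %d/%d living cells captured in %d spots",
        int(inside.sum()), int(cells["alive"].sum()), len(spots),
    )
    return SyntheticTissue(cells, tissue.genotypes, config, spots)


def sample_expression(
    tissue: SyntheticTissue,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> CountMatrix:
    """Sample per-spot UMI counts from copy-number-scaled intensities.

    Per-gene intensity in a spot is ``sum_cells baseline[g] * copy[c, g] / 2``;
    spot depth is negative-binomial around ``mean_spot_depth`` and counts
    are multinomial over genes proportional to intensity.
    """
    config = config or tissue.config
    if tissue.spots is None:
        raise ValueError("bin_cells_to_spots must run before sample_expression")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    baselines = config.baselines()

    barcodes = tissue.spots["barcode"].tolist()
    counts = np.zeros((len(barcodes), config.n_genes), dtype=np.int64)
    assigned = tissue.cells[tissue.cells["spot"].notna()]
    geno_by_spot = assigned.groupby("spot")["genotype_id"]

    mean = config.mean_spot_depth
    disp = config.depth_dispersion
    for i, barcode in enumerate(barcodes):
        gids = geno_by_spot.get_group(barcode).to_numpy()
        intensity = baselines * (tissue.genotypes[gids].sum(axis=0) / 2.0)
        total = intensity.sum()
        if total == 0:
            logger.warning("spot %s has zero total intensity; emitting zeros", barcode)
            continue
        if mean <= 0:
            continue
        depth = int(rng.negative_binomial(disp, disp / (disp + mean)))
        if depth == 0:
            continue
        counts[i] = rng.multinomial(depth, intensity / total)
    section_of = {b: "sim" for b in barcodes}
    return CountMatrix(barcodes, [f"g{j:04d}" for j in range(config.n_genes)],
                       counts, section_of)


def simulated_gene_positions(config: SimulationConfig):
    """Gene position table for the artificial chromosome (1 kb per gene)."""
    from sicnv.genome_io import GenePositionTable

    n = config.n_genes
    df = pd.DataFrame(
        {
            "gene_id": [f"g{j:04d}" for j in range(n)],
            "chromosome": SIM_CHROMOSOME,
            "start": np.arange(n) * 1000 + 1,
            "stop": np.arange(n) * 1000 + 1000,
            "genome_rank": np.arange(n),
        }
    )
    return GenePositionTable(df, (SIM_CHROMOSOME,))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

CATEGORIES = ("deletion", "neutral", "amplification")


def _round_nearest(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties to even (0.5 -> 0, 1.5 -> 2)."""
    return np.round(x).astype(int)


def categorize_relative_copy(rounded_relative: np.ndarray) -> np.ndarray:
    """<1 -> deletion, ==1 -> neutral, >1 -> amplification."""
    out = np.full(rounded_relative.shape, "neutral", dtype=object)
    out[rounded_relative < 1] = "deletion"
    out[rounded_relative > 1] = "amplification"
    return out


@dataclass
class GroundTruth:
    """Truth tables derived from a binned tissue.

    Copy numbers are reported in reference-relative units (diploid = 1).
    ``spot_clone`` is the modal clone among each spot's cells.
    """

    per_spot_mean_copy: pd.DataFrame     # spots x genes, relative
    per_spot_rounded_copy: pd.DataFrame  # spots x genes, int
    per_clone_category: pd.DataFrame     # clones x genes in CATEGORIES
    spot_clone: pd.Series                # barcode -> clone label
    clone_genotypes: np.ndarray          # clones x genes absolute copies


def ground_truth_categories(tissue: SyntheticTissue) -> GroundTruth:
    """Per-spot rounded relative copy and per-clone gene categories.

    Spot averages pool all assigned cells; clone categories apply the
    <1 / =1 / >1 rule to the clone-level rounded relative copy number.
    """
    if tissue.spots is None:
        raise ValueError("bin_cells_to_spots must run before ground_truth_categories")
    labels, clone_genotypes = tissue.clone_labels()
    alive = tissue.alive.copy()
    alive["clone"] = labels
    assigned = alive[alive["spot"].notna()]
    barcodes = tissue.spots["barcode"].tolist()
    gene_ids = [f"g{j:04d}" for j in range(tissue.config.n_genes)]

    mean_copy = np.zeros((len(barcodes), tissue.config.n_genes))
    spot_clone = []
    grouped = assigned.groupby("spot")
    for i, barcode in enumerate(barcodes):
        grp = grouped.get_group(barcode)
        vecs = tissue.genotypes[grp["genotype_id"].to_numpy()]
        mean_copy[i] = vecs.mean(axis=0) / 2.0
        # modal clone; ties resolved by label order
        spot_clone.append(grp["clone"].value_counts().idxmax())

    rounded = _round_nearest(mean_copy)
    clone_names = [f"clone_{k:02d}" for k in range(len(clone_genotypes))]
    clone_rounded = _round_nearest(clone_genotypes / 2.0)
    clone_cat = np.stack([categorize_relative_copy(r) for r in clone_rounded])

    return GroundTruth(
        per_spot_mean_copy=pd.DataFrame(mean_copy, index=barcodes, columns=gene_ids),
        per_spot_rounded_copy=pd.DataFrame(rounded, index=barcodes, columns=gene_ids),
        per_clone_category=pd.DataFrame(clone_cat, index=clone_names, columns=gene_ids),
        spot_clone=pd.Series(spot_clone, index=barcodes, name="clone"),
        clone_genotypes=clone_genotypes,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    truth.per_spot_rounded_copy.to_csv(
        os.path.join(outdir, "spot_rounded_copy.tsv"), sep="\t"
    )
    truth.per_clone_category.to_csv(
        os.path.join(outdir, "clone_categories.tsv"), sep="\t"
    )
    truth.spot_clone.to_csv(os.path.join(outdir, "spot_clones.csv"))


def write_cell_table(tissue: SyntheticTissue, path: str | os.PathLike) -> None:
    alive = tissue.alive.copy()
    labels, _ = tissue.clone_labels()
    alive["clone"] = labels
    alive[["cell_id", "x", "y", "parent_id", "clone"]].to_csv(path, index=False)
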
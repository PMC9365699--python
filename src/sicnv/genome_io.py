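"""I/O for spot count matrices, gene position tables and annotations.

Formats handled:

* gene position file: headerless TSV ``(gene, chromosome, start, stop)``,
  1-based inclusive coordinates;
* counts: MatrixMarket triplet directory (``matrix.mtx`` + ``barcodes.tsv``
  + ``features.tsv``, 10x dialect), dense TSV (genes in rows), or the
  10x HDF5 filtered-matrix dialect;
* spot annotations: CSV with header ``Barcode,Annotation`` (Loupe export);
* spot positions: CSV ``(barcode, in_tissue, array_row, array_col,
  pixel_row, pixel_col)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Natural human chromosome order used to rank genes along the genome.
DEFAULT_CHROMOSOME_ORDER: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)


class GenomeIOError(ValueError):
    """Raised for malformed genome/count/annotation inputs."""


# ---------------------------------------------------------------------------
# Gene positions
# ---------------------------------------------------------------------------


@dataclass
class GenePositionTable:
    """Genome ordering of genes.

    ``df`` holds columns ``gene_id, chromosome, start, stop, genome_rank``
    sorted by ``genome_rank`` (chromosome order, then start). Coordinates
    are 1-based inclusive.
    """

    df: pd.DataFrame
    chromosome_order: tuple[str, ...] = DEFAULT_CHROMOSOME_ORDER

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start", "stop", "genome_rank"}
        missing = required - set(self.df.columns)
        if missing:
            raise GenomeIOError(f"gene position table missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            dup = self.df.loc[self.df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise GenomeIOError(f"duplicate gene_id in position table: {dup!r}")
        if (self.df["stop"] < self.df["start"]).any():
            bad = self.df.loc[self.df["stop"] < self.df["start"]].iloc[0]
            raise GenomeIOError(f"stop < start for gene {bad['gene_id']!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    @property
    def n_genes(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list[str]:
        """Chromosomes present, in genome order."""
        return list(dict.fromkeys(self.df["chromosome"]))

    def subset(self, gene_ids: Iterable[str]) -> "GenePositionTable":
        """Restrict to ``gene_ids``, preserving genome order."""
        keep = set(gene_ids)
        sub = self.df[self.df["gene_id"].isin(keep)].reset_index(drop=True)
        return GenePositionTable(sub, self.chromosome_order)

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """Contiguous row slices per chromosome, in genome order."""
        out: list[tuple[str, slice]] = []
        chroms = self.df["chromosome"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out


def _chromosome_sort_key(order: Sequence[str]):
    rank = {c: i for i, c in enumerate(order)}

    def key(chrom: str) -> tuple[int, str]:
        return (rank.get(chrom, len(order)), chrom)

    return key


def read_gene_positions(
    path: str | os.PathLike,
    excluded_chromosomes: Iterable[str] = ("chrM",),
    chromosome_order: Sequence[str] = DEFAULT_CHROMOSOME_ORDER,
) -> GenePositionTable:
    """Read a headerless 4-column gene position TSV and rank the genome.

    Genes on ``excluded_chromosomes`` are dropped; the remainder is sorted
    by (chromosome order, start) and assigned ``genome_rank`` 0..n-1.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene_id", "chromosome", "start", "stop"],
        dtype={"gene_id": str, "chromosome": str},
    )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise GenomeIOError(f"duplicate gene_id in {path}: {dup!r}")
    bad = df.index[df["stop"] < df["start"]]
    if len(bad):
        raise GenomeIOError(
            f"stop < start at line {bad[0] + 1} of {path} "
            f"(gene {df.loc[bad[0], 'gene_id']!r})"
        )
    excluded = set(excluded_chromosomes)
    df = df[~df["chromosome"].isin(excluded)]
    key = _chromosome_sort_key(chromosome_order)
    df = df.assign(_ck=[key(c) for c in df["chromosome"]])
    df = df.sort_values(["_ck", "start", "gene_id"]).drop(columns="_ck")
    df = df.reset_index(drop=True)
    df["genome_rank"] = np.arange(len(df))
    return GenePositionTable(df, tuple(chromosome_order))


def write_gene_positions(table: GenePositionTable, path: str | os.PathLike) -> None:
    table.df[["gene_id", "chromosome", "start", "stop"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Spot-by-gene nonnegative integer UMI counts.

    ``counts`` is dense ``(n_spots, n_genes)`` int64; barcodes are
    section-qualified once sections are merged.
    """

    barcodes: list[str]
    gene_ids: list[str]
    counts: np.ndarray
    section_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.gene_ids)):
            raise GenomeIOError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.gene_ids)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise GenomeIOError("duplicate barcodes in count matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise GenomeIOError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise GenomeIOError("counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def spot_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def genes_detected(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=1)

    def select_spots(self, keep: np.ndarray | list[str]) -> "CountMatrix":
        """Subset spots by boolean mask or barcode list (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            idx = np.array([pos[b] for b in keep], dtype=int)
        barcodes = [self.barcodes[i] for i in idx]
        section_of = {b: self.section_of[b] for b in barcodes if b in self.section_of}
        return CountMatrix(barcodes, list(self.gene_ids), self.counts[idx], section_of)


def _load_mtx_dir(path: str | os.PathLike) -> CountMatrix:
    def _pick(*names: str) -> str:
        for n in names:
            p = os.path.join(path, n)
            if os.path.exists(p):
                return p
        raise GenomeIOError(f"none of {names} found in {path}")

    mat = scipy.io.mmread(_pick("matrix.mtx", "matrix.mtx.gz"))
    barcodes = pd.read_csv(
        _pick("barcodes.tsv", "barcodes.tsv.gz"), sep="\t", header=None
    )[0].astype(str).tolist()
    feat = pd.read_csv(_pick("features.tsv", "features.tsv.gz", "genes.tsv"), sep="\t", header=None)
    # 10x features.tsv: id, symbol, type; use the symbol column when present
    gene_ids = feat[1 if feat.shape[1] > 1 else 0].astype(str).tolist()
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise GenomeIOError(
            f"matrix dimensions {mat.shape} do not match "
            f"{len(gene_ids)} features x {len(barcodes)} barcodes"
        )
    if (mat.data < 0).any():
        raise GenomeIOError("negative count in MatrixMarket triplet")
    counts = np.asarray(mat.todense()).T  # genes-in-rows on disk -> spots x genes
    return CountMatrix(barcodes, gene_ids, counts)


def _load_dense_tsv(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.to_numpy().T
    if (counts < 0).any():
        raise GenomeIOError("negative count in dense TSV")
    return CountMatrix(
        [str(c) for c in df.columns], [str(g) for g in df.index], counts
    )


def _load_h5(path: str | os.PathLike) -> CountMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["matrix"]
        data = grp["data"][:]
        indices = grp["indices"][:]
        indptr = grp["indptr"][:]
        shape = tuple(grp["shape"][:])  # (n_genes, n_barcodes), CSC over barcodes
        barcodes = [b.decode() for b in grp["barcodes"][:]]
        feats = grp["features"]["name"][:]
        gene_ids = [g.decode() for g in feats]
    mat = scipy.sparse.csc_matrix((data, indices, indptr), shape=shape)
    if (mat.data < 0).any():
        raise GenomeIOError("negative count in HDF5 matrix")
    counts = np.asarray(mat.todense()).T
    return CountMatrix(barcodes, gene_ids, counts)


def load_count_matrix(path: str | os.PathLike, format: str = "auto") -> CountMatrix:
    """Load a spot-by-gene count matrix.

    ``format`` is one of ``mtx`` (MatrixMarket triplet directory), ``tsv``
    (dense, genes in rows), ``h5`` (10x filtered-matrix dialect) or
    ``auto`` to sniff from the path.
    """
    if format == "auto":
        if os.path.isdir(path):
            format = "mtx"
        elif str(path).endswith((".h5", ".hdf5")):
            format = "h5"
        else:
            format = "tsv"
    if format == "mtx":
        return _load_mtx_dir(path)
    if format == "tsv":
        return _load_dense_tsv(path)
    if format == "h5":
        return _load_h5(path)
    raise GenomeIOError(f"unknown count matrix format {format!r}")


def write_count_matrix(
    matrix: CountMatrix, path: str | os.PathLike, format: str = "mtx"
) -> None:
    """Write counts as a MatrixMarket triplet directory or dense TSV."""
    if format == "mtx":
        os.makedirs(path, exist_ok=True)
        sp = scipy.sparse.coo_matrix(matrix.counts.T)  # genes in rows on disk
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp, field="integer")
        pd.Series(matrix.barcodes).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False
        )
        feat = pd.DataFrame(
            {"id": matrix.gene_ids, "name": matrix.gene_ids, "type": "Gene Expression"}
        )
        feat.to_csv(os.path.join(path, "features.tsv"), sep="\t", header=False, index=False)
    elif format == "tsv":
        df = pd.DataFrame(
            matrix.counts.T, index=matrix.gene_ids, columns=matrix.barcodes
        )
        df.to_csv(path, sep="\t")
    else:
        raise GenomeIOError(f"unknown output format {format!r}")


def merge_sections(
    matrices_with_section_ids: Sequence[tuple[CountMatrix, str]],
) -> CountMatrix:
    """Concatenate per-section matrices into one section-qualified matrix.

    Barcodes become ``<section>_<barcode>``; the gene universe is the union
    (first-seen order) with zeros filled for genes absent from a section.
    """
    if not matrices_with_section_ids:
        raise GenomeIOError("no matrices to merge")
    sections = [s for _, s in matrices_with_section_ids]
    if len(set(sections)) != len(sections):
        raise GenomeIOError(f"colliding section labels: {sections}")

    gene_union: list[str] = []
    seen: set[str] = set()
    for m, _ in matrices_with_section_ids:
        for g in m.gene_ids:
            if g not in seen:
                seen.add(g)
                gene_union.append(g)
    gene_pos = {g: j for j, g in enumerate(gene_union)}

    barcodes: list[str] = []
    section_of: dict[str, str] = {}
    blocks = []
    for m, section in matrices_with_section_ids:
        block = np.zeros((m.n_spots, len(gene_union)), dtype=np.int64)
        cols = [gene_pos[g] for g in m.gene_ids]
        block[:, cols] = m.counts
        blocks.append(block)
        for b in m.barcodes:
            qb = f"{section}_{b}"
            barcodes.append(qb)
            section_of[qb] = section
    return CountMatrix(barcodes, gene_union, np.vstack(blocks), section_of)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCConfig:
    """Spot-level QC thresholds.

    Spots with total counts <= ``min_spot_counts`` or fewer than
    ``min_spot_genes`` detected genes are removed.
    """

    min_spot_counts: int = 500
    min_spot_genes: int = 100

    def __post_init__(self) -> None:
        if self.min_spot_counts < 0 or self.min_spot_genes < 0:
            raise GenomeIOError("QC thresholds must be >= 0")


def qc_filter_spots(counts: CountMatrix, qc_config: QCConfig = QCConfig()) -> CountMatrix:
    """Drop low-depth and low-complexity spots.

    A spot is removed when its total UMI count is <= ``min_spot_counts``
    (inclusive: a spot at exactly the threshold is removed) or it detects
    fewer than ``min_spot_genes`` genes.
    """
    totals = counts.spot_totals()
    ngenes = counts.genes_detected()
    keep = (totals > qc_config.min_spot_counts) & (ngenes >= qc_config.min_spot_genes)
    n_removed = int((~keep).sum())
    logger.info(
        "qc_filter_spots: removed %d of %d spots (min_counts>%d, min_genes>=%d)",
        n_removed, counts.n_spots, qc_config.min_spot_counts, qc_config.min_spot_genes,
    )
    if not keep.any():
        raise GenomeIOError(
            "all spots removed by QC; review min_spot_counts/min_spot_genes"
        )
    return counts.select_spots(keep)


# ---------------------------------------------------------------------------
# Annotations and spot positions
# ---------------------------------------------------------------------------


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Read a Loupe-dialect ``Barcode,Annotation`` CSV."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["Barcode", "Annotation"]:
        raise GenomeIOError(
            f"expected header 'Barcode,Annotation', got {list(df.columns)!r}"
        )
    df.columns = cols
    if df["Barcode"].duplicated().any():
        dup = df.loc[df["Barcode"].duplicated(), "Barcode"].iloc[0]
        raise GenomeIOError(f"duplicate barcode in annotations: {dup!r}")
    return df[["Barcode", "Annotation"]]


def annotation_of(
    annotations: pd.DataFrame, barcodes: Iterable[str], default: str = "exclude"
) -> dict[str, str]:
    """Label per barcode; barcodes absent from annotations map to ``default``."""
    table = dict(zip(annotations["Barcode"], annotations["Annotation"]))
    return {b: table.get(b, default) for b in barcodes}


def write_annotations(labels: Mapping[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"Barcode": list(labels.keys()), "Annotation": list(labels.values())}
    ).to_csv(path, index=False)


def read_spot_positions(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tissue-positions CSV dialect.

    Columns: barcode, in_tissue, array_row, array_col, pixel_row, pixel_col
    (headerless or headered variants both accepted).
    """
    names = ["barcode", "in_tissue", "array_row", "array_col", "pixel_row", "pixel_col"]
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = str(first.iloc[0, 0]).lower() in {"barcode", "barcodes"}
    df = pd.read_csv(path, header=0 if has_header else None)
    df.columns = names[: df.shape[1]]
    return df
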
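"""siCNV core: residual profiles and 6-state HMM segmentation.

The pipeline mirrors the classic expression-based CNV workflow: restrict
to genome-mapped genes, filter lowly expressed genes, depth-normalize and
log-transform, centre against a reference spot set, smooth along the
genome with a pyramidal window, denoise, and decode discrete copy states
per spot or per clone with an exact Viterbi pass.

Residuals live in log2-ratio-to-reference space; HMM state means are
log2 of the relative copy levels (state 3 = neutral = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from sicnv.genome_io import CountMatrix, GenePositionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InferenceConfig:
    gene_mean_cutoff: float = 0.1
    max_centered_value: float = 3.0
    smoothing_window_genes: int = 101
    denoise_sd_multiplier: float = 1.5
    hmm_state_levels: tuple[float, ...] = (0.01, 0.5, 1.0, 1.5, 2.0, 3.0)
    hmm_transition_prob: float = 1e-6
    excluded_chromosomes: frozenset[str] = frozenset({"chrM"})
    denoise_before_hmm: bool = False

    def __post_init__(self) -> None:
        if self.gene_mean_cutoff < 0:
            raise ValueError("gene_mean_cutoff must be >= 0")
        if self.smoothing_window_genes < 1 or self.smoothing_window_genes % 2 == 0:
            raise ValueError("smoothing_window_genes must be odd and >= 1")
        levels = self.hmm_state_levels
        if len(levels) != 6 or any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("hmm_state_levels must be 6 strictly increasing values")
        if levels[2] != 1:
            raise ValueError("third hmm_state_level must be 1 (copy-neutral)")


@dataclass
class LogExpressionMatrix:
    """Depth-normalized log2 expression, genes in genome order."""

    values: np.ndarray  # spots x genes
    barcodes: list[str]
    genes: GenePositionTable


@dataclass
class ResidualMatrix:
    """Smoothed, reference-centred log2-ratio profiles (the siCNV signal)."""

    values: np.ndarray  # spots x genes
    barcodes: list[str]
    genes: GenePositionTable
    reference_barcodes: list[str]
    reference_sd: float = float("nan")

    def row(self, barcode: str) -> np.ndarray:
        return self.values[self.barcodes.index(barcode)]

    def reference_rows(self) -> np.ndarray:
        idx = [self.barcodes.index(b) for b in self.reference_barcodes]
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.barcodes, columns=self.genes.gene_ids
        )


@dataclass
class HMMStateMatrix:
    """Discrete copy states in 1..6 (3 = neutral) per spot or per group."""

    states: np.ndarray  # rows x genes, int
    row_labels: list[str]
    genes: GenePositionTable
    mode: str  # "cells" (per spot) or "samples" (per group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states, index=self.row_labels, columns=self.genes.gene_ids
        )


# ---------------------------------------------------------------------------
# Preprocess
# ---------------------------------------------------------------------------


def preprocess(
    counts: CountMatrix,
    gene_positions: GenePositionTable,
    config: InferenceConfig = InferenceConfig(),
) -> LogExpressionMatrix:
    """Filter genes, normalize depth and log-transform.

    Genes are restricted to those in the position table (excluded
    chromosomes removed), genes with mean raw count below
    ``gene_mean_cutoff`` are dropped, spot totals are scaled to the median
    spot total, values become log2(1 + x), and columns are sorted into
    genome order.
    """
    genes = gene_positions.df
    genes = genes[~genes["chromosome"].isin(config.excluded_chromosomes)]
    mapped = set(genes["gene_id"]) & set(counts.gene_ids)
    n_unmapped = counts.n_genes - len(mapped)
    if n_unmapped:
        logger.warning("preprocess: dropping %d genes absent from position table",
                       n_unmapped)

    table = gene_positions.subset(mapped)
    col_of = {g: j for j, g in enumerate(counts.gene_ids)}
    cols = [col_of[g] for g in table.gene_ids]
    mat = counts.counts[:, cols].astype(float)

    gene_means = mat.mean(axis=0)
    keep = gene_means >= config.gene_mean_cutoff
    logger.info("preprocess: %d/%d genes pass mean-count cutoff %.3g",
                int(keep.sum()), len(keep), config.gene_mean_cutoff)
    mat = mat[:, keep]
    table = table.subset(np.array(table.gene_ids)[keep])

    for chrom, sl in table.chromosome_slices():
        if sl.stop - sl.start >= config.smoothing_window_genes:
            break
    else:
        raise ValueError(
            "fewer than smoothing_window_genes surviving genes on every chromosome; "
            "lower smoothing_window_genes or gene_mean_cutoff"
        )

    totals = mat.sum(axis=1)
    median_total = np.median(totals[totals > 0])
    scale = np.divide(median_total, totals, out=np.ones_like(totals),
                      where=totals > 0)
    mat = np.log2(1.0 + mat * scale[:, None])
    return LogExpressionMatrix(mat, list(counts.barcodes), table)


# ---------------------------------------------------------------------------
# Centre + smooth
# ---------------------------------------------------------------------------


def pyramidal_weights(window: int) -> np.ndarray:
    """Triangular weights rising linearly to the centre, summing to 1."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    w = np.concatenate([np.arange(1, half + 2), np.arange(half, 0, -1)]).astype(float)
    return w / w.sum()


def _smooth_by_chromosome(
    values: np.ndarray, genes: GenePositionTable, window: int
) -> np.ndarray:
    """Weighted moving average per chromosome, renormalized at the edges."""
    w = pyramidal_weights(window)
    out = np.empty_like(values)
    for chrom, sl in genes.chromosome_slices():
        block = values[:, sl]
        if block.shape[1] == 0:
            logger.warning("chromosome %s has zero genes; skipped", chrom)
            continue
        num = convolve1d(block, w, axis=1, mode="constant", cval=0.0)
        den = convolve1d(np.ones(block.shape[1]), w, mode="constant", cval=0.0)
        out[:, sl] = num / den
    return out


def center_and_smooth(
    log_matrix: LogExpressionMatrix,
    reference_barcodes: Sequence[str],
    config: InferenceConfig = InferenceConfig(),
) -> ResidualMatrix:
    """Centre against the reference and smooth along the genome.

    Steps: subtract the per-gene reference mean; clip to
    ±``max_centered_value``; pyramidal moving average within each
    chromosome; subtract each spot's median; subtract the per-gene
    reference mean again (so reference columns are exactly re-centred).
    """
    reference_barcodes = list(reference_barcodes)
    if not reference_barcodes:
        raise ValueError("reference_barcodes must be nonempty "
                         "(unsupervised mode: pass all barcodes)")
    missing = set(reference_barcodes) - set(log_matrix.barcodes)
    if missing:
        raise ValueError(f"reference barcodes not in matrix: {sorted(missing)[:5]}")

    ref_idx = [log_matrix.barcodes.index(b) for b in reference_barcodes]
    vals = log_matrix.values.copy()
    vals -= vals[ref_idx].mean(axis=0)
    np.clip(vals, -config.max_centered_value, config.max_centered_value, out=vals)
    vals = _smooth_by_chromosome(vals, log_matrix.genes, config.smoothing_window_genes)
    vals -= np.median(vals, axis=1, keepdims=True)
    vals -= vals[ref_idx].mean(axis=0)

    sd = float(vals[ref_idx].std())
    return ResidualMatrix(
        vals, list(log_matrix.barcodes), log_matrix.genes,
        reference_barcodes, reference_sd=sd,
    )


def denoise(
    residuals: ResidualMatrix, config: InferenceConfig = InferenceConfig()
) -> ResidualMatrix:
    """Zero out entries within ``denoise_sd_multiplier`` reference SDs of 0."""
    sigma = float(residuals.reference_rows().std())
    if sigma == 0:
        logger.warning("denoise: reference SD is 0; skipping")
        return replace_values(residuals, residuals.values.copy())
    threshold = config.denoise_sd_multiplier * sigma
    vals = residuals.values.copy()
    vals[np.abs(vals) <= threshold] = 0.0
    return replace_values(residuals, vals)


def replace_values(residuals: ResidualMatrix, values: np.ndarray) -> ResidualMatrix:
    return ResidualMatrix(
        values, list(residuals.barcodes), residuals.genes,
        list(residuals.reference_barcodes), residuals.reference_sd,
    )


# ---------------------------------------------------------------------------
# HMM decoding
# ---------------------------------------------------------------------------


def _viterbi_rows(
    obs: np.ndarray, means: np.ndarray, sigma: float, t: float
) -> np.ndarray:
    """Exact Viterbi for all rows at once; shared Gaussian emissions.

    Self-transition probability is 1 - 5t, cross-transition t.
    """
    n_rows, n_genes = obs.shape
    k = len(means)
    log_self = np.log1p(-(k - 1) * t)
    log_cross = np.log(t)
    # emission log-likelihood up to a shared constant
    ll = -0.5 * ((obs[:, :, None] - means[None, None, :]) / sigma) ** 2

    delta = ll[:, 0, :].copy()
    psi = np.zeros((n_rows, n_genes, k), dtype=np.int8)
    for g in range(1, n_genes):
        # score of arriving in state s from state r
        stay = delta + log_self
        best_prev = delta.max(axis=1, keepdims=True)
        jump = best_prev + log_cross
        take_stay = stay >= jump
        psi[:, g, :] = np.where(
            take_stay,
            np.arange(k)[None, :],
            delta.argmax(axis=1)[:, None],
        )
        delta = np.where(take_stay, stay, jump) + ll[:, g, :]
    states = np.empty((n_rows, n_genes), dtype=np.int8)
    states[:, -1] = delta.argmax(axis=1)
    for g in range(n_genes - 1, 0, -1):
        states[:, g - 1] = psi[np.arange(n_rows), g, states[:, g]]
    return states + 1  # 1-based states


def hmm_states(
    residuals: ResidualMatrix,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    config: InferenceConfig = InferenceConfig(),
) -> HMMStateMatrix:
    """Decode 6 copy states per gene by Viterbi, chromosome by chromosome.

    ``groups`` maps group label -> member barcodes; ``None`` decodes every
    spot on its own (mode "cells"). Each group's observation sequence is
    the unweighted mean residual over member spots. Emissions are Gaussian
    at log2 of each relative level (the lowest level floored at 0.01) with
    a shared SD estimated from the reference residuals.
    """
    if config.denoise_before_hmm:
        residuals = denoise(residuals, config)
    if groups is None:
        mode = "cells"
        labels = list(residuals.barcodes)
        obs = residuals.values
    else:
        mode = "samples"
        labels = list(groups)
        idx_of = {b: i for i, b in enumerate(residuals.barcodes)}
        rows = []
        for label in labels:
            members = list(groups[label])
            if not members:
                raise ValueError(f"group {label!r} has no spots")
            missing = [b for b in members if b not in idx_of]
            if missing:
                raise ValueError(f"group {label!r} has unknown barcodes: {missing[:5]}")
            rows.append(residuals.values[[idx_of[b] for b in members]].mean(axis=0))
        obs = np.vstack(rows)

    means = np.log2(np.maximum(config.hmm_state_levels, 0.01))
    sigma = residuals.reference_sd
    if not np.isfinite(sigma) or sigma <= 0:
        sigma = float(residuals.reference_rows().std())
    if sigma <= 0:
        sigma = 1e-3  # degenerate reference; nearest-mean decoding

    states = np.empty(obs.shape, dtype=np.int8)
    for _, sl in residuals.genes.chromosome_slices():
        states[:, sl] = _viterbi_rows(
            obs[:, sl], means, sigma, config.hmm_transition_prob
        )
    return HMMStateMatrix(states, labels, residuals.genes, mode)


def call_region_events(
    state_matrix: HMMStateMatrix,
    gene_positions: Optional[GenePositionTable] = None,
) -> pd.DataFrame:
    """Maximal same-state non-neutral runs as region events.

    Columns mirror the region-file dialect: group, chromosome, gene_start,
    gene_end, n_genes, state, direction.
    """
    genes = gene_positions or state_matrix.genes
    gene_ids = np.array(genes.gene_ids)
    records = []
    for r, label in enumerate(state_matrix.row_labels):
        row = state_matrix.states[r]
        for chrom, sl in genes.chromosome_slices():
            block = row[sl]
            start = 0
            n = sl.stop - sl.start
            for i in range(1, n + 1):
                if i == n or block[i] != block[start]:
                    state = int(block[start])
                    if state != 3:
                        records.append(
                            {
                                "group": label,
                                "chromosome": chrom,
                                "gene_start": gene_ids[sl.start + start],
                                "gene_end": gene_ids[sl.start + i - 1],
                                "rank_start": sl.start + start,
                                "rank_end": sl.start + i - 1,
                                "n_genes": i - start,
                                "state": state,
                                "direction": "loss" if state < 3 else "gain",
                            }
                        )
                    start = i
    return pd.DataFrame(
        records,
        columns=["group", "chromosome", "gene_start", "gene_end",
                 "rank_start", "rank_end", "n_genes", "state", "direction"],
    )


def run_inference(
    counts: CountMatrix,
    gene_positions: GenePositionTable,
    reference_barcodes: Optional[Sequence[str]] = None,
    config: InferenceConfig = InferenceConfig(),
    apply_denoise: bool = True,
) -> ResidualMatrix:
    """Convenience pipeline: preprocess -> centre/smooth -> (denoise)."""
    logm = preprocess(counts, gene_positions, config)
    refs = list(reference_barcodes) if reference_barcodes else list(logm.barcodes)
    refs = [b for b in refs if b in set(logm.barcodes)]
    residuals = center_and_smooth(logm, refs, config)
    if apply_denoise:
        residuals = denoise(residuals, config)
    return residuals
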
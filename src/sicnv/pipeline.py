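"""End-to-end synthetic benchmarks: simulate, infer, score against truth."""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional

import numpy as np

from sicnv.clones import assign_clones, clone_recovery_score, cluster_spots
from sicnv.genome_io import QCConfig, qc_filter_spots
from sicnv.inference import InferenceConfig, hmm_states, run_inference
from sicnv.simulator import (
    GroundTruth,
    SimulationConfig,
    SyntheticTissue,
    bin_cells_to_spots,
    ground_truth_categories,
    sample_expression,
    simulate_tissue,
    simulated_gene_positions,
)
from sicnv.summaries import clone_accuracy, states_to_categories

logger = logging.getLogger(__name__)

#: Inference settings matched to the desk-scale simulator (600 genes on one
#: chromosome; the genome-wide 101-gene window would blur 60-gene events).
SIMULATION_INFERENCE_CONFIG = InferenceConfig(smoothing_window_genes=31)

MIN_CLONE_SPOTS = 10  # clones below this are not scored (display-rule analog)


def synthesize(
    seed: int, sim_config: Optional[SimulationConfig] = None
) -> tuple[SyntheticTissue, "GroundTruth", object]:
    """Simulate, bin and sample a synthetic experiment at ``seed``."""
    config = sim_config or SimulationConfig()
    config = replace(config, seed=seed)
    tissue = bin_cells_to_spots(simulate_tissue(config))
    counts = sample_expression(tissue)
    truth = ground_truth_categories(tissue)
    return tissue, truth, counts


def diploid_clone_label(truth: GroundTruth) -> str:
    """Label of the all-diploid (benign-analog) clone."""
    diploid = np.flatnonzero((truth.clone_genotypes == 2).all(axis=1))
    if len(diploid) == 0:
        raise ValueError("no diploid clone in this tissue; cannot pick a reference")
    return f"clone_{diploid[0]:02d}"


def evaluate_synthetic(
    seed: int = 0,
    sim_config: Optional[SimulationConfig] = None,
    inference_config: InferenceConfig = SIMULATION_INFERENCE_CONFIG,
    min_clone_spots: int = MIN_CLONE_SPOTS,
) -> dict:
    """Clone recovery and per-clone category accuracy on simulated tissue.

    Diploid-clone spots serve as the benign reference; scoring covers the
    non-reference spots, restricted to true clones holding at least
    ``min_clone_spots`` spots. Clustering is cut at the true clone count;
    category accuracy decodes per-true-clone HMM states and compares the
    deletion/neutral/amplification calls with ground truth, as in the
    synthetic-evaluation scheme.
    """
    tissue, truth, counts = synthesize(seed, sim_config)
    counts = qc_filter_spots(counts, QCConfig(min_spot_counts=500, min_spot_genes=0))
    genes = simulated_gene_positions(tissue.config)

    benign = diploid_clone_label(truth)
    spot_clone = truth.spot_clone.loc[counts.barcodes]
    reference = spot_clone.index[spot_clone == benign].tolist()
    observed = spot_clone.index[spot_clone != benign].tolist()
    if not reference or not observed:
        raise ValueError("simulation produced no reference or no observed spots")

    residuals = run_inference(counts, genes, reference, inference_config,
                              apply_denoise=True)

    # clones big enough to score, mirroring the <10-spot display rule
    observed_clone = spot_clone.loc[observed]
    sizes = observed_clone.value_counts()
    eligible = sizes.index[sizes >= min_clone_spots].tolist()
    scored = observed_clone.index[observed_clone.isin(eligible)].tolist()
    if len(eligible) < 1 or len(scored) < 2:
        raise ValueError("no clone holds enough spots to score; reseed or "
                         "increase mutation pressure")

    # --- clone recovery at the true clone count
    idx = [residuals.barcodes.index(b) for b in scored]
    obs_residuals = residuals.values[idx]
    dend = cluster_spots(obs_residuals, barcodes=scored)
    assignment = assign_clones(dend, len(eligible))
    ari = clone_recovery_score(assignment, observed_clone.loc[scored].to_dict())

    # --- per-clone category accuracy via per-true-clone HMM decoding
    groups = {c: observed_clone.index[observed_clone == c].tolist()
              for c in eligible}
    states = hmm_states(residuals, groups, inference_config)
    categories = states_to_categories(states.states)
    truth_cat = truth.per_clone_category[states.genes.gene_ids]
    accuracies = {}
    for r, clone in enumerate(states.row_labels):
        accuracies[clone] = clone_accuracy(categories[r], truth_cat.loc[clone].to_numpy())

    return {
        "seed": seed,
        "n_spots": int(counts.n_spots),
        "n_reference_spots": len(reference),
        "n_scored_spots": len(scored),
        "n_clones_scored": len(eligible),
        "clone_recovery_score": float(ari),
        "per_clone_accuracy": {k: float(v) for k, v in accuracies.items()},
        "mean_clone_accuracy": float(np.mean(list(accuracies.values()))),
    }


def null_tissue_neutrality(
    seed: int = 0,
    sim_config: Optional[SimulationConfig] = None,
    inference_config: InferenceConfig = SIMULATION_INFERENCE_CONFIG,
) -> dict:
    """Fraction of neutral per-spot HMM states on mutation-free tissue.

    The benign-lymph-node analog: unsupervised inference (reference = all
    spots), denoising, then per-spot decoding should call state 3 almost
    everywhere.
    """
    config = sim_config or SimulationConfig()
    config = replace(config, seed=seed, p_mutation_at_division=0.0)
    tissue = bin_cells_to_spots(simulate_tissue(config))
    counts = sample_expression(tissue)
    counts = qc_filter_spots(counts, QCConfig(min_spot_counts=500, min_spot_genes=0))
    genes = simulated_gene_positions(config)

    residuals = run_inference(counts, genes, None, inference_config,
                              apply_denoise=True)
    states = hmm_states(residuals, None, inference_config)
    neutral_fraction = float((states.states == 3).mean())
    zero_fraction = float((residuals.values == 0).mean())
    return {
        "seed": seed,
        "n_spots": int(counts.n_spots),
        "neutral_state_fraction": neutral_fraction,
        "zero_residual_fraction": zero_fraction,
    }
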
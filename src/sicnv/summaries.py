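"""Organ-wide event maps, evaluation against ground truth, and clonal SNVs."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sicnv.inference import HMMStateMatrix

logger = logging.getLogger(__name__)

STATE_CATEGORY = {
    1: "deletion",
    2: "deletion",
    3: "neutral",
    4: "amplification",
    5: "amplification",
    6: "amplification",
}


def map_hmm_state_to_category(state: int) -> str:
    """1,2 -> deletion; 3 -> neutral; 4,5,6 -> amplification."""
    try:
        key = int(state)
        if key != state:
            raise ValueError
        return STATE_CATEGORY[key]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"HMM state must be an integer in 1..6, got {state!r}")


def states_to_categories(states: np.ndarray) -> np.ndarray:
    """Vectorized state -> category mapping."""
    states = np.asarray(states)
    if not np.isin(states, list(STATE_CATEGORY)).all():
        bad = states[~np.isin(states, list(STATE_CATEGORY))][0]
        raise ValueError(f"HMM state must be an integer in 1..6, got {bad!r}")
    lut = np.array([""] + [STATE_CATEGORY[s] for s in range(1, 7)], dtype=object)
    return lut[states]


def clone_accuracy(
    inferred_categories: Sequence[str], truth_categories: Sequence[str]
) -> float:
    """Fraction of genes whose category labels agree."""
    inferred = np.asarray(inferred_categories, dtype=object)
    truth = np.asarray(truth_categories, dtype=object)
    if inferred.shape != truth.shape:
        raise ValueError("category vectors differ in length")
    if inferred.size == 0:
        raise ValueError("empty gene set")
    return float((inferred == truth).mean())


# ---------------------------------------------------------------------------
# Organ-wide dual-threshold event map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GlobalThresholdConfig:
    """Retention thresholds for the organ-wide event map."""

    dataset_fraction: float = 0.35
    section_fraction: float = 0.45

    def __post_init__(self) -> None:
        for v in (self.dataset_fraction, self.section_fraction):
            if not 0 <= v <= 1:
                raise ValueError("threshold fractions must lie in [0, 1]")


def global_event_map(
    per_spot_states: HMMStateMatrix,
    section_of: Mapping[str, str],
    threshold_config: GlobalThresholdConfig = GlobalThresholdConfig(),
) -> pd.DataFrame:
    """Per-spot counts of retained gene-level events.

    A non-neutral state at gene g in a spot counts only when the fraction
    of all spots non-neutral at g is >= ``dataset_fraction`` AND the
    fraction within the spot's section is >= ``section_fraction`` (both
    inclusive). Returns columns (barcode, section, event_count).
    """
    if per_spot_states.mode != "cells":
        raise ValueError("global_event_map needs per-spot (mode 'cells') states")
    barcodes = per_spot_states.row_labels
    missing = [b for b in barcodes if b not in section_of]
    if missing:
        raise ValueError(f"unknown section for barcodes: {missing[:5]}")
    sections = np.array([section_of[b] for b in barcodes])

    nonneutral = per_spot_states.states != 3
    dataset_frac = nonneutral.mean(axis=0)
    dataset_ok = dataset_frac >= threshold_config.dataset_fraction

    counts = np.zeros(len(barcodes), dtype=int)
    for section in np.unique(sections):
        rows = sections == section
        section_frac = nonneutral[rows].mean(axis=0)
        retained = dataset_ok & (section_frac >= threshold_config.section_fraction)
        counts[rows] = (nonneutral[rows] & retained).sum(axis=1)
    return pd.DataFrame(
        {"barcode": barcodes, "section": sections, "event_count": counts}
    )


def threshold_sweep(
    per_spot_states: HMMStateMatrix,
    section_of: Mapping[str, str],
    fractions: Sequence[float] = tuple(np.arange(0.10, 0.91, 0.05)),
) -> pd.DataFrame:
    """Retained-event totals over a grid of (dataset, section) fractions."""
    records = []
    for df_ in fractions:
        for sf in fractions:
            cfg = GlobalThresholdConfig(round(float(df_), 4), round(float(sf), 4))
            m = global_event_map(per_spot_states, section_of, cfg)
            records.append(
                {
                    "dataset_fraction": cfg.dataset_fraction,
                    "section_fraction": cfg.section_fraction,
                    "total_events": int(m["event_count"].sum()),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Clonal SNV summaries
# ---------------------------------------------------------------------------

SNV_COLUMNS = ["barcode", "chrom", "pos", "ref_count", "alt_count"]


def read_snv_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-spot per-locus ref/alt count TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SNV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNV table missing columns: {sorted(missing)}")
    return validate_snv_counts(df)


def validate_snv_counts(df: pd.DataFrame) -> pd.DataFrame:
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("negative allele counts in SNV table")
    df = df.copy()
    df["locus"] = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
    if df.duplicated(["barcode", "locus"]).any():
        raise ValueError("duplicate (barcode, locus) rows in SNV table")
    return df


def _clone_of(snv_counts: pd.DataFrame, clone_labels: Mapping[str, str]) -> pd.DataFrame:
    df = snv_counts if "locus" in snv_counts.columns else validate_snv_counts(snv_counts)
    unassigned = ~df["barcode"].isin(clone_labels)
    if unassigned.any():
        logger.warning(
            "dropping %d SNV rows from barcodes without a clone", int(unassigned.sum())
        )
        df = df[~unassigned]
    df = df.copy()
    df["clone"] = df["barcode"].map(clone_labels)
    return df


def clonal_vaf(
    snv_counts: pd.DataFrame, clone_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Pooled per-(clone, locus) allele summaries.

    Reports pooled ref/alt counts, ``alt_fraction`` = alt/(ref+alt)
    (NaN when uncovered), and the raw ``ref_alt_ratio`` (inf when alt=0);
    both readings of "ratio of reference to alternative reads" are kept.
    """
    df = _clone_of(snv_counts, clone_labels)
    out = (
        df.groupby(["clone", "locus"], sort=True)[["ref_count", "alt_count"]]
        .sum()
        .reset_index()
    )
    total = out["ref_count"] + out["alt_count"]
    out["alt_fraction"] = np.where(total > 0, out["alt_count"] / total.where(total > 0, 1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ref_alt_ratio"] = np.where(
            out["alt_count"] > 0,
            out["ref_count"] / out["alt_count"].where(out["alt_count"] > 0, 1),
            np.where(out["ref_count"] > 0, np.inf, np.nan),
        )
    out["covered"] = total > 0
    return out


def spot_percentage(
    snv_counts: pd.DataFrame, clone_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage of each clone's spots with >= 1 read at each locus."""
    df = _clone_of(snv_counts, clone_labels)
    clone_sizes: dict[str, int] = {}
    for clone in set(clone_labels.values()):
        size = sum(1 for c in clone_labels.values() if c == clone)
        if size == 0:
            raise ValueError(f"clone {clone!r} has no spots")
        clone_sizes[clone] = size

    df = df[(df["ref_count"] + df["alt_count"]) > 0]
    covered = (
        df.groupby(["clone", "locus"])["barcode"].nunique().rename("n_covered_spots")
    )
    loci = sorted(
        (snv_counts if "locus" in snv_counts.columns else validate_snv_counts(snv_counts))["locus"].unique()
    )
    index = pd.MultiIndex.from_product(
        [sorted(clone_sizes), loci], names=["clone", "locus"]
    )
    out = covered.reindex(index, fill_value=0).reset_index()
    out["n_clone_spots"] = out["clone"].map(clone_sizes)
    out["spot_percentage"] = 100.0 * out["n_covered_spots"] / out["n_clone_spots"]
    return out
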
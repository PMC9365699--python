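"""Benign-reference selection and clone calling by hierarchical clustering."""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score

from sicnv.genome_io import CountMatrix, GenePositionTable
from sicnv.inference import InferenceConfig, ResidualMatrix, run_inference

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Binary merge tree over spot barcodes.

    Node ids follow scipy convention: 0..n-1 are leaves (in input order),
    n..2n-2 internal merge nodes in merge order. ``linkage_matrix`` is the
    scipy ``(n-1, 4)`` linkage array.
    """

    barcodes: list[str]
    linkage_matrix: np.ndarray
    _members: dict[int, list[int]] = field(default_factory=dict, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.barcodes)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def node_ids(self) -> list[int]:
        return list(range(2 * self.n_leaves - 1))

    def members(self, node_id: int) -> list[str]:
        """Leaf barcodes under a node, in leaf-index order."""
        return [self.barcodes[i] for i in self._member_indices(node_id)]

    def _member_indices(self, node_id: int) -> list[int]:
        n = self.n_leaves
        if node_id < n:
            return [node_id]
        if node_id in self._members:
            return self._members[node_id]
        left, right = self.linkage_matrix[node_id - n, :2].astype(int)
        out = sorted(self._member_indices(left) + self._member_indices(right))
        self._members[node_id] = out
        return out

    def merge_height(self, node_id: int) -> float:
        n = self.n_leaves
        return 0.0 if node_id < n else float(self.linkage_matrix[node_id - n, 2])

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` flat clusters; returns barcode -> cluster index."""
        flat = sch.cut_tree(self.linkage_matrix, n_clusters=k).ravel()
        return dict(zip(self.barcodes, flat.tolist()))

    def to_text(self) -> str:
        """Nested-parenthesis export with node ids."""

        def render(node_id: int) -> str:
            n = self.n_leaves
            if node_id < n:
                return self.barcodes[node_id]
            left, right = self.linkage_matrix[node_id - n, :2].astype(int)
            return f"({render(left)},{render(right)})#{node_id}"

        return render(self.root) + ";"


def cluster_spots(
    residuals: ResidualMatrix | np.ndarray,
    linkage: str = "ward",
    metric: str = "euclidean",
    barcodes: Optional[Sequence[str]] = None,
) -> Dendrogram:
    """Agglomerative clustering of genome-ordered residual rows.

    Deterministic given input order; scipy breaks distance ties by the
    lower cluster index, i.e. earlier barcodes merge first.
    """
    if isinstance(residuals, ResidualMatrix):
        values = residuals.values
        barcodes = list(residuals.barcodes)
    else:
        values = np.asarray(residuals)
        if barcodes is None:
            raise ValueError("barcodes required when passing a bare array")
        barcodes = list(barcodes)
    if len(barcodes) < 2:
        raise ValueError("need at least 2 spots to cluster")
    if np.isnan(values).any():
        raise ValueError("NaNs in residuals")
    Z = sch.linkage(values, method=linkage, metric=metric)
    return Dendrogram(barcodes, Z)


# ---------------------------------------------------------------------------
# Pure-benign reference selection
# ---------------------------------------------------------------------------


def select_pure_reference(
    benign_counts: CountMatrix,
    gene_positions: GenePositionTable,
    config: InferenceConfig = InferenceConfig(),
    burden_quantile: float = 0.5,
    min_fraction: float = 0.1,
    max_outlier_fraction: float = 0.1,
) -> list[str]:
    """Pick a low-CNV-burden subgroup of benign spots.

    Residuals are computed unsupervised (reference = all benign spots) and
    denoised; each spot's burden is its mean absolute residual. Nodes are
    scanned largest-first; the first node holding at least ``min_fraction``
    of the spots whose members' median burden is at most the
    ``burden_quantile`` quantile of all burdens — and at most
    ``max_outlier_fraction`` of whose members are burden outliers
    (boxplot rule: > Q3 + 1.5 IQR) — is returned.

    A CNV carried uniformly by every spot is invisible against a
    self-reference, so a homogeneous input returns all spots.
    """
    if not 0 < burden_quantile < 1:
        raise ValueError("burden_quantile must lie in (0, 1)")
    residuals = run_inference(benign_counts, gene_positions, None, config,
                              apply_denoise=True)
    burden = pd.Series(
        np.abs(residuals.values).mean(axis=1), index=residuals.barcodes
    )
    threshold = burden.quantile(burden_quantile)
    q1, q3 = burden.quantile([0.25, 0.75])
    outlier_cut = q3 + 1.5 * (q3 - q1)

    dend = cluster_spots(residuals)
    nodes = sorted(
        dend.node_ids(),
        key=lambda nid: -len(dend._member_indices(nid)),
    )
    min_size = max(1, int(np.ceil(min_fraction * dend.n_leaves)))
    for nid in nodes:
        members = dend.members(nid)
        if len(members) < min_size:
            break
        node_burden = burden.loc[members]
        if (node_burden.median() <= threshold
                and (node_burden > outlier_cut).mean() <= max_outlier_fraction):
            logger.info(
                "select_pure_reference: node %d with %d/%d spots "
                "(median burden %.4g <= %.4g)",
                nid, len(members), dend.n_leaves, node_burden.median(), threshold,
            )
            return members
    raise ValueError(
        "no dendrogram node satisfies the low-burden criterion; "
        "choose a reference node manually"
    )


# ---------------------------------------------------------------------------
# Clone assignment
# ---------------------------------------------------------------------------


def _clone_letters(n: int) -> list[str]:
    letters = list(string.ascii_uppercase)
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


@dataclass
class CloneAssignment:
    """Barcode -> clone letter, labels ordered by decreasing clone size."""

    labels: dict[str, str]
    min_display_spots: int = 10

    def clones(self) -> list[str]:
        return sorted(set(self.labels.values()), key=lambda c: (len(c), c))

    def members(self, clone: str) -> list[str]:
        return [b for b, c in self.labels.items() if c == clone]

    def sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for c in self.labels.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    @property
    def display_mask(self) -> dict[str, bool]:
        """Clones with fewer than ``min_display_spots`` spots are hidden."""
        return {c: s >= self.min_display_spots for c, s in self.sizes().items()}

    def groups(self) -> dict[str, list[str]]:
        return {c: self.members(c) for c in self.clones()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Barcode": list(self.labels), "Clone": list(self.labels.values())}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def assign_clones(
    dendrogram: Dendrogram,
    selection: int | Sequence[int],
    min_display_spots: int = 10,
) -> CloneAssignment:
    """Turn selected dendrogram nodes (or a k-cut) into clone labels.

    ``selection`` is either a target clone count ``k`` (tree cut) or an
    explicit list of node ids whose members become one clone each. Labels
    A, B, C, ... are assigned in decreasing clone size (ties by first
    barcode).
    """
    if isinstance(selection, (int, np.integer)):
        cut = dendrogram.cut(int(selection))
        groups: list[list[str]] = [[] for _ in range(int(selection))]
        for b, c in cut.items():
            groups[c].append(b)
        groups = [g for g in groups if g]
    else:
        groups = []
        seen: dict[str, int] = {}
        for nid in selection:
            members = dendrogram.members(int(nid))
            overlap = [b for b in members if b in seen]
            if overlap:
                raise ValueError(
                    f"overlapping node selection; shared barcodes: {overlap[:5]}"
                )
            for b in members:
                seen[b] = nid
            groups.append(members)

    groups.sort(key=lambda g: (-len(g), g[0]))
    letters = _clone_letters(len(groups))
    labels = {b: letters[i] for i, g in enumerate(groups) for b in g}
    return CloneAssignment(labels, min_display_spots)


def clone_recovery_score(
    assignment: CloneAssignment | Mapping[str, str],
    ground_truth_labels: Mapping[str, str],
) -> float:
    """Chance-adjusted partition agreement (adjusted Rand index) in [-1, 1]."""
    labels = assignment.labels if isinstance(assignment, CloneAssignment) else assignment
    common = sorted(set(labels) & set(ground_truth_labels))
    if not common:
        raise ValueError("assignment and ground truth share no barcodes")
    if set(labels) != set(ground_truth_labels):
        logger.warning(
            "clone_recovery_score: restricting to %d shared barcodes", len(common)
        )
    a = [labels[b] for b in common]
    b = [ground_truth_labels[k] for k in common]
    return float(adjusted_rand_score(a, b))
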
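"""Clone phylogenies from CNV event sets.

Observed clones are related through shared events under a no-reversal
assumption: clones sharing events inherit them from a common ancestor, so
nested event sets define ancestry. Branch lengths and clone diameters
follow fixed pixel formulas; a maximum-parsimony tree over gene-level
states provides an independent topology check.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from sicnv.inference import HMMStateMatrix, call_region_events

logger = logging.getLogger(__name__)

BRANCH_SCALE_PX = 100.0
BRANCH_OFFSET_PX = 300.0   # keeps single-event branches visible
DIAMETER_SCALE_PX = 10.0


class Event(NamedTuple):
    """One copy-number event: (chromosome, arm-or-span, direction, index)."""

    chromosome: str
    span: str
    direction: str  # "gain" | "loss"
    index: int = 0


def branch_length(parent_set: Iterable, child_set: Iterable) -> float:
    """Edge length in pixels: 100 * log2(|Z_child| - |Z_parent|) + 300."""
    parent_set, child_set = set(parent_set), set(child_set)
    if not parent_set <= child_set:
        raise ValueError("parent event set must be a subset of the child's")
    diff = len(child_set) - len(parent_set)
    if diff < 1:
        raise ValueError("degenerate edge: child adds no events over parent")
    return BRANCH_SCALE_PX * math.log2(diff) + BRANCH_OFFSET_PX


def clone_diameter(n_spots: int) -> float:
    """Clone circle diameter in pixels: 10 * log2(n_spots)."""
    if n_spots < 1:
        raise ValueError("clone must contain at least one spot")
    d = DIAMETER_SCALE_PX * math.log2(n_spots)
    if n_spots == 1:
        logger.warning("clone_diameter: single-spot clone renders at 0 px")
    return d


# ---------------------------------------------------------------------------
# Clone tree construction
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str
    events: frozenset
    is_ancestor: bool              # True for inferred, unobserved ancestors
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)
    branch_length_px: Optional[float] = None  # edge to parent
    diameter_px: Optional[float] = None
    uncertain: bool = False        # edge to parent flagged uncertain


@dataclass
class CloneTree:
    nodes: dict[str, TreeNode]
    root: str

    def node(self, name: str) -> TreeNode:
        return self.nodes[name]

    def edges(self) -> list[tuple[str, str]]:
        return [(n.parent, n.name) for n in self.nodes.values() if n.parent]

    def validate(self) -> None:
        """Assert the no-reversal invariant Z_parent <= Z_child on every edge."""
        for parent, child in self.edges():
            if not self.nodes[parent].events <= self.nodes[child].events:
                raise AssertionError(
                    f"no-reversal violated on edge {parent} -> {child}"
                )

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        def render(name: str) -> str:
            node = self.nodes[name]
            bl = "" if node.branch_length_px is None else f":{node.branch_length_px:.9f}"
            if not node.children:
                return f"{name}{bl}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){name}{bl}"

        return render(self.root) + ";"

    def to_json(self) -> str:
        payload = {
            "root": self.root,
            "nodes": {
                name: {
                    "events": sorted([list(e) for e in node.events]),
                    "is_ancestor": node.is_ancestor,
                    "parent": node.parent,
                    "branch_length_px": node.branch_length_px,
                    "diameter_px": node.diameter_px,
                    "uncertain_edge": node.uncertain,
                }
                for name, node in self.nodes.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_newick(cls, newick: str, sidecar_json: Optional[str] = None) -> "CloneTree":
        """Rebuild topology and branch lengths (events from the sidecar)."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=False)
        meta = json.loads(sidecar_json)["nodes"] if sidecar_json else {}
        nodes: dict[str, TreeNode] = {}
        root_name = None

        def name_of(nd) -> str:
            return nd.taxon.label if nd.taxon else (nd.label or "")

        for nd in tree.preorder_node_iter():
            name = name_of(nd)
            info = meta.get(name, {})
            events = frozenset(Event(*e) for e in info.get("events", []))
            node = TreeNode(
                name=name,
                events=events,
                is_ancestor=info.get("is_ancestor", nd.is_internal()),
                parent=name_of(nd.parent_node) if nd.parent_node else None,
                branch_length_px=(
                    float(nd.edge.length) if nd.edge.length is not None else None
                ),
                diameter_px=info.get("diameter_px"),
                uncertain=info.get("uncertain_edge", False),
            )
            if nd.parent_node is None:
                root_name = name
            else:
                nodes[node.parent].children.append(name)
            nodes[name] = node
        return cls(nodes, root_name)


def _event_sort_key(events: Iterable) -> tuple:
    return tuple(sorted(tuple(e) for e in events))


def build_clone_tree(
    event_sets: Mapping[str, Iterable],
    spot_positions: Optional[Mapping[str, np.ndarray]] = None,
    proximity_threshold: float = 8.0,
    clone_sizes: Optional[Mapping[str, int]] = None,
) -> CloneTree:
    """Group clones under ancestors bearing their shared events.

    Recursive maximal-shared-subset grouping: starting from an empty root,
    the clones sharing the largest common event intersection are grouped
    under an ancestor carrying that intersection; an observed clone whose
    event set equals the intersection becomes that ancestor itself. Ties
    break on lexicographic event order. When ``spot_positions`` (clone ->
    (n, 2) array) is given, an edge to an unobserved ancestor whose
    subtree is not spatially proximate to its siblings (min inter-clone
    spot distance > ``proximity_threshold``) is flagged uncertain.
    """
    sets = {name: frozenset(ev) for name, ev in event_sets.items()}
    if not sets:
        raise ValueError("no clones given")
    by_content: dict[frozenset, str] = {}
    for name, ev in sets.items():
        if ev in by_content:
            raise ValueError(
                f"duplicate event sets: {by_content[ev]!r} and {name!r}; "
                "deduplicate clones first"
            )
        by_content[ev] = name

    nodes: dict[str, TreeNode] = {}
    counter = {"anc": 0}

    def new_ancestor(events: frozenset) -> str:
        counter["anc"] += 1
        name = f"anc_{counter['anc']}"
        nodes[name] = TreeNode(name, events, is_ancestor=True)
        return name

    def attach(parent: str, child: str) -> None:
        nodes[child].parent = parent
        nodes[parent].children.append(child)
        nodes[child].branch_length_px = branch_length(
            nodes[parent].events, nodes[child].events
        )

    # root: the empty event set (an observed all-benign clone if present)
    if frozenset() in by_content:
        root = by_content[frozenset()]
        nodes[root] = TreeNode(root, frozenset(), is_ancestor=False)
    else:
        root = new_ancestor(frozenset())

    def build(parent: str, clones: dict[str, frozenset]) -> None:
        remaining = dict(clones)
        parent_events = nodes[parent].events
        while remaining:
            names = sorted(remaining)
            best: Optional[frozenset] = None
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    inter = remaining[a] & remaining[b]
                    if len(inter) <= len(parent_events):
                        continue
                    if (
                        best is None
                        or len(inter) > len(best)
                        or (len(inter) == len(best)
                            and _event_sort_key(inter) < _event_sort_key(best))
                    ):
                        best = inter
            if best is None:
                # nothing shared beyond the parent: attach all directly
                for name in names:
                    nodes[name] = TreeNode(name, remaining[name], is_ancestor=False)
                    attach(parent, name)
                return
            group = {n: ev for n, ev in remaining.items() if best <= ev}
            for n in group:
                del remaining[n]
            if best in {ev for ev in group.values()}:
                anc = next(n for n, ev in group.items() if ev == best)
                nodes[anc] = TreeNode(anc, best, is_ancestor=False)
                del group[anc]
            else:
                anc = new_ancestor(best)
            attach(parent, anc)
            build(anc, group)

    build(root, {n: ev for n, ev in sets.items() if n != root})

    tree = CloneTree(nodes, root)
    tree.validate()

    if clone_sizes:
        for name, node in nodes.items():
            if not node.is_ancestor and name in clone_sizes:
                node.diameter_px = clone_diameter(clone_sizes[name])

    if spot_positions is not None:
        _flag_uncertain_edges(tree, spot_positions, proximity_threshold)
    return tree


def _subtree_leaf_positions(
    tree: CloneTree, name: str, spot_positions: Mapping[str, np.ndarray]
) -> np.ndarray:
    node = tree.nodes[name]
    chunks = []
    if not node.is_ancestor and name in spot_positions:
        chunks.append(np.asarray(spot_positions[name], dtype=float))
    for child in node.children:
        pos = _subtree_leaf_positions(tree, child, spot_positions)
        if len(pos):
            chunks.append(pos)
    return np.vstack(chunks) if chunks else np.empty((0, 2))


def _flag_uncertain_edges(
    tree: CloneTree,
    spot_positions: Mapping[str, np.ndarray],
    threshold: float,
) -> None:
    from scipy.spatial.distance import cdist

    for name, node in tree.nodes.items():
        if len(node.children) < 2:
            continue
        positions = {c: _subtree_leaf_positions(tree, c, spot_positions)
                     for c in node.children}
        for child in node.children:
            child_node = tree.nodes[child]
            if not (child_node.is_ancestor and node.is_ancestor):
                continue
            mine = positions[child]
            others = [positions[s] for s in node.children if s != child]
            others = [p for p in others if len(p)]
            if not len(mine) or not others:
                continue
            min_dist = min(cdist(mine, p).min() for p in others)
            if min_dist > threshold:
                child_node.uncertain = True


# ---------------------------------------------------------------------------
# Consensus events from HMM states
# ---------------------------------------------------------------------------


def consensus_events_from_states(
    state_matrix: HMMStateMatrix,
    min_genes_per_event: int = 20,
    min_reciprocal_overlap: float = 0.5,
) -> dict[str, frozenset]:
    """Per-clone event sets from per-clone HMM region calls.

    Regions shorter than ``min_genes_per_event`` genes are dropped; region
    calls from different clones unify into one event identity when they
    share chromosome and direction and overlap reciprocally by at least
    ``min_reciprocal_overlap`` of each span.
    """
    regions = call_region_events(state_matrix)
    regions = regions[regions["n_genes"] >= min_genes_per_event].reset_index(drop=True)
    if regions.empty:
        return {label: frozenset() for label in state_matrix.row_labels}

    parent = list(range(len(regions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for (_, _), group in regions.groupby(["chromosome", "direction"]):
        idx = group.index.to_numpy()
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                a, b = regions.loc[i], regions.loc[j]
                inter = (
                    min(a["rank_end"], b["rank_end"])
                    - max(a["rank_start"], b["rank_start"]) + 1
                )
                if inter <= 0:
                    continue
                if (inter / a["n_genes"] >= min_reciprocal_overlap
                        and inter / b["n_genes"] >= min_reciprocal_overlap):
                    union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(regions)):
        clusters.setdefault(find(i), []).append(i)

    # event identity: representative span, indexed within (chromosome, direction)
    reps = []
    for members in clusters.values():
        sub = regions.loc[members]
        reps.append(
            {
                "members": members,
                "chromosome": sub["chromosome"].iloc[0],
                "direction": sub["direction"].iloc[0],
                "rank_start": int(sub["rank_start"].min()),
                "span": f"{sub['gene_start'].iloc[0]}-{sub['gene_end'].iloc[0]}",
            }
        )
    reps.sort(key=lambda r: (r["chromosome"], r["direction"], r["rank_start"]))
    index_counter: dict[tuple[str, str], int] = {}
    event_of_region: dict[int, Event] = {}
    for rep in reps:
        key = (rep["chromosome"], rep["direction"])
        index_counter[key] = index_counter.get(key, 0) + 1
        event = Event(rep["chromosome"], rep["span"], rep["direction"],
                      index_counter[key])
        for i in rep["members"]:
            event_of_region[i] = event

    out: dict[str, set] = {label: set() for label in state_matrix.row_labels}
    for i, row in regions.iterrows():
        out[row["group"]].add(event_of_region[i])
    return {label: frozenset(ev) for label, ev in out.items()}


def event_table(event_sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Flat TSV-ready table (clone, chromosome, span, direction, index)."""
    rows = [
        {"clone": clone, "chromosome": e.chromosome, "span": e.span,
         "direction": e.direction, "index": e.index}
        for clone, events in sorted(event_sets.items())
        for e in sorted(events)
    ]
    return pd.DataFrame(rows, columns=["clone", "chromosome", "span",
                                       "direction", "index"])


# ---------------------------------------------------------------------------
# Maximum parsimony
# ---------------------------------------------------------------------------

EXHAUSTIVE_MAX_CLONES = 8


@dataclass
class ParsimonyResult:
    """Unrooted topology (nested tuples of clone labels) and Fitch score."""

    tree: object  # nested tuple; a flat tuple of all labels for a star tree
    score: int
    method: str  # "exhaustive" | "nni" | "star"

    def to_newick(self) -> str:
        def render(t) -> str:
            if isinstance(t, tuple):
                return "(" + ",".join(render(x) for x in t) + ")"
            return str(t)

        return render(self.tree) + ";"


def _insertions(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def _all_rooted_trees(leaves: Sequence):
    """All rooted binary shapes over ``leaves`` ((2m-3)!! of them)."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for base in trees for t in _insertions(base, leaf)]
    return trees


def _fitch_sets(tree, chars: Mapping) -> tuple[frozenset, int]:
    if not isinstance(tree, tuple):
        return frozenset((chars[tree],)), 0
    (s1, c1), (s2, c2) = (_fitch_sets(t, chars) for t in tree)
    inter = s1 & s2
    if inter:
        return inter, c1 + c2
    return s1 | s2, c1 + c2 + 1


def fitch_score(tree, char_matrix: pd.DataFrame) -> int:
    """Total Fitch parsimony changes over all characters (columns)."""
    total = 0
    for col in char_matrix.columns:
        chars = char_matrix[col].to_dict()
        total += _fitch_sets(tree, chars)[1]
    return total


def _nni_neighbors(tree):
    if not isinstance(tree, tuple):
        return
    left, right = tree
    if isinstance(left, tuple):
        a, b = left
        yield ((a, right), b)
        yield ((b, right), a)
        for t in _nni_neighbors(left):
            yield (t, right)
    if isinstance(right, tuple):
        a, b = right
        yield ((left, a), b)
        yield ((left, b), a)
        for t in _nni_neighbors(right):
            yield (left, t)


def _nj_topology(labels: list, dist: np.ndarray):
    """Neighbor joining; returns a nested-tuple topology over ``labels``."""
    nodes: list = list(labels)
    d = dist.astype(float).copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        new_node = (nodes[i], nodes[j])
        dk = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [new_node]
        d = d_new
    a, b, c = nodes
    return ((a, b), c)


def parsimony_tree(gene_level_state_matrix: pd.DataFrame) -> ParsimonyResult:
    """Maximum-parsimony topology over clones from multistate gene characters.

    Rows are clones, columns genes, entries HMM states 1..6; missing
    entries are imputed to the diploid state 3. With at most 8 clones
    every unrooted topology is scored exhaustively; beyond that a
    neighbor-joining start is refined by nearest-neighbor-interchange
    hill climbing.
    """
    mat = gene_level_state_matrix.copy()
    if mat.shape[0] < 3:
        raise ValueError("parsimony_tree needs at least 3 clones")
    mat = mat.fillna(3).astype(int)
    if not mat.isin(range(1, 7)).all().all():
        raise ValueError("states must lie in 1..6")

    labels = list(mat.index)
    if (mat.nunique(axis=0) == 1).all():
        logger.warning("parsimony_tree: all clones identical; returning star tree")
        return ParsimonyResult(tuple(labels), 0, "star")

    # keep only variable characters; constant columns never add changes
    variable = mat.loc[:, mat.nunique(axis=0) > 1]

    if len(labels) <= EXHAUSTIVE_MAX_CLONES:
        best_tree, best_score = None, None
        for shape in _all_rooted_trees(labels[1:]):
            tree = (labels[0], shape)
            score = fitch_score(tree, variable)
            if best_score is None or score < best_score:
                best_tree, best_score = tree, score
        return ParsimonyResult(best_tree, int(best_score), "exhaustive")

    # heuristic search
    idx = {lab: i for i, lab in enumerate(labels)}
    arr = variable.to_numpy()
    dist = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[i, j] = dist[j, i] = (arr[i] != arr[j]).sum()
    current = _nj_topology(labels, dist)
    current_score = fitch_score(current, variable)
    for _ in range(200):
        best_neighbor, best_score = None, current_score
        for neighbor in _nni_neighbors(current):
            s = fitch_score(neighbor, variable)
            if s < best_score:
                best_neighbor, best_score = neighbor, s
        if best_neighbor is None:
            break
        current, current_score = best_neighbor, best_score
    return ParsimonyResult(current, int(current_score), "nni")
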
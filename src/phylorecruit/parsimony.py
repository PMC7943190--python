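"""Unit-cost parsimony ancestral-state reconstruction for binary characters.

The reconstruction is a Sankoff-style dynamic program over the rooted tree
(polytomies handled natively, "?" tip states free to take either state), run
in two passes:

* an *inside* (postorder) pass computing, for every node v and state s, the
  minimal number of changes within v's subtree given v = s;
* an *outside* (preorder) pass computing the minimal number of changes in the
  rest of the tree given v = s, with v's own subtree excluded.

Their sum is the minimal whole-tree cost with v pinned to s, from which the
per-node MPR state sets fall out directly: a state is in a node's MPR set
exactly when pinning it there still achieves the global parsimony score.
Pinning both endpoints of an edge the same way yields the set of
parent/child state pairs realized by at least one most-parsimonious
reconstruction, which is what the ambiguous / most-parsimonious /
unambiguous change classification needs. Ambiguity is reported, never
resolved: no ACCTRAN/DELTRAN is applied.

All quantities are computed for every gene at once (arrays of shape
``(n_genes, 2)`` per node), which keeps genome-scale matrices (tens of
thousands of characters on a few dozen taxa) fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, CharacterMatrix, Phylogeny

__all__ = [
    "MPRProfile",
    "EdgeEvent",
    "RecruitmentResult",
    "parsimony_score",
    "mpr_profile",
    "edge_events",
    "classify_recruitment",
    "branch_change_counts",
]

_INF = np.float64(1e15)

GAIN = (0, 1)
LOSS = (1, 0)

CLASSIFICATIONS = (
    "unambiguous_gain",
    "most_parsimonious_gain",
    "unambiguous_loss",
    "most_parsimonious_loss",
    "no_change",
    "uninformative",
)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class MPRProfile:
    """Per-node constrained costs and MPR state sets for one character."""

    character_id: str
    score: int
    node_cost: dict[str, tuple[int, int]]  # label -> (cost | state 0, cost | state 1)
    mpr_set: dict[str, frozenset[int]]  # label -> subset of {0, 1}


@dataclass
class EdgeEvent:
    """Change classification for one edge under one character.

    ``pairs`` is the set of (parent state, child state) assignments realized
    by at least one most-parsimonious reconstruction. A gain (0 -> 1) or loss
    (1 -> 0) is *possible* when its pair appears in ``pairs`` and
    *unambiguous* when it is the only pair.
    """

    edge: tuple[str, str]
    pairs: frozenset[tuple[int, int]]
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.category = _categorize(self.pairs)

    @property
    def gain_possible(self) -> bool:
        return GAIN in self.pairs

    @property
    def loss_possible(self) -> bool:
        return LOSS in self.pairs

    @property
    def gain_unambiguous(self) -> bool:
        return self.pairs == {GAIN}

    @property
    def loss_unambiguous(self) -> bool:
        return self.pairs == {LOSS}


def _categorize(pairs: frozenset[tuple[int, int]]) -> str:
    if not pairs:
        raise ValueError("edge with empty joint-assignment set")
    if pairs == {GAIN}:
        return "unambiguous_gain"
    if pairs == {LOSS}:
        return "unambiguous_loss"
    # gains take precedence if both a gain and a loss are possible
    if GAIN in pairs:
        return "possible_gain"
    if LOSS in pairs:
        return "possible_loss"
    return "unambiguous_none" if len(pairs) == 1 else "possible_none"


@dataclass
class RecruitmentResult:
    """Per-gene focal-branch classifications with summary counts.

    ``most_parsimonious_gains`` reports the union most-parsimonious count
    (unambiguous gains are a subset of most-parsimonious gains), and
    symmetrically for losses.
    """

    focal_edge: tuple[str, str]
    classifications: pd.Series  # gene -> one of CLASSIFICATIONS

    @property
    def counts(self) -> dict[str, int]:
        vc = self.classifications.value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSIFICATIONS}

    @property
    def unambiguous_gains(self) -> int:
        return self.counts["unambiguous_gain"]

    @property
    def most_parsimonious_gains(self) -> int:
        c = self.counts
        return c["unambiguous_gain"] + c["most_parsimonious_gain"]

    @property
    def unambiguous_losses(self) -> int:
        return self.counts["unambiguous_loss"]

    @property
    def most_parsimonious_losses(self) -> int:
        c = self.counts
        return c["unambiguous_loss"] + c["most_parsimonious_loss"]

    def genes(self, classification: str) -> list[str]:
        if classification not in CLASSIFICATIONS:
            raise KeyError(f"unknown classification {classification!r}")
        return list(self.classifications.index[self.classifications == classification])


# ---------------------------------------------------------------------------
# The dynamic program
# ---------------------------------------------------------------------------


class _DP:
    """Inside-outside unit-cost parsimony over all genes simultaneously."""

    def __init__(self, tree: Phylogeny, codes: np.ndarray):
        # codes: (n_genes, n_leaves) aligned to tree.leaf_labels order
        n_genes = codes.shape[0]
        n_nodes = len(tree.postorder)
        self.tree = tree
        self.inside = [None] * n_nodes  # (G, 2) cost within subtree given state
        self.msg = [None] * n_nodes  # child's message to its parent, per parent state
        leaf_pos = {lab: j for j, lab in enumerate(tree.leaf_labels)}

        for i in range(n_nodes):  # postorder
            if tree.is_leaf[i]:
                c = codes[:, leaf_pos[tree.labels[i]]]
                ins = np.full((n_genes, 2), _INF)
                ins[c != 1, 0] = 0.0  # state 0 observed, or missing
                ins[c != 0, 1] = 0.0
                self.inside[i] = ins
            else:
                ins = np.zeros((n_genes, 2))
                for ch in tree.children[i]:
                    ins += self.msg[ch]
                self.inside[i] = ins
            # min over this node's state t of inside[t] + [s != t], per parent state s
            m = np.empty_like(self.inside[i])
            m[:, 0] = np.minimum(self.inside[i][:, 0], self.inside[i][:, 1] + 1)
            m[:, 1] = np.minimum(self.inside[i][:, 1], self.inside[i][:, 0] + 1)
            self.msg[i] = m

        root = tree.root_index
        self.score = self.inside[root].min(axis=1)
        self.outside = [None] * n_nodes  # cost outside subtree given state
        self.excl = [None] * n_nodes  # parent-side cost excluding this child's subtree
        self.outside[root] = np.zeros((n_genes, 2))
        for i in reversed(range(n_nodes)):  # preorder
            for ch in tree.children[i]:
                excl = self.outside[i] + self.inside[i] - self.msg[ch]
                self.excl[ch] = excl
                out = np.empty_like(excl)
                out[:, 0] = np.minimum(excl[:, 0], excl[:, 1] + 1)
                out[:, 1] = np.minimum(excl[:, 1], excl[:, 0] + 1)
                self.outside[ch] = out

    def node_cost(self, i: int) -> np.ndarray:
        """(G, 2): whole-tree minimal cost with node i pinned per state."""
        return self.inside[i] + self.outside[i]

    def mpr(self, i: int) -> np.ndarray:
        """(G, 2) bool: states achieving the global score at node i."""
        return self.node_cost(i) <= self.score[:, None] + 0.5

    def edge_pairs(self, child: int) -> np.ndarray:
        """(G, 2, 2) bool: possible (parent state, child state) joint assignments."""
        excl = self.excl[child]  # (G, 2) indexed by parent state
        ins = self.inside[child]
        sub = np.array([[0.0, 1.0], [1.0, 0.0]])
        joint = excl[:, :, None] + sub[None, :, :] + ins[:, None, :]
        return joint <= self.score[:, None, None] + 0.5


def _codes_for_tree(tree: Phylogeny, matrix: CharacterMatrix) -> np.ndarray:
    missing = [t for t in tree.leaf_labels if t not in matrix.taxa]
    if missing:
        raise KeyError(f"tree leaves without character states: {missing}")
    extra = sorted(set(matrix.taxa) - set(tree.leaf_labels))
    if extra:
        raise KeyError(f"character matrix taxa absent from tree: {extra}")
    order = [matrix.taxa.index(t) for t in tree.leaf_labels]
    return matrix.codes[:, order]


def _character_to_codes(tree: Phylogeny, character: Mapping[str, object]) -> np.ndarray:
    lookup = {"0": 0, "1": 1, "?": MISSING, 0: 0, 1: 1}
    row = np.empty((1, tree.n_leaves), dtype=np.int8)
    for j, leaf in enumerate(tree.leaf_labels):
        if leaf not in character:
            raise KeyError(f"leaf {leaf!r} has no state entry")
        state = character[leaf]
        if state not in lookup:
            raise ValueError(f"invalid state {state!r} for leaf {leaf!r}")
        row[0, j] = lookup[state]
    return row


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def parsimony_score(tree: Phylogeny, character: Mapping[str, object]) -> int:
    """Minimum number of 0 <-> 1 changes explaining one character's tip states.

    ``character`` maps every leaf label to a state in {0, 1, "?"}; "?" leaves
    may take either state at no cost.
    """
    dp = _DP(tree, _character_to_codes(tree, character))
    return int(dp.score[0])


def mpr_profile(
    tree: Phylogeny, character: Mapping[str, object], character_id: str = "char"
) -> MPRProfile:
    """Constrained per-node costs and MPR state sets for one character."""
    dp = _DP(tree, _character_to_codes(tree, character))
    node_cost: dict[str, tuple[int, int]] = {}
    mpr_set: dict[str, frozenset[int]] = {}
    for i, label in enumerate(tree.labels):
        costs = dp.node_cost(i)[0]
        node_cost[label] = tuple(int(c) if c < _INF / 2 else -1 for c in costs)
        mpr_set[label] = frozenset(int(s) for s in (0, 1) if dp.mpr(i)[0, s])
    return MPRProfile(character_id, int(dp.score[0]), node_cost, mpr_set)


def edge_events(tree: Phylogeny, character: Mapping[str, object]) -> list[EdgeEvent]:
    """Classify every edge's change status for one character."""
    dp = _DP(tree, _character_to_codes(tree, character))
    events = []
    for i in range(len(tree.postorder)):
        if tree.parent[i] is None:
            continue
        pairs = dp.edge_pairs(i)[0]
        pairset = frozenset(
            (s, t) for s in (0, 1) for t in (0, 1) if pairs[s, t]
        )
        events.append(EdgeEvent((tree.labels[tree.parent[i]], tree.labels[i]), pairset))
    return events


def classify_recruitment(
    tree: Phylogeny,
    matrix: CharacterMatrix,
    focal_taxa: Sequence[str],
) -> RecruitmentResult:
    """Classify every gene's change status on the focal branch.

    The focal branch is the edge subtending the most recent common ancestor
    of ``focal_taxa`` (its stem lineage). Per gene:

    * ``unambiguous_gain`` — every most-parsimonious reconstruction places a
      0 -> 1 change on the focal edge;
    * ``most_parsimonious_gain`` — at least one (but not every) MPR does;
    * losses symmetric;
    * ``uninformative`` — all observed tip states identical, or all missing;
    * ``no_change`` — otherwise.

    If both a gain and a loss are possible on the edge (distinct MPRs
    disagreeing on direction) the gene is reported as a most-parsimonious
    gain; gains are checked first.
    """
    parent_label, child_label = tree.focal_edge(focal_taxa)
    child = tree.labels.index(child_label)
    codes = _codes_for_tree(tree, matrix)
    dp = _DP(tree, codes)
    pairs = dp.edge_pairs(child)  # (G, 2, 2)

    observed = codes != MISSING
    n_obs = observed.sum(axis=1)
    any0 = ((codes == 0) & observed).any(axis=1)
    any1 = ((codes == 1) & observed).any(axis=1)
    uninformative = (n_obs == 0) | ~(any0 & any1)

    n_pairs = pairs.sum(axis=(1, 2))
    gain = pairs[:, 0, 1]
    loss = pairs[:, 1, 0]

    labels = np.full(matrix.n_genes, "no_change", dtype=object)
    labels[loss & (n_pairs > 1)] = "most_parsimonious_loss"
    labels[loss & (n_pairs == 1)] = "unambiguous_loss"
    labels[gain & (n_pairs > 1)] = "most_parsimonious_gain"
    labels[gain & (n_pairs == 1)] = "unambiguous_gain"
    labels[uninformative] = "uninformative"

    series = pd.Series(labels, index=matrix.genes, name="classification")
    return RecruitmentResult((parent_label, child_label), series)


def branch_change_counts(
    tree: Phylogeny, matrix: CharacterMatrix
) -> pd.DataFrame:
    """Per-edge totals of gains and losses over all genes.

    Returns one row per edge with columns parent, child,
    unambiguous_gains, unambiguous_losses, possible_gains, possible_losses
    (possible counts include the unambiguous ones). These totals are the
    change counts a branch-length-by-changes tree drawing uses.
    """
    codes = _codes_for_tree(tree, matrix)
    dp = _DP(tree, codes)
    rows = []
    for i in range(len(tree.postorder)):
        if tree.parent[i] is None:
            continue
        pairs = dp.edge_pairs(i)  # (G, 2, 2)
        n_pairs = pairs.sum(axis=(1, 2))
        gain = pairs[:, 0, 1]
        loss = pairs[:, 1, 0]
        rows.append(
            {
                "parent": tree.labels[tree.parent[i]],
                "child": tree.labels[i],
                "unambiguous_gains": int((gain & (n_pairs == 1)).sum()),
                "unambiguous_losses": int((loss & (n_pairs == 1)).sum()),
                "possible_gains": int(gain.sum()),
                "possible_losses": int(loss.sum()),
            }
        )
    return pd.DataFrame(rows)


def annotated_newick(
    tree: Phylogeny, counts: pd.DataFrame, weight: str = "unambiguous"
) -> str:
    """Newick with per-edge change counts as branch lengths.

    ``weight="unambiguous"`` uses unambiguous gains + losses;
    ``weight="possible"`` uses the most-parsimonious (possible) totals.
    """
    if weight == "unambiguous":
        total = counts["unambiguous_gains"] + counts["unambiguous_losses"]
    elif weight == "possible":
        total = counts["possible_gains"] + counts["possible_losses"]
    else:
        raise ValueError(f"unknown weight {weight!r}")
    lengths = {
        (row.parent, row.child): float(t)
        for row, t in zip(counts.itertuples(), total)
    }
    return tree.as_newick(edge_lengths=lengths)
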
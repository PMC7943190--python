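"""Generators for every input the pipeline consumes.

Binary characters evolve root-to-tips by independent per-edge Bernoulli
flips (gain 0 -> 1 and loss 1 -> 0 probabilities per edge) — a flip-
probability model rather than a continuous-time rate, because the analysis
tree carries no meaningful time-calibrated branch lengths. Missing-data
masking is applied after evolution, and the true per-gene change history is
returned so recovery tests can compare inference against truth. Expression
tables are drawn around well-separated expressed/silent means straddling the
expressed-call threshold, and two-group assay measurements are Gaussian
replicates on the log scale with the raw scale obtained by exponentiation.

All generators are pure functions of their seed.

A 27-leaf amniote topology (15 Eutherians, 3 Marsupials, a monotreme, 2
birds, 5 lepidosaurs and an amphibian outgroup) ships as a labelled test
fixture for realistic-shape tests; it is a synthetic transcription of the
study system's taxon sampling, not a scientific claim about relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    AssayTable,
    CharacterMatrix,
    ExpressionMatrix,
    Phylogeny,
    parse_newick,
)

__all__ = [
    "CharSimConfig",
    "AssaySimConfig",
    "simulate_characters",
    "simulate_single_gain_characters",
    "simulate_expression",
    "simulate_assay",
    "random_tree",
    "amniote_tree",
    "AMNIOTE_NEWICK",
    "EUTHERIA",
]

#: Synthetic transcription of the study's 27-taxon amniote sampling
#: (Eutheria, Marsupialia, Monotremata, birds, lepidosaurs, amphibian
#: outgroup). A labelled fixture for realistic-shape tests.
AMNIOTE_NEWICK = (
    "(frog,((((anole,fence_lizard),(gecko,(skink,dragon))),(chicken,zebra_finch)),"
    "(platypus,((opossum,(wallaby,possum)),"
    "(armadillo,(((bat,(dog,horse)),(cow,pig)),"
    "((rabbit,((mouse,rat),(hamster,squirrel))),"
    "((macaque,baboon),(human,chimpanzee)))))Eutheria)Theria)));"
)

#: The 15 Eutherian leaves of the fixture tree (their MRCA subtends the
#: Eutherian stem branch).
EUTHERIA = (
    "armadillo", "bat", "dog", "horse", "cow", "pig", "rabbit",
    "mouse", "rat", "hamster", "squirrel", "macaque", "baboon",
    "human", "chimpanzee",
)


def amniote_tree() -> Phylogeny:
    """The 27-leaf amniote fixture topology."""
    return parse_newick(AMNIOTE_NEWICK)


# ---------------------------------------------------------------------------
# Character evolution
# ---------------------------------------------------------------------------


@dataclass
class CharSimConfig:
    """Per-edge Bernoulli flip model for binary character evolution.

    ``gain_probability`` (0 -> 1) and ``loss_probability`` (1 -> 0) apply
    independently on every edge; ``missing_rate`` masks cells to "?" after
    evolution. Defaults mimic rarely-changing expression characters.
    """

    tree: Phylogeny
    n_genes: int = 100
    root_state_probability: float = 0.5
    gain_probability: float = 0.05
    loss_probability: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("root_state_probability", "gain_probability",
                     "loss_probability", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def simulate_characters(
    config: CharSimConfig,
) -> tuple[CharacterMatrix, list[list[tuple[str, int, int]]]]:
    """Evolve binary characters down the tree; return matrix and true histories.

    Each history lists the realized changes of one gene as
    (child label of the edge, from state, to state) tuples, recorded before
    any missing-data masking.
    """
    tree = config.tree
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n_nodes = len(tree.postorder)
    states = np.empty((n_nodes, G), dtype=np.int8)
    histories: list[list[tuple[str, int, int]]] = [[] for _ in range(G)]

    root = tree.root_index
    states[root] = rng.random(G) < config.root_state_probability
    for i in reversed(range(n_nodes)):  # preorder (root first)
        if i == root:
            continue
        parent_states = states[tree.parent[i]]
        u = rng.random(G)
        flip = np.where(
            parent_states == 0,
            u < config.gain_probability,
            u < config.loss_probability,
        )
        states[i] = np.where(flip, 1 - parent_states, parent_states)
        for g in np.nonzero(flip)[0]:
            histories[g].append(
                (tree.labels[i], int(parent_states[g]), int(states[i, g]))
            )

    leaf_idx = [tree.labels.index(lab) for lab in tree.leaf_labels]
    codes = states[leaf_idx].T.copy()  # (G, n_leaves)
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = MISSING
    genes = [f"g{j:05d}" for j in range(G)]
    return CharacterMatrix(genes, list(tree.leaf_labels), codes), histories


def simulate_single_gain_characters(
    tree: Phylogeny,
    edge_child: str,
    n_genes: int,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> CharacterMatrix:
    """Characters with exactly one 0 -> 1 change, on the edge above ``edge_child``.

    The root and everything outside the chosen clade is 0; every leaf inside
    it is 1. Optional "?" masking is applied per cell afterwards.
    """
    rng = np.random.default_rng(seed)
    child = tree.labels.index(edge_child)
    inside = np.zeros(len(tree.postorder), dtype=bool)
    inside[child] = True
    for i in reversed(range(len(tree.postorder))):
        if tree.parent[i] is not None and inside[tree.parent[i]]:
            inside[i] = True
    leaf_states = np.array(
        [1 if inside[tree.labels.index(lab)] else 0 for lab in tree.leaf_labels],
        dtype=np.int8,
    )
    codes = np.tile(leaf_states, (n_genes, 1))
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = MISSING
    genes = [f"g{j:05d}" for j in range(n_genes)]
    return CharacterMatrix(genes, list(tree.leaf_labels), codes)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def simulate_expression(
    matrix: CharacterMatrix,
    expressed_mean: float = 10.0,
    silent_mean: float = 0.1,
    noise_sd: float = 0.5,
    replicates: int = 3,
    seed: int = 0,
) -> ExpressionMatrix:
    """TPM values whose encoded calls recover ``matrix`` with high probability.

    Expressed (state 1) cells draw Gaussian TPM around ``expressed_mean``,
    silent (state 0) cells around ``silent_mean``, both truncated at zero;
    "?" cells become missing in every replicate sample of that species.
    ``expressed_mean`` must exceed the expressed-call threshold and
    ``silent_mean`` lie below it for recovery to make sense.
    """
    rng = np.random.default_rng(seed)
    G, T = matrix.codes.shape
    samples = []
    species_of = {}
    cols = []
    for t, taxon in enumerate(matrix.taxa):
        for r in range(replicates):
            name = f"{taxon}_r{r + 1}"
            samples.append(name)
            species_of[name] = taxon
            means = np.where(matrix.codes[:, t] == 1, expressed_mean, silent_mean)
            vals = np.clip(rng.normal(means, noise_sd), 0.0, None)
            vals[matrix.codes[:, t] == MISSING] = np.nan
            cols.append(vals)
    data = pd.DataFrame(np.column_stack(cols), index=matrix.genes, columns=samples)
    return ExpressionMatrix(data, species_of)


# ---------------------------------------------------------------------------
# Assay tables
# ---------------------------------------------------------------------------


@dataclass
class AssaySimConfig:
    """Two-group assay generator: Gaussian replicates on the log scale.

    Defaults match the assay design being emulated: n = 12 replicates per
    group and a log-scale replicate spread of 0.1.
    """

    group_means: dict[str, float] = field(
        default_factory=lambda: {"control": 2.0, "test": 2.5}
    )
    sd: float = 0.1
    n_per_group: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be > 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def simulate_assay(config: AssaySimConfig) -> dict[str, AssayTable]:
    """Simulate grouped replicate measurements.

    Returns ``{"log": ..., "raw": ...}``; the raw scale is 10**log,
    mimicking luminescence readouts spanning orders of magnitude.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group, mu in config.group_means.items():
        vals = rng.normal(mu, config.sd, size=config.n_per_group)
        for r, v in enumerate(vals, start=1):
            rows.append((group, r, v))
    log_df = pd.DataFrame(rows, columns=["group", "replicate", "value"])
    raw_df = log_df.assign(value=10.0 ** log_df["value"])
    return {"log": AssayTable(log_df, "log"), "raw": AssayTable(raw_df, "raw")}


# ---------------------------------------------------------------------------
# Random topologies
# ---------------------------------------------------------------------------


def random_tree(n_taxa: int, seed: int = 0, prefix: str = "t") -> Phylogeny:
    """Uniformly random rooted binary topology with ``n_taxa`` labelled leaves.

    Built by sequential leaf addition onto a uniformly chosen edge (including
    a new root stem), which yields the uniform distribution over rooted
    binary topologies.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    root: list = [labels[0], labels[1]]
    for label in labels[2:]:
        # 2k-1 attachable positions: every edge plus the root stem
        edges = _collect_edges(root)
        parent, child = edges[rng.integers(len(edges))]
        if parent is None:
            root = [root, label]
        else:
            parent[parent.index(child)] = [child, label]
    return parse_newick(_to_newick(root) + ";")


def _collect_edges(node: list) -> list[tuple[list | None, object]]:
    out: list[tuple[list | None, object]] = [(None, node)]
    stack = [node]
    while stack:
        cur = stack.pop()
        for ch in cur:
            out.append((cur, ch))
            if isinstance(ch, list):
                stack.append(ch)
    return out


def _to_newick(node) -> str:
    if isinstance(node, list):
        return "(" + ",".join(_to_newick(c) for c in node) + ")"
    return str(node)
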
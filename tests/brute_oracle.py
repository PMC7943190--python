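"""Independent brute-force parsimony oracle: exhaustive enumeration.

Enumerates all 2^(number of internal nodes) ancestral labelings (with "?"
leaves free to match their parent at no cost), computes every labeling's
change count directly from the edge list, and derives the score, per-node
constrained costs, MPR state sets and per-edge realized parent/child state
pairs by brute force. Completely independent of the package's inside-outside
dynamic program.
"""

from __future__ import annotations

import numpy as np

from phylorecruit.io_formats import MISSING, Phylogeny

INF = np.float64(1e15)


def brute_profile(tree: Phylogeny, codes: np.ndarray) -> dict:
    """Exhaustive-enumeration reconstruction for all genes at once.

    ``codes`` is (n_genes, n_leaves) aligned to ``tree.leaf_labels``.
    Returns score (G,), per-internal-node constrained costs and MPR masks,
    per-leaf MPR masks, and per-edge (2, 2) possible-pair masks keyed by the
    child's node index.
    """
    n_nodes = len(tree.postorder)
    G = codes.shape[0]
    internal = [i for i in range(n_nodes) if not tree.is_leaf[i]]
    pos = {node: j for j, node in enumerate(internal)}
    I = len(internal)
    L = 1 << I
    lab = ((np.arange(L)[:, None] >> np.arange(I)) & 1).astype(np.int8)  # (L, I)

    # cost between internal parent and internal child, same for every gene
    base = np.zeros(L, dtype=np.int64)
    # per-gene cost from leaves (missing leaves contribute 0)
    leafcost = np.zeros((L, G), dtype=np.int64)
    leaf_col = {lab_: j for j, lab_ in enumerate(tree.leaf_labels)}
    for i in range(n_nodes):
        p = tree.parent[i]
        if p is None:
            continue
        if tree.is_leaf[i]:
            c = codes[:, leaf_col[tree.labels[i]]]  # (G,)
            observed = c != MISSING
            mism = (lab[:, pos[p]][:, None] != c[None, :]) & observed[None, :]
            leafcost += mism
        else:
            base += lab[:, pos[p]] != lab[:, pos[i]]

    total = base[:, None] + leafcost  # (L, G)
    score = total.min(axis=0)
    opt = total == score[None, :]

    node_cost = {}
    mpr = {}
    for i in internal:
        costs = np.empty((G, 2))
        for s in (0, 1):
            mask = lab[:, pos[i]] == s
            costs[:, s] = np.where(mask[:, None], total, np.inf).min(axis=0)
        node_cost[i] = costs
        mpr[i] = costs == score[:, None]
    for i in range(n_nodes):
        if not tree.is_leaf[i]:
            continue
        c = codes[:, leaf_col[tree.labels[i]]]
        m = np.zeros((G, 2), dtype=bool)
        p = pos[tree.parent[i]]
        for s in (0, 1):
            # pinning a "?" leaf to s is optimal iff some MPR has its parent at s
            parent_opt = (opt & (lab[:, p] == s)[:, None]).any(axis=0)
            m[:, s] = np.where(c == MISSING, parent_opt, c == s)
        mpr[i] = m

    edge_pairs = {}
    for i in range(n_nodes):
        p = tree.parent[i]
        if p is None:
            continue
        pairs = np.zeros((G, 2, 2), dtype=bool)
        for s in (0, 1):
            parent_opt = opt & (lab[:, pos[p]] == s)[:, None]  # (L, G)
            if tree.is_leaf[i]:
                c = codes[:, leaf_col[tree.labels[i]]]
                any_opt = parent_opt.any(axis=0)
                for t in (0, 1):
                    # observed leaf takes its state; "?" leaf matches parent
                    takes_t = np.where(c == MISSING, s == t, c == t)
                    pairs[:, s, t] = any_opt & takes_t
            else:
                for t in (0, 1):
                    pairs[:, s, t] = (
                        parent_opt & (lab[:, pos[i]] == t)[:, None]
                    ).any(axis=0)
        edge_pairs[i] = pairs

    return {
        "score": score,
        "node_cost": node_cost,
        "mpr": mpr,
        "edge_pairs": edge_pairs,
        "internal": internal,
    }


def random_topology(n_leaves: int, rng: np.random.Generator, p_polytomy: float = 0.3) -> str:
    """Random rooted topology newick, with polytomies created by contraction."""
    nodes: list = [f"t{i + 1}" for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 2
        if len(nodes) > 2 and rng.random() < p_polytomy:
            k = 3
        picks = rng.choice(len(nodes), size=k, replace=False)
        merged = [nodes[i] for i in picks]
        nodes = [n for j, n in enumerate(nodes) if j not in picks]
        nodes.append(merged)
    def render(n):
        if isinstance(n, list):
            return "(" + ",".join(render(c) for c in n) + ")"
        return n
    return render(nodes[0]) + ";"
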
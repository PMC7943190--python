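"""Over-representation analysis against custom gene sets and background.

The test statistic is the hypergeometric upper tail: given a background
universe of N genes of which K belong to a term, and a query of n background
genes with k in the term, p = P(X >= k) for X ~ Hypergeometric(N, K, n).
Term sizes K are counted *after* intersecting each set with the background
(the convention of ORA web tools that accept a custom background universe),
and FDR is Benjamini-Hochberg over the terms of one collection (one GMT), not
pooled across collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentRow", "hypergeom_upper", "bh_adjust", "run_ora"]


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's overlap counts and (adjusted) p-value."""

    term: str
    N: int
    K: int
    n: int
    k: int
    p: float
    q: float


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    ``N`` is the background size, ``K`` the term genes in background, ``n``
    the query genes in background and ``k`` the overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the pmf terms in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: Sequence[str],
    sets: GeneSetCollection,
    background: Sequence[str],
    min_overlap: int = 0,
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the background are dropped (their count is recorded
    in ``DataFrame.attrs["n_query_outside_background"]``). One row is
    produced per set with K >= ``min_set_size`` after background intersection
    and overlap k >= ``min_overlap``; rows are sorted by p and BH-adjusted
    over exactly the tested rows. Results are invariant to query/background
    ordering.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background gene list is empty")
    qset = frozenset(query)
    dropped = len(qset - bg)
    qset &= bg
    N, n = len(bg), len(qset)

    rows = []
    for term, (_desc, genes) in sets.sets.items():
        term_bg = frozenset(genes) & bg
        K = len(term_bg)
        if K == 0 or K < min_set_size:
            continue
        k = len(term_bg & qset)
        if k < min_overlap:
            continue
        rows.append((term, N, K, n, k, hypergeom_upper(k, n, K, N)))

    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df.attrs["n_query_outside_background"] = dropped
    return df
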
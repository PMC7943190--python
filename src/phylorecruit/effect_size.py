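"""Two-group estimation statistics for functional assays.

The effect size is the plain difference of group means, mean(test) -
mean(control). Uncertainty is quantified two ways, following estimation-
statistics practice for two independent groups:

* a bias-corrected and accelerated (BCa) bootstrap confidence interval,
  resampling each group independently with replacement (B = 5000 replicates
  by default, 95% level), with the bias term taken from the fraction of
  bootstrap deltas below the observed delta and the acceleration from a
  leave-one-out jackknife over all observations (each left out within its
  own group);
* a two-sided permutation test on the mean difference (P = 5000 label
  reshuffles by default, or exhaustive enumeration when the number of
  distinct splits is small), reporting the plain proportion of reshuffles
  with |delta*| >= |delta| — so a perfectly separated comparison can print
  p = 0.00 — alongside the conservative add-one estimate (count+1)/(P+1).

All resampling is driven by a single integer seed; identical seeds give
identical results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .io_formats import AssayTable

__all__ = [
    "EffectSizeResult",
    "mean_difference",
    "bca_interval",
    "permutation_p",
    "analyze_two_groups",
    "analyze_table",
]


@dataclass
class EffectSizeResult:
    """Mean difference with BCa CI and permutation p, plus resampling provenance."""

    delta: float
    ci_low: float
    ci_high: float
    p_perm: float
    p_perm_addone: float
    B: int
    P: int | str  # number of reshuffles, or "exhaustive"
    level: float
    seed: int
    n_control: int
    n_test: int


def _check_group(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} group is empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} group contains non-finite values")
    return arr


def mean_difference(control, test) -> float:
    """mean(test) - mean(control)."""
    c = _check_group(control, "control")
    t = _check_group(test, "test")
    return float(t.mean() - c.mean())


def bca_interval(
    control,
    test,
    B: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """BCa bootstrap CI for the mean difference (independent within-group resampling).

    Degenerate bootstrap distributions (all replicate deltas equal) return
    the point interval [delta, delta] with a warning; a bias fraction of 0 or
    1 is clamped to 1/(2B) with a warning. Groups should have >= 3
    observations for the jackknife; B >= 1000 is recommended.
    """
    c = _check_group(control, "control")
    t = _check_group(test, "test")
    if rng is None:
        rng = np.random.default_rng(seed)
    delta = float(t.mean() - c.mean())

    boot_c = c[rng.integers(0, c.size, size=(B, c.size))].mean(axis=1)
    boot_t = t[rng.integers(0, t.size, size=(B, t.size))].mean(axis=1)
    boot = boot_t - boot_c

    if np.ptp(boot) == 0:
        warnings.warn("degenerate bootstrap distribution; returning point interval")
        return delta, delta

    frac_below = float(np.mean(boot < delta))
    if frac_below in (0.0, 1.0):
        warnings.warn("bias fraction at the boundary; clamped to 1/(2B)")
        frac_below = 1.0 / (2 * B) if frac_below == 0.0 else 1.0 - 1.0 / (2 * B)
    z0 = norm.ppf(frac_below)

    # leave-one-out over the pooled observations, each within its own group
    jack = np.concatenate(
        [
            t.mean() - (c.sum() - c) / (c.size - 1) if c.size > 1 else [delta],
            (t.sum() - t) / (t.size - 1) - c.mean() if t.size > 1 else [delta],
        ]
    )
    dev = jack.mean() - jack
    denom = (dev**2).sum() ** 1.5
    accel = (dev**3).sum() / (6 * denom) if denom > 0 else 0.0

    alpha = 1.0 - level
    bounds = []
    for z_alpha in (norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1 - accel * (z0 + z_alpha))
        bounds.append(float(np.quantile(boot, norm.cdf(adj))))
    return bounds[0], bounds[1]


def permutation_p(
    control,
    test,
    P: int = 5000,
    seed: int = 0,
    exhaustive_cap: int = 20000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, int | str]:
    """Two-sided permutation test on the mean difference.

    Returns ``(p_plain, p_addone, P_used)``. When the number of distinct
    control/test splits is at most ``exhaustive_cap``, all splits are
    enumerated and both p values equal the exact proportion (``P_used`` is
    the string "exhaustive"); otherwise ``P`` random reshuffles are drawn and
    ``p_plain`` is the plain proportion with |delta*| >= |delta| while
    ``p_addone`` is (count + 1) / (P + 1).
    """
    c = _check_group(control, "control")
    t = _check_group(test, "test")
    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate([c, t])
    n, nc = pooled.size, c.size
    obs = abs(t.mean() - c.mean())
    total = pooled.sum()

    def delta_from_csum(csum: np.ndarray) -> np.ndarray:
        return (total - csum) / (n - nc) - csum / nc

    n_splits = math.comb(n, nc)
    if n_splits <= exhaustive_cap:
        idx = np.array(list(combinations(range(n), nc)))
        csums = pooled[idx].sum(axis=1)
        count = int((np.abs(delta_from_csum(csums)) >= obs - 1e-12).sum())
        p = count / n_splits
        return p, p, "exhaustive"

    order = np.argsort(rng.random((P, n)), axis=1)[:, :nc]
    csums = pooled[order].sum(axis=1)
    count = int((np.abs(delta_from_csum(csums)) >= obs - 1e-12).sum())
    return count / P, (count + 1) / (P + 1), P


def analyze_two_groups(
    control,
    test,
    B: int = 5000,
    P: int = 5000,
    level: float = 0.95,
    seed: int = 0,
    exhaustive_cap: int = 20000,
) -> EffectSizeResult:
    """Full two-group analysis: delta, BCa CI and permutation p.

    The bootstrap and the permutation test draw from independent streams
    spawned from ``seed``, so B and P can be changed independently without
    perturbing each other.
    """
    c = _check_group(control, "control")
    t = _check_group(test, "test")
    boot_seed, perm_seed = np.random.SeedSequence(seed).spawn(2)
    delta = mean_difference(c, t)
    lo, hi = bca_interval(c, t, B=B, level=level, rng=np.random.default_rng(boot_seed))
    p, p1, p_used = permutation_p(
        c, t, P=P, exhaustive_cap=exhaustive_cap, rng=np.random.default_rng(perm_seed)
    )
    return EffectSizeResult(
        delta=delta,
        ci_low=lo,
        ci_high=hi,
        p_perm=p,
        p_perm_addone=p1,
        B=B,
        P=p_used,
        level=level,
        seed=seed,
        n_control=c.size,
        n_test=t.size,
    )


def analyze_table(
    table: AssayTable,
    control_label: str,
    test_label: str,
    **kwargs,
) -> EffectSizeResult:
    """Run :func:`analyze_two_groups` on two groups of an assay table."""
    return analyze_two_groups(table.group(control_label), table.group(test_label), **kwargs)
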
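"""Discretize continuous transcript abundance into character states.

A gene is called expressed in a species when its abundance reaches the
threshold (TPM >= 2.0 by default, an inclusive boundary), not expressed below
it, and missing ("?") where the species contributes no data. Multiple
replicate samples per species are collapsed to one value per species before
thresholding (mean by default; median provided), or thresholded per sample
and combined by majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, CharacterMatrix, ExpressionMatrix

__all__ = ["EncodingConfig", "collapse_replicates", "binarize", "encode_characters"]

_RULES = ("mean", "median", "majority")


@dataclass(frozen=True)
class EncodingConfig:
    """Expressed-call threshold (TPM) and replicate-collapse rule."""

    threshold: float = 2.0
    replicate_rule: str = "mean"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if self.replicate_rule not in _RULES:
            raise ValueError(
                f"unknown replicate_rule {self.replicate_rule!r}; expected one of {_RULES}"
            )


def collapse_replicates(
    matrix: ExpressionMatrix, config: EncodingConfig = EncodingConfig()
) -> ExpressionMatrix:
    """Collapse replicate samples to one abundance column per species.

    Mean or median is taken over non-missing replicate values; a species with
    all values missing for a gene stays missing. The majority rule operates
    on binary calls, not abundances, and is handled by
    :func:`encode_characters`.
    """
    if config.replicate_rule == "majority":
        raise ValueError(
            "majority rule votes over per-sample binary calls; use encode_characters"
        )
    groups = pd.Series(matrix.sample_species)[matrix.samples]
    agg = matrix.data.T.groupby(groups.values, sort=False)
    collapsed = (agg.mean() if config.replicate_rule == "mean" else agg.median()).T
    collapsed = collapsed[matrix.species]
    return ExpressionMatrix(collapsed, {sp: sp for sp in collapsed.columns})


def binarize(
    matrix: ExpressionMatrix, config: EncodingConfig = EncodingConfig()
) -> CharacterMatrix:
    """Threshold a collapsed (one column per species) matrix into {0, 1, ?}.

    value >= threshold -> 1, value < threshold -> 0, missing -> "?".
    Monotone in the abundances: raising a value never flips 1 to 0.
    """
    vals = matrix.data.to_numpy(dtype=float)
    codes = np.where(vals >= config.threshold, 1, 0).astype(np.int8)
    codes[np.isnan(vals)] = MISSING
    return CharacterMatrix(matrix.genes, list(matrix.data.columns), codes)


def encode_characters(
    matrix: ExpressionMatrix, config: EncodingConfig = EncodingConfig()
) -> CharacterMatrix:
    """Full encoding: replicate collapse then threshold.

    Under ``mean``/``median`` the abundances are combined first and the
    combined value thresholded (the default order). Under ``majority`` each
    sample is thresholded first and the species call is the majority of
    non-missing calls, ties rounding up to expressed (mirroring the inclusive
    threshold); a species with no non-missing samples for a gene is "?".
    """
    if config.replicate_rule in ("mean", "median"):
        return binarize(collapse_replicates(matrix, config), config)

    vals = matrix.data.to_numpy(dtype=float)
    calls = np.where(vals >= config.threshold, 1.0, 0.0)
    calls[np.isnan(vals)] = np.nan
    species = matrix.species
    codes = np.empty((len(matrix.genes), len(species)), dtype=np.int8)
    sample_cols = np.array([matrix.sample_species[s] for s in matrix.samples])
    for j, sp in enumerate(species):
        block = calls[:, sample_cols == sp]
        n_obs = np.sum(~np.isnan(block), axis=1)
        n_on = np.nansum(block, axis=1)
        col = np.where(2 * n_on >= n_obs, 1, 0).astype(np.int8)
        col[n_obs == 0] = MISSING
        codes[:, j] = col
    return CharacterMatrix(matrix.genes, species, codes)
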
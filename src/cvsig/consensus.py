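"""Moderated z-score (MODZ) consensus signatures.

The consensus of a group of signatures is their weighted average, with the
weight of each member given by the row sums of the group's pairwise Spearman
correlation matrix after clamping: diagonal entries are set to 0 first, then
negative correlations are set to 0.01, and the row sums are normalized to 1.
This de-weights outlying members while never letting an anti-correlated
member flip the consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import SignatureSet

__all__ = ["ConsensusResult", "modz", "group_consensus"]

#: value assigned to clamped (negative or undefined) correlations
NEGATIVE_CLAMP = 0.01


@dataclass
class ConsensusResult:
    consensus: np.ndarray        # length G
    weights: np.ndarray          # length n, sums to 1
    member_ids: list

    def __post_init__(self) -> None:
        if len(self.weights) < 1:
            raise ValueError("consensus needs at least one member")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


def modz(signatures: np.ndarray, member_ids=None) -> ConsensusResult:
    """MODZ consensus of an n x G signature matrix.

    A single signature is returned unchanged with weight 1.  Constant rows
    (undefined Spearman correlation) are treated as the clamp value with a
    warning.
    """
    sigs = np.asarray(signatures, dtype=float)
    if sigs.ndim != 2:
        raise ValueError("signatures must be a 2-D matrix")
    n, g = sigs.shape
    if n < 1 or g < 2:
        raise ValueError("need n >= 1 signatures over G >= 2 genes")
    if member_ids is None:
        member_ids = list(range(n))
    member_ids = list(member_ids)
    if n == 1:
        return ConsensusResult(sigs[0].copy(), np.array([1.0]), member_ids)

    ranks = rankdata(sigs, axis=1)  # average ranks on ties
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ranks)
    if np.isnan(corr).any():
        warnings.warn("constant signature row: undefined Spearman correlation "
                      f"clamped to {NEGATIVE_CLAMP}", stacklevel=2)
        corr = np.where(np.isnan(corr), -1.0, corr)  # clamped below
    np.fill_diagonal(corr, 0.0)          # diagonal first,
    corr[corr < 0] = NEGATIVE_CLAMP      # then negatives
    weights = corr.sum(axis=1)
    total = weights.sum()
    if total <= 0:  # all off-diagonals exactly zero: fall back to equal weights
        weights = np.full(n, 1.0 / n)
    else:
        weights = weights / total
    return ConsensusResult(weights @ sigs, weights, member_ids)


def group_consensus(sigset: SignatureSet, group_by) -> dict:
    """MODZ consensus per group of instances.

    ``group_by`` is a metadata key or list of keys from ``row_meta`` (the
    instance index itself may be named via ``"instance_id"``).  Returns a map
    group key -> :class:`ConsensusResult`; size-1 groups pass through.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    meta = sigset.row_meta.copy()
    meta.index.name = None  # avoid index/column ambiguity in groupby
    meta["instance_id"] = sigset.row_meta.index
    for key in group_by:
        if key not in meta.columns:
            raise KeyError(f"group_by key {key!r} not in row metadata")
    out = {}
    values = sigset.values
    for key, idx in meta.groupby(list(group_by), sort=True, dropna=False).groups.items():
        block = values.loc[idx]
        out[key] = modz(block.to_numpy(), member_ids=list(block.index))
    return out
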
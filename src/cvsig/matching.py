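"""Condition collapsing and signature–viability matching.

A viability record (cell, perturbagen[, dose]) is paired with the signature
instance of the same cell and perturbagen whose dose is closest on the log10
scale, provided the absolute log10 concentration difference is strictly below
the tolerance (default 0.2, about a 1.5-fold concentration difference).
shRNA records match on the exact (cell, perturbagen) key; dose is ignored.
One viability value may be reused by signatures at several measurement
times — matching is performed per time point and the result can be split by
time afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import modz
from .data_io import SignatureSet, ViabilityTable

__all__ = ["MatchedDataset", "collapse_conditions", "match_records",
           "split_by_time"]

DEFAULT_TOLERANCE_LOG10 = 0.2


@dataclass
class MatchedDataset:
    """Aligned signature matrix X and viability vector y with provenance."""

    X: pd.DataFrame        # instances x genes
    y: pd.Series           # aligned with X rows, in the source metric
    meta: pd.DataFrame     # per row: cell, perturbagen, doses, delta, time_h
    tag: str = ""

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.meta)):
            raise ValueError("X, y and meta must be aligned 1:1")
        self.y = pd.Series(np.asarray(self.y, dtype=float), index=self.X.index,
                           name="viability")
        self.meta.index = self.X.index

    def __len__(self) -> int:
        return len(self.X)

    @property
    def genes(self) -> pd.Index:
        return self.X.columns

    def to_signature_set(self, perturbagen_type: str = "compound") -> SignatureSet:
        """View the matched rows as a SignatureSet (for similarity analyses)."""
        row_meta = pd.DataFrame(index=self.X.index)
        row_meta["cell_line_id"] = self.meta["cell_line_id"].to_numpy()
        row_meta["perturbagen_id"] = self.meta["perturbagen_id"].to_numpy()
        row_meta["perturbagen_type"] = perturbagen_type
        if perturbagen_type == "compound":
            row_meta["dose_um"] = self.meta["dose_signature"].to_numpy()
        else:
            row_meta["dose_um"] = np.nan
        row_meta["time_h"] = self.meta["time_h"].to_numpy()
        col_meta = pd.DataFrame({"gene_symbol": self.X.columns},
                                index=self.X.columns)
        return SignatureSet(self.X, row_meta, col_meta)


def _condition_key(row_meta: pd.DataFrame) -> pd.Series:
    """Grouping key: (perturbagen, cell, time, dose-if-compound)."""
    dose = row_meta["dose_um"].where(row_meta["perturbagen_type"] == "compound")
    return (row_meta["perturbagen_id"].astype(str) + "|"
            + row_meta["cell_line_id"].astype(str) + "|"
            + row_meta["time_h"].astype(float).astype(str) + "|"
            + dose.astype(float).astype(str))


def collapse_conditions(sigset: SignatureSet) -> SignatureSet:
    """One row per condition; duplicate groups replaced by their MODZ consensus."""
    key = _condition_key(sigset.row_meta)
    if not key.duplicated().any():
        return sigset
    values, row_meta = [], []
    for _, idx in key.groupby(key, sort=False).groups.items():
        block = sigset.values.loc[idx]
        if len(block) == 1:
            values.append(block.iloc[0].to_numpy())
            row_meta.append(sigset.row_meta.loc[idx[0]])
        else:
            res = modz(block.to_numpy(), member_ids=list(block.index))
            values.append(res.consensus)
            meta = sigset.row_meta.loc[idx[0]].copy()
            meta.name = "|".join(map(str, sorted(idx)))
            row_meta.append(meta)
    row_meta = pd.DataFrame(row_meta)
    row_meta.index.name = "instance_id"
    values = pd.DataFrame(np.asarray(values), index=row_meta.index,
                          columns=sigset.values.columns)
    return SignatureSet(values, row_meta, sigset.col_meta)


def match_records(sigset: SignatureSet, viab: ViabilityTable,
                  tolerance_log10: float = DEFAULT_TOLERANCE_LOG10,
                  tag: str = "") -> MatchedDataset:
    """Pair viability records with their closest-dose signature instances.

    For each viability record and each signature time point, the candidate
    instances share (cell, perturbagen); among compounds the instance
    minimizing |delta log10 dose| is paired iff the minimum is strictly below
    the tolerance (ties broken by lower signature dose, then instance_id).
    Unmatched records are dropped.  An empty cell/perturbagen intersection
    yields an empty dataset with a warning, not an error.
    """
    sig_meta = sigset.row_meta.reset_index()
    recs = viab.records.reset_index(drop=True).reset_index(names="record_idx")

    merged = recs.merge(sig_meta, on=["cell_line_id", "perturbagen_id"],
                        suffixes=("_viability", "_signature"))
    if merged.empty:
        warnings.warn("no overlap between viability records and signature "
                      "instances; returning an empty dataset", stacklevel=2)
        empty_meta = pd.DataFrame(columns=["cell_line_id", "perturbagen_id",
                                           "dose_signature", "dose_viability",
                                           "delta_log10", "time_h"])
        return MatchedDataset(sigset.values.iloc[:0],
                              pd.Series(dtype=float), empty_meta, tag=tag)

    is_compound = merged["perturbagen_type"] == "compound"
    delta = pd.Series(0.0, index=merged.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta[is_compound] = np.abs(
            np.log10(merged.loc[is_compound, "dose_um_signature"].astype(float))
            - np.log10(merged.loc[is_compound, "dose_um_viability"].astype(float)))
    merged["delta_log10"] = delta
    merged = merged[~merged["delta_log10"].isna()]
    # strict "<" tolerance; shRNA/control rows have delta 0
    merged = merged[merged["delta_log10"] < tolerance_log10]
    # deterministic best-candidate choice per (record, time point)
    merged = merged.sort_values(
        ["record_idx", "time_h", "delta_log10", "dose_um_signature",
         "instance_id"], kind="mergesort")
    best = merged.groupby(["record_idx", "time_h"], sort=True,
                          dropna=False).head(1)

    X = sigset.values.loc[best["instance_id"]]
    y = best["viability"].to_numpy(dtype=float)
    meta = pd.DataFrame({
        "cell_line_id": best["cell_line_id"].to_numpy(),
        "perturbagen_id": best["perturbagen_id"].to_numpy(),
        "dose_signature": best["dose_um_signature"].to_numpy(),
        "dose_viability": best["dose_um_viability"].to_numpy(),
        "delta_log10": best["delta_log10"].to_numpy(),
        "time_h": best["time_h"].to_numpy(),
    })
    # a signature may serve several viability-record times -> reindex rows
    X = X.set_axis(pd.Index(
        [f"{iid}#{r}" for iid, r in zip(best["instance_id"],
                                        best["record_idx"])],
        name="instance_id"))
    return MatchedDataset(X, pd.Series(y, index=X.index), meta, tag=tag)


def split_by_time(ds: MatchedDataset) -> dict[float, MatchedDataset]:
    """Partition a matched dataset by signature measurement time."""
    out = {}
    for t, idx in ds.meta.groupby("time_h", sort=True).groups.items():
        out[float(t)] = MatchedDataset(
            ds.X.loc[idx], ds.y.loc[idx], ds.meta.loc[idx],
            tag=f"{ds.tag}-{t:g}h" if ds.tag else f"{t:g}h")
    return out
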
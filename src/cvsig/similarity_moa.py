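"""Signature similarity, the cell-viability confounder, and MoA prediction.

Toxic compounds with unrelated mechanisms share the cell-death component of
their signatures, which inflates their pairwise Spearman similarity and
confounds similarity-based mechanism-of-action discovery.  The module
quantifies the effect (pair-group similarity distributions for toxic /
nontoxic / random pairs), removes it (dropping the genes most correlated
with viability — statistics taken from an independent screen to avoid
leakage — or regressing viability out per gene), and evaluates MoA
prediction by ROC / precision-recall over pair similarities, optionally
fused with structure (Tanimoto) or sensitivity-profile similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.mixture import GaussianMixture

from .data_io import AnnotationTable, SignatureSet
from .matching import MatchedDataset
from .signature_functional import GeneViabilityStats

__all__ = ["SimilarityMatrix", "PairGroupReport", "EvalReport",
           "pairwise_spearman", "toxicity_threshold_gmm",
           "pair_similarity_groups", "reduce_by_viability_genes",
           "residualize_on_viability", "auxiliary_similarity",
           "fuse_similarities", "binary_score_eval"]

FALLBACK_THRESHOLD = 0.8


@dataclass
class SimilarityMatrix:
    """Symmetric entity x entity similarity; the diagonal is never used."""

    values: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1] or not self.values.index.equals(
                self.values.columns):
            raise ValueError("similarity matrix must be square with matching ids")
        if np.nanmax(np.abs(v - v.T)) > 1e-12:
            raise ValueError("similarity matrix must be symmetric")

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def offdiag_pairs(self):
        """(i, j) integer index pairs with i < j."""
        n = len(self.ids)
        return np.triu_indices(n, k=1)


@dataclass
class PairGroupReport:
    """Similarity distributions per pair group and scope, with medians."""

    distributions: dict      # scope -> group -> np.ndarray
    threshold: float
    groups: tuple = ("nontoxic_shared_moa", "toxic_different_moa", "random")
    scopes: tuple = ("any_cell", "same_cell")

    def median(self, scope: str, group: str) -> float:
        d = self.distributions[scope][group]
        return float(np.median(d)) if len(d) else np.nan


@dataclass
class EvalReport:
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float
    pr_precision: np.ndarray
    pr_recall: np.ndarray
    pr_auc: float


def pairwise_spearman(values) -> SimilarityMatrix:
    """All-pairs Spearman correlation of signature rows (average-rank ties)."""
    if isinstance(values, SignatureSet):
        values = values.values
    mat = np.asarray(values, dtype=float)
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    ids = (values.index if isinstance(values, pd.DataFrame)
           else pd.RangeIndex(mat.shape[0]))
    ranks = rankdata(mat, axis=1)
    sim = np.corrcoef(ranks)
    sim = (sim + sim.T) / 2.0
    return SimilarityMatrix(pd.DataFrame(sim, index=ids, columns=ids),
                            method="spearman_signature")


def toxicity_threshold_gmm(viabilities, seed: int = 0) -> float:
    """Data-driven nontoxic/toxic threshold from a 2-component Gaussian mixture.

    The nontoxic component is the one with the larger mean (fraction
    viability near 1); the threshold is its mean - 2 SD.  If the mixture
    collapses (component means closer than half the larger SD) the fixed 0.8
    fallback is returned with a warning.
    """
    v = np.asarray(viabilities, dtype=float).reshape(-1, 1)
    if len(v) < 50:
        raise ValueError("need at least 50 viability values")
    if np.std(v) < 1e-9:
        warnings.warn("viability values are (near-)constant: falling back to "
                      f"threshold {FALLBACK_THRESHOLD}", stacklevel=2)
        return FALLBACK_THRESHOLD
    try:
        gm = GaussianMixture(n_components=2, n_init=10, random_state=seed)
        gm.fit(v)
    except Exception:
        warnings.warn("mixture fit failed: falling back to threshold "
                      f"{FALLBACK_THRESHOLD}", stacklevel=2)
        return FALLBACK_THRESHOLD
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    hi = int(np.argmax(means))
    if abs(means[0] - means[1]) < 0.5 * max(sds):
        warnings.warn("mixture components collapsed: falling back to "
                      f"threshold {FALLBACK_THRESHOLD}", stacklevel=2)
        return FALLBACK_THRESHOLD
    return float(means[hi] - 2.0 * sds[hi])


def pair_similarity_groups(simmat: SimilarityMatrix, meta: pd.DataFrame,
                           moa: AnnotationTable, viab,
                           threshold: float) -> PairGroupReport:
    """Similarity distributions for toxicity/MoA-defined pair groups.

    Groups (disjoint, same-perturbagen pairs excluded throughout):
    ``nontoxic_shared_moa`` — both members above the viability threshold and
    sharing at least one MoA label; ``toxic_different_moa`` — both below the
    threshold with disjoint labels; ``random`` — every other pair.  Each
    group is reported for all pairs (``any_cell``) and for same-cell-line
    pairs (``same_cell``).
    """
    ids = simmat.ids
    if not (len(meta) == len(ids)):
        raise ValueError("meta must align with similarity entities")
    v = np.asarray(viab, dtype=float)
    if len(v) != len(ids):
        raise ValueError("viability vector must align with similarity entities")
    perts = meta["perturbagen_id"].astype(str).to_numpy()
    cells = meta["cell_line_id"].astype(str).to_numpy()
    label_sets = [moa.labels_of(p) for p in perts]

    iu, ju = simmat.offdiag_pairs()
    sims = simmat.values.to_numpy()[iu, ju]
    same_pert = perts[iu] == perts[ju]
    same_cell = cells[iu] == cells[ju]
    nontoxic = (v[iu] > threshold) & (v[ju] > threshold)
    toxic = (v[iu] < threshold) & (v[ju] < threshold)
    shared = np.fromiter((bool(label_sets[a] & label_sets[b])
                          for a, b in zip(iu, ju)), bool, len(iu))
    has_labels = np.fromiter(
        (bool(label_sets[a]) and bool(label_sets[b])
         for a, b in zip(iu, ju)), bool, len(iu))

    keep = ~same_pert
    g_nontox = keep & nontoxic & shared
    g_tox = keep & toxic & ~shared & has_labels
    g_rand = keep & ~g_nontox & ~g_tox
    dists = {}
    for scope, scope_mask in (("any_cell", keep),
                              ("same_cell", keep & same_cell)):
        dists[scope] = {
            "nontoxic_shared_moa": sims[g_nontox & scope_mask],
            "toxic_different_moa": sims[g_tox & scope_mask],
            "random": sims[g_rand & scope_mask],
        }
    return PairGroupReport(dists, threshold)


def reduce_by_viability_genes(sigset: SignatureSet, stats: GeneViabilityStats,
                              n: int, mode: str = "top",
                              seed: int | None = None) -> SignatureSet:
    """Drop the n genes most correlated (|r|) with viability (or n random).

    The statistics should come from an independent dataset (e.g. the shRNA
    screen when reducing compound signatures) to avoid information leakage.
    Ties in |r| break by gene_id; ``mode="random"`` removes n random genes
    (the control experiment) using ``seed``.
    """
    genes = sigset.values.columns
    if not genes.isin(stats.r.index).all():
        raise ValueError("stats must cover every signature gene")
    if not 0 <= n < len(genes):
        raise ValueError(f"n must be in [0, {len(genes)}) — removing all "
                         "genes leaves an empty signature")
    if n == 0:
        return sigset
    if mode == "top":
        # sort on -|r| with gene_id tiebreak
        ranked = sorted(genes, key=lambda g: (-abs(stats.r[g]), g))
        drop = set(ranked[:n])
    elif mode == "random":
        rng = np.random.default_rng(seed)
        drop = set(rng.choice(genes.to_numpy(), size=n, replace=False))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = [g for g in genes if g not in drop]
    return sigset.subset_genes(keep)


def residualize_on_viability(ds: MatchedDataset) -> SignatureSet:
    """Replace each gene's values by residuals of its regression on viability."""
    if len(ds) < 3:
        raise ValueError("need at least 3 samples")
    y = ds.y.to_numpy(dtype=float)
    yc = y - y.mean()
    denom = float(yc @ yc)
    X = ds.X.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if denom == 0:
        resid = Xc
    else:
        slope = (Xc.T @ yc) / denom
        resid = Xc - np.outer(yc, slope)
    values = pd.DataFrame(resid, index=ds.X.index, columns=ds.X.columns)
    row_meta = pd.DataFrame(index=values.index)
    for f_ in ("cell_line_id", "perturbagen_id"):
        row_meta[f_] = ds.meta[f_].to_numpy() if f_ in ds.meta else None
    row_meta["perturbagen_type"] = None
    row_meta["dose_um"] = np.nan
    row_meta["time_h"] = (ds.meta["time_h"].to_numpy()
                          if "time_h" in ds.meta else np.nan)
    col_meta = pd.DataFrame({"gene_symbol": values.columns}, index=values.columns)
    return SignatureSet(values, row_meta, col_meta)


def _tanimoto_matrix(fingerprints: pd.DataFrame) -> SimilarityMatrix:
    ids = fingerprints.index
    bits = np.vstack(fingerprints["fingerprint"].to_numpy()).astype(bool)
    inter = (bits[:, None, :] & bits[None, :, :]).sum(axis=2).astype(float)
    union = (bits[:, None, :] | bits[None, :, :]).sum(axis=2).astype(float)
    empty = union == 0
    if empty.any():
        warnings.warn("fingerprint pairs with empty union scored 0",
                      stacklevel=3)
    sim = np.where(empty, 0.0, inter / np.where(empty, 1.0, union))
    return SimilarityMatrix(pd.DataFrame(sim, index=ids, columns=ids),
                            method="tanimoto")


def _profile_matrix(profiles: pd.DataFrame) -> SimilarityMatrix:
    """Pearson similarity of drug sensitivity profiles across shared cells."""
    ids = profiles.index
    n = len(ids)
    sim = np.full((n, n), np.nan)
    mat = profiles.to_numpy(dtype=float)
    for i in range(n):
        sim[i, i] = 1.0
        for j in range(i + 1, n):
            mask = np.isfinite(mat[i]) & np.isfinite(mat[j])
            if mask.sum() < 3:
                continue  # missing: fewer than 3 shared cells
            a, b = mat[i, mask], mat[j, mask]
            if a.std() == 0 or b.std() == 0:
                continue
            sim[i, j] = sim[j, i] = np.corrcoef(a, b)[0, 1]
    return SimilarityMatrix(pd.DataFrame(sim, index=ids, columns=ids),
                            method="sensitivity_profile")


def auxiliary_similarity(kind: str, data) -> SimilarityMatrix:
    """Structure (Tanimoto) or sensitivity-profile similarity.

    ``tanimoto``: ``data`` is an :class:`AnnotationTable` (or frame) with a
    fingerprint column; Tanimoto = |A & B| / |A | B| (both empty -> 0).
    ``sensitivity_profile``: ``data`` is a drugs x cells table of AUCs;
    Pearson over >= 3 shared finite cells, otherwise missing.
    """
    if kind == "tanimoto":
        frame = data.frame if isinstance(data, AnnotationTable) else data
        return _tanimoto_matrix(frame)
    if kind == "sensitivity_profile":
        return _profile_matrix(data)
    raise ValueError(f"unknown similarity kind {kind!r}")


def fuse_similarities(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Sum of z-normalized similarities (off-diagonal normalization).

    Each matrix's off-diagonal entries are standardized before the
    elementwise sum, so differently-scaled similarity types contribute
    comparably.
    """
    if not mats:
        raise ValueError("need at least one similarity matrix")
    ids = mats[0].ids
    for m in mats[1:]:
        if not m.ids.equals(ids):
            raise ValueError("all matrices must share the same entity set")
    iu, ju = np.triu_indices(len(ids), k=1)
    total = np.zeros((len(ids), len(ids)))
    for m in mats:
        v = m.values.to_numpy(dtype=float)
        off = v[iu, ju]
        finite = np.isfinite(off)
        mu, sd = off[finite].mean(), off[finite].std()
        z = np.zeros_like(v)
        zoff = np.where(finite, (off - mu) / (sd if sd > 0 else 1.0), 0.0)
        z[iu, ju] = zoff
        z[ju, iu] = zoff
        total += z
    return SimilarityMatrix(pd.DataFrame(total, index=ids, columns=ids),
                            method="fused")


def binary_score_eval(scores, truth) -> EvalReport:
    """Threshold-sweep ROC and precision-recall curves with trapezoidal AUCs.

    Equal scores are grouped at one threshold; ROC AUC therefore equals the
    tie-aware concordance (U-statistic) probability.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(bool)
    if len(s) != len(t):
        raise ValueError("scores and truth must align")
    P, N = int(t.sum()), int((~t).sum())
    if P == 0 or N == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, t_sorted = s[order], t[order]
    # group ties: cumulative counts at distinct thresholds
    distinct = np.where(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(t_sorted)[idx].astype(float)
    fps = np.cumsum(~t_sorted)[idx].astype(float)
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision = np.r_[1.0, tps / (tps + fps)]
    recall = np.r_[0.0, tps / P]
    pr_auc = float(np.trapezoid(precision, recall))
    return EvalReport(fpr, tpr, roc_auc, precision, recall, pr_auc)
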
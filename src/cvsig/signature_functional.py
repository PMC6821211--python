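"""Gene-level viability statistics and generic signature diagnostics.

The gene-level statistic is the per-gene Pearson correlation between
expression and matched viability.  It is the input both for external
GSEA-family enrichment engines (exported as a ranked TSV) and for the
in-repo weighted-gene-set permutation z-score, which permutes gene labels of
the statistic vector while holding set membership fixed.  The module also
provides the average-silhouette clustering diagnostic on a 2-D embedding and
the PC1–viability association check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import pearsonr, spearmanr

from .data_io import SignatureSet
from .matching import MatchedDataset

__all__ = ["GeneViabilityStats", "WeightedGeneSet", "SetScore",
           "gene_viability_correlations", "weighted_set_zscore",
           "activity_vs_essentiality", "silhouette_by_factor",
           "pc_viability_association", "write_ranked_stats"]


@dataclass
class GeneViabilityStats:
    """Per-gene Pearson r with viability (zero-variance genes flagged, r=0)."""

    r: pd.Series            # indexed by gene_id
    n: int
    tag: str = ""
    zero_variance: pd.Index = None

    def __post_init__(self) -> None:
        if ((self.r < -1 - 1e-12) | (self.r > 1 + 1e-12)).any():
            raise ValueError("correlations must lie in [-1, 1]")
        if self.zero_variance is None:
            self.zero_variance = pd.Index([])


@dataclass
class WeightedGeneSet:
    """Named gene -> signed weight map (unweighted sets use weight 1)."""

    name: str
    weights: dict

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("gene set must be non-empty")


@dataclass
class SetScore:
    score: float
    z: float                # NaN when undefined (flag set)
    n_genes: int
    undefined: bool = False


def gene_viability_correlations(ds: MatchedDataset,
                                tag: str | None = None) -> GeneViabilityStats:
    """Per-gene Pearson r of expression against viability."""
    if len(ds) < 3:
        raise ValueError("need at least 3 matched samples")
    X = ds.X.to_numpy(dtype=float)
    y = ds.y.to_numpy(dtype=float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = yc.std()
    zero_var = sx == 0
    denom = np.where(zero_var, 1.0, sx) * (sy if sy > 0 else 1.0)
    r = (Xc.T @ yc) / (len(y) * denom)
    r[zero_var] = 0.0
    if sy == 0:
        r[:] = 0.0
        zero_var = np.ones_like(zero_var)
    return GeneViabilityStats(
        pd.Series(np.clip(r, -1, 1), index=ds.X.columns, name="r"),
        n=len(ds), tag=tag if tag is not None else ds.tag,
        zero_variance=ds.X.columns[zero_var])


def weighted_set_zscore(stats: GeneViabilityStats, gene_set: WeightedGeneSet,
                        n_perm: int = 1000, seed: int = 0) -> SetScore:
    """Weighted-sum set score with a gene-label permutation z-score.

    score = sum over the set/statistic intersection of weight_g * r_g;
    the null permutes gene labels of the statistic vector, holding the set
    fixed.  A zero permutation SD leaves z undefined (flagged).
    """
    genes = [g for g in gene_set.weights if g in stats.r.index]
    if len(genes) < 2:
        raise ValueError("need >= 2 set genes present in the statistic vector")
    w = np.array([gene_set.weights[g] for g in genes], dtype=float)
    r_all = stats.r.to_numpy(dtype=float)
    score = float(w @ stats.r.loc[genes].to_numpy())
    rng = np.random.default_rng(seed)
    m = len(genes)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = w @ r_all[rng.choice(r_all.size, size=m, replace=False)]
    sd = null.std(ddof=1)
    if sd == 0:
        warnings.warn(f"set {gene_set.name!r}: permutation SD is 0, z undefined",
                      stacklevel=2)
        return SetScore(score, np.nan, m, undefined=True)
    return SetScore(score, float((score - null.mean()) / sd), m)


def activity_vs_essentiality(activities, essentiality) -> float:
    """Pearson r between two named score maps over their shared names."""
    shared = sorted(set(activities) & set(essentiality))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared names")
    a = np.array([activities[k] for k in shared], dtype=float)
    e = np.array([essentiality[k] for k in shared], dtype=float)
    return float(pearsonr(a, e)[0])


def silhouette_by_factor(embedding: np.ndarray, labels) -> float:
    """Average silhouette (b - a) / max(a, b) with Euclidean distances.

    a = mean intra-cluster distance of a point, b = mean distance to the
    nearest other cluster.  Points in singleton clusters score 0.
    """
    E = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    D = squareform(pdist(E))
    n = len(E)
    scores = np.zeros(n)
    masks = {lab: labels == lab for lab in uniq}
    for i in range(n):
        own = masks[labels[i]]
        size = own.sum()
        if size == 1:
            continue  # singleton convention: silhouette 0
        a = D[i, own].sum() / (size - 1)
        b = min(D[i, masks[lab]].mean() for lab in uniq if lab != labels[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def pc_viability_association(sigset: SignatureSet, viab):
    """PC1 scores of the centered signatures and their Spearman r to viability.

    PC1's sign is fixed so its loading points toward the mean signature of
    the lowest-viability decile (the "death" direction), making the reported
    correlation's sign reproducible.
    """
    y = np.asarray(viab, dtype=float)
    if len(y) != sigset.n_instances:
        raise ValueError("viability vector must align with instances")
    X = sigset.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    # PC1 via SVD of the centered matrix
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    decile = np.quantile(y, 0.1)
    death_mean = X[y <= decile].mean(axis=0)
    if loading @ death_mean < 0:
        loading = -loading
    scores = Xc @ loading
    r = float(spearmanr(scores, y)[0])
    return pd.Series(scores, index=sigset.values.index, name="PC1"), r


def write_ranked_stats(stats: GeneViabilityStats, path) -> None:
    """Export the gene-level statistic as a ranked TSV for enrichment tools."""
    ranked = stats.r.sort_values(ascending=False)
    ranked.rename_axis("gene_id").to_frame("r").to_csv(str(path), sep="\t")
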
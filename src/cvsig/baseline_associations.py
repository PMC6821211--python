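"""Scoring baseline expression with a CVS model and association analyses.

A cell line's CVS score is the dot product of the model coefficients with
its per-gene z-normalized baseline expression.  The association analyses
mirror a pharmacogenomic workflow: per-drug linear models
Sensitivity = f(CVS, Tissue, MSI) with Benjamini–Hochberg FDR across drugs;
the general level of drug sensitivity (GLDS) as the cell effect of a two-way
additive Sensitivity = f(Cell, Drug) model; tissue-residual partial
correlations; and permutation / single-gene null comparisons that report the
fraction of null models doing at least as well as the real signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matching import MatchedDataset
from .viability_model import ViabilityModel, fit_ridge

__all__ = ["CvsScoreTable", "cvs_score", "drug_sensitivity_associations",
           "glds", "partial_correlation_factor", "null_signature_comparison"]


@dataclass
class CvsScoreTable:
    """One CVS score per cell line, with the normalization recorded."""

    scores: pd.Series          # indexed by cell_line_id
    model_tag: str = ""
    normalization: str = "genewise_z"
    n_genes_used: int = 0
    n_genes_dropped: int = 0


def _genewise_z(baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across cell lines; constant genes map to all-zero."""
    mu = baseline.mean(axis=1)
    sd = baseline.std(axis=1, ddof=0)
    z = baseline.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def cvs_score(model: ViabilityModel, baseline: pd.DataFrame,
              normalization: str = "genewise_z") -> CvsScoreTable:
    """Score each cell line's baseline expression with the CVS model.

    ``baseline`` is genes x cell lines.  At least half of the model genes
    must be present; missing model genes are dropped (count logged).
    """
    if normalization not in ("genewise_z", "none"):
        raise ValueError("normalization must be 'genewise_z' or 'none'")
    present = model.genes.intersection(baseline.index)
    if len(present) < 0.5 * len(model.genes):
        raise ValueError(
            f"only {len(present)}/{len(model.genes)} model genes in the panel "
            "(< 50% overlap)")
    dropped = len(model.genes) - len(present)
    if dropped:
        warnings.warn(f"{dropped} model genes absent from the baseline panel",
                      stacklevel=2)
    mat = baseline.loc[present]
    if normalization == "genewise_z":
        mat = _genewise_z(mat)
    scores = mat.T @ model.beta.loc[present]
    return CvsScoreTable(scores.rename("cvs_score"), model_tag=model.tag,
                         normalization=normalization,
                         n_genes_used=len(present), n_genes_dropped=dropped)


def _design_with_covariates(sub: pd.DataFrame):
    """CVS + tissue one-hot (reference level dropped) + MSI design matrix.

    Singleton tissue levels (or other rank deficiencies) are handled by
    dropping offending columns with a warning.
    """
    cols = {"const": np.ones(len(sub)), "cvs": sub["cvs"].to_numpy(float)}
    levels = sorted(sub["tissue"].astype(str).unique())
    for lev in levels[1:]:
        col = (sub["tissue"].astype(str) == lev).to_numpy(float)
        if 0 < col.sum() < len(sub):
            cols[f"tissue[{lev}]"] = col
    if "msi" in sub and sub["msi"].nunique() > 1:
        cols["msi"] = sub["msi"].astype(float).to_numpy()
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    # drop columns causing rank deficiency (keep const and cvs)
    while np.linalg.matrix_rank(X) < X.shape[1] and X.shape[1] > 2:
        warnings.warn("rank-deficient covariate design: dropping "
                      f"{names[-1]!r}", stacklevel=3)
        X, names = X[:, :-1], names[:-1]
    return X, names


def drug_sensitivity_associations(scores: CvsScoreTable,
                                  sensitivity: pd.DataFrame,
                                  tissue: pd.Series, msi: pd.Series,
                                  metric: str = "auc",
                                  min_cells: int = 8) -> pd.DataFrame:
    """Per-drug linear model Sensitivity = f(CVS, Tissue, MSI).

    Returns one row per drug with the CVS coefficient (effect size), its raw
    p value, the Benjamini–Hochberg FDR across drugs and the cell count.
    Drugs measured in fewer than ``min_cells`` cell lines are skipped.
    """
    rows = []
    for drug, grp in sensitivity.groupby("drug_id", sort=True):
        sub = pd.DataFrame({
            "y": grp.set_index("cell_line_id")[metric],
        })
        sub["cvs"] = scores.scores.reindex(sub.index)
        sub["tissue"] = tissue.reindex(sub.index)
        sub["msi"] = msi.reindex(sub.index)
        sub = sub.dropna(subset=["y", "cvs", "tissue"])
        if len(sub) < min_cells:
            continue
        X, names = _design_with_covariates(sub)
        y = sub["y"].to_numpy(float)
        coef, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = len(sub) - X.shape[1]
        if dof <= 0:
            continue
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(X.T @ X)
        j = names.index("cvs")
        se = np.sqrt(cov[j, j])
        tstat = coef[j] / se if se > 0 else 0.0
        p = 2 * sps.t.sf(abs(tstat), dof) if se > 0 else 1.0
        rows.append((drug, float(coef[j]), float(p), len(sub)))
    out = pd.DataFrame(rows, columns=["drug_id", "effect_size", "p_value",
                                      "n_cells"]).set_index("drug_id")
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


def glds(sensitivity: pd.DataFrame, metric: str = "auc") -> pd.Series:
    """Cell effects of the two-way additive Sensitivity = f(Cell, Drug) model.

    Fit by least squares with sum-to-zero constraints on both factors; the
    returned per-cell coefficients are identified up to the (absorbed)
    intercept, i.e. any common additive shift of the table leaves them
    unchanged.
    """
    df = sensitivity.dropna(subset=[metric])
    cells = sorted(df["cell_line_id"].astype(str).unique())
    drugs = sorted(df["drug_id"].astype(str).unique())
    counts_c = df["cell_line_id"].value_counts()
    counts_d = df["drug_id"].value_counts()
    if (counts_c < 2).any() or (counts_d < 2).any():
        raise ValueError("every cell and drug must appear at least twice")
    ci = {c: i for i, c in enumerate(cells)}
    di = {d: i for i, d in enumerate(drugs)}
    n = len(df)
    # effect (sum-to-zero) coding: last level = -sum of the others
    X = np.zeros((n, 1 + len(cells) - 1 + len(drugs) - 1))
    X[:, 0] = 1.0
    for r, (c, d) in enumerate(zip(df["cell_line_id"].astype(str),
                                   df["drug_id"].astype(str))):
        i = ci[c]
        if i < len(cells) - 1:
            X[r, 1 + i] = 1.0
        else:
            X[r, 1:len(cells)] = -1.0
        j = di[d]
        if j < len(drugs) - 1:
            X[r, len(cells) + j] = 1.0
        else:
            X[r, len(cells):] = -1.0
    coef, *_ = np.linalg.lstsq(X, df[metric].to_numpy(float), rcond=None)
    cell_eff = np.empty(len(cells))
    cell_eff[:-1] = coef[1:len(cells)]
    cell_eff[-1] = -cell_eff[:-1].sum()
    return pd.Series(cell_eff, index=pd.Index(cells, name="cell_line_id"),
                     name="glds")


def partial_correlation_factor(x, y, factor) -> float:
    """Pearson r between x and y after removing factor (group) means.

    Equivalent to residualizing both vectors on the one-way factor model and
    correlating the residuals.  Returns NaN with a warning when either
    residual vector has no variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    factor = np.asarray(factor)
    if len(x) < 3 or len(x) != len(y) or len(x) != len(factor):
        raise ValueError("need aligned vectors of length >= 3")
    rx, ry = x.copy(), y.copy()
    for lev in np.unique(factor):
        m = factor == lev
        rx[m] -= rx[m].mean()
        ry[m] -= ry[m].mean()
    if rx.std() == 0 or ry.std() == 0:
        warnings.warn("no within-level variance: partial correlation undefined",
                      stacklevel=2)
        return np.nan
    return float(sps.pearsonr(rx, ry)[0])


def null_signature_comparison(ds: MatchedDataset, baseline: pd.DataFrame,
                              statistic, reference_stat: float,
                              mode: str = "permute_genes",
                              n_reps: int = 100, seed: int = 0,
                              alpha: float = 1.0) -> float:
    """Empirical exceedance fraction of null signatures over the reference.

    For each replicate a null CVS model is built from ``ds`` by permuting
    gene labels (``permute_genes``) or sample labels (``permute_samples``)
    before the ridge fit, or each replicate uses a single gene's baseline
    expression as the score (``single_gene``).  ``statistic`` maps a per-cell
    score Series to a scalar (e.g. count of FDR hits, |partial r|); the
    returned value is the fraction of null statistics >= ``reference_stat``.
    """
    if mode not in ("permute_genes", "permute_samples", "single_gene"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_reps)
    zmat = _genewise_z(baseline)
    for rep in range(n_reps):
        if mode == "single_gene":
            gene = baseline.index[rng.integers(0, len(baseline.index))]
            scores = zmat.loc[gene].rename("cvs_score")
        else:
            if mode == "permute_genes":
                perm = rng.permutation(ds.X.shape[1])
                Xp = pd.DataFrame(ds.X.to_numpy()[:, perm], index=ds.X.index,
                                  columns=ds.X.columns)
                yp = ds.y
            else:
                perm = rng.permutation(len(ds))
                Xp, yp = ds.X, pd.Series(ds.y.to_numpy()[perm],
                                         index=ds.y.index)
            model = fit_ridge(MatchedDataset(Xp, yp, ds.meta.copy(),
                                             tag=f"null-{mode}-{rep}"),
                              alpha=alpha)
            scores = cvs_score(model, baseline).scores
        null_stats[rep] = statistic(scores)
    return float(np.mean(null_stats >= reference_stat))
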
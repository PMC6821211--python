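"""Ridge cell-viability-signature (CVS) models and validation harness.

The model is plain ridge regression y = X beta (alpha = 1.0, intercept
unpenalized, features not standardized: landmark z-scores already share a
scale).  Evaluation is random sub-sampling validation: 20 iterations of a
disjoint 50/50 split within a dataset, or — for across-dataset transfer —
fitting on a random half of the training dataset and scoring the Pearson
correlation between predicted and observed viability on the entire test
dataset.  Correlation is the only metric, which sidesteps the scale
mismatch between fraction viability and shRNA log fold changes.

The ID-based "standard" baseline replaces the signature features with
one-hot cell line and perturbagen identifiers (plus log10 dose for compound
data); it is a within-dataset gold standard but cannot transfer across
screens with disjoint perturbagens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr
from sklearn.linear_model import Ridge

from .matching import MatchedDataset

__all__ = ["ViabilityModel", "StandardModel", "ValidationReport",
           "fit_ridge", "fit_standard", "predict", "predict_standard",
           "validate", "save_model", "load_model"]

DEFAULT_ALPHA = 1.0
DEFAULT_N_ITER = 20


@dataclass
class ViabilityModel:
    """Per-gene ridge coefficients; the fitted CVS."""

    beta: pd.Series          # indexed by gene_id
    intercept: float
    alpha: float
    tag: str = ""

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.beta.index


@dataclass
class StandardModel:
    """Ridge over one-hot cell/perturbagen IDs (+ log10 dose for compounds)."""

    coef: np.ndarray
    intercept: float
    alpha: float
    cells: list
    perturbagens: list
    use_dose: bool
    tag: str = ""


@dataclass
class ValidationReport:
    """Per-iteration Pearson r between predicted and observed viability."""

    r_values: list = field(default_factory=list)
    mode: str = "within"
    train_tag: str = ""
    test_tag: str = ""
    n_iter: int = 0

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.r_values))


def fit_ridge(ds: MatchedDataset, alpha: float = DEFAULT_ALPHA) -> ViabilityModel:
    """Fit the CVS ridge model on a matched dataset."""
    if len(ds) < 2:
        raise ValueError("need at least 2 samples to fit")
    X = ds.X.to_numpy(dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(ds.y.to_numpy()).all():
        raise ValueError("missing/non-finite values in X or y")
    model = Ridge(alpha=alpha, fit_intercept=True, solver="cholesky")
    model.fit(X, ds.y.to_numpy())
    return ViabilityModel(pd.Series(model.coef_, index=ds.X.columns, name="beta"),
                          float(model.intercept_), alpha, tag=ds.tag)


def predict(model: ViabilityModel, X: pd.DataFrame) -> np.ndarray:
    """Apply X beta + intercept, aligning columns by gene_id."""
    missing = model.genes.difference(X.columns)
    if len(missing):
        raise ValueError(f"{len(missing)} model genes missing from input "
                         f"(e.g. {list(missing[:3])})")
    Xa = X.loc[:, model.genes].to_numpy(dtype=float)
    return Xa @ model.beta.to_numpy() + model.intercept


def _standard_design(meta: pd.DataFrame, cells, perturbagens, use_dose):
    n = len(meta)
    cols = []
    cell_idx = {c: i for i, c in enumerate(cells)}
    pert_idx = {p: i for i, p in enumerate(perturbagens)}
    C = np.zeros((n, len(cells)))
    P = np.zeros((n, len(perturbagens)))
    for r, (c, p) in enumerate(zip(meta["cell_line_id"], meta["perturbagen_id"])):
        if c in cell_idx:       # unseen IDs map to all-zero encodings
            C[r, cell_idx[c]] = 1.0
        if p in pert_idx:
            P[r, pert_idx[p]] = 1.0
    cols = [C, P]
    if use_dose:
        dose_col = meta.get("dose_signature", meta.get("dose_um"))
        cols.append(np.log10(pd.to_numeric(dose_col).to_numpy(dtype=float))
                    .reshape(-1, 1))
    return np.hstack(cols)


def fit_standard(ds: MatchedDataset, alpha: float = DEFAULT_ALPHA) -> StandardModel:
    """Fit the ID-based baseline on the same response."""
    if len(ds) < 2:
        raise ValueError("need at least 2 samples to fit")
    cells = sorted(ds.meta["cell_line_id"].astype(str).unique())
    perts = sorted(ds.meta["perturbagen_id"].astype(str).unique())
    dose_col = ds.meta.get("dose_signature", ds.meta.get("dose_um"))
    use_dose = dose_col is not None and pd.to_numeric(dose_col,
                                                      errors="coerce").notna().all()
    X = _standard_design(ds.meta, cells, perts, use_dose)
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(X, ds.y.to_numpy())
    return StandardModel(model.coef_.copy(), float(model.intercept_), alpha,
                         cells, perts, use_dose, tag=ds.tag)


def predict_standard(model: StandardModel, meta: pd.DataFrame) -> np.ndarray:
    X = _standard_design(meta, model.cells, model.perturbagens, model.use_dose)
    return X @ model.coef + model.intercept


def _safe_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        warnings.warn("degenerate variance: Pearson r undefined for this "
                      "iteration", stacklevel=3)
        return np.nan
    return float(pearsonr(pred, obs)[0])


def validate(train_ds: MatchedDataset, test_ds: MatchedDataset | None = None,
             n_iter: int = DEFAULT_N_ITER, frac: float = 0.5, seed: int = 0,
             alpha: float = DEFAULT_ALPHA,
             model: str = "signature") -> ValidationReport:
    """Random sub-sampling validation.

    ``within`` mode (``test_ds is None``): each iteration draws a disjoint
    50/50 split, fits on one half and scores Pearson r on the other.
    ``across`` mode: each iteration fits on a random half of ``train_ds``
    and scores on **all** of ``test_ds``.  Iteration i uses seed + i.
    ``model`` selects the signature ridge or the ID-based ``standard`` fit.
    """
    if model not in ("signature", "standard"):
        raise ValueError("model must be 'signature' or 'standard'")
    mode = "within" if test_ds is None else "across"
    n = len(train_ds)
    r_values = []
    for i in range(n_iter):
        rng = np.random.default_rng(seed + i)
        perm = rng.permutation(n)
        n_train = int(round(frac * n))
        tr = train_ds.X.index[perm[:n_train]]
        sub = MatchedDataset(train_ds.X.loc[tr], train_ds.y.loc[tr],
                             train_ds.meta.loc[tr], tag=train_ds.tag)
        if mode == "within":
            te = train_ds.X.index[perm[n_train:]]
            X_test, y_test = train_ds.X.loc[te], train_ds.y.loc[te]
            meta_test = train_ds.meta.loc[te]
        else:
            X_test, y_test = test_ds.X, test_ds.y
            meta_test = test_ds.meta
        if model == "signature":
            fitted = fit_ridge(sub, alpha=alpha)
            pred = predict(fitted, X_test)
        else:
            fitted = fit_standard(sub, alpha=alpha)
            pred = predict_standard(fitted, meta_test)
        r_values.append(_safe_pearson(pred, y_test.to_numpy()))
    mode_tag = mode if model == "signature" else "standard"
    return ValidationReport(r_values, mode_tag, train_ds.tag,
                            test_ds.tag if test_ds is not None else train_ds.tag,
                            n_iter)


# ---------------------------------------------------------------------------
# serialization: TSV body (gene_id, beta) with a YAML comment header
# ---------------------------------------------------------------------------

def save_model(model: ViabilityModel, path) -> None:
    header = yaml.safe_dump({"intercept": model.intercept,
                             "alpha": model.alpha, "tag": model.tag},
                            sort_keys=True).strip()
    with open(str(path), "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("gene_id\tbeta\n")
        for g, b in model.beta.items():
            fh.write(f"{g}\t{float(b)!r}\n")


def load_model(path) -> ViabilityModel:
    header_lines, body = [], []
    with open(str(path)) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
            else:
                body.append(line)
    meta = yaml.safe_load("\n".join(header_lines)) or {}
    from io import StringIO
    df = pd.read_csv(StringIO("".join(body)), sep="\t", index_col=0)
    return ViabilityModel(df["beta"], float(meta.get("intercept", 0.0)),
                          float(meta.get("alpha", DEFAULT_ALPHA)),
                          tag=str(meta.get("tag", "")))
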
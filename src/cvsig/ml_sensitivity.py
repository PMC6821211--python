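"""Random-forest drug-sensitivity prediction from consensus-signature features.

Per (cell line, drug) sensitivity (dose-response AUC, or ln IC50) is
regressed on concatenated cell-specific features (tissue one-hot plus
transcription-factor and pathway activities from standardized baseline
expression) and drug-specific features.  Drug features come in variants:
nominal-target one-hot, targeted-pathway one-hot, fingerprint bits, or
principal-component scores of MODZ consensus signatures.  Drugs are split
50/50 into train/test under three schemes — random, shared target (every
test drug has a same-target train partner) and different target (no target
spans the folds) — and performance is the per-cell Pearson correlation
between predicted and observed sensitivity, averaged over cells, across 20
resampled runs.

For the consensus variant the PCA is fit on the training-fold drugs only and
applied to the test drugs, so no fold information leaks through the
projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from .data_io import AnnotationTable
from .signature_functional import WeightedGeneSet
from .baseline_associations import _genewise_z

__all__ = ["DrugFeatures", "SplitScheme", "MlReport", "build_cell_features",
           "build_drug_features", "make_split", "fit_eval_rf"]

MAX_PCA_COMPONENTS = 40
PCA_VARIANCE_TARGET = 0.95
DEFAULT_N_TREES = 50
DEFAULT_N_RUNS = 20


@dataclass
class DrugFeatures:
    """One drug-feature variant: a drugs x features table.

    For ``kind="consensus"`` the table holds raw consensus signatures and
    the PCA projection is deferred to the fold (see :func:`fit_eval_rf`);
    :meth:`pca_scores` provides the standalone all-drug projection.
    """

    kind: str                 # target | pathway | fingerprint | consensus
    table: pd.DataFrame

    def pca_scores(self, n_components: int | None = None) -> pd.DataFrame:
        if self.kind != "consensus":
            raise ValueError("PCA scores only apply to the consensus variant")
        return _consensus_pca(self.table, self.table.index, n_components)[1]


@dataclass
class SplitScheme:
    scheme: str
    seed: int
    train_drugs: list
    test_drugs: list

    def __post_init__(self) -> None:
        if set(self.train_drugs) & set(self.test_drugs):
            raise ValueError("a drug appears in both folds")


@dataclass
class MlReport:
    per_run_mean_r: list = field(default_factory=list)
    kind: str = ""
    scheme: str = ""
    n_trees: int = DEFAULT_N_TREES
    excluded_cells: list = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        vals = [v for v in self.per_run_mean_r if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


def build_cell_features(baseline: pd.DataFrame, tissue: pd.Series,
                        tf_sets: dict, pathway_sets: dict) -> pd.DataFrame:
    """Tissue one-hot plus weighted-set activity scores per cell line.

    ``baseline`` is genes x cells; expression is standardized per gene
    (Z_gc = (E_gc - mu_g) / sigma_g, zero-variance genes -> 0) before the
    weighted-set scores (score = sum weight_g * Z_gc) are computed.
    """
    if baseline.shape[1] < 2:
        raise ValueError("need at least 2 cell lines")
    Z = _genewise_z(baseline)
    feats = pd.get_dummies(tissue.reindex(Z.columns), prefix="tissue",
                           dtype=float)

    def _score(sets: dict, prefix: str):
        for name, gs in sets.items():
            weights = gs.weights if isinstance(gs, WeightedGeneSet) else gs
            genes = [g for g in weights if g in Z.index]
            if not genes:
                continue
            wvec = np.array([weights[g] for g in genes], dtype=float)
            feats[f"{prefix}_{name}"] = wvec @ Z.loc[genes].to_numpy()

    _score(tf_sets, "tf")
    _score(pathway_sets, "pw")
    return feats


def _one_hot_labels(ann: AnnotationTable, prefix: str) -> pd.DataFrame:
    all_labels = sorted({l for s in ann.frame["labels"] for l in s})
    data = {f"{prefix}_{lab}": [float(lab in s) for s in ann.frame["labels"]]
            for lab in all_labels}
    return pd.DataFrame(data, index=ann.frame.index)


def _consensus_pca(consensus: pd.DataFrame, fit_drugs,
                   n_components: int | None = None):
    """PCA fit on ``fit_drugs`` rows, projecting all rows.

    Retains min(40, #components reaching 95% explained variance, n_fit - 1).
    """
    fit_mat = consensus.loc[fit_drugs]
    if len(fit_mat) < 2:
        raise ValueError("PCA needs at least 2 drugs")
    max_n = min(MAX_PCA_COMPONENTS, len(fit_mat) - 1, consensus.shape[1])
    pca = PCA(n_components=max_n, svd_solver="full")
    pca.fit(fit_mat.to_numpy(dtype=float))
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, PCA_VARIANCE_TARGET) + 1)
        n_components = min(n_components, max_n)
    scores = pca.transform(consensus.to_numpy(dtype=float))[:, :n_components]
    table = pd.DataFrame(scores, index=consensus.index,
                         columns=[f"pc{i + 1}" for i in range(n_components)])
    return pca, table


def build_drug_features(variant: str, annotations: AnnotationTable = None,
                        consensus: pd.DataFrame = None) -> DrugFeatures:
    """Assemble one drug-feature variant.

    ``target`` / ``pathway``: one-hot of annotation labels; ``fingerprint``:
    bit columns; ``consensus``: raw MODZ consensus signatures (drugs x
    genes) with fold-safe PCA applied downstream.
    """
    if variant in ("target", "pathway"):
        return DrugFeatures(variant, _one_hot_labels(annotations, variant))
    if variant == "fingerprint":
        bits = np.vstack(annotations.frame["fingerprint"].to_numpy())
        table = pd.DataFrame(bits.astype(float), index=annotations.frame.index,
                             columns=[f"bit{i}" for i in range(bits.shape[1])])
        return DrugFeatures(variant, table)
    if variant == "consensus":
        if consensus is None or len(consensus) < 2:
            raise ValueError("consensus variant needs >= 2 drug signatures")
        return DrugFeatures(variant, consensus)
    raise ValueError(f"unknown drug-feature variant {variant!r}")


def _target_components(drugs, targets: AnnotationTable):
    """Connected components of the shares-a-target graph (union-find)."""
    parent = {d: d for d in drugs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_label: dict = {}
    for d in drugs:
        for lab in targets.labels_of(d):
            by_label.setdefault(lab, []).append(d)
    for members in by_label.values():
        root = find(members[0])
        for m in members[1:]:
            parent[find(m)] = root
    comps: dict = {}
    for d in drugs:
        comps.setdefault(find(d), []).append(d)
    return list(comps.values())


def make_split(drugs, targets: AnnotationTable, scheme: str,
               seed: int = 0) -> SplitScheme:
    """Split drugs 50/50 into train/test under the named scheme.

    ``random``: plain shuffle.  ``shared_target``: members of every target
    class are divided between the folds so each test drug has a same-target
    train partner; singleton classes go to train with a warning.
    ``different_target``: whole target-sharing components are assigned to
    one fold, greedily balancing sizes.
    """
    drugs = list(drugs)
    rng = np.random.default_rng(seed)
    if scheme == "random":
        perm = rng.permutation(len(drugs))
        half = len(drugs) // 2
        train = [drugs[i] for i in perm[:half]]
        test = [drugs[i] for i in perm[half:]]
    elif scheme == "shared_target":
        train, test = [], []
        singletons = []
        comps = _target_components(drugs, targets)
        for comp in comps:
            if len(comp) < 2:
                singletons.extend(comp)
                continue
            perm = rng.permutation(len(comp))
            # at least one member on each side; alternate to balance
            for pos, i in enumerate(perm):
                (train if pos % 2 == 0 else test).append(comp[i])
        if singletons:
            warnings.warn(f"{len(singletons)} drugs with unshared targets "
                          "assigned to the training fold", stacklevel=2)
            train.extend(singletons)
    elif scheme == "different_target":
        comps = _target_components(drugs, targets)
        order = rng.permutation(len(comps))
        comps = sorted((comps[i] for i in order), key=len, reverse=True)
        train, test = [], []
        for comp in comps:
            (train if len(train) <= len(test) else test).extend(comp)
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    return SplitScheme(scheme, seed, sorted(train), sorted(test))


def check_split_invariants(split: SplitScheme, targets: AnnotationTable) -> None:
    """Structural leakage guards, asserted every run."""
    train, test = set(split.train_drugs), set(split.test_drugs)
    if train & test:
        raise AssertionError("drug in both folds")
    if split.scheme == "shared_target":
        for d in test:
            if not any(targets.shared_moa(d, t) for t in train):
                raise AssertionError(f"test drug {d} has no shared-target "
                                     "train partner")
    if split.scheme == "different_target":
        for d in test:
            if any(targets.shared_moa(d, t) for t in train):
                raise AssertionError(f"target of test drug {d} spans folds")


def fit_eval_rf(cell_feats: pd.DataFrame, drug_feats: DrugFeatures,
                sensitivity: pd.DataFrame, scheme: str,
                targets: AnnotationTable, metric: str = "auc",
                n_trees: int = DEFAULT_N_TREES, n_runs: int = DEFAULT_N_RUNS,
                seed: int = 0, min_test_drugs_per_cell: int = 3) -> MlReport:
    """Random-forest regression under resampled drug-level splits.

    Each run resamples the split (seed + run), fits a forest on the
    training-drug rows and reports the mean over cells of the per-cell
    Pearson correlation between predicted and observed sensitivity on the
    test-drug rows.  Cells with fewer than 3 test drugs are excluded from
    that run's average.
    """
    sens = sensitivity.dropna(subset=[metric])
    drugs = sorted(set(sens["drug_id"]) & set(drug_feats.table.index))
    excluded: list = []
    per_run = []
    for run in range(n_runs):
        split = make_split(drugs, targets, scheme, seed=seed + run)
        check_split_invariants(split, targets)
        if drug_feats.kind == "consensus":
            _, dtable = _consensus_pca(drug_feats.table, split.train_drugs)
        else:
            dtable = drug_feats.table

        def _design(rows):
            C = cell_feats.loc[rows["cell_line_id"]].to_numpy(dtype=float)
            D = dtable.loc[rows["drug_id"]].to_numpy(dtype=float)
            return np.hstack([C, D])

        train_rows = sens[sens["drug_id"].isin(split.train_drugs)]
        test_rows = sens[sens["drug_id"].isin(split.test_drugs)]
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   random_state=seed + run, n_jobs=1)
        rf.fit(_design(train_rows), train_rows[metric].to_numpy(dtype=float))
        pred = rf.predict(_design(test_rows))
        test_rows = test_rows.assign(pred=pred)
        rs = []
        for cell, grp in test_rows.groupby("cell_line_id"):
            if len(grp) < min_test_drugs_per_cell:
                excluded.append((run, cell))
                continue
            obs = grp[metric].to_numpy(dtype=float)
            prd = grp["pred"].to_numpy(dtype=float)
            if np.ptp(obs) == 0 or np.ptp(prd) == 0:
                rs.append(np.nan)  # constant predictions: r undefined
                continue
            rs.append(pearsonr(prd, obs)[0])
        finite = [r for r in rs if not np.isnan(r)]
        per_run.append(float(np.mean(finite)) if finite else np.nan)
    return MlReport(per_run, kind=drug_feats.kind, scheme=scheme,
                    n_trees=n_trees, excluded_cells=excluded)
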
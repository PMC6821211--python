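"""Signature similarity, toxicity threshold, de-confounding and evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from cvsig.data_io import AnnotationTable
from cvsig.signature_functional import (GeneViabilityStats,
                                        gene_viability_correlations)
from cvsig.similarity_moa import (auxiliary_similarity, binary_score_eval,
                                  fuse_similarities, pair_similarity_groups,
                                  pairwise_spearman, reduce_by_viability_genes,
                                  residualize_on_viability,
                                  toxicity_threshold_gmm)
from cvsig.synthetic_data import WorldConfig, build_world, simulate_compound_screen
from cvsig.matching import collapse_conditions, match_records, split_by_time
from conftest import make_sigset
from test_viability_model import make_ds


def ann_of(mapping):
    frame = pd.DataFrame({"labels": {k: frozenset(v) for k, v in
                                     mapping.items()}})
    frame.index.name = "perturbagen_id"
    return AnnotationTable(frame)


# -- pairwise Spearman ------------------------------------------------------

def test_pairwise_spearman_identities():
    row = np.array([0.3, -1.0, 2.0, 0.7])
    mat = np.vstack([row, row, -row])
    sim = pairwise_spearman(pd.DataFrame(mat))
    v = sim.values.to_numpy()
    assert v[0, 1] == pytest.approx(1.0)
    assert v[0, 2] == pytest.approx(-1.0)


def test_pairwise_spearman_matches_rank_then_pearson_oracle():
    mat = np.array([[3, 1, 4, 1], [5, 9, 2, 6], [5, 3, 5, 8]], dtype=float)
    sim = pairwise_spearman(pd.DataFrame(mat)).values.to_numpy()
    ranks = np.vstack([rankdata(r) for r in mat])
    oracle = np.corrcoef(ranks)
    assert np.allclose(sim, oracle, atol=1e-12)


# -- GMM threshold ----------------------------------------------------------

def test_gmm_threshold_recovers_mean_minus_two_sd():
    """Mixture N(1.0, 0.1^2) + N(0.3, 0.2^2): threshold tends to 0.8."""
    rng = np.random.default_rng(0)
    v = np.concatenate([rng.normal(1.0, 0.1, 4000),
                        rng.normal(0.3, 0.2, 2000)])
    thr = toxicity_threshold_gmm(v, seed=0)
    assert thr == pytest.approx(0.8, abs=0.03)


def test_gmm_collapse_falls_back():
    with pytest.warns(UserWarning):
        thr = toxicity_threshold_gmm(np.full(100, 0.95), seed=0)
    assert thr == 0.8


def test_gmm_threshold_on_synthetic_screen(compound_24h):
    thr = toxicity_threshold_gmm(compound_24h.y.to_numpy(), seed=1)
    assert 0.6 < thr < 0.95


# -- pair groups ------------------------------------------------------------

def test_pair_groups_toxicity_free_world():
    """MoA components dominate, no toxicity: shared-MoA pairs outrank random
    and the toxic group is empty."""
    rng = np.random.default_rng(1)
    m1, m2 = rng.standard_normal((2, 40))
    rows, perts = [], []
    for i in range(12):
        m = m1 if i % 2 == 0 else m2
        rows.append(3.0 * m + 0.5 * rng.standard_normal(40))
        perts.append(f"p{i}")
    ss = make_sigset(np.array(rows), perts=perts)
    sim = pairwise_spearman(ss.values)
    ann = ann_of({p: {"A" if i % 2 == 0 else "B"}
                  for i, p in enumerate(perts)})
    viab = np.full(12, 1.0)
    rep = pair_similarity_groups(sim, ss.row_meta, ann, viab, threshold=0.8)
    assert len(rep.distributions["any_cell"]["toxic_different_moa"]) == 0
    assert (rep.median("any_cell", "nontoxic_shared_moa")
            > rep.median("any_cell", "random"))
    # threshold -inf empties the toxic group without error
    rep2 = pair_similarity_groups(sim, ss.row_meta, ann, viab,
                                  threshold=-np.inf)
    assert len(rep2.distributions["any_cell"]["toxic_different_moa"]) == 0


def test_toxic_pairs_outrank_random_on_world(compound_24h, world):
    from cvsig.synthetic_data import moa_annotation
    ss = compound_24h.to_signature_set()
    sim = pairwise_spearman(ss.values)
    thr = toxicity_threshold_gmm(compound_24h.y.to_numpy(), seed=1)
    rep = pair_similarity_groups(sim, ss.row_meta, moa_annotation(world),
                                 compound_24h.y, thr)
    for scope in ("any_cell", "same_cell"):
        assert (rep.median(scope, "toxic_different_moa")
                > rep.median(scope, "random"))
        assert (rep.median(scope, "nontoxic_shared_moa")
                > rep.median(scope, "random"))


# -- reduction & residualization --------------------------------------------

def test_reduce_identity_boundary_and_count():
    rng = np.random.default_rng(2)
    ss = make_sigset(rng.standard_normal((4, 10)))
    stats = GeneViabilityStats(
        pd.Series(np.linspace(-1, 1, 10), index=ss.values.columns), n=10)
    assert reduce_by_viability_genes(ss, stats, 0) is ss
    red = reduce_by_viability_genes(ss, stats, 7)
    assert red.n_genes == 3
    with pytest.raises(ValueError):
        reduce_by_viability_genes(ss, stats, 10)
    # top-|r| genes are gone
    dropped = stats.r.abs().nlargest(7).index
    assert not set(red.values.columns) & set(dropped)


def test_reduce_700_of_978_keeps_278():
    rng = np.random.default_rng(3)
    ss = make_sigset(rng.standard_normal((3, 978)))
    stats = GeneViabilityStats(
        pd.Series(rng.uniform(-1, 1, 978), index=ss.values.columns), n=10)
    red = reduce_by_viability_genes(ss, stats, 700)
    assert red.n_genes == 278


def test_residualization_identities():
    rng = np.random.default_rng(4)
    y = rng.standard_normal(20)
    exact = 2.0 * y + 3.0
    uncorr = rng.standard_normal(20)
    X = np.column_stack([exact, uncorr])
    ds = make_ds(X, y)
    out = residualize_on_viability(ds)
    assert np.allclose(out.values.iloc[:, 0], 0.0, atol=1e-10)
    # uncorrelated gene only mean-centered (up to its tiny sample slope)
    resid = out.values.iloc[:, 1].to_numpy()
    assert np.allclose(np.corrcoef(resid, y)[0, 1], 0.0, atol=1e-10)


def test_residuals_orthogonal_to_viability_random_instance():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((20, 5))
    y = rng.standard_normal(20)
    out = residualize_on_viability(make_ds(X, y))
    yc = y - y.mean()
    corr = out.values.to_numpy().T @ yc
    assert np.max(np.abs(corr)) < 1e-10


# -- auxiliary similarities & fusion ----------------------------------------

def test_tanimoto_values():
    def fp(bits, n=6):
        v = np.zeros(n, dtype=np.uint8)
        v[list(bits)] = 1
        return v

    frame = pd.DataFrame({"labels": [frozenset({"x"})] * 3,
                          "fingerprint": [fp({1, 2, 3}), fp({2, 3, 4}),
                                          fp(set())]},
                         index=["a", "b", "c"])
    sim = auxiliary_similarity("tanimoto", AnnotationTable(frame))
    v = sim.values
    assert v.loc["a", "a"] == 1.0
    assert v.loc["a", "b"] == pytest.approx(0.5)  # 2 shared of 4 union
    assert v.loc["a", "c"] == 0.0


def test_sensitivity_profile_similarity_class_structure():
    rng = np.random.default_rng(6)
    cells = [f"c{i}" for i in range(10)]
    base_a = rng.standard_normal(10)
    base_b = rng.standard_normal(10)
    profiles = pd.DataFrame(
        [base_a + 0.1 * rng.standard_normal(10) for _ in range(3)]
        + [base_b + 0.1 * rng.standard_normal(10) for _ in range(3)],
        index=[f"d{i}" for i in range(6)], columns=cells)
    sim = auxiliary_similarity("sensitivity_profile", profiles).values
    within = [sim.iloc[0, 1], sim.iloc[0, 2], sim.iloc[3, 4]]
    between = [sim.iloc[0, 3], sim.iloc[1, 4], sim.iloc[2, 5]]
    assert np.mean(within) > np.mean(between)


def test_fusion_preserves_and_combines_rankings():
    rng = np.random.default_rng(7)
    n = 8
    a = rng.standard_normal((n, n))
    signal = (a + a.T) / 2
    np.fill_diagonal(signal, 1.0)
    ids = pd.Index([f"e{i}" for i in range(n)])
    from cvsig.similarity_moa import SimilarityMatrix
    S = SimilarityMatrix(pd.DataFrame(signal, index=ids, columns=ids), "x")
    fused_self = fuse_similarities([S, S])
    iu, ju = fused_self.offdiag_pairs()
    orig = signal[iu, ju]
    new = fused_self.values.to_numpy()[iu, ju]
    assert np.array_equal(np.argsort(orig), np.argsort(new))
    b = rng.standard_normal((n, n)) * 0.1
    noise = (b + b.T) / 2
    np.fill_diagonal(noise, 1.0)
    N = SimilarityMatrix(pd.DataFrame(noise, index=ids, columns=ids), "y")
    fused = fuse_similarities([S, N])
    from scipy.stats import spearmanr
    rho = spearmanr(orig, fused.values.to_numpy()[iu, ju])[0]
    assert rho > 0.7


# -- binary score evaluation ------------------------------------------------

def test_roc_pr_boundary_cases():
    rep = binary_score_eval([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert rep.roc_auc == 1.0
    assert rep.pr_auc == pytest.approx(1.0)
    rep4 = binary_score_eval([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0])
    assert rep4.roc_auc == pytest.approx(0.75)  # 3 of 4 concordant pairs


def test_roc_on_random_scores_is_half():
    rng = np.random.default_rng(8)
    scores = rng.standard_normal(10000)
    truth = rng.random(10000) < 0.3
    rep = binary_score_eval(scores, truth)
    assert rep.roc_auc == pytest.approx(0.5, abs=0.02)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(4, 12), st.integers(0, 10**6))
def test_roc_auc_equals_u_statistic(n, seed):
    """Tie-aware concordance count (U statistic) equals trapezoidal ROC AUC."""
    rng = np.random.default_rng(seed)
    scores = np.round(rng.standard_normal(n), 1)  # provoke ties
    truth = rng.random(n) < 0.5
    if truth.all() or not truth.any():
        truth[0] = ~truth[0]
    rep = binary_score_eval(scores, truth)
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert rep.roc_auc == pytest.approx(wins / (len(pos) * len(neg)),
                                        abs=1e-12)
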
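"""Gene-level statistics, permutation set scores, silhouette, PC1 association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from cvsig.signature_functional import (GeneViabilityStats, WeightedGeneSet,
                                        activity_vs_essentiality,
                                        gene_viability_correlations,
                                        pc_viability_association,
                                        silhouette_by_factor,
                                        weighted_set_zscore)
from test_viability_model import make_ds
from conftest import make_sigset


def test_gene_correlations_pin_to_unity():
    rng = np.random.default_rng(0)
    y = rng.standard_normal(30)
    X = np.column_stack([y, -y, rng.standard_normal(30)])
    stats = gene_viability_correlations(make_ds(X, y))
    assert stats.r.iloc[0] == pytest.approx(1.0)
    assert stats.r.iloc[1] == pytest.approx(-1.0)
    assert abs(stats.r.iloc[2]) < 1.0


def test_zero_variance_gene_flagged_r0():
    rng = np.random.default_rng(1)
    y = rng.standard_normal(20)
    X = np.column_stack([np.full(20, 3.0), y])
    stats = gene_viability_correlations(make_ds(X, y))
    assert stats.r.iloc[0] == 0.0
    assert "g0" in stats.zero_variance


def test_planted_loading_recovered_in_gene_stats(shrna_96h, world):
    """|r| ranks like |w| over genes on the shRNA screen."""
    stats = gene_viability_correlations(shrna_96h)
    rho = spearmanr(stats.r.abs(), world.w.abs())[0]
    assert rho > 0.6


def test_weighted_set_zscore_zero_weights_flagged():
    stats = GeneViabilityStats(
        pd.Series([0.5, -0.5, 0.1], index=["a", "b", "c"]), n=10)
    gs = WeightedGeneSet("null", {"a": 0.0, "b": 0.0})
    with pytest.warns(UserWarning, match="SD is 0"):
        res = weighted_set_zscore(stats, gs, n_perm=50, seed=0)
    assert res.score == 0.0
    assert res.undefined


def test_planted_axis_set_scores_extreme(shrna_96h, world):
    """The planted-w set scores far outside the permutation null; decoys not.

    Death lowers expression along -w, so gene-level r is sign-aligned with w
    and the signed-weight score is strongly positive.
    """
    stats = gene_viability_correlations(shrna_96h)
    gs = WeightedGeneSet("viability_axis", world.gene_sets["viability_axis"])
    res = weighted_set_zscore(stats, gs, n_perm=1000, seed=0)
    assert res.z > 3.0
    decoy = WeightedGeneSet("decoy0", world.gene_sets["decoy0"])
    dz = weighted_set_zscore(stats, decoy, n_perm=1000, seed=0)
    assert abs(dz.z) < 3.0


def test_zscore_matches_exhaustive_permutation_oracle():
    """5 genes: all 120 permutations enumerable; the sampled z agrees."""
    r = pd.Series([0.9, 0.1, -0.3, 0.5, -0.8],
                  index=list("abcde"))
    stats = GeneViabilityStats(r, n=50)
    weights = {"a": 1.0, "c": -2.0, "e": 0.5}
    gs = WeightedGeneSet("s", weights)
    score = sum(weights[g] * r[g] for g in weights)
    null = []
    w = np.array([1.0, -2.0, 0.5])
    for perm in itertools.permutations(r.to_numpy(), 3):
        null.append(w @ np.array(perm))
    null = np.array(null)
    z_exact = (score - null.mean()) / null.std(ddof=1)
    res = weighted_set_zscore(stats, gs, n_perm=4000, seed=1)
    assert res.score == pytest.approx(score)
    assert res.z == pytest.approx(z_exact, abs=0.2)  # sampling error


def test_zscore_invariant_to_gene_order_and_zero_weight_padding():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(40)]
    r = pd.Series(rng.uniform(-1, 1, 40), index=genes)
    stats = GeneViabilityStats(r, n=99)
    base = {"g3": 1.0, "g7": -1.0, "g11": 2.0}
    res1 = weighted_set_zscore(stats, WeightedGeneSet("s", base), 400, seed=3)
    stats_shuffled = GeneViabilityStats(r.sample(frac=1, random_state=0), n=99)
    res2 = weighted_set_zscore(stats_shuffled, WeightedGeneSet("s", base),
                               400, seed=3)
    assert res1.score == pytest.approx(res2.score)
    padded = dict(base, g20=0.0, g21=0.0)
    res3 = weighted_set_zscore(stats, WeightedGeneSet("s", padded), 400, seed=3)
    assert res3.score == pytest.approx(res1.score)


def test_activity_vs_essentiality_identities():
    v = {f"t{i}": float(i) for i in range(10)}
    assert activity_vs_essentiality(v, v) == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    a = {f"t{i}": rng.standard_normal() for i in range(100)}
    b = {f"t{i}": rng.standard_normal() for i in range(100)}
    assert abs(activity_vs_essentiality(a, b)) < 0.3
    with pytest.raises(ValueError):
        activity_vs_essentiality({"x": 1.0}, {"x": 1.0})


def test_planted_tf_essentiality_link(shrna_96h, world):
    stats = gene_viability_correlations(shrna_96h)
    acts = {t: weighted_set_zscore(stats, WeightedGeneSet(t, reg),
                                   n_perm=300, seed=0).z
            for t, reg in world.tf_regulons.items()}
    r = activity_vs_essentiality(acts, world.tf_mean_essentiality.to_dict())
    assert r > 0.5


def silhouette_oracle(E, labels):
    """Brute-force per-point silhouette with explicit loops."""
    E = np.asarray(E, float)
    labels = np.asarray(labels)
    out = []
    for i in range(len(E)):
        own = [j for j in range(len(E)) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = np.mean([np.linalg.norm(E[i] - E[j]) for j in own])
        b = min(np.mean([np.linalg.norm(E[i] - E[j])
                         for j in range(len(E)) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        out.append((b - a) / max(a, b))
    return float(np.mean(out))


def test_silhouette_separated_clusters_near_one():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 0.01, (20, 2))
    b = rng.normal(10, 0.01, (20, 2)) + 10
    E = np.vstack([a, b])
    labels = ["a"] * 20 + ["b"] * 20
    assert silhouette_by_factor(E, labels) > 0.9


def test_silhouette_random_labels_nonpositive():
    rng = np.random.default_rng(6)
    E = rng.standard_normal((200, 2))
    labels = rng.integers(0, 4, 200)
    assert silhouette_by_factor(E, labels) <= 0.05


def test_silhouette_four_point_hand_example():
    """{(0,0),(0,1)} vs {(4,0),(4,1)}: a = 1, b = (4 + sqrt(17))/2 per point."""
    E = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]])
    labels = ["l", "l", "r", "r"]
    a = 1.0
    b = (4.0 + np.sqrt(17.0)) / 2.0
    expected = (b - a) / max(a, b)
    assert silhouette_by_factor(E, labels) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(4, 12), st.integers(2, 4), st.integers(0, 10**6))
def test_silhouette_matches_bruteforce(n, k, seed):
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n, 2))
    labels = rng.integers(0, k, n)
    if len(set(labels.tolist())) < 2:
        labels[0] = 0
        labels[1] = 1
    assert silhouette_by_factor(E, labels) == pytest.approx(
        silhouette_oracle(E, labels), abs=1e-10)


def test_pc1_association_null_and_duplication():
    rng = np.random.default_rng(7)
    ss = make_sigset(rng.standard_normal((2000, 6)),
                     perts=[f"p{i}" for i in range(2000)])
    y = rng.standard_normal(2000)
    _, r = pc_viability_association(ss, y)
    assert abs(r) < 0.1
    # duplicating every row leaves the Spearman r unchanged
    vals2 = np.vstack([ss.values.to_numpy()] * 2)
    ss2 = make_sigset(vals2, perts=[f"p{i}" for i in range(4000)])
    _, r2 = pc_viability_association(ss2, np.concatenate([y, y]))
    assert r2 == pytest.approx(r, abs=1e-9)


def test_pc1_viability_association_on_world(compound_24h):
    """Sign convention points PC1 at the death direction, so the association
    with viability is negative and clearly nonzero."""
    ss = compound_24h.to_signature_set()
    _, r = pc_viability_association(ss, compound_24h.y)
    assert abs(r) > 0.2
    assert r < 0
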
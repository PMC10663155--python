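"""Network-module machinery: adjacency semantics, soft-power selection,
consensus operations, TOM against a brute-force oracle, module cutting on
planted partitions, eigenmetabolite conventions and mix-pixel projection."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from ioncoloc.netmods import (
    consensus_adjacency,
    cut_modules,
    merge_similar_modules,
    module_eigenmetabolite,
    pick_consensus_soft_power,
    project_mix,
    scale_free_fit_index,
    signed_hybrid_adjacency,
    single_quantile_normalize,
    smallest_qualifying_power,
    topological_overlap,
)


def _two_block_data(rng, n_pixels=300, block=25, noise=0.3):
    """Two independent latent factors, ``block`` features each."""
    z1, z2 = rng.normal(size=(2, n_pixels))
    X = np.empty((n_pixels, 2 * block))
    for j in range(block):
        X[:, j] = z1 + noise * rng.normal(size=n_pixels)
        X[:, block + j] = z2 + noise * rng.normal(size=n_pixels)
    truth = np.repeat([0, 1], block)
    return X, truth


# ------------------------------------------------------------------ adjacency

def test_signed_hybrid_clamps_negative_correlations():
    rng = np.random.default_rng(0)
    z = rng.normal(size=200)
    X = np.column_stack([z, -z + 0.01 * rng.normal(size=200)])
    A = signed_hybrid_adjacency(X, beta=4)
    assert A[0, 1] == 0.0
    assert A[0, 0] == 1.0


def test_signed_hybrid_power_is_applied():
    # two features correlating ~0.5: adjacency ~ 0.25 at beta = 2
    rng = np.random.default_rng(1)
    z = rng.normal(size=200_000)
    X = np.column_stack([z + rng.normal(size=z.size), z + rng.normal(size=z.size)])
    A = signed_hybrid_adjacency(X, beta=2)
    assert A[0, 1] == pytest.approx(0.25, abs=0.01)


def test_perfect_correlation_gives_unit_adjacency():
    z = np.arange(50.0)
    X = np.column_stack([z, 2 * z + 1])
    A = signed_hybrid_adjacency(X, beta=7)
    assert A[0, 1] == pytest.approx(1.0)


# ------------------------------------------------------------------ soft power

def test_power_selection_is_max_of_first_crossings():
    # runs whose fits first exceed 0.85 at powers 4, 6 and 5 -> 6
    fits = {p: [
        0.9 if p >= 4 else 0.1,
        0.9 if p >= 6 else 0.1,
        0.9 if p >= 5 else 0.1,
    ] for p in range(1, 21)}
    assert smallest_qualifying_power(fits, 0.85) == 6


def test_single_run_crossing_at_three():
    fits = {p: [0.9 if p >= 3 else 0.2] for p in range(1, 21)}
    assert smallest_qualifying_power(fits, 0.85) == 3


def test_no_qualifying_power_reports_per_run_best():
    fits = {p: [0.5, 0.6] for p in range(1, 21)}
    with pytest.raises(ValueError, match="best R2"):
        smallest_qualifying_power(fits, 0.85)


def test_raising_r2_min_never_lowers_chosen_power():
    rng = np.random.default_rng(2)
    for _ in range(20):
        fits = {p: list(rng.uniform(0, 1, 3)) for p in range(1, 21)}
        chosen = []
        for r2 in (0.2, 0.4, 0.6):
            try:
                chosen.append(smallest_qualifying_power(fits, r2))
            except ValueError:
                chosen.append(np.inf)  # stricter threshold may stop qualifying
        assert chosen == sorted(chosen)


# ------------------------------------------------------------------ consensus

def test_single_quantile_normalization_matches_reference_quantile():
    rng = np.random.default_rng(3)
    A = np.abs(rng.uniform(0, 0.8, (20, 20)))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    B = 0.5 * A.copy()
    np.fill_diagonal(B, 1.0)
    outA, outB = single_quantile_normalize([A, B], q=0.95)
    off = ~np.eye(20, dtype=bool)
    assert np.quantile(outB[off], 0.95) == pytest.approx(np.quantile(outA[off], 0.95))
    np.testing.assert_allclose(outA, A)
    assert outB[off].max() <= 1.0


def test_consensus_is_entrywise_minimum_and_bounded():
    rng = np.random.default_rng(4)
    mats = [np.abs(rng.uniform(0, 1, (10, 10))) for _ in range(3)]
    cons = consensus_adjacency(mats)
    for M in mats:
        assert np.all(cons <= M + 1e-12)
    np.testing.assert_array_equal(cons, np.minimum.reduce(mats))


# ------------------------------------------------------------------ TOM

def _tom_bruteforce(A):
    n = A.shape[0]
    k = A.sum(axis=0) - 1.0
    T = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (num + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def test_tom_matches_bruteforce_on_random_matrices():
    rng = np.random.default_rng(5)
    for _ in range(5):
        A = rng.uniform(0, 1, (10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        np.testing.assert_allclose(
            topological_overlap(A), _tom_bruteforce(A), atol=1e-10
        )


def test_tom_isolated_and_fully_connected_limits():
    A = np.eye(4)
    assert topological_overlap(A)[0, 1] == 0.0
    F = np.ones((3, 3))
    np.testing.assert_allclose(topological_overlap(F)[0, 1], 1.0)


# ------------------------------------------------------------------ cutting

def test_planted_blocks_recovered_exactly():
    rng = np.random.default_rng(6)
    X, truth = _two_block_data(rng, block=25)
    A = signed_hybrid_adjacency(X, beta=6)
    tom = topological_overlap(A)
    labels = cut_modules(tom, min_size=20, X=X)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_fewer_features_than_min_size_all_unassigned():
    tom = np.eye(10)
    with pytest.warns(UserWarning):
        labels = cut_modules(tom, min_size=20)
    assert set(labels) == {"unassigned"}


def test_cut_invariant_to_feature_order():
    rng = np.random.default_rng(7)
    X, truth = _two_block_data(rng, block=25)
    tom = topological_overlap(signed_hybrid_adjacency(X, beta=6))
    labels = cut_modules(tom, min_size=20, X=X)
    perm = rng.permutation(X.shape[1])
    tom_p = topological_overlap(signed_hybrid_adjacency(X[:, perm], beta=6))
    labels_p = cut_modules(tom_p, min_size=20, X=X[:, perm])
    assert adjusted_rand_score(labels[perm], labels_p) == 1.0


# ------------------------------------------------------------------ eigenmetabolites

def test_rank_one_module_explains_everything():
    z = np.linspace(1, 5, 60)
    X = np.column_stack([z, 3 * z])
    eig = module_eigenmetabolite(X, np.array([0, 1]))
    assert eig.var_explained == pytest.approx(1.0)
    assert abs(np.corrcoef(eig.scores, z)[0, 1]) == pytest.approx(1.0)


def test_sign_anchored_to_module_average():
    rng = np.random.default_rng(8)
    z = rng.normal(size=100)
    X = np.column_stack([z + 0.1 * rng.normal(size=100) for _ in range(4)]) + 10
    eig = module_eigenmetabolite(X, np.arange(4))
    assert np.corrcoef(eig.scores, X.mean(axis=1))[0, 1] > 0
    eig_neg = module_eigenmetabolite(-X, np.arange(4))
    assert np.corrcoef(eig_neg.scores, (-X).mean(axis=1))[0, 1] > 0


def test_scores_match_eigendecomposition_oracle():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
    eig = module_eigenmetabolite(X, np.arange(5))
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    evals, evecs = np.linalg.eigh(Z.T @ Z / 1.0)
    v = evecs[:, -1]
    scores = Z @ v
    c = np.corrcoef(scores, eig.scores)[0, 1]
    assert abs(c) == pytest.approx(1.0, abs=1e-10)
    assert eig.var_explained == pytest.approx(evals[-1] / evals.sum())


# ------------------------------------------------------------------ merging

def _correlated_module_data(rng, rho):
    """Two 3-feature modules whose latent factors correlate rho."""
    n = 4000
    z1 = rng.normal(size=n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
    X = np.column_stack(
        [z1 + 0.05 * rng.normal(size=n) for _ in range(3)]
        + [z2 + 0.05 * rng.normal(size=n) for _ in range(3)]
    )
    labels = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
    return X, labels


def test_me_correlation_above_085_merges_below_does_not():
    rng = np.random.default_rng(10)
    X_hi, labels = _correlated_module_data(rng, rho=0.95)
    merged, _ = merge_similar_modules(X_hi, labels, threshold=0.85)
    assert len(set(merged)) == 1
    X_lo, labels = _correlated_module_data(rng, rho=0.3)
    kept, _ = merge_similar_modules(X_lo, labels, threshold=0.85)
    assert len(set(kept)) == 2


def test_merge_is_transitive_closure():
    rng = np.random.default_rng(11)
    n = 4000
    z1 = rng.normal(size=n)
    z2 = 0.93 * z1 + np.sqrt(1 - 0.93**2) * rng.normal(size=n)
    z3 = 0.93 * z2 + np.sqrt(1 - 0.93**2) * rng.normal(size=n)
    # cor(z1,z3) ~ 0.86^..., engineered so A~B and B~C merge; A~C alone may not
    X = np.column_stack(
        [z + 0.05 * rng.normal(size=n) for z in (z1, z1, z2, z2, z3, z3)]
    )
    labels = np.array(["A", "A", "B", "B", "C", "C"], dtype=object)
    merged, _ = merge_similar_modules(X, labels, threshold=0.9)
    assert len(set(merged)) == 1


# ------------------------------------------------------------------ projection

def test_projection_self_consistency():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(80, 6)) + rng.normal(size=(80, 1))
    eig = module_eigenmetabolite(X, np.arange(6))
    proj = project_mix(X, eig)
    np.testing.assert_allclose(proj, eig.scores, atol=1e-10)


def test_projection_missing_column_errors():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(50, 4))
    eig = module_eigenmetabolite(X, np.arange(4))
    with pytest.raises(ValueError, match="lacks feature"):
        project_mix(X[:, :2], eig)


def test_average_linkage_matches_naive_on_four_leaves():
    rng = np.random.default_rng(14)
    D = rng.uniform(0.2, 1.0, (4, 4))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D), method="average")
    # naive average linkage: merge closest pair, distances = group means
    clusters = {i: [i] for i in range(4)}
    dist = {frozenset((i, j)): D[i, j] for i in range(4) for j in range(i + 1, 4)}
    merge_heights = []
    while len(clusters) > 1:
        pair = min(dist, key=dist.get)
        merge_heights.append(dist[pair])
        a, b = sorted(pair)
        new = max(clusters) + 1
        members = clusters.pop(a) + clusters.pop(b)
        for c in list(clusters):
            d = np.mean([D[x, y] for x in members for y in clusters[c]])
            dist[frozenset((new, c))] = d
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        clusters[new] = members
    np.testing.assert_allclose(sorted(Z[:, 2]), sorted(merge_heights), atol=1e-12)


# ------------------------------------------------------------------ pipeline-level

def test_network_never_reads_mix_pixels(small_feature_table):
    """Corrupting every mixed-clone pixel must not change the modules."""
    import copy
    from ioncoloc.netmods import detect_modules

    ft, _ = small_feature_table
    ms1 = detect_modules(ft, min_size=5, beta=6)
    ft2 = copy.deepcopy(ft)
    mix = (ft2.obs["genotype"] == "mix").to_numpy()
    rng = np.random.default_rng(0)
    ft2.X[mix] = rng.uniform(0, 1e4, ft2.X[mix].shape)
    ms2 = detect_modules(ft2, min_size=5, beta=6)
    np.testing.assert_array_equal(ms1.labels, ms2.labels)
    assert ms1.provenance["mix_pixels_used"] == 0
    for m in ms1.eigens:
        np.testing.assert_allclose(ms1.eigens[m].scores, ms2.eigens[m].scores)


def test_projected_mix_me_tracks_clone_zonation(small_feature_table):
    """The genotype-linked module's projected scores separate the true
    high/low zones of the mixed tissue (pixelwise AUC > 0.9)."""
    from sklearn.metrics import roc_auc_score
    from ioncoloc.netmods import detect_modules, project_mix

    ft, truth = small_feature_table
    ms = detect_modules(ft, min_size=5)
    # identify the detected module matching the planted genotype-linked one
    true_labels = np.array([truth.module_of(m) for m in ft.mz])
    import collections
    linked = collections.Counter(
        ms.labels[true_labels == truth.linked_module]
    ).most_common(1)[0][0]
    assert linked != "unassigned"
    genotype = ft.obs["genotype"].to_numpy()
    mix = genotype == "mix"
    scores = project_mix(ft.X[mix], ms.eigens[linked])
    run_ids = ft.obs["run_id"].to_numpy()
    # true clone of each mix pixel, via flat pixel index row * n_cols + col
    flat = []
    for r in np.unique(run_ids[mix]):
        sel = mix & (run_ids == r)
        rows = ft.obs.loc[sel, "row"].to_numpy()
        cols = ft.obs.loc[sel, "col"].to_numpy()
        _, n_cols = truth.grid_shape[r]
        flat.append(truth.true_clone[r][rows * n_cols + cols])
    clone = np.concatenate(flat)
    auc = roc_auc_score(clone == "high", scores)
    assert max(auc, 1 - auc) > 0.9
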
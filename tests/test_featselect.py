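"""Feature selectors: MI estimator, mRMR, lasso / stability selection, Fisher."""

from itertools import combinations, product

import numpy as np
import pytest

from bandnet import (
    FeatureTable,
    discretize,
    fisher_score,
    lambda_max,
    lasso_fit,
    mrmr_rank,
    mutual_information,
    sslr_rank,
)

from conftest import null_table


# ---------------------------------------------------------------------------
# discretization / MI


def test_discretize_gaussian_mid_fraction(rng):
    x = rng.standard_normal(20000)
    levels = discretize(x)
    # P(|Z| < 1) ~ 0.683
    assert (levels == 1).mean() == pytest.approx(0.683, abs=0.02)


def test_discretize_constant_single_level():
    levels = discretize(np.full(50, 3.5))
    assert set(levels) == {1}


def test_discretize_affine_invariance(rng):
    x = rng.standard_normal(500)
    np.testing.assert_array_equal(discretize(x), discretize(3.0 * x - 7.0))


def test_mi_of_identical_vector_is_entropy(rng):
    a = rng.integers(0, 3, size=300)
    counts = np.bincount(a) / len(a)
    entropy = -np.sum(counts[counts > 0] * np.log(counts[counts > 0]))
    assert mutual_information(a, a) == pytest.approx(entropy, abs=1e-12)


def test_mi_perfectly_dependent_binary_pair_is_ln2():
    a = np.array([0] * 5 + [1] * 5)
    assert mutual_information(a, a.copy()) == pytest.approx(np.log(2), abs=1e-12)


def test_mi_independent_large_sample_near_zero(rng):
    a = rng.integers(0, 2, size=30000)
    b = rng.integers(0, 2, size=30000)
    mi = mutual_information(a, b)
    assert 0 <= mi < 5e-4


def test_mi_nonnegative_random_tables(rng):
    for _ in range(20):
        a = rng.integers(0, 3, size=60)
        b = rng.integers(0, 4, size=60)
        assert mutual_information(a, b) >= -1e-15


# ---------------------------------------------------------------------------
# mRMR


def test_first_mrmr_pick_is_max_relevance(rng):
    X = rng.standard_normal((80, 6))
    y = np.where(rng.random(80) < 0.5, 1, -1)
    X[:, 3] += 2.0 * y  # dominant relevance
    table = FeatureTable(X, y)
    ranking = mrmr_rank(table, 3)
    assert ranking.order[0] == 3
    rel = [mutual_information(discretize(X[:, j]), (y > 0).astype(int)) for j in range(6)]
    assert ranking.order[0] == int(np.argmax(rel))


def test_duplicate_feature_ranked_below_non_redundant_one(rng):
    y = np.where(rng.random(120) < 0.5, 1, -1)
    strong = 1.5 * y + 0.3 * rng.standard_normal(120)
    other = 1.0 * y + 0.8 * rng.standard_normal(120)
    noise = rng.standard_normal(120)
    X = np.column_stack([strong, strong.copy(), other, noise])
    ranking = mrmr_rank(FeatureTable(X, y))  # rank all four
    assert ranking.order[0] == 0          # strongest feature first
    order = list(ranking.order)
    assert order.index(2) < order.index(1)  # duplicate penalized below `other`


def oa_instance(rng, n_rep=2):
    """Random instance on a GF(3) orthogonal array: 5 pairwise-balanced
    ternary columns (27 runs, replicated), so every pairwise MI is exactly 0
    and greedy mRMR provably equals exhaustive subset search."""
    coeffs = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1)]
    runs = np.array(list(product(range(3), repeat=3)))
    cols = np.array([[sum(c * r for c, r in zip(co, run)) % 3 for co in coeffs] for run in runs])
    cols = np.tile(cols, (n_rep, 1)).astype(float)
    cols = cols[:, rng.permutation(5)]
    cols += rng.uniform(-0.05, 0.05, size=cols.shape)  # jitter below level gaps
    y = np.where(rng.random(len(cols)) < 0.5, 1, -1)
    return FeatureTable(cols, y)


def subset_objective(table, subset):
    """Mean relevance minus mean pairwise redundancy of a feature subset."""
    disc = {j: discretize(table.X[:, j]) for j in subset}
    yy = (table.y > 0).astype(int)
    d = np.mean([mutual_information(disc[i], yy) for i in subset])
    r = sum(
        mutual_information(disc[i], disc[j]) for i in subset for j in subset if i != j
    ) / len(subset) ** 2
    return d - r


def exhaustive_mrmr(table, k):
    """Brute-force maximum of the subset objective over all k-subsets."""
    best_val, best = -np.inf, None
    for sub in combinations(range(table.n_features), k):
        v = subset_objective(table, sub)
        if v > best_val:
            best_val, best = v, set(sub)
    return best, best_val


def test_mrmr_equals_exhaustive_on_zero_redundancy_instances(rng):
    """With exactly zero pairwise redundancy the greedy selection provably
    attains the exhaustive subset optimum (value equality guards against
    float-epsilon relevance ties between balanced columns)."""
    for _ in range(10):
        table = oa_instance(rng)
        greedy = mrmr_rank(table, 3).order.tolist()
        best, best_val = exhaustive_mrmr(table, 3)
        assert subset_objective(table, tuple(greedy)) == pytest.approx(best_val, abs=1e-9)


def test_greedy_mrmr_usually_finds_set_optimum(rng):
    """On generic correlated instances the first-order greedy search is an
    approximation to the NP-hard subset objective; it should coincide with
    the exhaustive optimum in a clear majority of random instances."""
    agree = 0
    n_trials = 40
    for _ in range(n_trials):
        X = rng.standard_normal((50, 5))
        y = np.where(rng.random(50) < 0.5, 1, -1)
        X[:, 0] += 0.9 * y
        X[:, 1] += 0.6 * y
        table = FeatureTable(X, y)
        greedy = set(mrmr_rank(table, 3).order.tolist())
        agree += greedy == exhaustive_mrmr(table, 3)[0]
    assert agree / n_trials >= 0.6


def test_mrmr_feature_permutation_equivariance(rng):
    table = null_table(rng, n=40, m=8)
    perm = rng.permutation(8)
    permuted = FeatureTable(table.X[:, perm], table.y)
    orig = mrmr_rank(table, 5).order
    new = mrmr_rank(permuted, 5).order
    np.testing.assert_array_equal([int(perm[j]) for j in new], orig)


# ---------------------------------------------------------------------------
# lasso


def test_univariate_lasso_matches_soft_threshold(rng):
    x = rng.standard_normal(60)
    y = 0.8 * x + 0.4 * rng.standard_normal(60)
    xs = (x - x.mean()) / x.std()
    for lam in (0.05, 0.2, 0.5):
        w = lasso_fit(x[:, None], y, lam)
        rho = xs @ y / len(y)
        expect = np.sign(rho) * max(abs(rho) - lam / 2.0, 0.0)
        assert w[0] == pytest.approx(expect, abs=1e-8)


def test_lambda_above_lambda_max_gives_zero_vector(rng):
    X = rng.standard_normal((40, 6))
    y = np.where(rng.random(40) < 0.5, 1.0, -1.0)
    lam = lambda_max(X, y)
    assert np.all(lasso_fit(X, y, lam * 1.0001) == 0.0)
    assert np.any(lasso_fit(X, y, lam * 0.5) != 0.0)


def test_lasso_objective_not_worse_than_zero_solution(rng):
    X = rng.standard_normal((50, 8))
    y = X[:, 0] - 0.5 * X[:, 3] + 0.2 * rng.standard_normal(50)
    lam = 0.1
    w = lasso_fit(X, y, lam)
    Xs = (X - X.mean(0)) / X.std(0)
    obj = lambda w_: np.mean((Xs @ w_ - y) ** 2) + lam * np.abs(w_).sum()
    assert obj(w) <= obj(np.zeros(8)) + 1e-12


def test_lasso_rejects_nonpositive_penalty(rng):
    X = rng.standard_normal((10, 2))
    with pytest.raises(ValueError):
        lasso_fit(X, np.ones(10), 0.0)


# ---------------------------------------------------------------------------
# stability selection


def test_sslr_constant_feature_scored_zero_and_last(rng):
    X = rng.standard_normal((40, 5))
    y = np.where(X[:, 0] + 0.3 * rng.standard_normal(40) > 0, 1, -1)
    X[:, 4] = 2.0  # constant -> coefficient always exactly 0
    ranking = sslr_rank(FeatureTable(X, y), n_subsamples=20, seed=0)
    assert ranking.order[-1] == 4
    assert ranking.scores[-1] == 0.0


def test_sslr_strong_feature_has_high_stability(rng):
    y = np.where(rng.random(60) < 0.5, 1, -1)
    X = rng.standard_normal((60, 12))
    X[:, 5] = y + 0.45 * rng.standard_normal(60)  # r ~ 0.9 with labels
    ranking = sslr_rank(FeatureTable(X, y), n_subsamples=30, seed=1)
    assert ranking.order[0] == 5
    assert ranking.scores[0] >= 0.9


def test_sslr_permuted_labels_drop_signal_feature_stability(rng):
    """Permuting labels collapses the stability of the (formerly) predictive
    feature toward the chance level of its peers."""
    y = np.where(rng.random(60) < 0.5, 1, -1)
    X = rng.standard_normal((60, 80))
    X[:, 5] = y + 0.45 * rng.standard_normal(60)

    def score_of(ranking, feature):
        return float(ranking.scores[list(ranking.order).index(feature)])

    signal = sslr_rank(FeatureTable(X, y), n_subsamples=30, seed=2)
    assert signal.order[0] == 5
    perm = rng.permutation(60)
    null = sslr_rank(FeatureTable(X, y[perm]), n_subsamples=30, seed=2)
    assert score_of(null, 5) < score_of(signal, 5)
    # under the null the former signal feature is unremarkable among peers
    assert score_of(null, 5) <= np.quantile(null.scores, 0.95)


def test_sslr_deterministic_given_seed(rng):
    table = null_table(rng, n=30, m=10)
    a = sslr_rank(table, n_subsamples=15, seed=7)
    b = sslr_rank(table, n_subsamples=15, seed=7)
    np.testing.assert_array_equal(a.order, b.order)
    np.testing.assert_array_equal(a.scores, b.scores)


# ---------------------------------------------------------------------------
# Fisher Score


def test_fisher_score_hand_example():
    X = np.array([[1.0], [2.0], [3.0], [5.0], [6.0], [7.0]])
    y = np.array([1, 1, 1, -1, -1, -1])
    ranking = fisher_score(FeatureTable(X, y))
    assert ranking.scores[0] == pytest.approx(6.0, abs=1e-12)


def test_fisher_zero_for_equal_class_means(rng):
    x = np.concatenate([rng.standard_normal(20), rng.standard_normal(20)])
    x[:20] -= x[:20].mean()
    x[20:] -= x[20:].mean()
    y = np.array([1] * 20 + [-1] * 20)
    ranking = fisher_score(FeatureTable(x[:, None], y))
    assert ranking.scores[0] == pytest.approx(0.0, abs=1e-20)


def test_fisher_scale_invariance(rng):
    table = null_table(rng, n=30, m=6)
    scaled = FeatureTable(table.X * 17.3, table.y)
    np.testing.assert_allclose(fisher_score(table).scores, fisher_score(scaled).scores, rtol=1e-10)
    np.testing.assert_array_equal(fisher_score(table).order, fisher_score(scaled).order)


def test_fisher_zero_variance_nonzero_gap_ranked_first(rng):
    X = rng.standard_normal((20, 3))
    y = np.array([1] * 10 + [-1] * 10)
    X[:10, 2] = 1.0
    X[10:, 2] = 2.0  # zero within-class variance, nonzero gap
    ranking = fisher_score(FeatureTable(X, y))
    assert ranking.order[0] == 2
    assert np.isinf(ranking.scores[0])


def test_fisher_single_class_rejected(rng):
    with pytest.raises(ValueError):
        fisher_score(FeatureTable(rng.standard_normal((10, 2)), np.ones(10, dtype=int)))
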
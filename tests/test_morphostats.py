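"""Statistics against independent textbook/brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from optmorph.morphostats import (
    bonferroni,
    group_mean_distance,
    interlandmark_distance,
    linear_r2,
    mann_whitney_u,
    one_way_anova,
    pca,
    permutation_test,
    pls_two_block,
    rv_coefficient,
    shape_from_scores,
    welch_t,
)
from optmorph.procrustes import gpa
from optmorph.synthetic import SyntheticSpec, make_limb_bud


# ---------------------------------------------------------------------------
# textbook oracles (independent implementations)
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all rank assignments."""
    na = len(a)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0

    def u_of(idx_a):
        ra = ranks[list(idx_a)].sum()
        return ra - na * (na + 1) / 2

    observed = u_of(range(na))
    n2 = len(pooled) * 1.0
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), na)]
    mean_u = na * (len(b)) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(observed - mean_u))
    return observed, extreme / len(us)


def anova_oracle(groups):
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    from scipy.stats import f as fdist
    return f, fdist.sf(f, df1, df2)


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def test_welch_identical_and_example():
    a = [1.0, 2.0, 3.0]
    res = welch_t(a, list(a))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)

    res = welch_t([10, 11, 12, 13], [20, 21, 22, 23])
    assert res.statistic == pytest.approx(-10.9545, abs=1e-3)
    assert res.df == pytest.approx(6.0)


def test_welch_matches_oracle_seeded():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1 + rng.random(), size=rng.integers(3, 12))
        b = rng.normal(rng.normal(), 2, size=rng.integers(3, 12))
        res = welch_t(a, b)
        t, df, p = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-9)
        assert res.df == pytest.approx(df, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)


def test_mwu_example_and_degenerate():
    res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 6, rel=1e-9)
    assert mann_whitney_u([5.0], [5.0]).p_value == 1.0


def test_mwu_matches_enumeration_oracle():
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        a = rng.permutation(100)[: rng.integers(2, 6)].astype(float)
        b = rng.permutation(100)[100 - rng.integers(2, 6):].astype(float)
        if len(np.unique(np.concatenate([a, b]))) < len(a) + len(b):
            continue
        res = mann_whitney_u(a, b, mode="exact")
        u, p = mwu_enumeration_oracle(a, b)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p, abs=1e-3)


def test_anova_identical_groups_and_t_squared(rng):
    g = [1.0, 2.0, 3.0, 4.0]
    res = one_way_anova([g, list(g)])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)

    a, b = rng.normal(size=8), rng.normal(1, 1, size=8)
    f = one_way_anova([a, b]).statistic
    # pooled-variance two-sample t squared equals F for two groups
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    assert f == pytest.approx(t ** 2, rel=1e-9)


def test_anova_matches_sum_of_squares_oracle():
    for seed in range(100):
        rng = np.random.default_rng(2000 + seed)
        groups = [rng.normal(rng.normal(), 1, size=rng.integers(3, 9))
                  for _ in range(3)]
        res = one_way_anova(groups)
        f, p = anova_oracle(groups)
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0]])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_single_axis_and_rank():
    data = np.zeros((6, 4))
    data[:, 2] = np.arange(6.0)
    res = pca(data)
    assert res.percent_variance[0] == pytest.approx(100.0)
    assert pca(np.random.default_rng(0).normal(size=(2, 5))).eigenvalues[1:].max() < 1e-12


def test_pca_matches_eigendecomposition_oracle():
    for seed in range(100):
        rng = np.random.default_rng(3000 + seed)
        data = rng.normal(size=(10, 6))
        res = pca(data)
        cov = np.cov(data, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.abs(res.eigenvalues - evals[: len(res.eigenvalues)]).max() < 1e-9
        # trace identity: total variance conserved
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov), rel=1e-9)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-9


def test_pca_validation():
    with pytest.raises(ValueError):
        pca(np.zeros((1, 3)))


# ---------------------------------------------------------------------------
# PLS and RV
# ---------------------------------------------------------------------------

def test_pls_percent_covariation_from_constructed_singular_values(rng):
    n = 9
    raw = rng.normal(size=(n, 2))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    x = q * np.sqrt(n - 1)
    y = q @ np.diag([3.0, 1.0]) * np.sqrt(n - 1)
    res = pls_two_block(x, y, n_permutations=99, seed=0)
    assert np.allclose(res.singular_values, [3.0, 1.0], atol=1e-9)
    assert np.allclose(res.percent_covariation, [90.0, 10.0], atol=1e-9)


def test_pls_y_equals_x_gives_rv_one(rng):
    x = rng.normal(size=(12, 5))
    res = pls_two_block(x, x.copy(), n_permutations=99, seed=1)
    assert res.rv == pytest.approx(1.0)


def test_pls_matches_svd_oracle():
    for seed in range(100):
        rng = np.random.default_rng(4000 + seed)
        x = rng.normal(size=(11, 5))
        y = rng.normal(size=(11, 4))
        res = pls_two_block(x, y, n_permutations=99, seed=0)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        cov = np.zeros((5, 4))
        for i in range(11):                # explicit outer-product oracle
            cov += np.outer(xc[i], yc[i])
        cov /= 10
        d = np.linalg.svd(cov, compute_uv=False)
        assert np.abs(res.singular_values - d).max() < 1e-9
        assert res.percent_covariation.sum() == pytest.approx(100.0, abs=1e-9)


def test_rv_oracle_and_invariances(rng):
    for seed in range(100):
        r = np.random.default_rng(5000 + seed)
        x = r.normal(size=(9, 4))
        y = r.normal(size=(9, 3))
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        sxy = xc.T @ yc
        oracle = np.trace(sxy @ sxy.T) / np.sqrt(
            np.trace((xc.T @ xc) @ (xc.T @ xc))
            * np.trace((yc.T @ yc) @ (yc.T @ yc))
        )
        assert rv_coefficient(x, y) == pytest.approx(oracle, rel=1e-9)

    x = rng.normal(size=(10, 4))
    y = rng.normal(size=(10, 4))
    base = rv_coefficient(x, y)
    assert rv_coefficient(y, x) == pytest.approx(base, rel=1e-12)
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    assert rv_coefficient(x @ q, y) == pytest.approx(base, rel=1e-9)
    assert rv_coefficient(5.0 * x, 0.1 * y) == pytest.approx(base, rel=1e-9)
    assert 0.0 <= base <= 1.0


def test_rv_full_rank_self_is_one(rng):
    x = rng.normal(size=(10, 4))
    assert rv_coefficient(x, x) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_maximal_statistic(rng):
    x = rng.normal(size=(30, 4))
    p = permutation_test(rv_coefficient, x, x.copy(), n_permutations=999, seed=0)
    assert p == pytest.approx(1 / 1000)


def test_permutation_seed_reproducible(rng):
    x = rng.normal(size=(15, 3))
    y = rng.normal(size=(15, 3))
    p1 = permutation_test(rv_coefficient, x, y, n_permutations=199, seed=42)
    p2 = permutation_test(rv_coefficient, x, y, n_permutations=199, seed=42)
    assert p1 == p2


def test_permutation_degenerate_statistic(rng):
    x = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="degenerate"):
        permutation_test(lambda a, b: 1.0, x, x, n_permutations=99, seed=0)


# ---------------------------------------------------------------------------
# the rest of the toolbox
# ---------------------------------------------------------------------------

def test_bonferroni():
    adjusted, flags = bonferroni([0.01], m=20)
    assert adjusted[0] == pytest.approx(0.2)
    adjusted, _ = bonferroni([0.9], m=5)
    assert adjusted[0] == 1.0
    p = [0.001, 0.02, 0.5]
    _, flags = bonferroni(p, alpha=0.05)
    assert list(flags) == [pv <= 0.05 / 3 for pv in p]
    with pytest.raises(ValueError):
        bonferroni([1.5])


def test_linear_r2(rng):
    x = np.arange(10.0)
    res = linear_r2(x, 2 * x + 1)
    assert res["r2"] == pytest.approx(1.0)
    assert res["slope"] == pytest.approx(2.0)

    x = rng.normal(size=50)
    y = 1.5 * x + rng.normal(size=50)
    res = linear_r2(x, y)
    assert res["r2"] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-12)
    with pytest.raises(ValueError):
        linear_r2(np.ones(5), np.arange(5.0))


def test_interlandmark_distance(rng):
    config = np.array([[0, 0, 0], [3, 4, 0.0]])
    assert interlandmark_distance(config, 0, 1) == pytest.approx(5.0)
    assert interlandmark_distance(config, 0, 0) == 0.0
    pts = rng.normal(size=(6, 3))
    assert interlandmark_distance(pts, 1, 4) == pytest.approx(
        np.linalg.norm(pts[1] - pts[4])
    )
    with pytest.raises(IndexError):
        interlandmark_distance(config, 0, 5)


def test_shape_from_scores_reconstruction(rng):
    data = rng.normal(size=(8, 15))        # 5 landmarks x 3
    res = pca(data)
    base = res.mean.reshape(-1, 3)
    i = 3
    rebuilt = shape_from_scores(res.loadings, base, res.scores[i])
    assert np.abs(rebuilt.ravel() - data[i]).max() < 1e-9
    assert np.array_equal(
        shape_from_scores(res.loadings, base, np.zeros(res.scores.shape[1])),
        base,
    )
    plus = shape_from_scores(res.loadings[:, :1], base, [0.5])
    minus = shape_from_scores(res.loadings[:, :1], base, [-0.5])
    assert np.allclose((plus + minus) / 2, base)
    with pytest.raises(ValueError):
        shape_from_scores(res.loadings, base, np.zeros(99))


# ---------------------------------------------------------------------------
# parameter recovery on synthetic two-group shape data
# ---------------------------------------------------------------------------

def group_pc1_separation(effect, n=8, seed=0):
    """Standardized PC1 distance between group means of synthetic buds."""
    rng = np.random.default_rng(seed)
    sets, labels = [], []
    for group in ("wildtype", "mutant"):
        for _ in range(n):
            spec = SyntheticSpec(stage=1.0, group_effect=effect, noise_sd=6.0,
                                 seed=int(rng.integers(2 ** 31)))
            _, lms = make_limb_bud(spec, group)
            sets.append(lms.points)
            labels.append(group)
    res = gpa(sets)
    scores = pca(res.aligned.reshape(len(sets), -1)).scores[:, 0]
    labels = np.array(labels)
    a, b = scores[labels == "wildtype"], scores[labels == "mutant"]
    pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    return abs(a.mean() - b.mean()) / pooled_sd


def test_group_separation_grows_with_planted_effect():
    seps = [group_pc1_separation(e) for e in (0.0, 0.75, 1.5)]
    assert seps[0] < 1.0          # overlap at zero effect
    assert seps[0] < seps[1] < seps[2]
    assert seps[2] > 3.0          # clear separation at large effect


def test_group_mean_distance_statistic(rng):
    labels = np.array(["a"] * 5 + ["b"] * 5)
    data = np.vstack([np.zeros((5, 3)), np.ones((5, 3))])
    assert group_mean_distance(labels, data) == pytest.approx(np.sqrt(3))
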
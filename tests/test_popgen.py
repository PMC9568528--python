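"""Structure statistics against independent oracles and known equivalences."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f_oneway

import selmort as sm
from selmort.cohort import MISSING


# ---------------------------------------------------------------------- #
# Weir-Cockerham theta


def wc_oracle_two_pops(counts_a, counts_b) -> float:
    """Scalar Weir & Cockerham (1984) theta from genotype counts (AA, Aa, aa),
    written independently of the vectorized implementation."""
    n_a = sum(counts_a)
    n_b = sum(counts_b)
    r = 2
    p_a = (2 * counts_a[0] + counts_a[1]) / (2 * n_a)
    p_b = (2 * counts_b[0] + counts_b[1]) / (2 * n_b)
    h_a = counts_a[1] / n_a
    h_b = counts_b[1] / n_b
    nbar = (n_a + n_b) / 2
    nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1)
    pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
    s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n_a * h_a + n_b * h_b) / (r * nbar)
    a = nbar / nc * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def counts_to_genotypes(counts) -> np.ndarray:
    return np.array([0] * counts[0] + [1] * counts[1] + [2] * counts[2])[:, None]


def test_theta_zero_for_identical_frequency_groups():
    g = counts_to_genotypes((25, 50, 25))
    res = sm.weir_cockerham_fst(g, g.copy())
    assert res.theta <= 0 and abs(res.theta) < 0.01


def test_theta_one_for_fixed_difference():
    res = sm.weir_cockerham_fst(
        np.zeros((20, 1), dtype=int), np.full((20, 1), 2)
    )
    assert res.theta == pytest.approx(1.0)


@pytest.mark.parametrize(
    "counts_a,counts_b",
    [
        ((10, 10, 0), (0, 10, 10)),
        ((30, 15, 5), (5, 20, 25)),
        ((8, 4, 0), (2, 6, 12)),
    ],
)
def test_theta_matches_textbook_oracle(counts_a, counts_b):
    res = sm.weir_cockerham_fst(
        counts_to_genotypes(counts_a), counts_to_genotypes(counts_b)
    )
    assert res.theta == pytest.approx(wc_oracle_two_pops(counts_a, counts_b), abs=1e-10)


def test_theta_ignores_missing_calls():
    g_a = counts_to_genotypes((10, 10, 0))
    g_b = counts_to_genotypes((0, 10, 10))
    g_a2 = np.vstack([g_a, np.full((5, 1), MISSING)])
    res = sm.weir_cockerham_fst(g_a2, g_b)
    assert res.theta == pytest.approx(
        sm.weir_cockerham_fst(g_a, g_b).theta, abs=1e-12
    )


def test_no_polymorphic_locus_raises():
    g = np.zeros((10, 2), dtype=int)
    with pytest.raises(ValueError, match="polymorphic"):
        sm.weir_cockerham_fst(g, g.copy())


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_theta_invariant_to_allele_label_swap(seed):
    rng = np.random.default_rng(seed)
    g_a = rng.binomial(2, rng.uniform(0.1, 0.9, 6), size=(12, 6)).astype(np.int8)
    g_b = rng.binomial(2, rng.uniform(0.1, 0.9, 6), size=(15, 6)).astype(np.int8)
    try:
        t1 = sm.weir_cockerham_fst(g_a, g_b).theta
    except ValueError:
        return  # all loci monomorphic in this draw
    t2 = sm.weir_cockerham_fst(2 - g_a, 2 - g_b).theta
    assert t1 == pytest.approx(t2, abs=1e-12)
    assert t1 <= 1.0


def test_multiallelic_theta_agrees_with_biallelic_coding():
    """On biallelic data the per-allele summed estimator equals the
    alt-allele-only biallelic path."""
    rng = np.random.default_rng(1)
    g_a = rng.binomial(2, rng.uniform(0.2, 0.8, 5), size=(14, 5)).astype(np.int8)
    g_b = rng.binomial(2, rng.uniform(0.2, 0.8, 5), size=(11, 5)).astype(np.int8)

    def to_alleles(g):
        a1 = (g == 2).astype(np.int8)
        a2 = (g >= 1).astype(np.int8)
        return np.stack([a1, a2], axis=2)

    t_bi = sm.weir_cockerham_fst(g_a, g_b).theta
    t_multi = sm.weir_cockerham_fst_alleles(to_alleles(g_a), to_alleles(g_b)).theta
    assert t_bi == pytest.approx(t_multi, abs=1e-10)


def test_fst_permutation_identical_groups_p_is_one():
    g = counts_to_genotypes((10, 20, 10))
    g2 = np.hstack([g, g[::-1]])
    p, _ = sm.fst_permutation_test(g2, g2.copy(), n_perm=199, seed=0)
    assert p == pytest.approx(1.0)


def test_fst_permutation_fixed_difference_p_is_minimal():
    p, res = sm.fst_permutation_test(
        np.zeros((20, 5), dtype=int), np.full((20, 5), 2), n_perm=999, seed=1
    )
    assert res.theta == pytest.approx(1.0)
    assert p == pytest.approx(1 / 1000)


# ---------------------------------------------------------------------- #
# PERMANOVA


def test_univariate_euclidean_pseudo_f_equals_anova_f():
    rng = np.random.default_rng(0)
    y = rng.normal(size=30)
    groups = np.repeat(["a", "b", "c"], 10)
    res = sm.permanova(y, pd.Series(groups, name="grp"), n_perm=49, seed=1)
    f_ref = f_oneway(y[:10], y[10:20], y[20:]).statistic
    assert res.table.loc["grp", "pseudo_f"] == pytest.approx(f_ref, rel=1e-12)


def test_identical_group_multisets_show_no_effect():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.concatenate([vals, vals])
    groups = pd.Series(np.repeat(["g1", "g2"], 4), name="grp")
    res = sm.permanova(y, groups, n_perm=499, seed=2)
    assert res.table.loc["grp", "r2"] == pytest.approx(0.0, abs=1e-12)
    assert res.table.loc["grp", "p_value"] > 0.5


def test_sequential_ss_matches_classical_type_i_anova():
    """2x2 design (unbalanced): sequential distance-based SS must equal the
    classical type-I ANOVA decomposition for a univariate Euclidean response."""
    import statsmodels.api as sma
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(5)
    n = 15
    age = np.array((["s"] * 4 + ["v"] * 4) * 2)[:n]
    loc = np.repeat(["N", "S"], 8)[:n]
    y = rng.normal(size=n) + (age == "v") * 0.8 + (loc == "S") * 0.5
    df = pd.DataFrame({"y": y, "age": age, "loc": loc})
    ref = sma.stats.anova_lm(smf.ols("y ~ age*loc", data=df).fit(), typ=1)
    res = sm.permanova(y, df[["age", "loc"]], n_perm=9, seed=1)
    assert res.table.loc["age", "ss"] == pytest.approx(ref.loc["age", "sum_sq"])
    assert res.table.loc["loc", "ss"] == pytest.approx(ref.loc["loc", "sum_sq"])
    assert res.table.loc["age x loc", "ss"] == pytest.approx(
        ref.loc["age:loc", "sum_sq"]
    )
    assert res.table.loc["Residual", "ss"] == pytest.approx(
        ref.loc["Residual", "sum_sq"]
    )


def test_r2_partition_sums_to_one_and_df_to_n_minus_one():
    rng = np.random.default_rng(3)
    y = rng.normal(size=(24, 3))
    factors = pd.DataFrame(
        {
            "age": np.tile(np.repeat(["s", "v"], 6), 2),
            "loc": np.repeat(["N", "S"], 12),
        }
    )
    res = sm.permanova(y, factors, n_perm=49, seed=0)
    terms = res.table.drop(index="Total")
    assert terms["r2"].sum() == pytest.approx(1.0)
    assert terms["df"].sum() == 24 - 1


def test_permanova_against_vegan_adonis2(tmp_path):
    """Cross-check the full sequential table against vegan's adonis2."""
    rng = np.random.default_rng(7)
    n = 16
    age = np.tile(np.repeat(["s", "v"], 4), 2)
    loc = np.repeat(["N", "S"], 8)
    y = rng.normal(size=n) + (age == "v") * 1.0
    df = pd.DataFrame({"y": y, "age": age, "loc": loc})
    csv = tmp_path / "resp.csv"
    df.to_csv(csv, index=False)
    r_code = (
        "suppressMessages(library(vegan));"
        f"d <- read.csv('{csv}');"
        "a <- adonis2(d['y'] ~ age*loc, data=d, method='euclidean',"
        "permutations=99, by='terms');"
        "cat(a$SumOfSqs, a$F, sep='\\n')"
    )
    proc = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        pytest.fail(f"Rscript/vegan oracle failed: {proc.stderr[-500:]}")
    values = [float(v) for v in proc.stdout.split() if v not in ("NA",)]
    ss_ref = values[:4]  # age, loc, age:loc, residual
    res = sm.permanova(y, df[["age", "loc"]], n_perm=9, seed=1)
    got = [
        res.table.loc["age", "ss"],
        res.table.loc["loc", "ss"],
        res.table.loc["age x loc", "ss"],
        res.table.loc["Residual", "ss"],
    ]
    assert got == pytest.approx(ss_ref, rel=1e-6)


def test_degenerate_response_raises():
    with pytest.raises(ValueError, match="degenerate"):
        sm.permanova(
            np.ones(8), pd.Series(np.repeat(["a", "b"], 4), name="g"), n_perm=9
        )


def test_permanova_null_pvalues_roughly_uniform():
    """Under a pure-noise response, permutation p-values populate their grid
    uniformly (coarse 3-bin check, seeded replicates)."""
    rng = np.random.default_rng(11)
    pvals = []
    for rep in range(120):
        y = rng.normal(size=18)
        groups = pd.Series(np.repeat(["a", "b", "c"], 6), name="g")
        res = sm.permanova(y, groups, n_perm=99, seed=rep)
        pvals.append(res.table.loc["g", "p_value"])
    pvals = np.array(pvals)
    for lo, hi in [(0.0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.0001)]:
        frac = ((pvals > lo) & (pvals <= hi)).mean()
        assert 0.15 <= frac <= 0.55


# ---------------------------------------------------------------------- #
# DAPC


def test_dapc_default_retains_one_third_of_individuals():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.normal(size=(105, 60)))
    groups = pd.Series(np.repeat(["a", "b", "c"], 35))
    res = sm.dapc(x, groups)
    assert res.n_pcs == 35


def test_dapc_perfectly_separated_groups():
    rng = np.random.default_rng(1)
    x = rng.binomial(2, 0.5, size=(40, 30)).astype(float)
    x[:20, :10] = 0.0
    x[20:, :10] = 2.0  # disjoint fixed alleles at 10 loci
    groups = pd.Series(np.repeat(["g1", "g2"], 20))
    res = sm.dapc(pd.DataFrame(x), groups, n_pcs=10)
    predicted = res.posterior.idxmax(axis=1).to_numpy()
    assert (predicted == groups.to_numpy()).all()
    assert np.allclose(res.posterior.sum(axis=1), 1.0)


def test_dapc_with_all_pcs_matches_fisher_lda_direction():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(2)
    x = rng.normal(size=(30, 6))
    x[:15] += 1.0
    groups = pd.Series(np.repeat(["a", "b"], 15))
    res = sm.dapc(pd.DataFrame(x), groups, n_pcs=6)
    xs = (x - x.mean(0)) / x.std(0)
    ref = LinearDiscriminantAnalysis().fit(xs, groups)
    direction = res.axes[:, 0]
    ref_dir = ref.scalings_[:, 0]
    cos = abs(direction @ ref_dir) / (
        np.linalg.norm(direction) * np.linalg.norm(ref_dir)
    )
    assert cos > 0.999


def test_dapc_scores_invariant_to_individual_order():
    rng = np.random.default_rng(3)
    x = pd.DataFrame(rng.normal(size=(24, 12)))
    groups = pd.Series(np.repeat(["a", "b"], 12), index=x.index)
    res = sm.dapc(x, groups, n_pcs=6)
    perm = rng.permutation(24)
    res_p = sm.dapc(x.iloc[perm], groups.iloc[perm], n_pcs=6)
    a = res.scores.iloc[perm].to_numpy()
    b = res_p.scores.to_numpy()
    # axes are defined up to sign
    for k in range(a.shape[1]):
        assert np.allclose(a[:, k], b[:, k], atol=1e-8) or np.allclose(
            a[:, k], -b[:, k], atol=1e-8
        )


def test_dapc_rejects_too_many_pcs():
    x = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 5)))
    with pytest.raises(ValueError, match="n_pcs"):
        sm.dapc(x, pd.Series(np.repeat(["a", "b"], 6)), n_pcs=12)
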
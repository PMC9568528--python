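"""Redundancy-analysis scan tests: collinearity filter, imputation, RDA
against a brute-force oracle, outlier rule and predictor assignment."""

import numpy as np
import pandas as pd
import pytest

import selmort as sm
from selmort.cohort import MISSING


def rda_oracle(y: np.ndarray, x: np.ndarray):
    """Hat-matrix + eigendecomposition oracle for the constrained axes."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    h = xc @ np.linalg.inv(xc.T @ xc) @ xc.T
    fitted = h @ yc
    w, v = np.linalg.eigh(fitted.T @ fitted / (y.shape[0] - 1))
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


# ---------------------------------------------------------------------- #
# collinearity filter


def pheno_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    hatch = rng.normal(size=n)
    pld = rng.normal(size=n)
    return pd.DataFrame(
        {
            "hatch_date": hatch,
            "pld": pld,
            "sst": rng.normal(size=n),
            "settlement_date": hatch + pld * 0.1 + rng.normal(scale=0.1, size=n),
        }
    )


def test_settlement_date_dropped_for_hatch_date_correlation():
    pm = sm.drop_correlated_predictors(pheno_frame())
    assert "settlement_date" not in pm.names
    assert "hatch_date" in pm.names
    dropped, kept, r = pm.dropped[0]
    assert (dropped, kept) == ("settlement_date", "hatch_date")
    assert abs(r) > 0.8
    # standardized output
    assert np.allclose(pm.data.mean(), 0, atol=1e-12)
    assert np.allclose(pm.data.std(ddof=0), 1, atol=1e-12)


def test_orthogonal_predictors_all_kept():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
    pm = sm.drop_correlated_predictors(df)
    assert pm.names == list("abcd")
    assert pm.dropped == []


def test_three_mutually_correlated_keep_first_in_canonical_order():
    rng = np.random.default_rng(2)
    base = rng.normal(size=300)
    df = pd.DataFrame(
        {
            "a": base + rng.normal(scale=0.2, size=300),
            "b": base + rng.normal(scale=0.2, size=300),
            "c": base + rng.normal(scale=0.2, size=300),
        }
    )
    assert df.corr().abs().to_numpy()[np.triu_indices(3, 1)].min() > 0.8
    pm = sm.drop_correlated_predictors(df)
    assert pm.names == ["a"]
    assert {d for d, _, _ in pm.dropped} == {"b", "c"}
    assert all(k == "a" for _, k, _ in pm.dropped)


def test_constant_predictor_raises_by_name():
    df = pheno_frame()
    df["sst"] = 1.0
    with pytest.raises(ValueError, match="sst"):
        sm.drop_correlated_predictors(df)


# ---------------------------------------------------------------------- #
# imputation


def test_impute_mode_ties_and_identity():
    col = np.array([[0], [0], [1], [MISSING]])
    assert sm.impute_missing_genotypes(col)[3, 0] == 0
    tie = np.array([[0], [0], [2], [2], [MISSING]])
    assert sm.impute_missing_genotypes(tie)[4, 0] == 0  # tie -> lower code
    full = np.array([[0, 1], [2, 1], [1, 0]])
    assert np.array_equal(sm.impute_missing_genotypes(full), full.astype(float))


def test_impute_empty_column_uses_global_mode_or_raises():
    local = np.full((4, 1), MISSING)
    global_calls = np.array([[2], [2], [1], [0]])
    filled = sm.impute_missing_genotypes(local, global_calls=global_calls)
    assert (filled == 2).all()
    with pytest.raises(ValueError):
        sm.impute_missing_genotypes(local)
    with pytest.raises(ValueError):
        sm.impute_missing_genotypes(local, global_calls=local)


# ---------------------------------------------------------------------- #
# RDA


def test_rda_perfect_linear_snp_fully_constrained():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(40, 1))
    y = 0.7 + 0.5 * x  # genotype exactly linear in the predictor
    xs = pd.DataFrame((x - x.mean()) / x.std(), columns=["sst"])
    scan = sm.rda_fit(pd.DataFrame(y), xs)
    assert len(scan.eigenvalues) == 1
    assert scan.constrained_inertia == pytest.approx(scan.total_inertia, rel=1e-10)
    assert abs(scan.loadings.iloc[0, 0]) == pytest.approx(1.0)


def test_rda_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    n, m, p = 10, 8, 3
    y = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    x = rng.normal(size=(n, p))
    xs = (x - x.mean(0)) / x.std(0)
    scan = sm.rda_fit(pd.DataFrame(y), pd.DataFrame(xs, columns=list("abc")))
    w_ref, v_ref = rda_oracle(y, xs)
    k = len(scan.eigenvalues)
    assert np.allclose(scan.eigenvalues, w_ref[:k], atol=1e-8)
    for j in range(k):
        cos = abs(scan.loadings.iloc[:, j].to_numpy() @ v_ref[:, j])
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_rda_null_constrained_inertia_fraction():
    """With genotypes independent of predictors, the constrained fraction of
    inertia concentrates near its p/(n-1) chance expectation (20 seeds)."""
    n, m, p = 200, 500, 3
    fracs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        x = rng.normal(size=(n, p))
        xs = (x - x.mean(0)) / x.std(0)
        scan = sm.rda_fit(
            pd.DataFrame(y), pd.DataFrame(xs, columns=["a", "b", "c"])
        )
        fracs.append(scan.constrained_inertia / scan.total_inertia)
    expected = p / (n - 1)
    assert 0.8 * expected <= np.mean(fracs) <= 1.2 * expected


def test_rda_equivariant_to_predictor_column_order():
    rng = np.random.default_rng(3)
    y = rng.binomial(2, 0.4, size=(30, 12)).astype(float)
    x = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    s1 = sm.rda_fit(pd.DataFrame(y), x)
    s2 = sm.rda_fit(pd.DataFrame(y), x[["c", "a", "b"]])
    assert np.allclose(s1.eigenvalues, s2.eigenvalues, atol=1e-10)
    for j in range(len(s1.eigenvalues)):
        cos = abs(
            s1.loadings.iloc[:, j].to_numpy() @ s2.loadings.iloc[:, j].to_numpy()
        )
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_rda_constrained_inertia_bounded_by_total():
    rng = np.random.default_rng(4)
    y = rng.binomial(2, 0.4, size=(25, 40)).astype(float)
    x = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
    scan = sm.rda_fit(pd.DataFrame(y), x)
    assert scan.constrained_inertia <= scan.total_inertia + 1e-10
    assert len(scan.eigenvalues) <= 4


def test_rda_rank_deficient_predictors_raise():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(20, 2))
    df = pd.DataFrame(np.hstack([x, x[:, :1]]), columns=["a", "b", "a_copy"])
    y = rng.binomial(2, 0.5, size=(20, 6)).astype(float)
    with pytest.raises(ValueError, match="rank-deficient"):
        sm.rda_fit(pd.DataFrame(y), df)


# ---------------------------------------------------------------------- #
# outlier rule


def test_outliers_degenerate_axis_flags_nothing():
    ld = pd.DataFrame({"RDA1": np.ones(50)})
    assert len(sm.detect_outliers(ld)) == 0


def test_outliers_planted_extreme_loading_is_flagged():
    rng = np.random.default_rng(0)
    v = rng.normal(size=500)
    v[7] = v.mean() + 5 * v.std()
    ld = pd.DataFrame({"RDA1": v}, index=[f"s{i}" for i in range(500)])
    out = sm.detect_outliers(ld)
    assert "s7" in out.index


def test_outlier_union_over_axes_records_triggering_axis():
    rng = np.random.default_rng(1)
    ld = pd.DataFrame(
        {"RDA1": rng.normal(size=300), "RDA2": rng.normal(size=300)},
        index=[f"s{i}" for i in range(300)],
    )
    ld.loc["s0", "RDA1"] = 10.0
    ld.loc["s1", "RDA2"] = -10.0
    out = sm.detect_outliers(ld)
    assert out.loc["s0", "axes"] == "RDA1"
    assert out.loc["s1", "axes"] == "RDA2"
    out1 = sm.detect_outliers(ld, n_axes=1)
    assert "s1" not in out1.index
    with pytest.raises(ValueError):
        sm.detect_outliers(ld, n_axes=3)


# ---------------------------------------------------------------------- #
# predictor assignment


def test_assignment_identity_and_sign():
    rng = np.random.default_rng(0)
    n = 50
    sst = rng.normal(size=n)
    hatch = rng.normal(size=n)
    pred = pd.DataFrame(
        {
            "hatch_date": (hatch - hatch.mean()) / hatch.std(),
            "sst": (sst - sst.mean()) / sst.std(),
        }
    )
    geno = pd.DataFrame({"snp_sst": pred["sst"], "snp_neg": -pred["hatch_date"]})
    assign, corr = sm.assign_predictor(geno, pred)
    assert assign.loc["snp_sst", "predictor"] == "sst"
    assert assign.loc["snp_sst", "r"] == pytest.approx(1.0)
    assert assign.loc["snp_neg", "predictor"] == "hatch_date"
    assert assign.loc["snp_neg", "sign"] == -1
    assert (corr.abs() <= 1 + 1e-12).all().all()


def test_assignment_exact_tie_prefers_earlier_predictor():
    rng = np.random.default_rng(1)
    n = 40
    base = rng.normal(size=n)
    # duplicated predictor column -> bitwise-equal correlations
    pred = pd.DataFrame({"grpld": base, "sst": base.copy()})
    geno = pd.DataFrame({"snp": rng.normal(size=n) + 0.5 * base})
    assign, _ = sm.assign_predictor(geno, pred)
    assert assign.loc["snp", "predictor"] == "grpld"


def test_assignment_drops_zero_variance_snp_with_warning():
    pred = pd.DataFrame({"sst": np.random.default_rng(0).normal(size=20)})
    geno = pd.DataFrame({"flat": np.ones(20), "ok": pred["sst"] * 1.0})
    with pytest.warns(UserWarning, match="zero-variance"):
        assign, _ = sm.assign_predictor(geno, pred)
    assert list(assign.index) == ["ok"]


# ---------------------------------------------------------------------- #
# end-to-end locality scan


def test_scan_locality_flags_a_strong_planted_snp():
    rng = np.random.default_rng(7)
    n, m = 120, 400
    calls = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
    pheno = pd.DataFrame(
        rng.normal(size=(n, 3)), columns=["hatch_date", "grpld", "sst"]
    )
    # plant a SNP tracking sst
    calls[:, 0] = np.clip(np.round(1 + pheno["sst"]), 0, 2).astype(np.int8)
    calls[rng.random((n, m)) < 0.02] = MISSING
    snp_ids = [f"t{j}_snp1" for j in range(m)]
    scan = sm.scan_locality(calls, snp_ids, pheno, locality="L")
    assert "t0_snp1" in scan.outliers.index
    assert scan.outliers.loc["t0_snp1", "predictor"] == "sst"
    assert scan.outliers.loc["t0_snp1", "sign"] == 1
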
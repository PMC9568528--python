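"""Population-structure statistics, authored from first principles.

* Weir & Cockerham (1984) variance-components F_ST (theta) for two groups,
  biallelic (vectorized) and multi-allelic (haplotype loci), with a
  label-permutation significance test.
* PERMANOVA (McArdle & Anderson partitioning of a Gower-centered distance
  matrix) with sequential sums of squares and free permutation of rows.
* DAPC: linear discriminant analysis on retained principal components of a
  (genotype or haplotype-dosage) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from selmort.cohort import MISSING

# ---------------------------------------------------------------------- #
# Weir-Cockerham theta


@dataclass
class FstResult:
    group_a: str
    group_b: str
    theta: float
    theta_per_locus: np.ndarray
    n_loci_used: int
    p_value: float | None = None
    n_permutations: int | None = None


def _wc_sums_biallelic(
    n_a: np.ndarray,
    p_a: np.ndarray,
    h_a: np.ndarray,
    n_b: np.ndarray,
    p_b: np.ndarray,
    h_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham a and a+b+c for two groups (alt allele).

    Inputs are per-locus sample sizes (genotyped individuals), alternate
    allele frequencies and heterozygote frequencies; arrays broadcast, so a
    leading permutation axis is allowed. Loci where either group has fewer
    than two genotyped individuals come back NaN.
    """
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n_a + n_b) / r
        nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1.0)
        pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
        s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n_a * h_a + n_b * h_b) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    denom = a + b + c
    bad = (n_a < 2) | (n_b < 2) | ~np.isfinite(denom)
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)
    return a, denom


def _group_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n, p_alt, het frequency) from a 0/1/2 matrix with MISSING."""
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, (g == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def weir_cockerham_fst(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Multi-locus Weir-Cockerham theta for two groups of biallelic genotypes.

    ``genotypes_*`` are (individuals, loci) 0/1/2 matrices with
    :data:`selmort.cohort.MISSING` for uncalled genotypes. Per-locus theta is
    a/(a+b+c); the multi-locus estimate is the ratio of summed components,
    excluding loci with a zero (or undefined) denominator.
    """
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape[1] != gb.shape[1]:
        raise ValueError("the two groups must share the same loci")
    n_a, p_a, h_a = _group_stats(ga)
    n_b, p_b, h_b = _group_stats(gb)
    a, denom = _wc_sums_biallelic(n_a, p_a, h_a, n_b, p_b, h_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(np.abs(denom) > 0, a / denom, np.nan)
    usable = np.isfinite(denom) & (np.abs(denom) > 0)
    if not usable.any():
        raise ValueError("no shared polymorphic locus between the two groups")
    theta = float(np.nansum(a[usable]) / np.nansum(denom[usable]))
    return FstResult(
        group_a=labels[0],
        group_b=labels[1],
        theta=theta,
        theta_per_locus=per_locus,
        n_loci_used=int(usable.sum()),
    )


def weir_cockerham_fst_alleles(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Weir-Cockerham theta for multi-allelic loci (e.g. haplotype loci).

    ``alleles_*`` are (individuals, loci, 2) integer allele codes with
    :data:`selmort.cohort.MISSING`. Variance components are computed per
    allele and summed over alleles and loci.
    """
    aa = np.asarray(alleles_a)
    ab = np.asarray(alleles_b)
    if aa.shape[1] != ab.shape[1]:
        raise ValueError("the two groups must share the same loci")
    n_loci = aa.shape[1]
    sum_a = 0.0
    sum_d = 0.0
    per_locus = np.full(n_loci, np.nan)
    used = 0
    for j in range(n_loci):
        la = aa[:, j, :]
        lb = ab[:, j, :]
        ok_a = (la != MISSING).all(axis=1)
        ok_b = (lb != MISSING).all(axis=1)
        n_a = float(ok_a.sum())
        n_b = float(ok_b.sum())
        if n_a < 2 or n_b < 2:
            continue
        la = la[ok_a]
        lb = lb[ok_b]
        alleles = np.unique(np.concatenate([la.ravel(), lb.ravel()]))
        loc_a = loc_d = 0.0
        for al in alleles:
            ca = (la == al).sum(axis=1)
            cb = (lb == al).sum(axis=1)
            p_a = ca.sum() / (2.0 * n_a)
            p_b = cb.sum() / (2.0 * n_b)
            h_a = (ca == 1).mean()
            h_b = (cb == 1).mean()
            a_j, d_j = _wc_sums_biallelic(
                np.array(n_a), np.array(p_a), np.array(h_a),
                np.array(n_b), np.array(p_b), np.array(h_b),
            )
            if np.isfinite(d_j):
                loc_a += float(a_j)
                loc_d += float(d_j)
        if abs(loc_d) > 0:
            per_locus[j] = loc_a / loc_d
            sum_a += loc_a
            sum_d += loc_d
            used += 1
    if used == 0:
        raise ValueError("no shared polymorphic locus between the two groups")
    return FstResult(
        group_a=labels[0],
        group_b=labels[1],
        theta=sum_a / sum_d,
        theta_per_locus=per_locus,
        n_loci_used=used,
    )


def fst_permutation_test(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, FstResult]:
    """Permutation p-value for theta between two biallelic genotype groups.

    Individuals are permuted between groups preserving group sizes;
    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    obs = weir_cockerham_fst(genotypes_a, genotypes_b)
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    g = np.vstack([ga, gb]).astype(np.float64)
    n_tot, n_loci = g.shape
    na = ga.shape[0]
    called = g != MISSING
    g0 = np.where(called, g, 0.0)
    het = (g == 1).astype(np.float64)

    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm, n_tot))
    for b in range(n_perm):
        member[b, rng.permutation(n_tot)[:na]] = 1.0

    n_a = member @ called  # (B, L) genotyped counts in permuted group A
    alt_a = member @ g0
    het_a = member @ het
    n_t = called.sum(axis=0)
    alt_t = g0.sum(axis=0)
    het_t = het.sum(axis=0)
    n_b = n_t - n_a
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = alt_a / (2.0 * n_a)
        p_b = (alt_t - alt_a) / (2.0 * n_b)
        h_a = het_a / n_a
        h_b = (het_t - het_a) / n_b
    a, denom = _wc_sums_biallelic(n_a, p_a, h_a, n_b, p_b, h_b)
    usable = np.isfinite(denom) & (np.abs(denom) > 0)
    a = np.where(usable, a, 0.0)
    denom = np.where(usable, denom, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_perm = a.sum(axis=1) / denom.sum(axis=1)
    theta_perm = np.where(np.isfinite(theta_perm), theta_perm, -np.inf)
    p = float((1 + (theta_perm >= obs.theta).sum()) / (n_perm + 1))
    obs.p_value = p
    obs.n_permutations = n_perm
    return p, obs


# ---------------------------------------------------------------------- #
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential (Type-I) PERMANOVA table.

    ``table`` rows are the model terms in entry order, plus ``Residual`` and
    ``Total``; columns: df, ss, pseudo_f, r2, p_value.
    """

    table: pd.DataFrame
    distance: str
    n_permutations: int


def _gower_center(d2: np.ndarray) -> np.ndarray:
    a = -0.5 * d2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _distance_matrix(y: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        d = pdist(y, metric="euclidean")
    elif metric == "manhattan":
        d = pdist(y, metric="cityblock")
    elif metric == "gower":
        # numeric Gower: range-normalized manhattan averaged over columns
        rng_ = y.max(axis=0) - y.min(axis=0)
        rng_[rng_ == 0] = 1.0
        d = pdist(y / rng_, metric="cityblock") / y.shape[1]
    else:
        raise ValueError(f"unknown distance {metric!r}")
    return squareform(d)


def _dummies(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values.astype("category")).to_numpy(dtype=float)


def permanova(
    response,
    factors,
    distance: str = "euclidean",
    n_perm: int = 999,
    seed: int | None = None,
    interaction: bool = True,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    Parameters
    ----------
    response
        (n,) or (n, q) numeric values per individual (no missing values).
    factors
        Series (single factor) or DataFrame whose columns are the factors in
        the order terms enter the model; with two or more factors and
        ``interaction=True`` the all-way interaction is added last.
    distance
        ``euclidean`` (default), ``manhattan`` or numeric ``gower``.

    The pseudo-F of each sequential term is tested by free permutation of
    individuals. For a univariate Euclidean response with a single factor,
    the pseudo-F equals the classical one-way ANOVA F.
    """
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    if isinstance(factors, pd.Series):
        factors = factors.to_frame()
    factors = pd.DataFrame(factors)
    n = y.shape[0]
    if len(factors) != n:
        raise ValueError("response and factors have different lengths")
    for col in factors.columns:
        if factors[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")

    d2 = _distance_matrix(y, distance) ** 2
    g = _gower_center(d2)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        raise ValueError("degenerate response: zero total sum of squares")

    # sequential design blocks
    blocks: list[tuple[str, np.ndarray]] = [
        (str(col), _dummies(factors[col])) for col in factors.columns
    ]
    if interaction and len(factors.columns) >= 2:
        cell = factors.astype(str).agg(":".join, axis=1)
        blocks.append((" x ".join(map(str, factors.columns)), _dummies(cell)))

    def orth(mat: np.ndarray) -> np.ndarray:
        # orthonormal basis of the column space (rank-revealing, unlike
        # unpivoted QR on dummy-coded designs)
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        return u[:, s > s[0] * 1e-10]

    hats: list[np.ndarray] = []
    dfs: list[int] = []
    x = np.ones((n, 1))
    rank_prev = 1
    for _, block in blocks:
        x = np.hstack([x, block])
        qk = orth(x)
        hats.append(qk @ qk.T)
        rank = qk.shape[1]
        dfs.append(rank - rank_prev)
        rank_prev = rank

    # per-term projector differences (trace against permuted G)
    j = np.full((n, n), 1.0 / n)
    diffs = []
    prev = j
    for h in hats:
        diffs.append(h - prev)
        prev = h
    h_full = hats[-1]
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((d * gmat).sum()) for d in diffs])
        ss_res = ss_total - float((h_full - j).ravel() @ gmat.ravel()) - 0.0
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(blocks))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        ss_p, ss_res_p = term_stats(gp)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs
    p_vals = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for (name, _), df_t, ss_t, f_t, p_t in zip(blocks, dfs, ss_obs, f_obs, p_vals):
        rows.append((name, df_t, ss_t, f_t, ss_t / ss_total, p_t))
    rows.append(("Residual", df_res, ss_res_obs, np.nan, ss_res_obs / ss_total, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "ss", "pseudo_f", "r2", "p_value"]
    ).set_index("term")
    return PermanovaResult(table=table, distance=distance, n_permutations=n_perm)


# ---------------------------------------------------------------------- #
# DAPC


@dataclass
class DapcResult:
    n_pcs: int
    axes: np.ndarray  # discriminant directions in original-feature space
    scores: pd.DataFrame  # individuals x discriminant axes
    posterior: pd.DataFrame  # individuals x groups assignment probabilities
    groups: pd.Series
    explained_variance: np.ndarray


def dapc(
    table,
    groups,
    n_pcs: int | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components.

    ``table`` is an individuals x features numeric matrix (genotype dosages
    or one-hot haplotype-allele counts; NaN cells are mean-imputed). Columns
    are centered and unit-scaled, ``n_pcs`` principal components retained
    (default: one third of the individuals, floored), and a linear
    discriminant analysis of the group labels fitted on the PC scores.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    x = pd.DataFrame(table)
    groups = pd.Series(groups, index=x.index) if not isinstance(groups, pd.Series) else groups
    if groups.nunique() < 2:
        raise ValueError("DAPC requires at least two groups")
    n = x.shape[0]
    if n_pcs is None:
        n_pcs = n // 3
    if n_pcs < 1 or n_pcs >= n:
        raise ValueError(f"n_pcs must lie in [1, n_individuals); got {n_pcs}")

    m = x.to_numpy(dtype=float)
    col_mean = np.nanmean(m, axis=0)
    nan_mask = np.isnan(m)
    m[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    m -= m.mean(axis=0)
    sd = m.std(axis=0)
    sd[sd == 0] = 1.0
    m /= sd

    pca = PCA(n_components=min(n_pcs, m.shape[1], n - 1), svd_solver="full")
    pcs = pca.fit_transform(m)
    lda = LinearDiscriminantAnalysis()
    lda.fit(pcs, groups.to_numpy())
    scores = lda.transform(pcs)
    posterior = lda.predict_proba(pcs)
    # map discriminant directions back to the standardized feature space
    axes = pca.components_.T @ lda.scalings_[:, : scores.shape[1]]

    axis_names = [f"LD{i + 1}" for i in range(scores.shape[1])]
    return DapcResult(
        n_pcs=pcs.shape[1],
        axes=axes,
        scores=pd.DataFrame(scores, index=x.index, columns=axis_names),
        posterior=pd.DataFrame(posterior, index=x.index, columns=lda.classes_),
        groups=groups,
        explained_variance=pca.explained_variance_ratio_,
    )
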
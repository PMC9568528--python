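"""Per-locality redundancy analysis (RDA) outlier scans.

The genotype matrix of a locality (settlers and survivors pooled, missing
calls imputed to the within-locality modal genotype) is regressed on the
standardized phenotypic/environmental predictors; the constrained axes are
the singular directions of the fitted matrix. SNPs whose loading on any
screened axis falls more than ``sd_mult`` standard deviations from that
axis's mean loading (default 3, a two-tailed normal tail of ~0.0027) are
candidate loci, each assigned the predictor with the strongest absolute
Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from selmort.cohort import MISSING
from selmort.simulate import PREDICTORS


@dataclass
class PredictorMatrix:
    """Standardized predictor table with the collinearity-drop log."""

    data: pd.DataFrame  # individuals x predictors, mean 0 / SD 1 columns
    means: pd.Series
    sds: pd.Series
    dropped: list[tuple[str, str, float]]  # (dropped, kept, offending r)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)


def drop_correlated_predictors(
    pheno: pd.DataFrame, threshold: float = 0.8
) -> PredictorMatrix:
    """Drop the later of each |r| > threshold predictor pair, then standardize.

    Pairs are processed in canonical column order (hatch -> larval ->
    settlement variables); for each offending pair the later column is
    dropped and logged with the correlation that triggered it.
    """
    cols = list(pheno.columns)
    values = pheno.to_numpy(dtype=float)
    sds = values.std(axis=0)
    for name, sd in zip(cols, sds):
        if sd == 0:
            raise ValueError(f"constant predictor {name!r} (zero standard deviation)")
    r = np.corrcoef(values, rowvar=False)
    active = {c: True for c in cols}
    dropped: list[tuple[str, str, float]] = []
    for i in range(len(cols)):
        if not active[cols[i]]:
            continue
        for j in range(i + 1, len(cols)):
            if not active[cols[j]]:
                continue
            if abs(r[i, j]) > threshold:
                active[cols[j]] = False
                dropped.append((cols[j], cols[i], float(r[i, j])))
    kept = [c for c in cols if active[c]]
    if not kept:
        raise ValueError("all predictors dropped by the correlation filter")
    sub = pheno[kept].astype(float)
    means = sub.mean()
    sds = sub.std(ddof=0)
    data = (sub - means) / sds
    return PredictorMatrix(data=data, means=means, sds=sds, dropped=dropped)


def impute_missing_genotypes(
    calls: np.ndarray, global_calls: np.ndarray | None = None
) -> np.ndarray:
    """Fill missing genotype codes with the per-SNP modal genotype.

    Ties between equally common codes resolve to the lower code. A SNP with
    no genotyped individual in ``calls`` falls back to the modal genotype of
    ``global_calls``; if it is missing there too (or no global matrix is
    given) an error is raised.
    """
    calls = np.asarray(calls)
    out = calls.astype(np.float64)
    out[calls == MISSING] = np.nan

    def modal(mat: np.ndarray) -> np.ndarray:
        counts = np.stack([(mat == code).sum(axis=0) for code in (0, 1, 2)])
        total = counts.sum(axis=0)
        mode = counts.argmax(axis=0).astype(float)  # argmax ties -> lower code
        mode[total == 0] = np.nan
        return mode

    mode = modal(calls)
    empty = np.isnan(mode)
    if empty.any():
        if global_calls is None:
            raise ValueError(
                f"{int(empty.sum())} SNP(s) entirely missing and no global matrix given"
            )
        gmode = modal(np.asarray(global_calls))
        if np.isnan(gmode[empty]).any():
            raise ValueError("SNP missing in every individual, cannot impute")
        mode[empty] = gmode[empty]
    nan_mask = np.isnan(out)
    out[nan_mask] = np.take(mode, np.nonzero(nan_mask)[1])
    return out


@dataclass
class RdaScan:
    """Constrained-ordination result for one locality."""

    locality: str
    eigenvalues: np.ndarray  # constrained eigenvalues (squared sv / (n-1))
    loadings: pd.DataFrame  # SNPs x constrained axes (right singular vectors)
    site_scores: pd.DataFrame  # individuals x constrained axes
    total_inertia: float
    constrained_inertia: float
    predictor_names: list[str]
    outliers: pd.DataFrame | None = None  # snp, axes, predictor, r, sign
    outlier_corr: pd.DataFrame | None = None  # outlier SNPs x all predictors


def rda_fit(
    genotypes,
    predictors: PredictorMatrix | pd.DataFrame,
    locality: str = "",
    scale_genotypes: bool = False,
) -> RdaScan:
    """Redundancy analysis of a complete genotype matrix on predictors.

    The centered genotype matrix is projected onto the predictor column
    space by least squares; the SVD of the fitted matrix gives constrained
    axes. Loadings are the (unit-norm) right singular vectors; eigenvalues
    are squared singular values over n - 1. Genotypes are centered but not
    variance-scaled unless ``scale_genotypes``.
    """
    xdf = predictors.data if isinstance(predictors, PredictorMatrix) else predictors
    names = list(xdf.columns)
    x = xdf.to_numpy(dtype=float)
    if isinstance(genotypes, pd.DataFrame):
        snp_ids = list(genotypes.columns)
        ind_ids = list(genotypes.index)
        y = genotypes.to_numpy(dtype=float)
    else:
        y = np.asarray(genotypes, dtype=float)
        snp_ids = [f"snp{j}" for j in range(y.shape[1])]
        ind_ids = [f"ind{i}" for i in range(y.shape[0])]
    n, m = y.shape
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("RDA requires complete matrices")
    if n <= x.shape[1]:
        raise ValueError("need more individuals than predictors")

    yc = y - y.mean(axis=0)
    if scale_genotypes:
        sd = yc.std(axis=0)
        sd[sd == 0] = 1.0
        yc = yc / sd
    xc = x - x.mean(axis=0)
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    bad = diag <= 1e-9 * max(1.0, diag.max())
    if bad.any():
        collinear = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient predictors after standardization: {collinear}")

    b = q.T @ yc  # (p, m); SVD of the fitted matrix via its row-space image
    u, s, vt = np.linalg.svd(b, full_matrices=False)
    tol = max(b.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = int((s > tol).sum())
    u, s, vt = u[:, :k], s[:k], vt[:k]

    eig = s**2 / (n - 1)
    loadings = pd.DataFrame(
        vt.T, index=pd.Index(snp_ids, name="snp"),
        columns=[f"RDA{i + 1}" for i in range(k)],
    )
    site = pd.DataFrame(
        (q @ u) * s, index=pd.Index(ind_ids, name="individual"),
        columns=loadings.columns,
    )
    total = float((yc**2).sum() / (n - 1))
    return RdaScan(
        locality=locality,
        eigenvalues=eig,
        loadings=loadings,
        site_scores=site,
        total_inertia=total,
        constrained_inertia=float(eig.sum()),
        predictor_names=names,
    )


def detect_outliers(
    loadings: pd.DataFrame | np.ndarray,
    n_axes: int | None = None,
    sd_mult: float = 3.0,
) -> pd.DataFrame:
    """Flag SNPs loading more than ``sd_mult`` SD from an axis's mean loading.

    Returns a table indexed by SNP with the list of triggering axes; the
    union over the first ``n_axes`` axes (default: all) is taken. An axis
    with zero loading spread flags nothing.
    """
    ld = pd.DataFrame(loadings)
    axes = list(ld.columns if n_axes is None else ld.columns[:n_axes])
    if n_axes is not None and n_axes > ld.shape[1]:
        raise ValueError("n_axes exceeds the available constrained axes")
    hits: dict = {}
    for ax in axes:
        v = ld[ax].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            continue
        flagged = np.abs(v - v.mean()) > sd_mult * sd
        for snp in ld.index[flagged]:
            hits.setdefault(snp, []).append(str(ax))
    return pd.DataFrame(
        {"axes": [";".join(hits[s]) for s in hits]},
        index=pd.Index(list(hits), name="snp"),
    )


def assign_predictor(
    genotypes: pd.DataFrame,
    predictors: PredictorMatrix | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each outlier SNP the predictor with the strongest |Pearson r|.

    ``genotypes`` holds the (imputed) genotype columns of the flagged SNPs.
    Ties resolve to the earlier predictor in canonical order (the column
    order of ``predictors``). Returns (assignments, full correlation matrix);
    zero-variance SNPs are dropped with a warning.
    """
    xdf = predictors.data if isinstance(predictors, PredictorMatrix) else predictors
    g = genotypes.to_numpy(dtype=float)
    x = xdf.to_numpy(dtype=float)
    n = g.shape[0]
    g_sd = g.std(axis=0)
    keep = g_sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance outlier SNP(s)",
            stacklevel=2,
        )
    g = g[:, keep]
    snp_ids = list(np.asarray(genotypes.columns)[keep])
    gz = (g - g.mean(axis=0)) / g.std(axis=0)
    xz = (x - x.mean(axis=0)) / x.std(axis=0)
    r = gz.T @ xz / n  # (snps, predictors)
    corr = pd.DataFrame(r, index=pd.Index(snp_ids, name="snp"), columns=xdf.columns)
    best = np.abs(r).argmax(axis=1)  # first max wins -> canonical tie-break
    r_best = r[np.arange(r.shape[0]), best]
    assignments = pd.DataFrame(
        {
            "predictor": [xdf.columns[b] for b in best],
            "r": r_best,
            "sign": np.sign(r_best).astype(int),
        },
        index=corr.index,
    )
    return assignments, corr


def scan_locality(
    calls: np.ndarray,
    snp_ids,
    pheno: pd.DataFrame,
    locality: str = "",
    global_calls: np.ndarray | None = None,
    corr_threshold: float = 0.8,
    n_axes: int | None = None,
    sd_mult: float = 3.0,
    scale_genotypes: bool = False,
) -> RdaScan:
    """Full per-locality scan: impute -> RDA -> outliers -> assignment."""
    pred = drop_correlated_predictors(pheno, threshold=corr_threshold)
    imputed = impute_missing_genotypes(calls, global_calls=global_calls)
    gdf = pd.DataFrame(imputed, index=pred.data.index, columns=snp_ids)
    scan = rda_fit(gdf, pred, locality=locality, scale_genotypes=scale_genotypes)
    flagged = detect_outliers(scan.loadings, n_axes=n_axes, sd_mult=sd_mult)
    if len(flagged):
        assignments, corr = assign_predictor(gdf[flagged.index], pred)
        out = flagged.join(assignments, how="inner")
    else:
        out = flagged.assign(predictor=[], r=[], sign=[])
        corr = pd.DataFrame(columns=pred.names)
    scan.outliers = out
    scan.outlier_corr = corr
    return scan
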
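"""Post-genotyping filter cascade and haplotype-locus collapsing.

The cascade applies, in fixed order: (1) per-call depth masking, (2) SNP
missingness, (3) minor-allele frequency, (4) per-tag mean-depth upper fence
(Tukey Q3 + 1.5 IQR by default, to remove likely collapsed paralogs), and
(5) a Hardy-Weinberg mid-p exact test per locality, removing SNPs out of
equilibrium in at least ``hwe_min_localities`` localities. The report makes
the per-stage attribution auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from selmort.cohort import MISSING, CohortGenotypes


@dataclass
class FilterConfig:
    min_depth: int = 5
    max_missingness: float = 0.30
    min_maf: float = 0.05
    depth_iqr_multiplier: float = 1.5
    depth_fence_center: str = "q3"  # "q3" (Tukey upper fence) or "median"
    hwe_alpha: float = 0.05
    hwe_min_localities: int = 2
    hwe_min_individuals: int = 5

    def validate(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")
        if not (0.0 <= self.max_missingness < 1.0):
            raise ValueError("max_missingness must lie in [0, 1)")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.depth_iqr_multiplier < 0:
            raise ValueError("depth_iqr_multiplier must be non-negative")
        if self.depth_fence_center not in ("q3", "median"):
            raise ValueError("depth_fence_center must be 'q3' or 'median'")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must lie in (0, 1)")
        if self.hwe_min_localities < 1:
            raise ValueError("hwe_min_localities must be positive")


@dataclass
class FilterReport:
    """Per-stage removal counts, in application order."""

    n_input_snps: int
    masked_calls: int = 0
    removed_missingness: int = 0
    removed_maf: int = 0
    removed_tag_depth: int = 0
    removed_hwe: int = 0
    n_output_snps: int = 0
    n_haplotype_loci: int = 0
    depth_fence: float = float("nan")

    def validate(self) -> None:
        removed = (
            self.removed_missingness
            + self.removed_maf
            + self.removed_tag_depth
            + self.removed_hwe
        )
        if self.n_input_snps - removed != self.n_output_snps:
            raise ValueError("stage removals do not sum to input minus output")

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "stages": [
                {"stage": "depth_mask", "masked_calls": self.masked_calls},
                {"stage": "missingness", "removed_snps": self.removed_missingness},
                {"stage": "maf", "removed_snps": self.removed_maf},
                {"stage": "tag_mean_depth", "removed_snps": self.removed_tag_depth},
                {"stage": "hwe", "removed_snps": self.removed_hwe},
            ],
            "depth_fence": self.depth_fence,
            "n_output_snps": self.n_output_snps,
            "n_haplotype_loci": self.n_haplotype_loci,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------- #
# Hardy-Weinberg exact test (mid-p)


def hwe_exact_midp(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Mid-p exact Hardy-Weinberg test from genotype counts.

    Conditional on the minor-allele count, the heterozygote count under HWE
    has the classical exact distribution; the mid-p value sums probabilities
    of outcomes less probable than the observed one plus half the probability
    of outcomes exactly as probable (including the observed).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    het = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - het) // 2
    hom_maj = n - het - hom_min
    logp = (
        gammaln(n + 1)
        - gammaln(het + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
        + het * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(het, n_het)]
    tol = 1e-12 * max(p_obs, 1e-300)
    lower = prob[prob < p_obs - tol].sum()
    equal = prob[np.abs(prob - p_obs) <= tol].sum()
    return float(min(1.0, lower + 0.5 * equal))


# ---------------------------------------------------------------------- #


def _maf(calls: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP over non-missing calls (nan if none)."""
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=0)
    n2 = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n2 > 0, alt / n2, np.nan)
    return np.minimum(p, 1.0 - p)


def apply_filters(
    cohort: CohortGenotypes, config: FilterConfig | None = None
) -> tuple[CohortGenotypes, FilterReport]:
    """Run the five-stage cascade; returns the filtered cohort and report."""
    config = config or FilterConfig()
    config.validate()
    report = FilterReport(n_input_snps=cohort.n_snps)
    n_ind = cohort.n_individuals

    # stage 1: mask low-depth calls
    low = (cohort.depth < config.min_depth) & (cohort.h1 != MISSING)
    report.masked_calls = int(low.sum())
    cur = cohort.mask_calls(low)

    # stage 2: SNP missingness over all individuals, after masking
    calls = cur.calls
    missingness = (calls == MISSING).sum(axis=0) / n_ind
    keep = missingness <= config.max_missingness
    report.removed_missingness = int((~keep).sum())
    cur = cur.subset_snps(keep)

    # stage 3: minor-allele frequency over non-missing calls; the boundary
    # MAF == min_maf is kept, fully missing SNPs (undefined MAF) are dropped
    maf = _maf(cur.calls)
    with np.errstate(invalid="ignore"):
        keep = maf >= config.min_maf
    report.removed_maf = int((~keep).sum())
    cur = cur.subset_snps(keep)

    # stage 4: per-tag mean depth upper fence
    calls = cur.calls
    called = calls != MISSING
    tags = cur.snps["tag"].to_numpy()
    tag_codes, tag_inv = np.unique(tags, return_inverse=True)
    depth_sum = np.zeros(tag_codes.size)
    depth_n = np.zeros(tag_codes.size)
    np.add.at(depth_sum, tag_inv, np.where(called, cur.depth, 0).sum(axis=0))
    np.add.at(depth_n, tag_inv, called.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        tag_mean = np.where(depth_n > 0, depth_sum / depth_n, np.nan)
    finite = tag_mean[np.isfinite(tag_mean)]
    if finite.size:
        q1, med, q3 = np.percentile(finite, [25, 50, 75])
        center = q3 if config.depth_fence_center == "q3" else med
        fence = center + config.depth_iqr_multiplier * (q3 - q1)
    else:
        fence = np.inf
    report.depth_fence = float(fence)
    bad_tag = tag_mean > fence
    keep = ~bad_tag[tag_inv]
    report.removed_tag_depth = int((~keep).sum())
    cur = cur.subset_snps(keep)

    # stage 5: HWE per locality (settlers and survivors pooled)
    calls = cur.calls
    localities = cur.localities
    loc_masks = [cur.locality_mask(loc) for loc in localities]
    n_out = np.zeros(cur.n_snps, dtype=int)
    skipped_small = 0
    for loc, mask in zip(localities, loc_masks):
        sub = calls[mask]
        for j in range(cur.n_snps):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size < config.hwe_min_individuals:
                skipped_small += 1
                continue
            n_het = int((col == 1).sum())
            n_alt_hom = int((col == 2).sum())
            n_ref_hom = col.size - n_het - n_alt_hom
            if hwe_exact_midp(n_ref_hom, n_het, n_alt_hom) < config.hwe_alpha:
                n_out[j] += 1
    if skipped_small:
        warnings.warn(
            f"HWE stage: {skipped_small} SNP-locality tests skipped "
            f"(< {config.hwe_min_individuals} genotyped individuals)",
            stacklevel=2,
        )
    keep = n_out < config.hwe_min_localities
    report.removed_hwe = int((~keep).sum())
    cur = cur.subset_snps(keep)

    report.n_output_snps = cur.n_snps
    report.n_haplotype_loci = int(cur.snps["tag"].nunique())
    report.validate()
    return cur, report


# ---------------------------------------------------------------------- #
# haplotype-locus collapsing


def collapse_haplotypes(cohort: CohortGenotypes) -> tuple[pd.DataFrame, int]:
    """Collapse within-tag SNPs into multi-allelic haplotype loci.

    Returns a long table (individual, tag, allele1, allele2) where alleles
    are the per-tag concatenations of phased SNP alleles (e.g. ``"01"``),
    plus the number of haplotype calls set missing because an individual was
    unphased-heterozygous at two or more SNPs of a multi-SNP tag. Missing
    haplotypes carry empty-string alleles.
    """
    tags = cohort.snps["tag"].to_numpy()
    tag_codes, tag_inv = np.unique(tags, return_inverse=True)
    individuals = cohort.individuals.index.to_numpy()
    h1, h2, phased = cohort.h1, cohort.h2, cohort.phased
    n_unphased_missing = 0
    rows = []
    for t_idx, tag in enumerate(tag_codes):
        cols = np.flatnonzero(tag_inv == t_idx)
        cols = cols[np.argsort(cohort.snps["pos"].to_numpy()[cols], kind="stable")]
        multi = cols.size > 1
        for i, ind in enumerate(individuals):
            a1 = h1[i, cols]
            a2 = h2[i, cols]
            if (a1 == MISSING).any():
                rows.append((ind, tag, "", ""))
                continue
            if multi:
                het = a1 != a2
                unph = het & ~phased[i, cols]
                if het.sum() >= 2 and unph.any():
                    # relative phase of the heterozygous sites is unknown
                    n_unphased_missing += 1
                    rows.append((ind, tag, "", ""))
                    continue
            rows.append(
                (ind, tag, "".join(map(str, a1)), "".join(map(str, a2)))
            )
    table = pd.DataFrame(rows, columns=["individual", "tag", "allele1", "allele2"])
    return table, n_unphased_missing


def haplotype_allele_counts(haplotypes: pd.DataFrame) -> pd.DataFrame:
    """One-hot allele-dosage table from a collapsed haplotype table.

    Returns individuals x (tag, allele) counts in {0, 1, 2}; missing
    haplotype calls become NaN across that tag's columns.
    """
    individuals = list(dict.fromkeys(haplotypes["individual"]))
    blocks = []
    for tag, grp in haplotypes.groupby("tag", sort=True):
        grp = grp.set_index("individual").reindex(individuals)
        alleles = sorted(
            set(grp["allele1"]).union(grp["allele2"]) - {"", np.nan} - {None}
        )
        counts = pd.DataFrame(
            0.0, index=individuals, columns=[f"{tag}:{a}" for a in alleles]
        )
        missing = (grp["allele1"] == "") | grp["allele1"].isna()
        for a in alleles:
            counts[f"{tag}:{a}"] = (
                (grp["allele1"] == a).astype(float) + (grp["allele2"] == a).astype(float)
            )
        counts.loc[missing.to_numpy(), :] = np.nan
        blocks.append(counts)
    return pd.concat(blocks, axis=1)


def write_haplotype_table(haplotypes: pd.DataFrame, path) -> None:
    haplotypes.to_csv(path, index=False)
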
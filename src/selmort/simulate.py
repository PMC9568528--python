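"""Synthetic settler/survivor cohorts with planted viability selection.

The generator emulates the statistical structure of a two-stage juvenile
sampling design in three partially differentiated localities:

* per-SNP ancestral allele frequencies, diversified per locality under the
  Balding-Nichols model (optionally hierarchical: locality 1 versus a shared
  parent of localities 2 and 3, mimicking a north/south oceanographic split);
* Hardy-Weinberg settler genotypes drawn as two haplotypes per individual so
  within-tag phase is defined;
* nine otolith-style phenotypic/environmental predictors drawn from a latent
  multivariate normal (including one strongly correlated pair, hatch date vs
  settlement date), shifted by planted SNP effects;
* survivors subsampled from a larger virtual settler pool with logistic
  viability selection on the linked predictors, producing allele-frequency
  shifts at selected loci;
* negative-binomial sequencing depth and random call missingness.

A truth table records which SNPs are selected, their linked predictor and
effect sign, and realized allele frequencies, for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from selmort.cohort import MISSING, CohortGenotypes

#: canonical predictor order: hatch -> larval -> settlement variables
PREDICTORS = (
    "hatch_date",
    "hatch_size",
    "moon_hatch",
    "pld",
    "grpld",
    "sst",
    "settlement_date",
    "settlement_size",
    "moon_settlement",
)

#: predictors entering the association scans (settlement date is dropped
#: upstream for its strong correlation with hatch date)
RDA_PREDICTORS = tuple(p for p in PREDICTORS if p != "settlement_date")

MOON_PREDICTORS = ("moon_hatch", "moon_settlement")

_DEFAULT_LOCALITIES = ("Blanes", "Xabia", "Aguamarga")

_NUCS = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Raised when a cohort cannot be generated under the given config."""


def default_pheno_corr() -> np.ndarray:
    """Default target correlation among the nine predictors.

    Identity except settlement date, which is tied to hatch date (r = 0.9,
    the pair the downstream collinearity filter must catch) and mildly to
    pelagic larval duration (r = 0.3).
    """
    c = np.eye(len(PREDICTORS))
    i_hatch = PREDICTORS.index("hatch_date")
    i_setd = PREDICTORS.index("settlement_date")
    i_pld = PREDICTORS.index("pld")
    c[i_hatch, i_setd] = c[i_setd, i_hatch] = 0.9
    c[i_pld, i_setd] = c[i_setd, i_pld] = 0.3
    return c


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults are the study conditions).

    ``snps_per_tag`` gives the probabilities that a RAD tag carries 1, 2 or 3
    SNPs. ``fst_baseline`` is the Balding-Nichols differentiation F between
    the ancestral pool and a locality (or parent group); ``fst_within`` the
    differentiation between the two southern localities and their shared
    parent when ``hierarchical``. ``effect_size_beta`` is the phenotype shift
    per alternate allele in phenotype-SD units; ``selection_strength`` the
    logistic coefficient of the linked predictor on survival.
    ``pool_multiplier`` sets the virtual settler pool from which survivors
    are subsampled, as a multiple of ``n_survivors_per_locality``.
    """

    n_localities: int = 3
    n_settlers_per_locality: int = 200
    n_survivors_per_locality: int = 100
    n_neutral_loci: int = 5000
    n_selected_loci: int = 50
    snps_per_tag: tuple[float, float, float] = (0.6, 0.3, 0.1)
    fst_baseline: float = 0.05
    fst_within: float = 0.01
    hierarchical: bool = True
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    effect_size_beta: float = 0.8
    selection_strength: float = 2.0
    pheno_corr_matrix: np.ndarray | None = None
    mean_depth: float = 29.67
    depth_dispersion: float = 5.7
    missing_rate: float = 0.02
    pool_multiplier: float = 4.0
    locality_names: tuple[str, ...] | None = None
    seed: int = 0

    def corr_matrix(self) -> np.ndarray:
        c = (
            default_pheno_corr()
            if self.pheno_corr_matrix is None
            else np.asarray(self.pheno_corr_matrix, dtype=float)
        )
        return c

    def names(self) -> tuple[str, ...]:
        if self.locality_names is not None:
            return tuple(self.locality_names)
        if self.n_localities == 3:
            return _DEFAULT_LOCALITIES
        return tuple(f"locality_{i + 1}" for i in range(self.n_localities))

    def validate(self) -> None:
        if self.n_localities < 1:
            raise ValueError("n_localities must be positive")
        for name in ("n_settlers_per_locality", "n_survivors_per_locality"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_neutral_loci < 0 or self.n_selected_loci < 0:
            raise ValueError("locus counts must be non-negative")
        if self.n_neutral_loci + self.n_selected_loci < 1:
            raise ValueError("at least one locus is required")
        for f in (self.fst_baseline, self.fst_within):
            if not (0.0 < f < 1.0):
                raise ValueError("F parameters must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        p = np.asarray(self.snps_per_tag, dtype=float)
        if p.shape != (3,) or (p < 0).any() or not math.isclose(p.sum(), 1.0):
            raise ValueError("snps_per_tag must be 3 probabilities summing to 1")
        c = self.corr_matrix()
        if c.shape != (len(PREDICTORS),) * 2:
            raise ValueError("pheno_corr_matrix must be 9 x 9")
        if not np.allclose(c, c.T):
            raise ValueError("pheno_corr_matrix must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("pheno_corr_matrix must be positive semi-definite")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.pool_multiplier < 1.0:
            raise ValueError("pool_multiplier must be >= 1")
        if len(self.names()) != self.n_localities:
            raise ValueError("locality_names length must equal n_localities")


class SimulatedCohort(NamedTuple):
    cohort: CohortGenotypes
    phenotypes: pd.DataFrame
    truth: pd.DataFrame


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw subpopulation frequencies Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if f < 1e-9:
        return p.copy()
    scale = (1.0 - f) / f
    q = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(q, 1e-6, 1.0 - 1e-6)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort, its phenotype table and the planted truth table.

    Identical configs (including seed) give identical outputs, down to the
    bytes of the VCF written by :func:`selmort.io.write_vcf`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.names()

    # ---- loci and SNPs ------------------------------------------------ #
    n_loci = config.n_neutral_loci + config.n_selected_loci
    selected_tag = np.zeros(n_loci, dtype=bool)
    sel_idx = rng.permutation(n_loci)[: config.n_selected_loci]
    selected_tag[sel_idx] = True
    snps_per = rng.choice([1, 2, 3], size=n_loci, p=np.asarray(config.snps_per_tag))

    tag_of_snp = np.repeat(np.arange(n_loci), snps_per)
    n_snps = tag_of_snp.size
    snp_in_tag = np.concatenate([np.arange(k) for k in snps_per])
    tag_ids = np.array([f"tag{i + 1:06d}" for i in range(n_loci)])
    snp_ids = np.array(
        [f"{tag_ids[t]}_snp{j + 1}" for t, j in zip(tag_of_snp, snp_in_tag)]
    )
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    positions = (snp_in_tag * 10 + 5).astype(int)  # within a ~34 bp tag

    selected_snp = selected_tag[tag_of_snp]
    # linked predictor per selected tag: one of the eight scan predictors
    link_pred_tag = np.full(n_loci, "", dtype=object)
    link_sign_tag = np.zeros(n_loci, dtype=int)
    sel_tags = np.flatnonzero(selected_tag)
    link_pred_tag[sel_tags] = rng.choice(np.array(RDA_PREDICTORS), size=sel_tags.size)
    link_sign_tag[sel_tags] = rng.choice(np.array([-1, 1]), size=sel_tags.size)

    # ---- allele frequencies ------------------------------------------- #
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=n_snps)
    p_loc = np.empty((config.n_localities, n_snps))
    if config.hierarchical and config.n_localities == 3:
        p_loc[0] = _balding_nichols(rng, p_anc, config.fst_baseline)
        parent = _balding_nichols(rng, p_anc, config.fst_baseline)
        p_loc[1] = _balding_nichols(rng, parent, config.fst_within)
        p_loc[2] = _balding_nichols(rng, parent, config.fst_within)
    else:
        for k in range(config.n_localities):
            p_loc[k] = _balding_nichols(rng, p_anc, config.fst_baseline)

    corr = config.corr_matrix()
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(corr.shape[0]))
    pred_index = {p: i for i, p in enumerate(PREDICTORS)}

    ind_rows: list[tuple[str, str, str]] = []
    h1_parts: list[np.ndarray] = []
    h2_parts: list[np.ndarray] = []
    pheno_parts: list[np.ndarray] = []
    truth_freq = {
        f"{w}_{nm}": np.full(n_snps, np.nan)
        for nm in names
        for w in ("p_locality", "p_settler", "p_survivor")
    }

    n_set = config.n_settlers_per_locality
    n_sur = config.n_survivors_per_locality
    pool_size = int(math.ceil(config.pool_multiplier * n_sur))

    for k, nm in enumerate(names):
        n_tot = n_set + pool_size
        hap1 = (rng.random((n_tot, n_snps)) < p_loc[k]).astype(np.int8)
        hap2 = (rng.random((n_tot, n_snps)) < p_loc[k]).astype(np.int8)
        geno = hap1 + hap2

        z = rng.standard_normal((n_tot, len(PREDICTORS))) @ chol.T
        for t in sel_tags:
            j = pred_index[link_pred_tag[t]]
            for s in np.flatnonzero(tag_of_snp == t):
                z[:, j] += link_sign_tag[t] * config.effect_size_beta * geno[:, s]

        # viability selection on the (standardized) linked predictors
        if sel_tags.size and config.selection_strength != 0.0:
            linked = sorted({link_pred_tag[t] for t in sel_tags}, key=PREDICTORS.index)
            zs = np.column_stack(
                [
                    (z[:, pred_index[q]] - z[:, pred_index[q]].mean())
                    / z[:, pred_index[q]].std()
                    for q in linked
                ]
            )
            score = zs.mean(axis=1)
        else:
            score = np.zeros(n_tot)
        p_surv = expit(config.selection_strength * score)

        pool = np.arange(n_set, n_tot)
        accepted = pool[rng.random(pool_size) < p_surv[pool]]
        if accepted.size < n_sur:
            raise SimulationError(
                f"survivor acceptance impossible in locality {nm!r}: "
                f"{accepted.size} accepted from a pool of {pool_size}, "
                f"{n_sur} required (selection too strong for pool size)"
            )
        survivors = accepted[:n_sur]
        settlers = np.arange(n_set)

        keep = np.concatenate([settlers, survivors])
        h1_parts.append(hap1[keep])
        h2_parts.append(hap2[keep])
        pheno_parts.append(z[keep])
        ind_rows += [(f"{nm}_set{i + 1:03d}", nm, "settler") for i in range(n_set)]
        ind_rows += [(f"{nm}_sur{i + 1:03d}", nm, "survivor") for i in range(n_sur)]

        truth_freq[f"p_locality_{nm}"] = p_loc[k]
        truth_freq[f"p_settler_{nm}"] = geno[settlers].mean(axis=0) / 2.0
        truth_freq[f"p_survivor_{nm}"] = geno[survivors].mean(axis=0) / 2.0

    h1 = np.vstack(h1_parts)
    h2 = np.vstack(h2_parts)
    z_all = np.vstack(pheno_parts)
    n_ind = h1.shape[0]

    # moon phases: ordinal 0-9 via the normal CDF of the (possibly shifted)
    # latent variable, each level covering ~10% of the latent distribution
    from scipy.stats import norm

    pheno = pd.DataFrame(z_all, columns=list(PREDICTORS))
    for col in MOON_PREDICTORS:
        v = pheno[col].to_numpy()
        u = norm.cdf((v - v.mean()) / v.std())
        pheno[col] = np.minimum((u * 10).astype(int), 9)

    individuals = pd.DataFrame(
        ind_rows, columns=["individual", "locality", "age_group"]
    ).set_index("individual")
    pheno.index = individuals.index

    # ---- depth and missingness ---------------------------------------- #
    k_disp = config.depth_dispersion
    depth = rng.negative_binomial(
        k_disp, k_disp / (k_disp + config.mean_depth), size=(n_ind, n_snps)
    ).astype(np.int32)
    if config.missing_rate > 0:
        drop = rng.random((n_ind, n_snps)) < config.missing_rate
        h1[drop] = MISSING
        h2[drop] = MISSING

    snps = pd.DataFrame(
        {
            "tag": tag_ids[tag_of_snp],
            "pos": positions,
            "ref": _NUCS[ref_idx],
            "alt": _NUCS[alt_idx],
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    cohort = CohortGenotypes(
        individuals=individuals,
        snps=snps,
        h1=h1,
        h2=h2,
        phased=np.ones((n_ind, n_snps), dtype=bool),
        depth=depth,
    )

    truth = pd.DataFrame(
        {
            "tag": tag_ids[tag_of_snp],
            "selected": selected_snp,
            "predictor": [link_pred_tag[t] for t in tag_of_snp],
            "sign": [link_sign_tag[t] for t in tag_of_snp],
            "p_ancestral": p_anc,
            **truth_freq,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    return SimulatedCohort(cohort=cohort, phenotypes=pheno, truth=truth)


# ---------------------------------------------------------------------- #


def write_metadata(cohort: CohortGenotypes, path) -> None:
    """Write the individual/locality/age-group table as CSV."""
    df = cohort.individuals.reset_index()
    df.columns = ["individual", "locality", "age_group"]
    df.to_csv(path, index=False)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    """Write the nine-predictor phenotype table as CSV (moon columns integer)."""
    df = phenotypes.copy()
    for col in MOON_PREDICTORS:
        if col in df.columns:
            df[col] = df[col].astype(int)
    df.reset_index().rename(columns={"index": "individual"}).to_csv(path, index=False)
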
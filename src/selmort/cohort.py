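"""In-memory container for a genotyped cohort of individuals.

Genotypes are stored as two haplotype arrays so that within-tag phase (from
read-phased RAD tags, or from simulation) survives a round trip through VCF.
The diploid genotype code of a call is the alternate-allele count ``h1 + h2``;
a call is missing when either haplotype allele is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing allele / genotype call
MISSING = -1


@dataclass
class CohortGenotypes:
    """Individuals x SNPs genotype calls with depth, grouped by RAD tag.

    Parameters
    ----------
    individuals
        DataFrame indexed by individual ID with columns ``locality`` and
        ``age_group`` (``settler`` / ``survivor``).
    snps
        DataFrame indexed by SNP ID with columns ``tag`` (RAD-tag locus ID),
        ``pos`` (position within the tag, 1-based), ``ref`` and ``alt``.
    h1, h2
        ``(n_individuals, n_snps)`` int8 arrays holding each haplotype's
        allele (0 = ref, 1 = alt, :data:`MISSING`).
    phased
        ``(n_individuals, n_snps)`` boolean array; ``True`` where the two
        haplotype alleles are read-phased within the tag.
    depth
        ``(n_individuals, n_snps)`` int32 read depths.
    """

    individuals: pd.DataFrame
    snps: pd.DataFrame
    h1: np.ndarray
    h2: np.ndarray
    phased: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.individuals), len(self.snps)
        for name in ("h1", "h2", "phased", "depth"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n, m)}"
                )
        miss = (self.h1 == MISSING) != (self.h2 == MISSING)
        if miss.any():
            # a half-called diploid genotype is not representable; callers
            # (VCF reader, simulator) must set both alleles missing together
            raise ValueError("half-missing calls: set both haplotype alleles missing")
        for col in ("locality", "age_group"):
            if col not in self.individuals.columns:
                raise ValueError(f"individuals table lacks column {col!r}")
        if "tag" not in self.snps.columns:
            raise ValueError("snps table lacks column 'tag'")

    # ------------------------------------------------------------------ #

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def calls(self) -> np.ndarray:
        """(n, m) int8 genotype codes 0/1/2, :data:`MISSING` where uncalled."""
        g = (self.h1 + self.h2).astype(np.int8)
        g[self.h1 == MISSING] = MISSING
        return g

    @property
    def localities(self) -> list[str]:
        return list(pd.unique(self.individuals["locality"]))

    def locality_mask(self, locality: str) -> np.ndarray:
        return (self.individuals["locality"] == locality).to_numpy()

    def age_mask(self, age_group: str) -> np.ndarray:
        return (self.individuals["age_group"] == age_group).to_numpy()

    # ------------------------------------------------------------------ #

    def subset_snps(self, keep: np.ndarray) -> "CohortGenotypes":
        """Return a cohort restricted to SNPs selected by a boolean/index array."""
        return CohortGenotypes(
            individuals=self.individuals,
            snps=self.snps.iloc[np.asarray(keep).nonzero()[0]]
            if np.asarray(keep).dtype == bool
            else self.snps.iloc[keep],
            h1=self.h1[:, keep],
            h2=self.h2[:, keep],
            phased=self.phased[:, keep],
            depth=self.depth[:, keep],
        )

    def subset_individuals(self, keep: np.ndarray) -> "CohortGenotypes":
        keep = np.asarray(keep)
        idx = keep.nonzero()[0] if keep.dtype == bool else keep
        return CohortGenotypes(
            individuals=self.individuals.iloc[idx],
            snps=self.snps,
            h1=self.h1[idx],
            h2=self.h2[idx],
            phased=self.phased[idx],
            depth=self.depth[idx],
        )

    def mask_calls(self, mask: np.ndarray) -> "CohortGenotypes":
        """Return a copy with calls under ``mask`` set missing (depth kept)."""
        h1 = self.h1.copy()
        h2 = self.h2.copy()
        h1[mask] = MISSING
        h2[mask] = MISSING
        return CohortGenotypes(
            individuals=self.individuals,
            snps=self.snps,
            h1=h1,
            h2=h2,
            phased=self.phased,
            depth=self.depth,
        )

    def copy(self) -> "CohortGenotypes":
        return CohortGenotypes(
            individuals=self.individuals.copy(),
            snps=self.snps.copy(),
            h1=self.h1.copy(),
            h2=self.h2.copy(),
            phased=self.phased.copy(),
            depth=self.depth.copy(),
        )
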
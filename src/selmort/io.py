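"""VCF and table I/O.

VCFs are read with cyvcf2 and written as plain VCF 4.2 text with ``GT:DP``
calls. SNP IDs of the form ``tag<k>_snp<j>`` carry the RAD-tag grouping; for
records without such an ID the CHROM field is used as the tag.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from selmort.cohort import MISSING, CohortGenotypes

_TAG_RE = re.compile(r"^(?P<tag>.+)_snp\d+$")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    required = {"individual", "locality", "age_group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta.set_index("individual")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "individual" not in df.columns:
        raise ValueError("phenotype table must have an 'individual' column")
    return df.set_index("individual")


def read_vcf(path, metadata_path) -> CohortGenotypes:
    """Load a multi-sample biallelic-SNP VCF into a :class:`CohortGenotypes`.

    Half-missing diploid calls are treated as missing. Non-biallelic records
    are skipped with a warning. Every VCF sample must appear in the metadata.
    """
    from cyvcf2 import VCF

    meta = read_metadata(metadata_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValueError(f"VCF sample(s) absent from metadata: {', '.join(unknown)}")

    h1_cols, h2_cols, ph_cols, dp_cols = [], [], [], []
    snp_rows = []
    n = len(samples)
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            warnings.warn(
                f"skipping non-biallelic-SNP record at {v.CHROM}:{v.POS}",
                stacklevel=2,
            )
            continue
        g = np.array(v.genotypes, dtype=np.int64)  # (n, 3): a1, a2, phased
        a1 = g[:, 0].astype(np.int8)
        a2 = g[:, 1].astype(np.int8)
        ph = g[:, 2].astype(bool)
        miss = (a1 < 0) | (a2 < 0)
        a1[miss] = MISSING
        a2[miss] = MISSING
        dp = v.format("DP")
        if dp is None:
            depth = np.zeros(n, dtype=np.int32)
        else:
            depth = np.asarray(dp, dtype=np.int64).reshape(n).astype(np.int32)
            depth[depth < 0] = 0
        snp_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        m = _TAG_RE.match(snp_id)
        tag = m.group("tag") if m else v.CHROM
        snp_rows.append((snp_id, tag, v.POS, v.REF, v.ALT[0]))
        h1_cols.append(a1)
        h2_cols.append(a2)
        ph_cols.append(ph)
        dp_cols.append(depth)

    snps = pd.DataFrame(
        snp_rows, columns=["snp", "tag", "pos", "ref", "alt"]
    ).set_index("snp")
    individuals = meta.loc[samples, ["locality", "age_group"]]
    stack = lambda cols: (
        np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int8)
    )
    return CohortGenotypes(
        individuals=individuals,
        snps=snps,
        h1=stack(h1_cols).astype(np.int8),
        h2=stack(h2_cols).astype(np.int8),
        phased=stack(ph_cols).astype(bool),
        depth=stack(dp_cols).astype(np.int32),
    )


def write_vcf(cohort: CohortGenotypes, path) -> None:
    """Write a cohort as VCF 4.2 with GT:DP fields (deterministic bytes)."""
    path = Path(path)
    tags = list(dict.fromkeys(cohort.snps["tag"]))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=selmort",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={t},length=34>" for t in tags]
    samples = list(cohort.individuals.index)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    h1, h2, ph, dp = cohort.h1, cohort.h2, cohort.phased, cohort.depth
    snps = cohort.snps
    for j, (snp_id, row) in enumerate(snps.iterrows()):
        calls = []
        for i in range(cohort.n_individuals):
            if h1[i, j] == MISSING:
                gt = "./."
            else:
                sep = "|" if ph[i, j] else "/"
                gt = f"{h1[i, j]}{sep}{h2[i, j]}"
            calls.append(f"{gt}:{dp[i, j]}")
        lines.append(
            f"{row['tag']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t{row['alt']}"
            f"\t.\tPASS\t.\tGT:DP\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
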
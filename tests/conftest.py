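"""Shared fixtures: hand-built cohorts and tiny annotation inputs."""

from __future__ import annotations

import textwrap

import numpy as np
import pandas as pd
import pytest

from selmort.cohort import MISSING, CohortGenotypes


def make_cohort(
    genotypes: np.ndarray,
    depth: np.ndarray,
    localities,
    age_groups,
    tags,
    snp_ids=None,
    phased: bool = True,
) -> CohortGenotypes:
    """Build a cohort from a 0/1/2/MISSING genotype matrix.

    Heterozygotes are phased as 0|1; MISSING genotypes become missing calls.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    h1 = np.where(g == 2, 1, 0).astype(np.int8)
    h2 = np.where(g >= 1, 1, 0).astype(np.int8)
    h1[g == MISSING] = MISSING
    h2[g == MISSING] = MISSING
    snp_ids = snp_ids or [f"{t}_snp1" for t in tags]
    individuals = pd.DataFrame(
        {
            "locality": list(localities),
            "age_group": list(age_groups),
        },
        index=pd.Index([f"ind{i:03d}" for i in range(n)], name="individual"),
    )
    snps = pd.DataFrame(
        {
            "tag": list(tags),
            "pos": [5] * m,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    return CohortGenotypes(
        individuals=individuals,
        snps=snps,
        h1=h1,
        h2=h2,
        phased=np.full((n, m), phased),
        depth=np.asarray(depth, dtype=np.int32),
    )


# A per-locality genotype block in good Hardy-Weinberg shape at MAF 0.5
# (3 hom-ref, 4 het, 3 hom-alt across 10 individuals).
CLEAN_BLOCK = [0, 0, 0, 1, 1, 1, 1, 2, 2, 2]


@pytest.fixture
def filter_cascade_cohort() -> tuple[CohortGenotypes, dict]:
    """Six-SNP cohort where four SNPs each trip exactly one cascade stage.

    30 individuals (3 localities x 10, half settlers / half survivors);
    SNPs, one per tag:

    * ``clean1``, ``clean2`` — survive every stage;
    * ``missfail`` — 12/30 calls below the 5x depth floor, so missingness
      0.4 > 0.3 after masking;
    * ``raremaf`` — a single heterozygote, MAF 1/60 < 0.05;
    * ``deeptag`` — tag mean depth 200 against the other tags' 20, beyond
      the Tukey fence Q3 + 1.5 IQR;
    * ``hwefail`` — every individual heterozygous, rejected by the HWE
      mid-p exact test in all three localities.
    """
    n = 30
    clean = CLEAN_BLOCK * 3
    rare = [0] * 15 + [1] + [0] * 14
    allhet = [1] * n
    genotypes = np.array([clean, clean, clean, rare, clean, allhet]).T
    depth = np.full((n, 6), 20, dtype=np.int32)
    depth[:12, 2] = 2  # masked at stage 1 -> missingness 0.4
    depth[:, 4] = 200
    tags = ["clean1", "clean2", "missfail", "raremaf", "deeptag", "hwefail"]
    cohort = make_cohort(
        genotypes,
        depth,
        localities=np.repeat(["A", "B", "C"], 10),
        age_groups=(["settler"] * 5 + ["survivor"] * 5) * 3,
        tags=tags,
    )
    expected = {
        "survivors": {"clean1_snp1", "clean2_snp1"},
        "masked_calls": 12,
        "removed_missingness": 1,
        "removed_maf": 1,
        "removed_tag_depth": 1,
        "removed_hwe": 1,
    }
    return cohort, expected


@pytest.fixture
def blast_and_gff(tmp_path):
    """Tiny BLAST outfmt-6 table + GFF3 covering every mapping/region case."""
    blast = tmp_path / "hits.tsv"
    blast.write_text(
        "exonlocus\tchr1\t100.0\t34\t0\t0\t1\t34\t101\t134\t1e-10\t60.0\n"
        "intronlocus\tchr1\t100.0\t34\t0\t0\t1\t34\t250\t283\t1e-10\t60.0\n"
        "minuslocus\tchr1\t100.0\t34\t0\t0\t1\t34\t500\t467\t1e-10\t60.0\n"
        "interlocus\tchr1\t100.0\t34\t0\t0\t1\t34\t900\t933\t1e-10\t60.0\n"
        "weaklocus\tchr1\t95.0\t34\t2\t0\t1\t34\t700\t733\t1e-3\t40.0\n"
        "multilocus\tchr1\t100.0\t34\t0\t0\t1\t34\t101\t134\t1e-10\t60.0\n"
        "multilocus\tchr1\t100.0\t34\t0\t0\t1\t34\t700\t733\t1e-10\t60.0\n"
        "duplocus\tchr1\t100.0\t34\t0\t0\t1\t34\t120\t153\t1e-10\t60.0\n"
        "duplocus\tchr1\t100.0\t34\t0\t0\t1\t34\t120\t153\t1e-9\t55.0\n"
        "junctionlocus\tchr1\t100.0\t34\t0\t0\t1\t34\t190\t223\t1e-10\t60.0\n"
        "otherctg\tchrZ\t100.0\t34\t0\t0\t1\t34\t10\t43\t1e-10\t60.0\n"
    )
    gff = tmp_path / "ref.gff3"
    gff.write_text(
        textwrap.dedent(
            """\
            ##gff-version 3
            chr1\tsrc\tgene\t50\t600\t.\t+\t.\tID=geneA;gene_biotype=protein_coding
            chr1\tsrc\tmRNA\t50\t600\t.\t+\t.\tID=mrnaA;Parent=geneA
            chr1\tsrc\texon\t50\t200\t.\t+\t.\tID=exA1;Parent=mrnaA
            chr1\tsrc\texon\t420\t600\t.\t+\t.\tID=exA2;Parent=mrnaA
            chr1\tsrc\tgene\t650\t800\t.\t-\t.\tID=geneB;gene_biotype=lncRNA
            chr1\tsrc\tmRNA\t650\t800\t.\t-\t.\tID=mrnaB;Parent=geneB
            chr1\tsrc\texon\t650\t800\t.\t-\t.\tID=exB1;Parent=mrnaB
            """
        )
    )
    return blast, gff
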
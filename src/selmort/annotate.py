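"""Genomic annotation of RAD loci from BLAST tabular hits and a GFF3.

Loci are classified by mapping status (unmapped / unique / multiple, after
coordinate deduplication), uniquely mapped hits are placed relative to gene
and exon features (exonic / intronic / intergenic), sets of loci are
compared with Pearson chi-squares, and exonic SNPs are translated into
amino-acid effects (strand-aware, joint substitution of SNPs sharing a
codon).

Coordinate conventions: BLAST subject coordinates and GFF3 features are
1-based inclusive on input; every internal interval is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy.stats import chi2

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# BLAST tabular parsing and mapping classification


def parse_blast_tab(path, evalue_cutoff: float = 1e-4) -> pd.DataFrame:
    """Parse an outfmt-6 BLAST table, keeping hits with E-value <= cutoff.

    Returns a DataFrame with the twelve standard columns plus normalized
    0-based half-open subject coordinates (``s0``, ``s1``) and ``strand``
    (minus when sstart > send). Malformed rows raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 12 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rec = dict(zip(BLAST6_COLUMNS, parts))
                for key in ("pident", "evalue", "bitscore"):
                    rec[key] = float(rec[key])
                for key in ("length", "mismatch", "gapopen", "qstart", "qend",
                            "sstart", "send"):
                    rec[key] = int(rec[key])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            rows.append(rec)
    df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    if df.empty:
        df = df.assign(s0=[], s1=[], strand=[])
        return df
    df = df[df["evalue"] <= evalue_cutoff].reset_index(drop=True)
    minus = df["sstart"] > df["send"]
    lo = np.where(minus, df["send"], df["sstart"])
    hi = np.where(minus, df["sstart"], df["send"])
    df["s0"] = lo - 1  # 0-based half-open
    df["s1"] = hi
    df["strand"] = np.where(minus, "-", "+")
    return df


def classify_mapping(hits: pd.DataFrame, loci=None) -> pd.DataFrame:
    """Per-locus mapping class from passing hits.

    After deduplicating identical-coordinate hits, 0 hits -> ``unmapped``,
    1 -> ``unique`` (with its reference interval), >= 2 -> ``multiple``.
    ``loci`` optionally supplies the full locus universe so that loci with
    no hit at all appear as unmapped.
    """
    dedup = hits.drop_duplicates(subset=["qseqid", "sseqid", "s0", "s1"])
    universe = list(loci) if loci is not None else sorted(dedup["qseqid"].unique())
    by_locus = {q: g for q, g in dedup.groupby("qseqid")}
    rows = []
    for locus in universe:
        g = by_locus.get(locus)
        if g is None or len(g) == 0:
            rows.append((locus, "unmapped", None, np.nan, np.nan, None))
        elif len(g) == 1:
            h = g.iloc[0]
            rows.append(
                (locus, "unique", h["sseqid"], int(h["s0"]), int(h["s1"]), h["strand"])
            )
        else:
            rows.append((locus, "multiple", None, np.nan, np.nan, None))
    return pd.DataFrame(
        rows, columns=["locus", "mapping", "contig", "start", "end", "strand"]
    ).set_index("locus")


# ---------------------------------------------------------------------- #
# GFF3 placement


@dataclass
class GffIndex:
    """Interval index of genes and their exons from a GFF3 annotation."""

    genes: dict[str, IntervalTree]  # contig -> tree of (start, end, gene_id)
    gene_info: dict[str, dict]  # gene_id -> {biotype, contig, start, end}
    exons: dict[str, IntervalTree]  # gene_id -> tree of exon intervals

    @classmethod
    def from_file(cls, path) -> "GffIndex":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes: dict[str, IntervalTree] = {}
        gene_info: dict[str, dict] = {}
        exons: dict[str, IntervalTree] = {}
        for gene in db.features_of_type("gene"):
            gid = gene.id
            start0, end0 = gene.start - 1, gene.end  # to 0-based half-open
            biotype = (
                gene.attributes.get("gene_biotype")
                or gene.attributes.get("biotype")
                or ["protein_coding"]
            )[0]
            genes.setdefault(gene.seqid, IntervalTree()).addi(start0, end0, gid)
            gene_info[gid] = {
                "biotype": biotype,
                "contig": gene.seqid,
                "start": start0,
                "end": end0,
                "strand": gene.strand,
            }
            tree = IntervalTree()
            for exon in db.children(gene, featuretype="exon"):
                tree.addi(exon.start - 1, exon.end)
            exons[gid] = tree
        return cls(genes=genes, gene_info=gene_info, exons=exons)


def locate_in_gff(
    contig: str, start: int, end: int, gff: GffIndex
) -> tuple[str, str | None, str | None]:
    """Region class of a 0-based half-open reference interval.

    Returns (region, gene_id, biotype) with region in {exonic, intronic,
    intergenic}. Overlapping >= 1 bp of any exon of the assigned gene is
    exonic; inside the gene with no exon overlap is intronic. With several
    overlapping genes the gene with the longest overlap wins (ties break to
    the lexicographically lowest gene ID). A contig absent from the GFF is
    classified intergenic with a warning.
    """
    tree = gff.genes.get(contig)
    if tree is None:
        warnings.warn(
            f"contig {contig!r} absent from the GFF; classifying as intergenic",
            stacklevel=2,
        )
        return "intergenic", None, None
    overlaps = tree.overlap(start, end)
    if not overlaps:
        return "intergenic", None, None
    best = max(
        overlaps,
        key=lambda iv: (min(iv.end, end) - max(iv.begin, start), _neg_lex(iv.data)),
    )
    gene_id = best.data
    exon_overlap = gff.exons.get(gene_id, IntervalTree()).overlap(start, end)
    region = "exonic" if exon_overlap else "intronic"
    return region, gene_id, gff.gene_info[gene_id]["biotype"]


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the lowest ID."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def annotate_loci(
    hits: pd.DataFrame, gff: GffIndex, loci=None
) -> pd.DataFrame:
    """Full annotation table: mapping class plus region/gene for unique hits."""
    table = classify_mapping(hits, loci=loci)
    regions, genes, biotypes = [], [], []
    for _, row in table.iterrows():
        if row["mapping"] != "unique":
            regions.append(None)
            genes.append(None)
            biotypes.append(None)
            continue
        region, gene, biotype = locate_in_gff(
            row["contig"], int(row["start"]), int(row["end"]), gff
        )
        regions.append(region)
        genes.append(gene)
        biotypes.append(biotype)
    table["region"] = regions
    table["gene"] = genes
    table["biotype"] = biotypes
    return table


# ---------------------------------------------------------------------- #
# enrichment chi-square


def enrichment_chisq(
    set_counts, background_counts, categories=None
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square comparing category counts of a set vs a background.

    Builds the (2 x k) contingency table; categories with zero combined
    total are dropped with a warning. Returns (statistic, p, table); the
    statistic is symmetric in which count vector is called the set.
    """
    a = np.asarray(set_counts, dtype=float)
    b = np.asarray(background_counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the same categories")
    if categories is None:
        categories = [f"cat{i}" for i in range(a.size)]
    total = a + b
    keep = total > 0
    if not keep.all():
        dropped = [c for c, k in zip(categories, keep) if not k]
        warnings.warn(f"dropping empty categories: {dropped}", stacklevel=2)
    a, b = a[keep], b[keep]
    categories = [c for c, k in zip(categories, keep) if k]
    if a.size < 2:
        raise ValueError("need at least two non-empty categories")
    obs = np.vstack([a, b])
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    p = float(chi2.sf(stat, df=df))
    table = pd.DataFrame(obs, index=["set", "background"], columns=categories)
    return stat, p, table


# ---------------------------------------------------------------------- #
# codon effects


@dataclass
class CodonEffect:
    gene: str
    strand: str
    codon_number: int  # 1-based position in the protein
    ref_codon: str
    alt_codon: str
    offsets: tuple[int, ...]  # 1/2/3 positions within the codon
    ref_aa: str | None
    alt_aa: str | None
    synonymous: bool | None  # None when undetermined (ambiguous bases)


def codon_effect(
    cds_seq: str,
    positions,
    ref_alleles,
    alt_alleles,
    strand: str = "+",
    gene: str = "",
) -> list[CodonEffect]:
    """Amino-acid effects of SNPs inside a coding sequence.

    Parameters
    ----------
    cds_seq
        The spliced CDS in genomic plus-strand orientation.
    positions
        0-based offsets of the SNPs within ``cds_seq`` (plus-strand).
    ref_alleles, alt_alleles
        Plus-strand alleles at those positions; each ref must match the
        sequence.
    strand
        ``+`` or ``-``; minus-strand genes are translated on the reverse
        complement, with positions and alleles converted accordingly.

    SNPs sharing a codon are substituted jointly. Codons containing
    ambiguous bases come back with an undetermined effect.
    """
    seq = str(cds_seq).upper()
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if len(seq) % 3 != 0:
        raise AnnotationError("CDS length is not a multiple of 3")
    n = len(seq)
    items = []
    for pos, ref, alt in zip(positions, ref_alleles, alt_alleles):
        pos = int(pos)
        if not (0 <= pos < n):
            raise AnnotationError(f"position {pos} not inside the CDS (length {n})")
        ref, alt = ref.upper(), alt.upper()
        if seq[pos] != ref:
            raise AnnotationError(
                f"reference allele mismatch at CDS position {pos}: "
                f"sequence has {seq[pos]}, got {ref}"
            )
        if strand == "-":
            cpos = n - 1 - pos
            cref = str(Seq(ref).complement())
            calt = str(Seq(alt).complement())
        else:
            cpos, cref, calt = pos, ref, alt
        items.append((cpos, cref, calt))

    coding = str(Seq(seq).reverse_complement()) if strand == "-" else seq
    by_codon: dict[int, list] = {}
    for cpos, cref, calt in items:
        by_codon.setdefault(cpos // 3, []).append((cpos, cref, calt))

    effects = []
    for codon_idx in sorted(by_codon):
        ref_codon = coding[3 * codon_idx : 3 * codon_idx + 3]
        alt_list = list(ref_codon)
        offsets = []
        for cpos, cref, calt in sorted(by_codon[codon_idx]):
            off = cpos - 3 * codon_idx
            if alt_list[off] != cref:
                raise AnnotationError("reference allele mismatch inside codon")
            alt_list[off] = calt
            offsets.append(off + 1)
        alt_codon = "".join(alt_list)
        if set(ref_codon + alt_codon) - set("ACGT"):
            ref_aa = alt_aa = None
            synonymous = None
        else:
            ref_aa = str(Seq(ref_codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            synonymous = ref_aa == alt_aa
        effects.append(
            CodonEffect(
                gene=gene,
                strand=strand,
                codon_number=codon_idx + 1,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                offsets=tuple(offsets),
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                synonymous=synonymous,
            )
        )
    return effects
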
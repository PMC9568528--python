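"""End-to-end orchestration with a single YAML config and a run manifest.

``run_all`` executes (optionally) simulate -> filter -> structure -> gea per
locality -> parallel -> annotate, writing each stage's outputs under the
output directory and a ``manifest.json`` with the config hash and per-file
SHA-256 checksums. Reruns with the same config and seeds reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from selmort import filtering, gea, io, parallel as par, popgen, simulate
from selmort.cohort import CohortGenotypes

log = logging.getLogger("selmort")


@dataclass
class RunConfig:
    output_dir: Path
    vcf: Path | None = None
    metadata: Path | None = None
    phenotypes: Path | None = None
    blast: Path | None = None
    gff: Path | None = None
    cds_fasta: Path | None = None
    simulate: simulate.SimulationConfig | None = None
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    corr_threshold: float = 0.8
    sd_mult: float = 3.0
    n_axes: int | None = None
    scale_genotypes: bool = False
    evalue_cutoff: float = 1e-4
    n_permutations: int = 999
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {"raw": raw}
        kwargs["output_dir"] = Path(raw.get("output_dir", "selmort_out"))
        for key in ("vcf", "metadata", "phenotypes", "blast", "gff", "cds_fasta"):
            if raw.get(key):
                kwargs[key] = Path(raw[key])
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"] if isinstance(raw["simulate"], dict) else {}
            kwargs["simulate"] = simulate.SimulationConfig(**sim)
        if "filter" in raw and raw["filter"]:
            kwargs["filter"] = filtering.FilterConfig(**raw["filter"])
        for key in (
            "corr_threshold",
            "sd_mult",
            "n_axes",
            "scale_genotypes",
            "evalue_cutoff",
            "n_permutations",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def validate(self) -> None:
        if self.simulate is None:
            for key in ("vcf", "metadata", "phenotypes"):
                value = getattr(self, key)
                if value is None:
                    raise ValueError(f"config lacks required path: {key}")
                if not Path(value).exists():
                    raise ValueError(f"{key} path does not exist: {value}")
        else:
            self.simulate.validate()
        for key in ("blast", "gff", "cds_fasta"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ValueError(f"{key} path does not exist: {value}")
        self.filter.validate()

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in sorted(self.raw.items())}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, outputs: list[Path], counts: dict, t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "counts": counts,
                "elapsed_s": round(time.time() - t0, 3),
            }
        )
        log.info("stage %s done: %s", stage, counts)

    try:
        # ---- simulate -------------------------------------------------- #
        t0 = time.time()
        if config.simulate is not None:
            sim = simulate.simulate_cohort(config.simulate)
            vcf_path = out / "simulated.vcf"
            meta_path = out / "metadata.csv"
            pheno_path = out / "phenotypes.csv"
            truth_path = out / "truth.csv"
            io.write_vcf(sim.cohort, vcf_path)
            simulate.write_metadata(sim.cohort, meta_path)
            simulate.write_phenotypes(sim.phenotypes, pheno_path)
            sim.truth.to_csv(truth_path)
            config.vcf, config.metadata, config.phenotypes = (
                vcf_path,
                meta_path,
                pheno_path,
            )
            record(
                "simulate",
                [vcf_path, meta_path, pheno_path, truth_path],
                {
                    "individuals": sim.cohort.n_individuals,
                    "snps": sim.cohort.n_snps,
                },
                t0,
            )
        cohort = io.read_vcf(config.vcf, config.metadata)
        pheno = io.read_phenotypes(config.phenotypes).loc[cohort.individuals.index]

        # ---- filter ---------------------------------------------------- #
        t0 = time.time()
        filtered, report = filtering.apply_filters(cohort, config.filter)
        report_path = out / "filter_report.json"
        report.to_json(report_path)
        filtered_vcf = out / "filtered.vcf"
        io.write_vcf(filtered, filtered_vcf)
        haplos, n_unphased = filtering.collapse_haplotypes(filtered)
        haplo_path = out / "haplotypes.csv"
        filtering.write_haplotype_table(haplos, haplo_path)
        record(
            "filter",
            [report_path, filtered_vcf, haplo_path],
            {
                "snps_in": report.n_input_snps,
                "snps_out": report.n_output_snps,
                "haplotype_loci": report.n_haplotype_loci,
                "unphased_set_missing": n_unphased,
            },
            t0,
        )

        # ---- structure ------------------------------------------------- #
        t0 = time.time()
        calls = filtered.calls
        localities = filtered.localities
        fst_rows = []
        for age in ("settler", "survivor"):
            age_mask = filtered.age_mask(age)
            for i in range(len(localities)):
                for j in range(i + 1, len(localities)):
                    ga = calls[age_mask & filtered.locality_mask(localities[i])]
                    gb = calls[age_mask & filtered.locality_mask(localities[j])]
                    p, res = popgen.fst_permutation_test(
                        ga,
                        gb,
                        n_perm=config.n_permutations,
                        seed=config.seed + 1000 * i + j,
                    )
                    fst_rows.append(
                        (age, localities[i], localities[j], res.theta, p)
                    )
        fst_df = pd.DataFrame(
            fst_rows, columns=["age_group", "a", "b", "theta", "p_value"]
        )
        fst_path = out / "fst_pairwise.csv"
        fst_df.to_csv(fst_path, index=False)

        perm_rows = []
        factors = filtered.individuals[["age_group", "locality"]]
        for var in pheno.columns:
            res = popgen.permanova(
                pheno[var].to_numpy(dtype=float),
                factors,
                n_perm=config.n_permutations,
                seed=config.seed,
            )
            for term, row in res.table.iterrows():
                perm_rows.append((var, term, *row.tolist()))
        perm_df = pd.DataFrame(
            perm_rows,
            columns=["variable", "term", "df", "ss", "pseudo_f", "r2", "p_value"],
        )
        perm_path = out / "permanova.csv"
        perm_df.to_csv(perm_path, index=False)

        hap_counts = filtering.haplotype_allele_counts(haplos)
        dapc_res = popgen.dapc(
            hap_counts, filtered.individuals["locality"]
        )
        dapc_path = out / "dapc_scores.csv"
        dapc_res.scores.join(dapc_res.posterior.add_prefix("p_")).to_csv(dapc_path)
        record(
            "structure",
            [fst_path, perm_path, dapc_path],
            {"fst_pairs": len(fst_df), "permanova_vars": pheno.shape[1],
             "dapc_pcs": dapc_res.n_pcs},
            t0,
        )

        # ---- gea (per-locality RDA scans) ------------------------------ #
        t0 = time.time()
        scans = {}
        scan_paths = []
        snp_ids = list(filtered.snps.index)
        for loc in localities:
            mask = filtered.locality_mask(loc)
            scan = gea.scan_locality(
                calls[mask],
                snp_ids,
                pheno.loc[mask],
                locality=loc,
                global_calls=calls,
                corr_threshold=config.corr_threshold,
                n_axes=config.n_axes,
                sd_mult=config.sd_mult,
                scale_genotypes=config.scale_genotypes,
            )
            scans[loc] = scan
            path = out / f"rda_candidates_{loc}.csv"
            scan.outliers.to_csv(path)
            scan_paths.append(path)
        record(
            "gea",
            scan_paths,
            {loc: len(scans[loc].outliers) for loc in localities},
            t0,
        )

        # ---- parallel --------------------------------------------------- #
        t0 = time.time()
        pset = par.intersect_parallel(scans)
        corr_by_loc = {loc: scans[loc].outlier_corr for loc in localities}
        categories = par.categorize_by_predictor(pset, corr_by_loc)
        members = pset.members.copy()
        chis = []
        for snp in members.index:
            jj = snp_ids.index(snp)
            set_counts = par.allele_counts(
                calls[filtered.age_mask("settler"), jj]
            )
            sur_counts = par.allele_counts(
                calls[filtered.age_mask("survivor"), jj]
            )
            test = par.allele_freq_change_test(set_counts, sur_counts, snp=snp)
            chis.append((test.statistic, test.p_value))
        members["chisq"] = [c[0] for c in chis]
        members["chisq_p"] = [c[1] for c in chis]
        pset_path = out / "parallel_set.csv"
        members.to_csv(pset_path)
        cat_path = out / "predictor_categories.csv"
        categories.assign(
            predictors=categories["predictors"].map(lambda c: "+".join(c))
        ).to_csv(cat_path, index=False)
        record(
            "parallel",
            [pset_path, cat_path],
            {"parallel_snps": len(members), "categories": len(categories)},
            t0,
        )

        # ---- annotate ---------------------------------------------------- #
        if config.blast is not None and config.gff is not None:
            from selmort import annotate as ann

            t0 = time.time()
            hits = ann.parse_blast_tab(config.blast, config.evalue_cutoff)
            gff_index = ann.GffIndex.from_file(config.gff)
            all_loci = sorted(filtered.snps["tag"].unique())
            table = ann.annotate_loci(hits, gff_index, loci=all_loci)
            ann_path = out / "annotation.csv"
            table.to_csv(ann_path)

            parallel_loci = set(
                filtered.snps.loc[
                    filtered.snps.index.intersection(members.index), "tag"
                ]
            )
            mapped = table["mapping"] != "unmapped"
            in_set = table.index.isin(parallel_loci)
            enrich: dict = {}
            if in_set.any() and (~in_set).any():
                stat, pval, _ = ann.enrichment_chisq(
                    [int((mapped & in_set).sum()), int((~mapped & in_set).sum())],
                    [int((mapped & ~in_set).sum()), int((~mapped & ~in_set).sum())],
                    categories=["mapped", "unmapped"],
                )
                enrich["mapped_vs_unmapped"] = {"chisq": stat, "p_value": pval}
            enrich_path = out / "enrichment.json"
            _write_json(enrich, enrich_path)
            record(
                "annotate",
                [ann_path, enrich_path],
                {
                    "loci": len(table),
                    "unique": int((table["mapping"] == "unique").sum()),
                },
                t0,
            )

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(manifest, manifest_path)
        raise
    _write_json(manifest, manifest_path)
    return manifest
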
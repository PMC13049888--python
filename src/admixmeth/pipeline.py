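"""End-to-end orchestration of the synthetic analysis pipeline.

Runs the stages in dependency order -- simulate, ancestry scan, species
contrast, meQTL mapping, composition, variance gain, reporter-assay
calls -- writing standard-format outputs and a provenance manifest
(config, seed, per-stage row counts at every filter). All randomness
flows from one root seed through named substreams, so the same config
always produces byte-identical outputs.

Repeat samples (the same individual profiled more than once) are
collapsed upstream of any scan by summing counts per individual.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .ancestry import filter_sites, scan
from .composition import build_records, compare
from .containers import MethCountMatrix
from .exceptions import DataError, StateError
from .meqtl import distance_effect, map_meqtl, pairs_from_cohort
from .mstarr import activity_scan, test_methylation_dependence
from .simulate import (
    ReporterConfig,
    SimConfig,
    simulate_cohort,
    simulate_parental_cohort,
    simulate_reporter,
)
from .species import concordance, filter_species_sites, test_species
from .variance import gain_vs_introgression, maf_shift, sd_gain

__all__ = ["PipelineConfig", "collapse_repeat_samples", "run", "STAGES"]

STAGES = ("simulate", "scan_ancestry", "species_diff", "map_meqtl",
          "compose", "variance", "mstarr", "report")
_DEPS = {
    "scan_ancestry": ("simulate",),
    "species_diff": ("simulate", "scan_ancestry"),
    "map_meqtl": ("simulate",),
    "compose": ("scan_ancestry", "map_meqtl"),
    "variance": ("simulate", "scan_ancestry", "map_meqtl"),
    "mstarr": (),
    "report": (),
}


@dataclass
class PipelineConfig:
    """Declarative configuration: thresholds named after the rules they set."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_individuals=80, n_snps=300, n_cpgs=300, chrom_length=5_000_000,
        mean_tract_bp=400_000.0))
    reporter: ReporterConfig = field(default_factory=lambda: ReporterConfig(
        n_windows=1500))
    stages: tuple = STAGES
    n_permutations: int = 10
    seed: int = 0
    fdr: float = 0.10
    species_nominal_p: float = 0.01
    meqtl_maf: float = 0.05
    pair_distance: int = 100
    min_per_state: int = 10
    meth_bounds: tuple = (0.1, 0.9)
    n_yellow: int = 6
    n_anubis: int = 9


def collapse_repeat_samples(matrix, sample_to_individual):
    """Sum counts across repeat samples of the same individual.

    ``sample_to_individual`` maps sample ID -> individual ID (dict or
    two-column DataFrame with columns sample, individual). A sample
    mapped to two individuals is an input error.
    """
    if isinstance(sample_to_individual, pd.DataFrame):
        conflicting = (
            sample_to_individual.groupby("sample")["individual"].nunique() > 1
        )
        if conflicting.any():
            bad = conflicting[conflicting].index.tolist()[:3]
            raise DataError(f"samples mapped to multiple individuals: {bad}")
        mapping = dict(
            zip(sample_to_individual["sample"], sample_to_individual["individual"])
        )
    else:
        mapping = dict(sample_to_individual)
    missing = [s for s in matrix.individuals if s not in mapping]
    if missing:
        raise DataError(f"samples without individual mapping: {missing[:3]}")
    individuals = sorted({mapping[s] for s in matrix.individuals}, key=str)
    idx = {ind: i for i, ind in enumerate(individuals)}
    ns = matrix.n_sites
    meth = np.zeros((ns, len(individuals)), dtype=matrix.meth.dtype)
    total = np.zeros_like(meth)
    for col, sample in enumerate(matrix.individuals):
        i = idx[mapping[sample]]
        meth[:, i] += matrix.meth[:, col]
        total[:, i] += matrix.total[:, col]
    return MethCountMatrix(
        chrom=matrix.chrom, pos=matrix.pos, individuals=individuals,
        meth=meth, total=total,
    )


def _config_hash(config):
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config, outdir):
    """Execute the enabled stages and write outputs plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    Raises StateError if an enabled stage's dependency is disabled.
    """
    for stage in config.stages:
        for dep in _DEPS.get(stage, ()):
            if dep not in config.stages:
                raise StateError(f"stage {stage!r} requires disabled stage {dep!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(int(config.seed))
    sub = {name: int(s.generate_state(1)[0]) % (2**31)
           for name, s in zip(STAGES, root.spawn(len(STAGES)))}
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": int(config.seed),
        "stages": {},
        "files": [],
    }

    def record(stage, **info):
        manifest["stages"][stage] = info

    cohort = scan_res = meqtl_res = None
    sim_cfg = dataclasses.replace(config.sim, seed=sub["simulate"])

    if "simulate" in config.stages:
        cohort = simulate_cohort(sim_cfg)
        io.write_vcf(cohort.genotypes, outdir / "genotypes.vcf")
        io.write_counts_tsv(cohort.counts, outdir / "meth_counts.tsv")
        io.write_ancestry_bed(cohort.panel, outdir / "ancestry_tracts.bed")
        pd.DataFrame({
            "cpg_chrom": cohort.counts.chrom,
            "cpg_pos": cohort.counts.pos,
            "m_ref": cohort.truth.m_ref,
            "m_alt": cohort.truth.m_alt,
            "linked_snp": cohort.truth.linked_snp,
            "is_disrupted": cohort.truth.is_disrupted,
            "true_ancestry_effect": cohort.truth.true_ancestry_effect,
        }).to_csv(outdir / "truth_cpgs.tsv", sep="\t", index=False)
        manifest["files"] += ["genotypes.vcf", "meth_counts.tsv",
                              "ancestry_tracts.bed", "truth_cpgs.tsv"]
        record("simulate", n_individuals=sim_cfg.n_individuals,
               n_cpgs=int(cohort.counts.n_sites),
               n_snps=int(cohort.genotypes.n_snps),
               n_pairs=int(len(cohort.pairs)))

    if "scan_ancestry" in config.stages:
        keep = filter_sites(cohort.counts, cohort.panel,
                            min_per_state=config.min_per_state,
                            meth_bounds=config.meth_bounds)
        sub_counts = cohort.counts.subset_sites(keep)
        sub_panel = cohort.panel.subset_loci(keep)
        scan_res = scan(sub_counts, sub_panel, n_perm=config.n_permutations,
                        seed=sub["scan_ancestry"], test_global=False)
        scan_res.table.to_csv(outdir / "ancestry_scan.tsv", sep="\t", index=False)
        manifest["files"].append("ancestry_scan.tsv")
        record("scan_ancestry", input_sites=int(cohort.counts.n_sites),
               filtered_sites=int(len(keep)),
               not_converged=int(scan_res.n_not_converged),
               significant=int((scan_res.table["q_local"] < config.fdr).sum()))
        scan_res._kept = keep

    if "species_diff" in config.stages:
        cy, ca = simulate_parental_cohort(
            cohort, config.n_yellow, config.n_anubis, sub["species_diff"])
        sp_keep = filter_species_sites(cy, ca, meth_bounds=config.meth_bounds)
        sp = test_species(cy.subset_sites(sp_keep), ca.subset_sites(sp_keep),
                          n_perm=config.n_permutations, seed=sub["species_diff"])
        sp.table.to_csv(outdir / "species_diff.tsv", sep="\t", index=False)
        conc = concordance(sp, scan_res.table, p_thresh=config.species_nominal_p,
                           fdr_thresh=config.fdr)
        (outdir / "concordance.json").write_text(json.dumps({
            "pearson_r": conc.pearson_r, "spearman_rho": conc.spearman_rho,
            "fisher_log2_or": conc.fisher_log2_or,
            "frac_directionally_concordant": conc.frac_directionally_concordant,
            "n_overlap": conc.n_overlap}, indent=1, default=float))
        manifest["files"] += ["species_diff.tsv", "concordance.json"]
        record("species_diff", input_sites=int(cohort.counts.n_sites),
               filtered_sites=int(len(sp_keep)),
               significant=int((sp.table["p"] <= config.species_nominal_p).sum()))

    if "map_meqtl" in config.stages:
        pairs = pairs_from_cohort(cohort, min_maf=config.meqtl_maf,
                                  meth_bounds=config.meth_bounds)
        meqtl_res = map_meqtl(pairs, n_perm=config.n_permutations,
                              seed=sub["map_meqtl"])
        meqtl_res.table.to_csv(outdir / "meqtl.tsv", sep="\t", index=False)
        manifest["files"].append("meqtl.tsv")
        record("map_meqtl", input_pairs=int(len(cohort.pairs)),
               filtered_pairs=int(len(pairs)),
               significant=int((meqtl_res.table["q"] < config.fdr).sum()))

    if "compose" in config.stages:
        freq_table = pd.DataFrame({
            "chrom": cohort.genotypes.chrom, "pos": cohort.genotypes.pos,
            "p_yellow": cohort.freqs.p_yellow, "p_anubis": cohort.freqs.p_anubis,
        })
        records = build_records(meqtl_res.table, scan_res.table, freq_table,
                                fdr_thresh=config.fdr)
        records.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        manifest["files"].append("composition.tsv")
        if len(records) >= 3:
            summary = compare(records)
            (outdir / "composition_summary.json").write_text(json.dumps({
                "spearman_rho": summary.spearman_rho,
                "frac_concordant": summary.frac_concordant,
                "quadrants": summary.quadrant_counts, "n": summary.n},
                indent=1, default=float))
            manifest["files"].append("composition_summary.json")
            record("compose", n_records=int(len(records)),
                   spearman_rho=summary.spearman_rho)
        else:
            record("compose", n_records=int(len(records)), spearman_rho=None)

    if "variance" in config.stages:
        meqtl_snps = meqtl_res.table[meqtl_res.table["q"] < config.fdr]
        snp_idx = [int(np.where(cohort.genotypes.pos == p)[0][0])
                   for p in meqtl_snps["snp_pos"]]
        per_snp, maf_summary = maf_shift(cohort.genotypes.dosage,
                                         cohort.snp_panel, snp_set=snp_idx)
        sig_sites = scan_res._kept[
            (scan_res.table["q_local"] < config.fdr).to_numpy(bool)]
        meqtl_sites = [int(np.where((cohort.counts.chrom == c)
                                    & (cohort.counts.pos == p))[0][0])
                       for c, p in zip(meqtl_snps["cpg_chrom"], meqtl_snps["cpg_pos"])]
        sets = {
            "meqtl": np.array(meqtl_sites, dtype=int),
            "meqtl_and_ancestry": np.intersect1d(np.array(meqtl_sites, dtype=int),
                                                 sig_sites),
        }
        per_site, sd_summary = sd_gain(cohort.counts, cohort.panel, cpg_sets=sets)
        per_snp.to_csv(outdir / "maf_shift.tsv", sep="\t", index=False)
        per_site.to_csv(outdir / "sd_gain.tsv", sep="\t", index=False)
        manifest["files"] += ["maf_shift.tsv", "sd_gain.tsv"]
        record("variance", **{"maf_" + k: v for k, v in maf_summary.items()},
               **{f"sd_{name}_{k}": v for name, s in sd_summary.items()
                  for k, v in s.items()})

    if "mstarr" in config.stages:
        rep_cfg = dataclasses.replace(config.reporter, seed=sub["mstarr"])
        rc = simulate_reporter(rep_cfg)
        io.write_reporter_tsv(rc, outdir / "reporter_counts.tsv")
        res, sub_rc, abund = activity_scan(rc, n_perm=config.n_permutations,
                                           seed=sub["mstarr"], fdr=config.fdr)
        res = test_methylation_dependence(res, sub_rc, abund,
                                          n_perm=config.n_permutations,
                                          seed=sub["mstarr"] + 1, fdr=config.fdr)
        res.table.to_csv(outdir / "mstarr_calls.tsv", sep="\t", index=False)
        manifest["files"] += ["reporter_counts.tsv", "mstarr_calls.tsv"]
        record("mstarr", **res.filter_log,
               active=int(res.table["active_any"].sum()),
               meth_dependent=int(res.table["meth_dependent"].sum()))

    if "report" in config.stages:
        record("report", n_files=len(manifest["files"]))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
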
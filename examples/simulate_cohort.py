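"""Generate a synthetic admixed cohort and inspect its ground truth.

Builds a hybrid population of 120 individuals whose chromosomes are
mosaics of yellow and anubis ancestry tracts, with meQTL whose allele
frequencies have drifted apart between the parental taxa, and RRBS-like
methylation counts.
"""

import numpy as np

from admixmeth.simulate import SimConfig, simulate_cohort

cfg = SimConfig(n_individuals=120, n_snps=400, n_cpgs=400, seed=42)
cohort = simulate_cohort(cfg)

print(f"individuals:        {cfg.n_individuals}")
print(f"CpG sites:          {cohort.counts.n_sites}")
print(f"SNP-CpG pairs:      {len(cohort.pairs)} "
      f"({int(cohort.pairs.disrupted.sum())} CpG-disrupting)")
print(f"mean global anubis ancestry: {cohort.panel.global_ancestry.mean():.3f} "
      f"(target {cfg.admix_alpha})")
print(f"mean coverage:      {cohort.counts.total.mean():.1f} reads/site "
      f"(target {cfg.mean_coverage})")

dp = np.abs(cohort.freqs.p_anubis - cohort.freqs.p_yellow)
print(f"ancestry-informative markers (|dp| >= 0.2): "
      f"{cohort.freqs.is_aim.mean():.0%} of SNPs")
eff = cohort.truth.true_ancestry_effect[cohort.truth.has_meqtl]
print(f"true per-allele ancestry effects at meQTL CpGs: "
      f"median |effect| = {np.median(np.abs(eff)):.3f} on the proportion scale")
# The ancestry effect of a CpG is its meQTL effect times the parental
# allele-frequency difference, so larger drift means larger effects.
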
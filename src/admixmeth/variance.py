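"""How admixture shifts meQTL allele frequencies and inflates
methylation variance.

Two comparisons, both contrasting the "unadmixed-like" subset (the
individuals with homozygous yellow local ancestry at a locus) with the
full hybrid sample: minor allele frequencies at meQTL SNPs, and the
standard deviation of per-individual methylation ratios at meQTL CpGs.
The minor allele is defined in the subset and held fixed for the
full-sample estimate, so a positive shift is frequency change introduced
by admixture, not a re-folding artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError

__all__ = ["maf_shift", "sd_gain", "gain_vs_introgression"]


def maf_shift(dosage, panel, snp_set=None, min_subset=2, low_freq=0.10):
    """Minor-allele frequency in the yellow-homozygous subset vs everyone.

    Parameters
    ----------
    dosage : array (n_individuals, n_snps)
        Alt-allele genotype dosage (0/1/2; -1 missing).
    panel : AncestryPanel
        Local-ancestry dosage at the same SNP loci.
    snp_set : index array, optional
        SNPs to evaluate (e.g. mapped meQTL); default all.
    min_subset : int
        Minimum yellow-homozygous individuals required at a locus.
    low_freq : float
        Threshold for the low-subset-MAF stratum summary.

    Returns
    -------
    (DataFrame, dict)
        Per-SNP: maf_subset, maf_full, shift (full - subset), plus a
        summary with the paired t-test over SNPs, the low-frequency
        stratum mean shift, and the count of variants invariant in the
        subset but polymorphic overall (admixture-introduced variation).
    """
    dosage = np.asarray(dosage)
    idx = np.arange(dosage.shape[1]) if snp_set is None else np.asarray(snp_set)
    rows = []
    for j in idx:
        g = dosage[:, j]
        anc = panel.dosage[:, j]
        called = g >= 0
        sub = called & (anc == 0)
        if sub.sum() < min_subset:
            rows.append((j, np.nan, np.nan, np.nan, "empty_subset"))
            continue
        p_sub = g[sub].mean() / 2.0
        # minor allele fixed by the subset
        flip = p_sub > 0.5
        maf_sub = 1.0 - p_sub if flip else p_sub
        p_full = g[called].mean() / 2.0
        maf_full = 1.0 - p_full if flip else p_full
        rows.append((j, maf_sub, maf_full, maf_full - maf_sub, ""))
    per_snp = pd.DataFrame(
        rows, columns=["snp", "maf_subset", "maf_full", "shift", "skip_reason"]
    )
    ok = per_snp["shift"].notna()
    summary = {"n_snps": int(ok.sum())}
    if ok.sum() >= 2:
        t = stats.ttest_rel(per_snp.loc[ok, "maf_full"], per_snp.loc[ok, "maf_subset"])
        summary.update(
            mean_shift=float(per_snp.loc[ok, "shift"].mean()),
            sd_shift=float(per_snp.loc[ok, "shift"].std()),
            paired_t_p=float(t.pvalue),
        )
        low = ok & (per_snp["maf_subset"] <= low_freq)
        summary["n_low_freq"] = int(low.sum())
        if low.sum() >= 2:
            t_low = stats.ttest_rel(
                per_snp.loc[low, "maf_full"], per_snp.loc[low, "maf_subset"]
            )
            summary.update(
                mean_shift_low_freq=float(per_snp.loc[low, "shift"].mean()),
                paired_t_p_low_freq=float(t_low.pvalue),
            )
        introduced = ok & (per_snp["maf_subset"] == 0.0) & (per_snp["maf_full"] > 0.0)
        summary["n_introduced"] = int(introduced.sum())
    return per_snp, summary


def sd_gain(matrix, panel, cpg_sets=None, min_subset=10):
    """Standard deviation of methylation ratios: yellow subset vs full sample.

    Uses the raw per-individual ratio meth/total (individuals with zero
    total excluded). Per site, the subset is individuals with homozygous
    yellow local ancestry there; sites with fewer than ``min_subset``
    such individuals are skipped. ``cpg_sets`` maps stratum name ->
    site index array (e.g. meQTL CpGs, meQTL-and-ancestry-associated
    CpGs); per-stratum paired t-tests are reported alongside.

    Returns (per-site DataFrame, {stratum: summary dict}).
    """
    rows = []
    for j in range(matrix.n_sites):
        total = matrix.total[j]
        anc = panel.dosage[:, j]
        covered = total > 0
        sub = covered & (anc == 0)
        if sub.sum() < min_subset:
            rows.append((j, np.nan, np.nan, np.nan, "small_subset"))
            continue
        ratio = matrix.meth[j][covered] / total[covered]
        ratio_sub = matrix.meth[j][sub] / total[sub]
        sd_full = float(np.std(ratio, ddof=1))
        sd_sub = float(np.std(ratio_sub, ddof=1))
        gain = (sd_full - sd_sub) / sd_sub * 100.0 if sd_sub > 0 else np.nan
        rows.append((j, sd_sub, sd_full, gain, ""))
    per_site = pd.DataFrame(
        rows, columns=["site", "sd_subset", "sd_full", "pct_gain", "skip_reason"]
    )
    if cpg_sets is None:
        cpg_sets = {"all": np.arange(matrix.n_sites)}
    summaries = {}
    for name, idx in cpg_sets.items():
        sub = per_site[per_site["site"].isin(np.asarray(idx))]
        sub = sub[sub["pct_gain"].notna()]
        entry = {"n_sites": int(len(sub))}
        if len(sub) >= 2:
            t = stats.ttest_rel(sub["sd_full"], sub["sd_subset"])
            entry.update(
                mean_pct_gain=float(sub["pct_gain"].mean()),
                paired_t_p=float(t.pvalue),
            )
        summaries[name] = entry
    return per_site, summaries


def gain_vs_introgression(per_site, panel, min_sites=20):
    """OLS slope of per-site variance gain on local anubis-ancestry frequency.

    The predictor is the frequency of introgressed (anubis) alleles at
    the site, mean dosage / 2 across individuals.
    """
    import statsmodels.api as sm

    sub = per_site[per_site["pct_gain"].notna()]
    if len(sub) < min_sites:
        raise ParameterError(f"need >= {min_sites} sites with gains, got {len(sub)}")
    sites = sub["site"].to_numpy(dtype=int)
    introgression = panel.dosage[:, sites].mean(axis=0) / 2.0
    if np.ptp(introgression) == 0:
        return dict(slope=np.nan, p=np.nan, degenerate=True)
    X = sm.add_constant(introgression)
    fit = sm.OLS(sub["pct_gain"].to_numpy() / 100.0, X).fit()
    return dict(slope=float(fit.params[1]), p=float(fit.pvalues[1]), degenerate=False)
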
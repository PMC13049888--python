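"""Predicting ancestry effects from meQTL effects and parental
allele-frequency divergence.

The core identity: if an meQTL's two alleles have methylation
probabilities m_ref and m_alt (per-allele effect delta = m_alt - m_ref)
and the alternate allele segregates at frequency p in a population (or a
pool of same-ancestry alleles in hybrids), the expected mean methylation
of that pool is (1 - p) m_ref + p m_alt. The difference between the
anubis and yellow pools is therefore delta * (p_anubis - p_yellow): an
ancestry effect needs no taxon-specific biology, only a frequency shift
at a shared-effect variant. Comparing this prediction with observed
ancestry effects site-by-site quantifies how much of ancestry-associated
methylation is explained by allele-frequency divergence alone; sites in
the discordant quadrants (predicted and observed effects of opposite
sign) are candidates for lineage-specific effects.

Worked example: alleles with m_ref = 0 and m_alt = 0.5, alt frequency
0.25 in yellow and 1.0 in anubis, give pool means 12.5% and 50% and an
ancestry effect of 0.5 * 0.75 = 37.5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError

__all__ = [
    "population_mean_methylation",
    "predict_ancestry_effect",
    "build_records",
    "compare",
    "CompositionSummary",
]


def _check_unit(name, value, lo=0.0, hi=1.0):
    v = np.asarray(value, float)
    if np.any(~np.isfinite(v)) or np.any(v < lo) or np.any(v > hi):
        raise ParameterError(f"{name} must be in [{lo}, {hi}]")


def population_mean_methylation(m_ref, m_alt, p_alt):
    """Frequency-weighted mean methylation of an allele pool.

    (1 - p_alt) * m_ref + p_alt * m_alt, all arguments in [0, 1].
    """
    _check_unit("m_ref", m_ref)
    _check_unit("m_alt", m_alt)
    _check_unit("p_alt", p_alt)
    m_ref, m_alt, p_alt = (np.asarray(x, float) for x in (m_ref, m_alt, p_alt))
    out = (1.0 - p_alt) * m_ref + p_alt * m_alt
    return float(out) if out.ndim == 0 else out


def predict_ancestry_effect(delta, p_yellow, p_anubis):
    """Predicted proportion-scale ancestry effect, delta * (p_anubis - p_yellow).

    Positive values mean anubis ancestry is predicted to be more
    methylated. ``delta`` is the per-allele meQTL effect (alt - ref) in
    [-1, 1]; frequencies are the alt-allele frequencies in each parental
    taxon.
    """
    _check_unit("delta", delta, -1.0, 1.0)
    _check_unit("p_yellow", p_yellow)
    _check_unit("p_anubis", p_anubis)
    delta, p_yellow, p_anubis = (np.asarray(x, float) for x in (delta, p_yellow, p_anubis))
    out = delta * (p_anubis - p_yellow)
    return float(out) if out.ndim == 0 else out


def _quadrant(pred, obs):
    q = np.full(pred.shape, "", dtype=object)
    q[(pred > 0) & (obs > 0)] = "I"
    q[(pred <= 0) & (obs > 0)] = "II"
    q[(pred <= 0) & (obs <= 0)] = "III"
    q[(pred > 0) & (obs <= 0)] = "IV"
    return q


def build_records(meqtl_table, scan_table, freq_table, fdr_thresh=0.1):
    """Composition records for CpGs with both an meQTL and an ancestry effect.

    Parameters
    ----------
    meqtl_table : DataFrame
        From the meQTL scan: cpg_chrom, cpg_pos, snp_chrom, snp_pos,
        delta, q, disrupted.
    scan_table : DataFrame
        From the ancestry scan: chrom, pos, effect_allele, q_local.
    freq_table : DataFrame
        Parental frequencies per SNP: chrom, pos, p_yellow, p_anubis.
    fdr_thresh : float
        Keep CpGs with meQTL q and ancestry q below this threshold.

    Returns a DataFrame with delta, p_yellow, p_anubis,
    predicted_effect, observed_effect and quadrant.
    """
    m = meqtl_table.rename(columns={"cpg_chrom": "chrom", "cpg_pos": "pos"})
    m = m[(m["q"] < fdr_thresh)]
    s = scan_table[scan_table["q_local"] < fdr_thresh]
    rec = m.merge(s[["chrom", "pos", "effect_allele"]], on=["chrom", "pos"], how="inner")
    f = freq_table.rename(columns={"chrom": "snp_chrom", "pos": "snp_pos"})
    rec = rec.merge(f[["snp_chrom", "snp_pos", "p_yellow", "p_anubis"]],
                    on=["snp_chrom", "snp_pos"], how="inner")
    rec["predicted_effect"] = predict_ancestry_effect(
        rec["delta"].to_numpy(), rec["p_yellow"].to_numpy(), rec["p_anubis"].to_numpy()
    )
    rec["observed_effect"] = rec["effect_allele"]
    rec["quadrant"] = _quadrant(
        rec["predicted_effect"].to_numpy(), rec["observed_effect"].to_numpy()
    )
    return rec


@dataclass
class CompositionSummary:
    spearman_rho: float
    spearman_p: float
    frac_concordant: float
    quadrant_counts: dict
    n: int
    degenerate: bool = False


def compare(records):
    """Rank correlation, sign concordance and quadrant census of
    predicted vs observed ancestry effects.

    ``records`` needs finite columns predicted_effect and
    observed_effect (>= 3 rows). Discordant quadrants (II and IV) are
    where other mechanisms than frequency divergence must be invoked.
    """
    rec = records[np.isfinite(records["predicted_effect"])
                  & np.isfinite(records["observed_effect"])]
    if len(rec) < 3:
        raise ParameterError("need at least 3 records with finite effects")
    pred = rec["predicted_effect"].to_numpy()
    obs = rec["observed_effect"].to_numpy()
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return CompositionSummary(np.nan, np.nan, np.nan, {}, len(rec), degenerate=True)
    rho = stats.spearmanr(pred, obs)
    quad = _quadrant(pred, obs)
    counts = {k: int((quad == k).sum()) for k in ("I", "II", "III", "IV")}
    frac = float(np.mean(np.sign(pred) == np.sign(obs)))
    return CompositionSummary(
        spearman_rho=float(rho.statistic),
        spearman_p=float(rho.pvalue),
        frac_concordant=frac,
        quadrant_counts=counts,
        n=len(rec),
    )
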
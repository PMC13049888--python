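"""Differential methylation between two unadmixed taxa, and its
concordance with within-hybrid ancestry effects.

The species contrast is a beta-binomial regression with a taxon
indicator (anubis = 1) plus optional technical covariates (e.g.
bisulfite conversion rate), calibrated by permuting taxon labels across
samples. The concordance analysis then asks whether
between-taxon differences are recapitulated by the yellow-vs-anubis
allele differences segregating inside the hybrid population: effect
correlations, a Fisher's exact overlap test of the two significant sets,
and the fraction of jointly significant sites whose effects agree in
sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bbcore import empirical_qvalues, fit_betabinom_glm
from .exceptions import AlignmentError, FitError

__all__ = [
    "SpeciesDiffResult",
    "ConcordanceResult",
    "filter_species_sites",
    "test_species",
    "concordance",
    "fisher_log2_or",
]


@dataclass
class SpeciesDiffResult:
    """Per-CpG between-taxon contrast (anubis minus yellow)."""

    table: pd.DataFrame
    p_perm: np.ndarray
    n_permutations: int


@dataclass
class ConcordanceResult:
    pearson_r: float
    spearman_rho: float
    fisher_log2_or: float
    fisher_ci: tuple
    fisher_p: float
    frac_directionally_concordant: float
    n_overlap: int
    degenerate: bool = False


def filter_species_sites(
    matrix_y, matrix_a, min_individuals=5, min_coverage=5.0, meth_bounds=(0.1, 0.9)
):
    """Sites testable for a species difference.

    Retains sites covered in at least ``min_individuals`` of each taxon,
    with mean coverage (across all samples of both taxa) strictly greater
    than ``min_coverage`` and pooled mean methylation inside
    ``meth_bounds``.
    """
    if set(matrix_y.individuals) & set(matrix_a.individuals):
        raise AlignmentError("taxon matrices share individual IDs")
    if matrix_y.n_sites != matrix_a.n_sites:
        raise AlignmentError("taxon matrices cover different site sets")
    cov_ok = (
        np.concatenate([matrix_y.total, matrix_a.total], axis=1).mean(axis=1)
        > min_coverage
    )
    n_ok = (matrix_y.n_covered() >= min_individuals) & (
        matrix_a.n_covered() >= min_individuals
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        meth = np.concatenate([matrix_y.meth, matrix_a.meth], axis=1)
        total = np.concatenate([matrix_y.total, matrix_a.total], axis=1)
        ratio = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    mean_m = np.nanmean(ratio, axis=1)
    m_ok = (mean_m >= meth_bounds[0]) & (mean_m <= meth_bounds[1])
    return np.where(cov_ok & n_ok & m_ok)[0]


def test_species(matrix_y, matrix_a, batch_covariate=None, n_perm=10, seed=0):
    """Beta-binomial species contrast with a label-permutation null.

    Parameters
    ----------
    matrix_y, matrix_a : MethCountMatrix
        Counts over the same (pre-filtered) sites for the yellow and
        anubis samples respectively.
    batch_covariate : array, optional
        One value per sample, yellow samples first then anubis (e.g.
        bisulfite conversion rate).

    Returns
    -------
    SpeciesDiffResult
        Table with beta_species (logit scale), delta_species (difference
        of predicted mean methylation, anubis minus yellow), p, q and a
        skip reason code for untestable sites.
    """
    rng = np.random.default_rng(seed)
    meth = np.concatenate([matrix_y.meth, matrix_a.meth], axis=1)
    total = np.concatenate([matrix_y.total, matrix_a.total], axis=1)
    n_y = matrix_y.n_individuals
    n_all = meth.shape[1]
    species = np.concatenate([np.zeros(n_y), np.ones(n_all - n_y)])
    cov = None
    if batch_covariate is not None:
        cov = np.asarray(batch_covariate, float)
        if cov.ndim == 1:
            cov = cov[:, None]

    perms = [rng.permutation(n_all) for _ in range(n_perm)]

    def site_fit(j, labels):
        ok = total[j] > 0
        if min((labels[ok] == 0).sum(), (labels[ok] == 1).sum()) < 2:
            return None
        cols = [np.ones(ok.sum()), labels[ok]]
        if cov is not None:
            cols.append(cov[ok, 0])
        X = np.column_stack(cols)
        try:
            return fit_betabinom_glm(meth[j][ok], total[j][ok], X), X
        except FitError:
            return None

    rows, p_perm = [], []
    for j in range(meth.shape[0]):
        res = site_fit(j, species)
        if res is None:
            rows.append((matrix_y.chrom[j], matrix_y.pos[j], np.nan, np.nan,
                         np.nan, np.nan, False, "too_few_per_group"))
        else:
            fit, X = res
            x0 = X.mean(axis=0).copy()
            x1 = x0.copy()
            x0[1], x1[1] = 0.0, 1.0
            delta = float(fit.predict_mean(x1[None, :])[0] - fit.predict_mean(x0[None, :])[0])
            rows.append(
                (matrix_y.chrom[j], matrix_y.pos[j], fit.coefficients[1], delta,
                 fit.pvalues[1], fit.phi, fit.converged, "")
            )
            for perm in perms:
                pres = site_fit(j, species[perm])
                if pres is not None and pres[0].converged:
                    p_perm.append(pres[0].pvalues[1])
    table = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "beta_species", "delta_species", "p", "phi",
                 "converged", "skip_reason"],
    )
    p_perm = np.asarray(p_perm)
    conv = table["converged"].to_numpy() & table["p"].notna().to_numpy()
    table["q"] = np.nan
    if conv.any() and p_perm.size:
        table.loc[conv, "q"] = empirical_qvalues(
            table.loc[conv, "p"].to_numpy(), p_perm,
            p_perm.size / max(int(conv.sum()), 1),
        )
    return SpeciesDiffResult(table=table, p_perm=p_perm, n_permutations=n_perm)


def fisher_log2_or(table):
    """Two-sided Fisher's exact test on a 2x2 table with a Woolf CI.

    Returns (log2 odds ratio, (lo, hi) 95% CI on the log2 scale, p).
    Zero margins are handled with a Haldane 0.5 correction for the OR and
    CI; the exact p is computed on the uncorrected table.
    """
    t = np.asarray(table, float)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if np.any(t == 0):
        t = t + 0.5
    log_or = np.log2(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    se = np.sqrt(np.sum(1.0 / t)) / np.log(2.0)
    return log_or, (log_or - 1.96 * se, log_or + 1.96 * se), p


def concordance(species_result, hybrid_table, p_thresh=0.01, fdr_thresh=0.1):
    """Compare between-taxon differences with within-hybrid allele effects.

    Parameters
    ----------
    species_result : SpeciesDiffResult
    hybrid_table : DataFrame
        Ancestry-scan table with chrom, pos, effect_allele, q_local.
    p_thresh : float
        Nominal species-difference threshold defining the
        species-significant set.
    fdr_thresh : float
        q-value threshold defining the ancestry-associated set.

    Returns
    -------
    ConcordanceResult
        Effect correlations among species-significant sites, the overlap
        Fisher log2 OR over the shared site universe, and directional
        concordance among jointly significant sites.
    """
    sp = species_result.table.merge(
        hybrid_table[["chrom", "pos", "effect_allele", "q_local"]],
        on=["chrom", "pos"],
        how="inner",
    )
    if len(sp) == 0:
        return ConcordanceResult(np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan,
                                 np.nan, 0, degenerate=True)
    sp_sig = sp["p"] <= p_thresh
    anc_sig = sp["q_local"] < fdr_thresh
    sig = sp[sp_sig]
    if len(sig) >= 3 and sig["delta_species"].nunique() > 1:
        pear = stats.pearsonr(sig["delta_species"], sig["effect_allele"]).statistic
        spear = stats.spearmanr(sig["delta_species"], sig["effect_allele"]).statistic
    else:
        pear = spear = np.nan
    tab = np.array(
        [
            [(sp_sig & anc_sig).sum(), (sp_sig & ~anc_sig).sum()],
            [(~sp_sig & anc_sig).sum(), (~sp_sig & ~anc_sig).sum()],
        ]
    )
    l2or, ci, p = fisher_log2_or(tab)
    joint = sp[sp_sig & anc_sig]
    if len(joint):
        frac = float(
            np.mean(np.sign(joint["delta_species"]) == np.sign(joint["effect_allele"]))
        )
    else:
        frac = np.nan
    return ConcordanceResult(
        pearson_r=float(pear),
        spearman_rho=float(spear),
        fisher_log2_or=float(l2or),
        fisher_ci=ci,
        fisher_p=float(p),
        frac_directionally_concordant=frac,
        n_overlap=int(len(joint)),
        degenerate=bool((tab == 0).any()),
    )
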
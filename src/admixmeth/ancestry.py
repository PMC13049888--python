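"""Per-CpG scan for local-ancestry effects on DNA methylation.

At each retained CpG the methylated read count is modeled as
beta-binomial with logit-linear mean in local ancestry dosage (count of
anubis alleles, additive 0/1/2), global ancestry fraction, and any
caller-supplied covariates. Significance is calibrated against
permutation nulls in which only the ancestry vector moves -- each
individual's counts and covariates stay attached to it -- and converted
to q-values with the empirical-null estimator.

Site filters mirror standard practice for population bisulfite data:
constitutively hypo-/hypermethylated sites (mean level outside
[0.10, 0.90]) are uninformative and excluded, as are sites where any
local-ancestry state (homozygous yellow, heterozygous, homozygous
anubis) has fewer than 10 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bbcore import empirical_qvalues, fit_betabinom_glm, lrt
from .exceptions import AlignmentError, FitError, StateError

__all__ = [
    "AncestryScanResult",
    "filter_sites",
    "scan",
    "test_additivity",
    "effect_to_proportion_scale",
    "state_counts",
]

MIN_PER_STATE = 10
METH_BOUNDS = (0.10, 0.90)


@dataclass
class AncestryScanResult:
    """Per-site scan output plus the permutation pools used for FDR."""

    table: pd.DataFrame
    p_perm_local: np.ndarray
    p_perm_global: np.ndarray
    n_permutations: int
    n_not_converged: int


def _check_alignment(matrix, panel):
    if list(matrix.individuals) != list(panel.individuals):
        shared = set(matrix.individuals) & set(panel.individuals)
        if not shared:
            raise AlignmentError("counts and ancestry panel share no individuals")
        raise AlignmentError(
            "counts and ancestry panel individuals differ; align them first"
        )
    if matrix.n_sites != panel.n_loci:
        raise AlignmentError(
            f"{matrix.n_sites} CpG sites but ancestry dosage at {panel.n_loci} loci"
        )


def state_counts(panel):
    """(n_loci, 3) count of individuals in dosage state 0/1/2 per locus."""
    d = panel.dosage
    return np.stack([(d.T == s).sum(axis=1) for s in (0, 1, 2)], axis=1)


def filter_sites(matrix, panel, min_per_state=MIN_PER_STATE, meth_bounds=METH_BOUNDS):
    """Indices of sites passing the mean-methylation and state-count filters.

    Retains sites with mean methylation (over covered individuals) in
    ``meth_bounds`` inclusive and at least ``min_per_state`` individuals
    in each of the three local-ancestry states.
    """
    _check_alignment(matrix, panel)
    mean_m = matrix.mean_methylation()
    in_bounds = (mean_m >= meth_bounds[0]) & (mean_m <= meth_bounds[1])
    enough = np.all(state_counts(panel) >= min_per_state, axis=1)
    return np.where(in_bounds & enough)[0]


def _design(dosage, global_anc, covariates):
    cols = [np.ones_like(global_anc), dosage.astype(float), global_anc]
    names = ["intercept", "local", "global"]
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
        names.extend([f"cov{i}" for i in range(cov.shape[1])])
    return np.column_stack(cols), names


def _site_fit(meth, total, dosage, global_anc, cov_arr):
    ok = (dosage >= 0) & (total > 0)
    X, names = _design(
        dosage[ok], global_anc[ok], None if cov_arr is None else cov_arr[ok]
    )
    fit = fit_betabinom_glm(meth[ok], total[ok], X, design_columns=names)
    return fit, X


def scan(matrix, panel, covariates=None, n_perm=10, seed=0, test_global=True):
    """Local- and global-ancestry association at each (pre-filtered) site.

    Parameters
    ----------
    matrix : MethCountMatrix
        Counts at the sites to test (already passed ``filter_sites``).
    panel : AncestryPanel
        Dosage per individual at each site, plus global ancestry.
    covariates : DataFrame or array, optional
        Additional numeric covariate columns (batch, age, conversion
        rate, ...), one row per individual.
    n_perm : int
        Permutations per null (local: dosage vectors shuffled across
        individuals; global: the global-ancestry vector shuffled),
        keeping everything else fixed.
    test_global : bool
        Also build the global-ancestry permutation null (set False to
        reduce cost when only local effects are of interest).

    Returns
    -------
    AncestryScanResult
        ``table`` columns include beta_local (logit scale), p_local,
        q_local, beta_global, p_global, q_global, effect_state (the
        homozygous-anubis minus homozygous-yellow difference in
        predicted mean methylation), effect_allele (= effect_state / 2),
        per-state counts n0/n1/n2, phi and the convergence flag.
        Non-converged sites are excluded from q-value computation.
    """
    _check_alignment(matrix, panel)
    rng = np.random.default_rng(seed)
    n_sites = matrix.n_sites
    n_ind = matrix.n_individuals
    cov_arr = None
    if covariates is not None:
        cov_arr = np.asarray(covariates, float)
        if cov_arr.ndim == 1:
            cov_arr = cov_arr[:, None]

    counts3 = state_counts(panel)
    perms_local = [rng.permutation(n_ind) for _ in range(n_perm)]
    perms_global = [rng.permutation(n_ind) for _ in range(n_perm)] if test_global else []

    rows = []
    p_perm_local, p_perm_global = [], []
    n_bad = 0
    for j in range(n_sites):
        meth, total = matrix.meth[j], matrix.total[j]
        dosage = panel.dosage[:, j]
        fit, X = _site_fit(meth, total, dosage, panel.global_ancestry, cov_arr)
        if not fit.converged:
            n_bad += 1
            effect_state = np.nan
        else:
            effect_state = effect_to_proportion_scale(fit, X)
        rows.append(
            (
                matrix.chrom[j],
                matrix.pos[j],
                fit.coefficients[1],
                fit.standard_errors[1],
                fit.pvalues[1],
                fit.coefficients[2],
                fit.pvalues[2],
                effect_state,
                effect_state / 2.0,
                counts3[j, 0],
                counts3[j, 1],
                counts3[j, 2],
                fit.phi,
                fit.converged,
            )
        )
        for perm in perms_local:
            try:
                pfit, _ = _site_fit(meth, total, dosage[perm], panel.global_ancestry, cov_arr)
                if pfit.converged:
                    p_perm_local.append(pfit.pvalues[1])
            except (FitError, FloatingPointError):
                continue
        for perm in perms_global:
            try:
                pfit, _ = _site_fit(meth, total, dosage, panel.global_ancestry[perm], cov_arr)
                if pfit.converged:
                    p_perm_global.append(pfit.pvalues[2])
            except (FitError, FloatingPointError):
                continue

    table = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "beta_local", "se_local", "p_local", "beta_global",
            "p_global", "effect_state", "effect_allele", "n0", "n1", "n2",
            "phi", "converged",
        ],
    )
    conv = table["converged"].to_numpy()
    p_perm_local = np.asarray(p_perm_local)
    p_perm_global = np.asarray(p_perm_global)
    table["q_local"] = np.nan
    table["q_global"] = np.nan
    m = max(int(conv.sum()), 1)
    if conv.any() and p_perm_local.size:
        # realized permutations per site (failed permutation fits drop out)
        table.loc[conv, "q_local"] = empirical_qvalues(
            table.loc[conv, "p_local"].to_numpy(), p_perm_local,
            p_perm_local.size / m,
        )
    if test_global and conv.any() and p_perm_global.size:
        table.loc[conv, "q_global"] = empirical_qvalues(
            table.loc[conv, "p_global"].to_numpy(), p_perm_global,
            p_perm_global.size / m,
        )
    return AncestryScanResult(
        table=table,
        p_perm_local=p_perm_local,
        p_perm_global=p_perm_global,
        n_permutations=n_perm,
        n_not_converged=n_bad,
    )


def effect_to_proportion_scale(fit, design, dosage_col=1, per_allele=False):
    """Ancestry effect on the proportion (methylation-level) scale.

    Difference in model-predicted mean methylation between the
    homozygous-anubis (dosage 2) and homozygous-yellow (dosage 0) states,
    with all other design columns at their observed means. With
    ``per_allele=True`` the state difference is halved to give the
    yellow-vs-anubis allele difference.
    """
    if not fit.converged:
        raise StateError("effect requested from a non-converged fit")
    xbar = np.asarray(design, float).mean(axis=0)
    x0, x2 = xbar.copy(), xbar.copy()
    x0[dosage_col] = 0.0
    x2[dosage_col] = 2.0
    diff = float(fit.predict_mean(x2[None, :])[0] - fit.predict_mean(x0[None, :])[0])
    return diff / 2.0 if per_allele else diff


def test_additivity(matrix, panel, covariates=None):
    """Per-site test of the additive dosage coding against a free 3-level fit.

    Adds a heterozygote indicator to the additive design and compares by
    likelihood ratio (1 df); small p flags departure from additivity
    (e.g. heterozygote advantage). Sites must already pass the scan
    filters so every ancestry state is represented.
    """
    _check_alignment(matrix, panel)
    cov_arr = None
    if covariates is not None:
        cov_arr = np.asarray(covariates, float)
        if cov_arr.ndim == 1:
            cov_arr = cov_arr[:, None]
    pvals = np.full(matrix.n_sites, np.nan)
    for j in range(matrix.n_sites):
        meth, total = matrix.meth[j], matrix.total[j]
        dosage = panel.dosage[:, j]
        ok = (dosage >= 0) & (total > 0)
        X_add, _ = _design(
            dosage[ok], panel.global_ancestry[ok],
            None if cov_arr is None else cov_arr[ok],
        )
        het = (dosage[ok] == 1).astype(float)
        X_fac = np.column_stack([X_add, het])
        try:
            f_add = fit_betabinom_glm(meth[ok], total[ok], X_add)
            f_fac = fit_betabinom_glm(meth[ok], total[ok], X_fac)
            if f_add.converged and f_fac.converged:
                pvals[j] = lrt(f_add, f_fac, df=1)
        except FitError:
            continue
    return pvals
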
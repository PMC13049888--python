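"""meQTL mapping from SNP-CpG pairs co-observed on reads.

A CpG and a nearby SNP (within 100 bp, so single reads can span both)
are tested jointly for a per-allele effect on methylation. The model
shares one allelic effect beta between two beta-binomial components:

* an individual-level component, where an individual with alt-allele
  dosage g has mean methylation (1 - g/2) * p0 + (g/2) * p1, the
  read-level mixture over its two haplotypes (p0 = expit(mu0) for the
  reference allele, p1 = expit(mu0 + beta) for the alternate);
* an allele-specific component, where reads inside heterozygotes that
  cover the SNP are split by allele: reference-allele reads have mean
  p0 and alternate-allele reads mean p1.

Both components enter one composite likelihood with a shared dispersion,
and the meQTL test is a 1-df likelihood ratio of beta = 0. Reads that
cover the SNP in a heterozygote contribute only to the allele-specific
component (the individual-level counts exclude them), so no read is
counted twice. The permutation null shuffles genotypes across
individuals and re-draws each heterozygote read's allele label
uniformly, preserving every individual's (meth, total) marginals.

The per-allele effect is also reported on the proportion scale,
delta = p1 - p0, the quantity that composes with parental
allele-frequency differences to predict ancestry effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .bbcore import _bb_logpmf, empirical_qvalues
from .exceptions import AlignmentError, DataError, ParameterError

__all__ = [
    "SnpCpgPair",
    "MeqtlResult",
    "build_pairs",
    "pairs_from_cohort",
    "fit_meqtl",
    "fit_pairs",
    "permutation_null",
    "map_meqtl",
    "disruption_regression",
    "distance_effect",
]

MAX_PAIR_DISTANCE = 100
_T_BOUNDS = (-2.2, 25.0)
_ETA_CLIP = 30.0


@dataclass
class SnpCpgPair:
    """One SNP-CpG pair with individual-level and allele-specific counts.

    ``meth``/``total`` are all reads at the CpG; ``meth_excl``/``total_excl``
    exclude heterozygotes' allele-assignable reads, which appear instead
    in ``meth_ref``/``total_ref``/``meth_alt``/``total_alt``.
    """

    pair_id: str
    snp_chrom: str
    snp_pos: int
    cpg_chrom: str
    cpg_pos: int
    distance: int
    disrupted: bool
    individuals: list
    genotype: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    meth_excl: np.ndarray
    total_excl: np.ndarray
    meth_ref: np.ndarray
    total_ref: np.ndarray
    meth_alt: np.ndarray
    total_alt: np.ndarray

    def __post_init__(self):
        if self.distance > MAX_PAIR_DISTANCE:
            raise DataError(f"pair distance {self.distance} exceeds {MAX_PAIR_DISTANCE} bp")
        as_total = self.total_ref + self.total_alt
        if np.any(as_total + self.total_excl != self.total):
            raise DataError("allele-specific + excluded counts must equal totals")

    @property
    def n_heterozygotes(self):
        return int(np.sum(self.genotype == 1))

    def maf(self):
        g = self.genotype[self.genotype >= 0]
        p = g.mean() / 2.0
        return min(p, 1.0 - p)

    def call_rate(self):
        return float(np.mean(self.genotype >= 0))


@dataclass
class MeqtlResult:
    """Tabular meQTL scan output plus the permutation pool."""

    table: pd.DataFrame
    p_perm: np.ndarray = None
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# composite likelihood


def _stack_pair(pair, genotype=None, as_counts=None):
    """Rows (k, n, w) where the mean is (1-w) p0 + w p1.

    Individual-level rows get w = g/2; heterozygote reference-allele rows
    w = 0 and alternate-allele rows w = 1.
    """
    g = pair.genotype if genotype is None else genotype
    if as_counts is None:
        mr, tr, ma, ta = pair.meth_ref, pair.total_ref, pair.meth_alt, pair.total_alt
    else:
        mr, tr, ma, ta = as_counts
    ks, ns, ws = [], [], []
    called = g >= 0
    het = called & (g == 1)
    has_pool = (pair.total_ref + pair.total_alt) > 0
    # individual-level: hets with an allele-assignable pool use the excluded
    # remainder; everyone else contributes all reads
    use_excl = het & has_pool
    k_ind = np.where(use_excl, pair.meth_excl, pair.meth)
    n_ind = np.where(use_excl, pair.total_excl, pair.total)
    keep = called & (n_ind > 0)
    ks.append(k_ind[keep])
    ns.append(n_ind[keep])
    ws.append(g[keep] / 2.0)
    # allele-specific rows for heterozygotes
    hr = use_excl & (tr > 0)
    ks.append(mr[hr]); ns.append(tr[hr]); ws.append(np.zeros(hr.sum()))
    ha = use_excl & (ta > 0)
    ks.append(ma[ha]); ns.append(ta[ha]); ws.append(np.ones(ha.sum()))
    return (
        np.concatenate(ks).astype(float),
        np.concatenate(ns).astype(float),
        np.concatenate(ws).astype(float),
    )


def _joint_nll_grad(params, k, n, w, fix_beta):
    mu0 = params[0]
    beta = 0.0 if fix_beta else params[1]
    t = params[-1]
    s = np.exp(t)
    p0 = special.expit(np.clip(mu0, -_ETA_CLIP, _ETA_CLIP))
    p1 = special.expit(np.clip(mu0 + beta, -_ETA_CLIP, _ETA_CLIP))
    m = np.clip((1.0 - w) * p0 + w * p1, 1e-12, 1.0 - 1e-12)
    a = m * s
    b = (1.0 - m) * s
    ll = np.sum(_bb_logpmf(k, n, m, s))
    psi_ka = special.digamma(k + a)
    psi_a = special.digamma(a)
    psi_nkb = special.digamma(n - k + b)
    psi_b = special.digamma(b)
    dl_dm = s * (psi_ka - psi_a - psi_nkb + psi_b)
    d0 = p0 * (1.0 - p0)
    d1 = p1 * (1.0 - p1)
    g_mu0 = np.sum(dl_dm * ((1.0 - w) * d0 + w * d1))
    dl_ds = np.sum(
        m * (psi_ka - psi_a) + (1.0 - m) * (psi_nkb - psi_b)
        - special.digamma(n + s) + special.digamma(s)
    )
    if fix_beta:
        grad = np.array([g_mu0, dl_ds * s])
    else:
        g_beta = np.sum(dl_dm * w * d1)
        grad = np.array([g_mu0, g_beta, dl_ds * s])
    return -ll, -grad


def _mom_t0(k, n):
    """Moment-based start for t = log((1-phi)/phi)."""
    pooled = np.clip(k.sum() / max(n.sum(), 1.0), 1e-3, 1 - 1e-3)
    pos = n > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.sum(
            (k[pos] - n[pos] * pooled) ** 2 / (n[pos] * pooled * (1 - pooled))
        )
    overdisp = chi2 / max(pos.sum() - 1, 1)
    nbar = float(np.mean(n[pos]))
    phi0 = np.clip((overdisp - 1.0) / max(nbar - 1.0, 1.0), 1e-4, 0.5)
    return float(np.clip(np.log((1.0 - phi0) / phi0), *_T_BOUNDS))


def _optimize_joint(k, n, w, fix_beta, x0s=None):
    pooled = np.clip(k.sum() / max(n.sum(), 1.0), 1e-3, 1 - 1e-3)
    mu0_0 = special.logit(pooled)
    if x0s is None:
        t0 = _mom_t0(k, n)
        t_starts = [t0] if abs(t0 - 5.0) < 1.5 else [t0, 5.0]
        x0s = [([mu0_0, t] if fix_beta else [mu0_0, 0.0, t]) for t in t_starts]
    bounds = ([(-15, 15), _T_BOUNDS] if fix_beta else [(-15, 15), (-15, 15), _T_BOUNDS])
    best = None
    for x0 in x0s:
        res = optimize.minimize(
            _joint_nll_grad, np.asarray(x0, float), args=(k, n, w, fix_beta),
            jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_meqtl(pair, genotype=None, as_counts=None):
    """Joint meQTL fit for one pair; returns a one-row result dict.

    The likelihood-ratio p-value tests the shared per-allele effect
    beta = 0 (1 df). ``delta`` is the per-allele effect on the
    proportion scale, expit(mu0 + beta) - expit(mu0). With no
    heterozygotes the fit degrades gracefully to the individual-level
    component alone, flagged via ``has_allele_specific``.
    """
    k, n, w = _stack_pair(pair, genotype=genotype, as_counts=as_counts)
    if k.size < 4 or np.unique(w).size < 2:
        return dict(
            pair_id=pair.pair_id, beta=np.nan, delta=np.nan, p=np.nan,
            loglik_alt=np.nan, loglik_null=np.nan, converged=False,
            has_allele_specific=False, phi=np.nan,
        )
    null = _optimize_joint(k, n, w, fix_beta=True)
    # warm-start the alternative at the null solution (guarantees nesting)
    warm = [np.array([null.x[0], 0.0, null.x[1]])]
    alt = _optimize_joint(k, n, w, fix_beta=False, x0s=warm)
    ll_alt, ll_null = -alt.fun, -null.fun
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    p = stats.chi2.sf(stat, 1)
    mu0, beta = alt.x[0], alt.x[1]
    delta = float(special.expit(mu0 + beta) - special.expit(mu0))
    # projected gradient: components pushing outside the box (boundary
    # solutions, e.g. an always-unmethylated allele) do not count
    _, grad = _joint_nll_grad(alt.x, k, n, w, False)
    proj = grad[:2].copy()
    for i, (lo, hi) in enumerate([(-15, 15), (-15, 15)]):
        if (alt.x[i] <= lo + 1e-8 and proj[i] > 0) or (
            alt.x[i] >= hi - 1e-8 and proj[i] < 0
        ):
            proj[i] = 0.0
    converged = bool(np.linalg.norm(proj) < 1e-3 * (1.0 + abs(ll_alt)))
    has_as = bool(np.sum((pair.total_ref + pair.total_alt)[pair.genotype == 1]) > 0)
    return dict(
        pair_id=pair.pair_id, beta=float(beta), delta=delta, p=float(p),
        loglik_alt=float(ll_alt), loglik_null=float(ll_null),
        converged=converged, has_allele_specific=has_as,
        phi=float(1.0 / (1.0 + np.exp(alt.x[-1]))),
    )


def fit_pairs(pairs):
    """Fit every pair; returns a MeqtlResult table (no q-values yet)."""
    rows = []
    for pair in pairs:
        entry = fit_meqtl(pair)
        entry.update(
            snp_chrom=pair.snp_chrom, snp_pos=pair.snp_pos,
            cpg_chrom=pair.cpg_chrom, cpg_pos=pair.cpg_pos,
            distance=pair.distance, disrupted=pair.disrupted,
            n_het=pair.n_heterozygotes, maf=pair.maf(),
        )
        rows.append(entry)
    return MeqtlResult(table=pd.DataFrame(rows))


def permutation_null(pairs, n_perm, seed):
    """Permutation p-value pool for the joint meQTL test.

    Each permutation (a) shuffles the genotype vector across individuals
    and (b) re-draws each heterozygote read's allele label uniformly
    (every assignable read goes to ref or alt with probability 1/2,
    independently for methylated and unmethylated reads). Individuals'
    (meth, total) marginals are untouched.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pool = []
    for b in range(n_perm):
        for pair in pairs:
            perm = rng.permutation(len(pair.genotype))
            g = pair.genotype[perm]
            meth_as = pair.meth_ref + pair.meth_alt
            total_as = pair.total_ref + pair.total_alt
            unmeth_as = total_as - meth_as
            mr = rng.binomial(meth_as, 0.5)
            ur = rng.binomial(unmeth_as, 0.5)
            as_counts = (mr, mr + ur, meth_as - mr, total_as - mr - ur)
            entry = fit_meqtl(pair, genotype=g, as_counts=as_counts)
            if entry["converged"] and np.isfinite(entry["p"]):
                pool.append(entry["p"])
    return np.asarray(pool)


def map_meqtl(pairs, n_perm=10, seed=0):
    """Fit all pairs and attach empirical q-values."""
    result = fit_pairs(pairs)
    pool = permutation_null(pairs, n_perm, seed)
    tab = result.table
    conv = tab["converged"].to_numpy() & tab["p"].notna().to_numpy()
    tab["q"] = np.nan
    if conv.any() and pool.size:
        tab.loc[conv, "q"] = empirical_qvalues(
            tab.loc[conv, "p"].to_numpy(), pool,
            pool.size / max(int(conv.sum()), 1),
        )
    return MeqtlResult(table=tab, p_perm=pool, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# pair construction


def build_pairs(
    variants,
    counts,
    read_pairs,
    max_distance=MAX_PAIR_DISTANCE,
    min_call_rate=0.5,
    min_maf=0.05,
    min_coverage=5.0,
    meth_bounds=(0.1, 0.9),
):
    """Assemble and filter SNP-CpG pairs from tabular inputs.

    Parameters
    ----------
    variants : DataFrame
        Columns chrom, pos, ref, alt plus one genotype-dosage column per
        individual (-1 = missing); e.g. from ``io.read_vcf``.
    counts : MethCountMatrix
        CpG counts for the same individuals.
    read_pairs : DataFrame
        Read-level co-observation counts, one row per (snp, cpg,
        individual): columns snp_chrom, snp_pos, cpg_chrom, cpg_pos,
        individual, meth, total, meth_excl, total_excl, meth_ref,
        total_ref, meth_alt, total_alt.

    Filters: pair distance <= 100 bp; SNP call rate >= 0.5 and MAF >=
    0.05; CpG mean coverage >= 5x and mean methylation in [0.1, 0.9].
    The disrupted flag is set when the SNP overlaps either base of the
    CpG dinucleotide (SNP position == CpG position or position + 1).

    Returns (pairs, filter_log) where filter_log counts pairs lost to
    each rule.
    """
    inds = list(counts.individuals)
    geno_cols = [c for c in variants.columns if c in set(inds)]
    if set(geno_cols) != set(inds):
        missing = sorted(set(inds) - set(geno_cols))[:5]
        raise AlignmentError(f"variant table lacks genotype columns for {missing}")
    site_index = {
        (c, p): i for i, (c, p) in enumerate(zip(counts.chrom, counts.pos))
    }
    var_index = {
        (c, p): i for i, (c, p) in enumerate(zip(variants["chrom"], variants["pos"]))
    }
    mean_cov = counts.coverage_mean()
    mean_meth = counts.mean_methylation()
    log = {"total": 0, "distance": 0, "call_rate": 0, "maf": 0,
           "cpg_coverage": 0, "cpg_methylation": 0, "retained": 0}
    pairs = []
    grouped = read_pairs.groupby(
        ["snp_chrom", "snp_pos", "cpg_chrom", "cpg_pos"], sort=True
    )
    for (sc, sp, cc, cp), sub in grouped:
        log["total"] += 1
        dist = abs(int(sp) - int(cp))
        if sc != cc or dist > max_distance:
            log["distance"] += 1
            continue
        vi = var_index.get((sc, sp))
        si = site_index.get((cc, cp))
        if vi is None or si is None:
            log["distance"] += 1
            continue
        g = variants.loc[vi, inds].to_numpy(dtype=float)
        g = np.where(np.isnan(g), -1, g).astype(int)
        call = np.mean(g >= 0)
        if call < min_call_rate:
            log["call_rate"] += 1
            continue
        p_alt = g[g >= 0].mean() / 2.0
        if min(p_alt, 1 - p_alt) < min_maf:
            log["maf"] += 1
            continue
        if mean_cov[si] < min_coverage:
            log["cpg_coverage"] += 1
            continue
        if not (meth_bounds[0] <= mean_meth[si] <= meth_bounds[1]):
            log["cpg_methylation"] += 1
            continue
        sub = sub.set_index("individual").reindex(inds)
        arr = lambda col: sub[col].fillna(0).to_numpy(dtype=np.int64)
        pairs.append(
            SnpCpgPair(
                pair_id=f"{sc}:{sp}_{cc}:{cp}",
                snp_chrom=sc, snp_pos=int(sp), cpg_chrom=cc, cpg_pos=int(cp),
                distance=dist, disrupted=int(sp) in (int(cp), int(cp) + 1),
                individuals=inds, genotype=g,
                meth=arr("meth"), total=arr("total"),
                meth_excl=arr("meth_excl"), total_excl=arr("total_excl"),
                meth_ref=arr("meth_ref"), total_ref=arr("total_ref"),
                meth_alt=arr("meth_alt"), total_alt=arr("total_alt"),
            )
        )
        log["retained"] += 1
    return pairs, log


def pairs_from_cohort(cohort, apply_filters=True, **filter_kwargs):
    """SnpCpgPair list straight from a simulated cohort.

    Bypasses the tabular route: uses the cohort's pair_counts table and
    true pair map. With ``apply_filters`` the standard MAF / coverage /
    methylation filters are applied (call rate is 1 in simulation).
    """
    inds = list(cohort.counts.individuals)
    mean_cov = cohort.counts.coverage_mean()
    mean_meth = cohort.counts.mean_methylation()
    min_maf = filter_kwargs.get("min_maf", 0.05)
    min_coverage = filter_kwargs.get("min_coverage", 5.0)
    meth_bounds = filter_kwargs.get("meth_bounds", (0.1, 0.9))
    pairs = []
    for _, row in cohort.pairs.iterrows():
        j, snp = int(row.cpg_index), int(row.snp_index)
        sub = cohort.pair_counts[cohort.pair_counts.cpg_index == j]
        sub = sub.set_index("individual").reindex(inds)
        g = sub["genotype"].to_numpy(dtype=int)
        if apply_filters:
            p_alt = g.mean() / 2.0
            if min(p_alt, 1 - p_alt) < min_maf:
                continue
            if mean_cov[j] < min_coverage:
                continue
            if not (meth_bounds[0] <= mean_meth[j] <= meth_bounds[1]):
                continue
        arr = lambda col: sub[col].to_numpy(dtype=np.int64)
        pairs.append(
            SnpCpgPair(
                pair_id=f"pair{j}",
                snp_chrom=str(cohort.genotypes.chrom[snp]),
                snp_pos=int(cohort.genotypes.pos[snp]),
                cpg_chrom=str(cohort.counts.chrom[j]),
                cpg_pos=int(cohort.counts.pos[j]),
                distance=int(row.distance), disrupted=bool(row.disrupted),
                individuals=inds, genotype=g,
                meth=arr("meth"), total=arr("total"),
                meth_excl=arr("meth_excl"), total_excl=arr("total_excl"),
                meth_ref=arr("meth_ref"), total_ref=arr("total_ref"),
                meth_alt=arr("meth_alt"), total_alt=arr("total_alt"),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# downstream summaries


def disruption_regression(deltas, freq_diff, observed_effects):
    """How much of the ancestry effect do disrupting variants explain?

    Regresses the observed proportion-scale ancestry effect on the
    predicted one (disrupting-allele effect x parental allele-frequency
    difference) across disrupted pairs. Returns dict with slope,
    intercept, correlation R, R^2 (variance explained) and n; flagged
    degenerate with fewer than 3 points or a constant predictor.
    """
    x = np.asarray(deltas, float) * np.asarray(freq_diff, float)
    y = np.asarray(observed_effects, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0:
        return dict(slope=np.nan, intercept=np.nan, r=np.nan, r2=np.nan,
                    n=int(x.size), degenerate=True)
    fit = stats.linregress(x, y)
    return dict(slope=float(fit.slope), intercept=float(fit.intercept),
                r=float(fit.rvalue), r2=float(fit.rvalue**2), n=int(x.size),
                degenerate=False)


def distance_effect(table, fdr_thresh=0.1, min_pairs=50):
    """Logistic slope of meQTL detection probability on SNP-CpG distance.

    Non-disrupted pairs only. Returns dict with slope (per bp), p and a
    separation flag.
    """
    import statsmodels.api as sm

    sub = table[~table["disrupted"] & table["q"].notna()]
    if len(sub) == 0:
        raise ParameterError("no non-disrupted pairs with q-values")
    if len(sub) < min_pairs:
        raise ParameterError(f"need >= {min_pairs} non-disrupted pairs, got {len(sub)}")
    y = (sub["q"] < fdr_thresh).astype(float).to_numpy()
    if y.min() == y.max():
        return dict(slope=np.nan, p=np.nan, separation=True)
    X = sm.add_constant(sub["distance"].to_numpy(dtype=float))
    try:
        fit = sm.Logit(y, X).fit(disp=0)
        return dict(slope=float(fit.params[1]), p=float(fit.pvalues[1]),
                    separation=False)
    except Exception:
        return dict(slope=np.nan, p=np.nan, separation=True)
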
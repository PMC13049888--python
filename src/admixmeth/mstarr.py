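"""Regulatory-activity and methylation-dependence calls from reporter
DNA/RNA replicate counts.

A window drives regulatory activity when its RNA abundance exceeds the
DNA input abundance; it is methylation-dependent when that RNA-vs-DNA
effect differs between the experimentally methylated and unmethylated
library conditions (an interaction). Counts are normalized to log2
abundances with library-composition scale factors; effects are linear
contrasts with pooled-variance t tests. False discovery rates are
estimated against permutation nulls that move labels only:

* activity: RNA/DNA labels swapped within each replicate pair, with each
  permutation's p-value pool subsampled to the observed number of
  positive-effect windows (observed data are asymmetric -- most windows
  have more DNA than RNA -- while permuted effects are balanced);
* interaction: condition labels reassigned across DNA-RNA replicate
  pairs, restricted to the active window set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bbcore import empirical_qvalues
from .exceptions import DataError, StateError

__all__ = [
    "MstarrResult",
    "filter_windows",
    "normalize",
    "test_activity",
    "activity_scan",
    "test_methylation_dependence",
]

CONDITIONS = ("methylated", "unmethylated")


@dataclass
class MstarrResult:
    """Per-window calls over the filtered window set."""

    table: pd.DataFrame
    filter_log: dict
    n_permutations: int


def _cols(rc):
    out = {}
    for cond in CONDITIONS:
        for assay in ("DNA", "RNA"):
            cols = rc.columns(assay, cond)
            if cols.size == 0:
                raise DataError(f"no {assay} samples in condition {cond}")
            out[(assay, cond)] = cols
    return out


def filter_windows(rc, min_median_dna=4.0, presence_frac=0.5):
    """Window filters applied in order, with per-rule loss counts.

    (i) median DNA coverage strictly greater than ``min_median_dna`` in
    both conditions; (ii) DNA count nonzero in at least half the DNA
    samples of both conditions (enough input to drive expression);
    (iii) nonzero counts in at least half the RNA replicates of either
    condition.

    Returns (retained index array, loss-count dict).
    """
    cols = _cols(rc)
    n = rc.n_windows
    keep = np.ones(n, dtype=bool)
    log = {"input": n}
    med_ok = np.ones(n, dtype=bool)
    for cond in CONDITIONS:
        med_ok &= np.median(rc.counts[:, cols[("DNA", cond)]], axis=1) > min_median_dna
    log["dna_median"] = int((keep & ~med_ok).sum())
    keep &= med_ok
    pres_ok = np.ones(n, dtype=bool)
    for cond in CONDITIONS:
        d = rc.counts[:, cols[("DNA", cond)]]
        pres_ok &= (d > 0).mean(axis=1) >= presence_frac
    log["dna_presence"] = int((keep & ~pres_ok).sum())
    keep &= pres_ok
    rna_ok = np.zeros(n, dtype=bool)
    for cond in CONDITIONS:
        r = rc.counts[:, cols[("RNA", cond)]]
        rna_ok |= (r > 0).mean(axis=1) >= presence_frac
    log["rna_presence"] = int((keep & ~rna_ok).sum())
    keep &= rna_ok
    log["retained"] = int(keep.sum())
    return np.where(keep)[0], log


def normalize(counts):
    """Log2 abundance with library-composition scale factors.

    Per sample: scale = library size x a median-of-ratios composition
    factor, where each sample's counts-per-million are compared to the
    geometric mean CPM of the *other* samples over windows nonzero
    everywhere. Abundance = log2(count / scale * 1e6 + 0.5), the
    pseudo-count applied after scaling so a zero count stays finite and
    doubling one sample's counts doubles its scale factor exactly while
    leaving every abundance unchanged. Samples with all-zero counts are
    excluded (columns returned as NaN) with a warning.
    """
    counts = np.asarray(counts, float)
    nw, ns = counts.shape
    lib = counts.sum(axis=0)
    abundance = np.full((nw, ns), np.nan)
    nonzero = lib > 0
    if not nonzero.all():
        import warnings

        warnings.warn(f"{int((~nonzero).sum())} all-zero sample(s) excluded")
    sub = counts[:, nonzero]
    lib_sub = lib[nonzero]
    cpm = sub / lib_sub * 1e6
    common = np.all(sub > 0, axis=1)
    if not common.any():
        common = np.ones(nw, dtype=bool)
    logcpm = np.log(np.where(cpm > 0, cpm, np.nan))[common]
    m = logcpm.shape[1]
    total_log = np.nansum(logcpm, axis=1, keepdims=True)
    # leave-one-out geometric-mean reference per sample
    loo_ref = (total_log - logcpm) / (m - 1) if m > 1 else np.zeros_like(logcpm)
    ratios = np.exp(logcpm - loo_ref)
    norm = np.nanmedian(ratios, axis=0)
    scale = norm * lib_sub
    abundance[:, nonzero] = np.log2(sub / scale * 1e6 + 0.5)
    return abundance


def test_activity(abund_rna, abund_dna):
    """Pooled-variance contrast of mean RNA vs mean DNA abundance.

    Vectorized over windows (rows). Returns (effect, p): effect is the
    log2 RNA-minus-DNA abundance difference; p a two-sided t with
    n_rna + n_dna - 2 df.
    """
    r = np.asarray(abund_rna, float)
    d = np.asarray(abund_dna, float)
    nr, nd = r.shape[1], d.shape[1]
    if nr < 2 or nd < 2:
        raise DataError("need at least 2 replicates per assay")
    effect = r.mean(axis=1) - d.mean(axis=1)
    s2 = ((nr - 1) * r.var(axis=1, ddof=1) + (nd - 1) * d.var(axis=1, ddof=1)) / (
        nr + nd - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2 * (1.0 / nr + 1.0 / nd))
    p = 2.0 * stats.t.sf(np.abs(t), nr + nd - 2)
    p = np.where(np.isfinite(t), p, 1.0)
    return effect, p


def _interaction(abund, cols_by_cond):
    """Interaction effect (unmethylated minus methylated activity) and p."""
    effects, s2s, dfs, ns = [], [], [], []
    for cond in CONDITIONS:
        r = abund[:, cols_by_cond[("RNA", cond)]]
        d = abund[:, cols_by_cond[("DNA", cond)]]
        nr, nd = r.shape[1], d.shape[1]
        effects.append(r.mean(axis=1) - d.mean(axis=1))
        s2s.append((nr - 1) * r.var(axis=1, ddof=1) + (nd - 1) * d.var(axis=1, ddof=1))
        dfs.append(nr + nd - 2)
        ns.append((nr, nd))
    inter = effects[1] - effects[0]
    df = sum(dfs)
    s2p = (s2s[0] + s2s[1]) / df
    var = s2p * sum(1.0 / nr + 1.0 / nd for nr, nd in ns)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = inter / np.sqrt(var)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(t), p, 1.0)
    return inter, p


def _swap_labels(abund, cols_by_cond, rng):
    """RNA/DNA labels swapped within each replicate pair (per condition)."""
    out = abund.copy()
    for cond in CONDITIONS:
        rna, dna = cols_by_cond[("RNA", cond)], cols_by_cond[("DNA", cond)]
        flips = rng.random(len(rna)) < 0.5
        for rcol, dcol, f in zip(rna, dna, flips):
            if f:
                out[:, [rcol, dcol]] = abund[:, [dcol, rcol]]
    return out


def activity_scan(rc, n_perm=10, seed=0, fdr=0.1):
    """Per-condition activity calls with the subsampled permutation null.

    Windows are filtered, normalized, and tested per condition; only
    windows with a positive RNA-vs-DNA effect in at least one condition
    are carried into FDR estimation. Each permutation swaps RNA/DNA
    labels within replicate pairs and its p-value pool is subsampled to
    the observed number of positive-effect windows per condition.

    Returns a MstarrResult whose table covers retained windows with
    effect_<cond>, p_<cond>, q_<cond> and active_<cond> columns.
    """
    keep, log = filter_windows(rc)
    sub = rc.subset_windows(keep)
    cols = _cols(sub)
    abund = normalize(sub.counts)
    rng = np.random.default_rng(seed)

    effects, pvals = {}, {}
    for cond in CONDITIONS:
        effects[cond], pvals[cond] = test_activity(
            abund[:, cols[("RNA", cond)]], abund[:, cols[("DNA", cond)]]
        )
    positive_any = (effects[CONDITIONS[0]] > 0) | (effects[CONDITIONS[1]] > 0)

    pools = {cond: [] for cond in CONDITIONS}
    n_pos = {cond: int((effects[cond] > 0).sum()) for cond in CONDITIONS}
    for _ in range(n_perm):
        perm_ab = _swap_labels(abund, cols, rng)
        for cond in CONDITIONS:
            e, p = test_activity(
                perm_ab[:, cols[("RNA", cond)]], perm_ab[:, cols[("DNA", cond)]]
            )
            pos = np.where(e > 0)[0]
            if pos.size > n_pos[cond]:
                pos = rng.choice(pos, size=n_pos[cond], replace=False)
            pools[cond].append(p[pos])

    table = pd.DataFrame(
        {
            "window_id": sub.window_id,
            "chrom": sub.chrom,
            "start": sub.start,
            "end": sub.end,
        }
    )
    for cond in CONDITIONS:
        table[f"effect_{cond}"] = effects[cond]
        table[f"p_{cond}"] = pvals[cond]
        qcol = np.full(len(table), np.nan)
        pos_mask = (effects[cond] > 0) & positive_any
        pool = np.concatenate(pools[cond]) if pools[cond] else np.array([])
        if pos_mask.any() and pool.size:
            # the retained set is signal-enriched and the permuted pool is
            # asymmetry-corrected; pi0 = 1 keeps the estimate conservative
            qcol[pos_mask] = empirical_qvalues(pvals[cond][pos_mask], pool,
                                               n_perm, pi0=1.0)
        table[f"q_{cond}"] = qcol
        table[f"active_{cond}"] = (qcol < fdr) & (effects[cond] > 0)
    table["active_any"] = table[[f"active_{c}" for c in CONDITIONS]].any(axis=1)
    return MstarrResult(table=table, filter_log=log, n_permutations=n_perm), sub, abund


def test_methylation_dependence(result, sub, abund, n_perm=10, seed=0, fdr=0.1):
    """Interaction (methylation-dependence) calls over the active set.

    The interaction contrasts the RNA-vs-DNA effect between conditions;
    its permutation null reassigns condition labels across DNA-RNA
    replicate pairs, keeping each pair's two count vectors intact.
    Windows outside the active set are not tested (columns stay NaN).

    Adds interaction, interaction_p, interaction_q, meth_dependent and
    direction ("more_active_unmethylated"/"more_active_methylated")
    columns to the result table and returns the result.
    """
    table = result.table
    if "active_any" not in table:
        raise StateError("run activity_scan before testing methylation dependence")
    active = table["active_any"].to_numpy()
    cols = _cols(sub)
    rng = np.random.default_rng(seed)
    inter, p_inter = _interaction(abund, cols)

    # condition permutation: reassign condition labels across replicate pairs
    pair_cols = []
    for cond in CONDITIONS:
        for dcol, rcol in zip(cols[("DNA", cond)], cols[("RNA", cond)]):
            pair_cols.append((dcol, rcol))
    n_pairs = len(pair_cols)
    pool = []
    act_idx = np.where(active)[0]
    for _ in range(n_perm):
        perm = rng.permutation(n_pairs)
        col_map = {}
        for slot, src in enumerate(perm):
            # pair in slot takes the condition of slot's original pair
            dst_d, dst_r = pair_cols[slot]
            src_d, src_r = pair_cols[src]
            col_map[dst_d], col_map[dst_r] = src_d, src_r
        # permuted column lookup instead of materializing a shuffled matrix
        perm_cols = {
            key: np.array([col_map[c] for c in cs]) for key, cs in cols.items()
        }
        _, pp = _interaction(abund, perm_cols)
        pool.append(pp[act_idx])
    pool = np.concatenate(pool) if pool else np.array([])

    q = np.full(len(table), np.nan)
    if active.any() and pool.size:
        # pi0 = 1: the active set is enriched for true interactions, which
        # both depresses the single-lambda estimate and (through inflated
        # within-group variance under permutation) thins the pool's small
        # p-values; the default estimator would be anti-conservative here
        q[active] = empirical_qvalues(p_inter[active], pool, n_perm, pi0=1.0)
    table["interaction"] = np.where(active, inter, np.nan)
    table["interaction_p"] = np.where(active, p_inter, np.nan)
    table["interaction_q"] = q
    table["meth_dependent"] = active & (q < fdr)
    direction = np.where(inter > 0, "more_active_unmethylated", "more_active_methylated")
    table["direction"] = np.where(table["meth_dependent"], direction, "")
    return result
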
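"""Genomic-context annotation and enrichment for CpG sites.

CpG islands are detected with the classic sliding-window criteria
(windows of 100 bp stepped by 1, GC fraction > 0.5 and observed/expected
CpG ratio > 0.6; maximal runs of qualifying windows longer than 200 bp),
shores as the 2 kb flanks. CpGs are then assigned multi-label contexts
(promoter, exon, intron/UTR, enhancer, island, shore), contexts are
tested for enrichment of ancestry-associated sites by Fisher's exact
test, and methylation significance is integrated with ancestry effects
on gene expression via per-context logistic regressions and directional
concordance odds ratios.

Coordinates are 0-based half-open internally; CpG positions arrive
1-based (the convention of methylation count tables) and are converted
at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ParameterError
from .species import fisher_log2_or

__all__ = [
    "find_cpg_islands",
    "gene_windows",
    "assign_context",
    "context_enrichment",
    "expression_integration",
]

ISLAND_WINDOW = 100
ISLAND_MIN_LENGTH = 200
ISLAND_GC_MIN = 0.5
ISLAND_OE_MIN = 0.6
SHORE_WIDTH = 2000
PROMOTER_WIDTH = 10_000
GENE_FLANK = 10_000
GENE_MIN_WINDOW = 50_000


def find_cpg_islands(sequence, window=ISLAND_WINDOW, min_length=ISLAND_MIN_LENGTH,
                     gc_min=ISLAND_GC_MIN, oe_min=ISLAND_OE_MIN,
                     shore_width=SHORE_WIDTH):
    """CpG islands and shores of one sequence.

    A length-``window`` window starting at position i qualifies when its
    GC fraction exceeds ``gc_min`` and its observed/expected CpG ratio
    (n_CpG * window / (n_C * n_G)) exceeds ``oe_min``; bases covered by
    any qualifying window are merged and maximal runs longer than
    ``min_length`` are islands. Shores are the ``shore_width`` flanks on
    either side, clipped at sequence ends and excluding island bases.

    Returns (islands, shores): lists of (start, end) 0-based half-open
    intervals. Case-insensitive; N bases count as neither C nor G.
    """
    seq = str(sequence).upper()
    L = len(seq)
    if L < window:
        return [], []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(L, dtype=bool)
    is_cpg[:-1] = is_c[:-1] & is_g[1:]
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(L - window + 1)
    n_c = cum_c[starts + window] - cum_c[starts]
    n_g = cum_g[starts + window] - cum_g[starts]
    # CpG dinucleotides fully inside the window start at i .. i+window-2
    n_cpg = cum_cpg[starts + window - 1] - cum_cpg[starts]
    gc = (n_c + n_g) / window
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cpg * window / (n_c * n_g), 0.0)
    good = (gc > gc_min) & (oe > oe_min)
    covered = np.zeros(L + 1, dtype=np.int32)
    np.add.at(covered, starts[good], 1)
    np.add.at(covered, starts[good] + window, -1)
    mask = np.cumsum(covered[:-1]) > 0
    islands = [
        (s, e) for s, e in _runs(mask) if e - s > min_length
    ]
    shores = []
    for s, e in islands:
        shores.append((max(0, s - shore_width), s))
        shores.append((e, min(L, e + shore_width)))
    shores = _subtract(_merge(shores), islands)
    return islands, shores


def _runs(mask):
    diff = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(intervals, holes):
    out = []
    for s, e in intervals:
        cur = s
        for hs, he in sorted(holes):
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
        if cur < e:
            out.append((cur, e))
    return [iv for iv in out if iv[1] > iv[0]]


def _points_in(chrom, pos0, interval_df):
    """Boolean: is each 0-based point inside any interval (per chromosome)?"""
    hit = np.zeros(len(pos0), dtype=bool)
    if interval_df is None or len(interval_df) == 0:
        return hit
    for c, sub in interval_df.groupby("chrom"):
        sel = chrom == c
        if not sel.any():
            continue
        merged = _merge(list(zip(sub["start"], sub["end"])))
        flat = np.array([b for iv in merged for b in iv])
        idx = np.searchsorted(flat, pos0[sel], side="right")
        hit[sel] = idx % 2 == 1
    return hit


def gene_windows(genes):
    """Per-gene ancestry windows: TSS - 10 kb to TES + 10 kb, widened
    symmetrically to at least 50 kb total for short genes.

    ``genes`` needs columns chrom, start, end (0-based half-open gene
    span), strand, gene_id.
    """
    g = genes.copy()
    start = g["start"].to_numpy(float) - GENE_FLANK
    end = g["end"].to_numpy(float) + GENE_FLANK
    width = end - start
    pad = np.maximum(0.0, (GENE_MIN_WINDOW - width) / 2.0)
    g["window_start"] = np.maximum(0, start - pad).astype(np.int64)
    g["window_end"] = (end + pad).astype(np.int64)
    return g


def assign_context(cpgs, genes=None, exons=None, enhancers=None,
                   islands=None, shores=None):
    """Multi-label genomic context per CpG.

    Parameters
    ----------
    cpgs : DataFrame
        Columns chrom, pos (1-based CpG cytosine position).
    genes : DataFrame, optional
        chrom, start, end, strand, gene_id (0-based half-open).
    exons : DataFrame, optional
        chrom, start, end (0-based half-open).
    enhancers : DataFrame, optional
        BED-like chrom, start, end.
    islands, shores : DataFrame, optional
        chrom, start, end from the island detector.

    Returns the cpgs frame with boolean columns promoter, exon,
    intron_utr, enhancer, cpg_island, cpg_shore. Promoters are the 10 kb
    strand-aware upstream of each gene's 5'-most TSS; intron_utr is gene
    body minus exons minus promoter.
    """
    out = cpgs.copy()
    chrom = out["chrom"].to_numpy()
    pos0 = out["pos"].to_numpy(dtype=np.int64) - 1
    known = set(chrom.tolist())
    for name, df in (("genes", genes), ("exons", exons), ("enhancers", enhancers),
                     ("islands", islands), ("shores", shores)):
        if df is not None and len(df) and not (set(df["chrom"]) & known):
            raise AlignmentError(
                f"no shared chromosome names between CpGs and {name}: "
                f"{sorted(set(df['chrom']))[:3]} vs {sorted(known)[:3]}"
            )
    if genes is not None and len(genes):
        proms = []
        for _, row in genes.iterrows():
            if row["strand"] == "-":
                proms.append((row["chrom"], row["end"], row["end"] + PROMOTER_WIDTH))
            else:
                proms.append((row["chrom"], max(0, row["start"] - PROMOTER_WIDTH), row["start"]))
        prom_df = pd.DataFrame(proms, columns=["chrom", "start", "end"])
        out["promoter"] = _points_in(chrom, pos0, prom_df)
        body = genes[["chrom", "start", "end"]]
        in_body = _points_in(chrom, pos0, body)
    else:
        out["promoter"] = False
        in_body = np.zeros(len(out), dtype=bool)
    out["exon"] = _points_in(chrom, pos0, exons) if exons is not None else False
    out["intron_utr"] = in_body & ~out["exon"].to_numpy() & ~out["promoter"].to_numpy()
    out["enhancer"] = _points_in(chrom, pos0, enhancers) if enhancers is not None else False
    out["cpg_island"] = _points_in(chrom, pos0, islands) if islands is not None else False
    out["cpg_shore"] = (
        _points_in(chrom, pos0, shores) & ~out["cpg_island"].to_numpy()
        if shores is not None
        else False
    )
    return out


def context_enrichment(foreground, contexts,
                       context_cols=("promoter", "exon", "intron_utr",
                                     "enhancer", "cpg_island", "cpg_shore")):
    """Fisher enrichment of a CpG subset in each genomic context.

    ``foreground`` is a boolean mask over the rows of ``contexts`` (the
    background universe). Returns a DataFrame with log2 OR, Woolf 95% CI
    and exact p per context. Zero-margin contexts keep their exact p but
    flag the OR as degenerate.
    """
    fg = np.asarray(foreground, bool)
    if fg.shape[0] != len(contexts):
        raise ParameterError("foreground mask must match the context table")
    rows = []
    for col in context_cols:
        if col not in contexts:
            continue
        inc = contexts[col].to_numpy(bool)
        tab = np.array(
            [
                [(fg & inc).sum(), (fg & ~inc).sum()],
                [(~fg & inc).sum(), (~fg & ~inc).sum()],
            ]
        )
        l2, ci, p = fisher_log2_or(tab)
        rows.append((col, l2, ci[0], ci[1], p, int(tab[0, 0]), bool((tab == 0).any())))
    return pd.DataFrame(
        rows,
        columns=["context", "log2_or", "ci_lo", "ci_hi", "p", "n_fg_in", "degenerate"],
    )


def expression_integration(cpg_table, gene_effects, min_cpgs=20,
                           context_cols=("promoter", "exon", "intron_utr")):
    """Couple CpG ancestry-methylation calls to gene-expression ancestry effects.

    Parameters
    ----------
    cpg_table : DataFrame
        One row per CpG-gene assignment, with columns significant (bool,
        ancestry-associated methylation), effect_allele (signed
        proportion-scale effect), gene_id, and boolean context columns.
    gene_effects : DataFrame
        gene_id, expr_effect (signed ancestry effect on expression),
        expr_significant (bool).
    min_cpgs : int
        Contexts with fewer assigned CpGs are skipped with a reason.

    Returns a DataFrame per context: logistic slope (probability of
    ancestry-associated methylation on |expression effect|) and its p,
    plus the concordance log2 OR (sign of methylation effect x sign of
    expression effect among jointly significant pairs).
    """
    import statsmodels.api as sm

    merged = cpg_table.merge(gene_effects, on="gene_id", how="inner")
    if len(merged) == 0:
        import warnings

        warnings.warn("no CpGs assigned to genes with expression effects")
        return pd.DataFrame(
            columns=["context", "n", "logit_beta", "logit_p",
                     "concordance_log2_or", "concordance_p", "skip_reason"]
        )
    rows = []
    for col in context_cols:
        sub = merged[merged[col].astype(bool)]
        if len(sub) < min_cpgs:
            rows.append((col, len(sub), np.nan, np.nan, np.nan, np.nan, "too_few_cpgs"))
            continue
        y = sub["significant"].astype(float).to_numpy()
        x = np.abs(sub["expr_effect"].to_numpy(float))
        if y.min() == y.max() or np.ptp(x) == 0:
            rows.append((col, len(sub), np.nan, np.nan, np.nan, np.nan, "degenerate"))
            continue
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        joint = sub[sub["significant"].astype(bool)
                    & sub["expr_significant"].astype(bool)]
        if len(joint) >= 4:
            up_meth = joint["effect_allele"].to_numpy() > 0
            up_expr = joint["expr_effect"].to_numpy() > 0
            tab = np.array(
                [
                    [(up_meth & up_expr).sum(), (up_meth & ~up_expr).sum()],
                    [(~up_meth & up_expr).sum(), (~up_meth & ~up_expr).sum()],
                ]
            )
            l2, _, cp = fisher_log2_or(tab)
        else:
            l2, cp = np.nan, np.nan
        rows.append(
            (col, len(sub), float(fit.params[1]), float(fit.pvalues[1]), l2, cp, "")
        )
    return pd.DataFrame(
        rows,
        columns=["context", "n", "logit_beta", "logit_p",
                 "concordance_log2_or", "concordance_p", "skip_reason"],
    )
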
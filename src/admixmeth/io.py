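"""Readers and writers for the standard interchange formats.

Genotypes travel as VCF (diploid GT, unphased by default), ancestry
tracts as BED-like 0-based half-open intervals with per-individual
dosage, methylation counts and reporter counts as long-format TSV.
Reading VCF goes through cyvcf2; everything tabular through pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AncestryPanel, MethCountMatrix, ReporterCounts
from .exceptions import DataError

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_gff_genes",
    "read_bed",
    "write_ancestry_bed",
    "read_ancestry_bed",
    "dosage_at_positions",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_reporter_tsv",
    "read_reporter_tsv",
]


def write_vcf(genotypes, path, phased=False):
    """Write simulated genotypes as a minimal VCF (GT field only)."""
    sep = "|" if phased else "/"
    inds = list(genotypes.individuals)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(genotypes.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(inds) + "\n")
        hap = genotypes.hap_alleles
        for j in range(genotypes.n_snps):
            gts = [f"{hap[i, 0, j]}{sep}{hap[i, 1, j]}" for i in range(len(inds))]
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.pos[j]}\tsnp{j}\t"
                f"{genotypes.ref[j]}\t{genotypes.alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path):
    """VCF -> DataFrame with chrom, pos, ref, alt and one dosage column
    per sample (alt-allele count; NaN for missing)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        dosages = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            dosages.append(sum(alleles) if alleles else np.nan)
        rows.append([var.CHROM, var.POS, var.REF, var.ALT[0] if var.ALT else "."]
                    + dosages)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"] + samples)


def read_gff_genes(path):
    """Gene and exon tables from a GFF3 gene model.

    Returns (genes, exons): genes has chrom, start, end (0-based
    half-open), strand and gene_id; exons has chrom, start, end. These
    are the inputs the context annotator expects.
    """
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    df = df.rename(columns={"Chromosome": "chrom", "Start": "start",
                            "End": "end", "Strand": "strand"})
    genes = df[df["Feature"] == "gene"].copy()
    id_col = "gene_id" if "gene_id" in genes.columns else "ID"
    genes["gene_id"] = genes[id_col].astype(str)
    genes = genes[["chrom", "start", "end", "strand", "gene_id"]].reset_index(drop=True)
    exons = df[df["Feature"] == "exon"][["chrom", "start", "end"]].reset_index(drop=True)
    return genes, exons


def read_bed(path):
    """BED intervals -> DataFrame with chrom, start, end (0-based half-open)."""
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    return df.rename(columns={"Chromosome": "chrom", "Start": "start",
                              "End": "end"})[["chrom", "start", "end"]]


def write_ancestry_bed(panel, path):
    """Per-individual ancestry dosage intervals (0-based half-open BED).

    Columns: chrom, start, end, individual, dosage. Haplotype tract
    pairs are intersected so each interval carries the diploid dosage.
    """
    if panel.tracts is None:
        raise DataError("panel has no tract information to write")
    rows = []
    for (ind, chrom), sub in panel.tracts.groupby(["individual", "chrom"], sort=True):
        h0 = sub[sub["haplotype"] == 0].sort_values("start")
        h1 = sub[sub["haplotype"] == 1].sort_values("start")
        bps = np.unique(np.concatenate([h0["start"], h0["end"], h1["start"], h1["end"]]))
        for s, e in zip(bps[:-1], bps[1:]):
            mid = (s + e) // 2
            d0 = h0[(h0["start"] <= mid) & (h0["end"] > mid)]["state"]
            d1 = h1[(h1["start"] <= mid) & (h1["end"] > mid)]["state"]
            dosage = int(d0.iloc[0] if len(d0) else 0) + int(d1.iloc[0] if len(d1) else 0)
            rows.append((chrom, int(s), int(e), panel.individuals[ind], dosage))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "individual", "dosage"])
    # merge adjacent equal-dosage intervals for compactness
    df.to_csv(path, sep="\t", index=False)
    return df


def read_ancestry_bed(path):
    return pd.read_csv(path, sep="\t")


def dosage_at_positions(tracts, chrom, pos, individuals):
    """Evaluate per-individual dosage from a BED-like tract frame.

    ``pos`` are 1-based positions; intervals are 0-based half-open.
    Returns (n_individuals, n_positions) int8 with -1 where uncovered.
    """
    chrom = np.asarray(chrom)
    pos0 = np.asarray(pos, dtype=np.int64) - 1
    out = np.full((len(individuals), len(pos0)), -1, dtype=np.int8)
    for i, ind in enumerate(individuals):
        sub = tracts[tracts["individual"] == ind]
        for c, csub in sub.groupby("chrom"):
            sel = chrom == c
            if not sel.any():
                continue
            csub = csub.sort_values("start")
            starts = csub["start"].to_numpy()
            ends = csub["end"].to_numpy()
            dosages = csub["dosage"].to_numpy()
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
            vals = np.where(ok, dosages[np.clip(idx, 0, len(dosages) - 1)], -1)
            out[i, sel] = vals
    return out


def write_counts_tsv(matrix, path):
    """Long-format methylation counts: chrom, pos, individual, meth, total."""
    ns, ni = matrix.meth.shape
    df = pd.DataFrame(
        {
            "chrom": np.repeat(matrix.chrom, ni),
            "pos": np.repeat(matrix.pos, ni),
            "individual": np.tile(np.asarray(matrix.individuals, dtype=object), ns),
            "meth": matrix.meth.ravel(),
            "total": matrix.total.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path):
    """Long-format counts TSV -> MethCountMatrix (uncovered cells 0/0)."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "pos", "individual", "meth", "total"}
    if not need.issubset(df.columns):
        raise DataError(f"counts TSV must have columns {sorted(need)}")
    meth = df.pivot_table(index=["chrom", "pos"], columns="individual",
                          values="meth", fill_value=0, aggfunc="sum", sort=True)
    total = df.pivot_table(index=["chrom", "pos"], columns="individual",
                           values="total", fill_value=0, aggfunc="sum", sort=True)
    total = total[meth.columns]
    chroms = meth.index.get_level_values(0).to_numpy()
    pos = meth.index.get_level_values(1).to_numpy()
    return MethCountMatrix(
        chrom=chroms,
        pos=pos,
        individuals=list(meth.columns),
        meth=meth.to_numpy(),
        total=total.to_numpy(),
    )


def write_reporter_tsv(rc, path):
    """Long-format reporter counts: window metadata x replicate counts."""
    rows = []
    for s_idx, meta in rc.samples.iterrows():
        for w in range(rc.n_windows):
            rows.append(
                (rc.window_id[w], rc.chrom[w], int(rc.start[w]), int(rc.end[w]),
                 int(meta["replicate"]), meta["assay"], meta["condition"],
                 int(rc.counts[w, s_idx]))
            )
    pd.DataFrame(
        rows,
        columns=["window_id", "chrom", "start", "end", "replicate_id",
                 "assay", "condition", "count"],
    ).to_csv(path, sep="\t", index=False)


def read_reporter_tsv(path):
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["assay", "condition", "replicate_id"]
    samples = (
        df[meta_cols].drop_duplicates().sort_values(meta_cols).reset_index(drop=True)
    )
    samples = samples.rename(columns={"replicate_id": "replicate"})
    windows = (
        df[["window_id", "chrom", "start", "end"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    counts = np.zeros((len(windows), len(samples)), dtype=np.int64)
    wid_index = {w: i for i, w in enumerate(windows["window_id"])}
    key_index = {
        (r["assay"], r["condition"], r["replicate"]): i
        for i, r in samples.iterrows()
    }
    for _, row in df.iterrows():
        counts[wid_index[row["window_id"]],
               key_index[(row["assay"], row["condition"], row["replicate_id"])]] = row["count"]
    return ReporterCounts(
        window_id=windows["window_id"].to_numpy(),
        chrom=windows["chrom"].to_numpy(),
        start=windows["start"].to_numpy(),
        end=windows["end"].to_numpy(),
        samples=samples,
        counts=counts,
    )
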
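"""Core in-memory containers shared across analysis stages.

These are thin, validated wrappers around numpy arrays / pandas frames:
a site-by-individual methylation count matrix, a local-ancestry panel
(anubis allele dosage per individual per locus plus global ancestry),
and a reporter-assay window-by-replicate count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = ["MethCountMatrix", "AncestryPanel", "ReporterCounts"]


@dataclass
class MethCountMatrix:
    """Methylated/total read counts at CpG sites for a set of individuals.

    ``meth`` and ``total`` are (n_sites, n_individuals) integer arrays;
    ``pos`` is the 1-based position of the CpG cytosine on the forward
    strand and must be strictly increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    individuals: list
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        ns, ni = self.meth.shape
        if self.total.shape != (ns, ni) or len(self.individuals) != ni:
            raise DataError("meth/total/individuals shapes do not align")
        if self.pos.shape != (ns,) or self.chrom.shape != (ns,):
            raise DataError("site annotation length does not match counts")
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise DataError("require 0 <= meth <= total elementwise")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise DataError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self):
        return self.meth.shape[0]

    @property
    def n_individuals(self):
        return self.meth.shape[1]

    def mean_methylation(self):
        """Per-site mean of per-individual methylation ratios (covered only)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)
        return np.nanmean(ratio, axis=1)

    def coverage_mean(self):
        """Per-site mean coverage over all individuals."""
        return self.total.mean(axis=1)

    def n_covered(self):
        """Per-site number of individuals with at least one read."""
        return (self.total > 0).sum(axis=1)

    def subset_sites(self, index):
        return MethCountMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            individuals=list(self.individuals),
            meth=self.meth[index],
            total=self.total[index],
        )

    def subset_individuals(self, mask):
        mask = np.asarray(mask)
        idx = np.where(mask)[0] if mask.dtype == bool else mask
        return MethCountMatrix(
            chrom=self.chrom,
            pos=self.pos,
            individuals=[self.individuals[i] for i in idx],
            meth=self.meth[:, idx],
            total=self.total[:, idx],
        )


@dataclass
class AncestryPanel:
    """Local-ancestry dosage (count of anubis alleles) per individual per locus.

    ``dosage`` is (n_individuals, n_loci) with values in {0, 1, 2} or -1
    for missing. ``global_ancestry`` is each individual's mean dosage / 2
    over non-missing loci. ``tracts`` (optional) is a BED-like frame of
    per-individual ancestry segments for export.
    """

    chrom: np.ndarray
    pos: np.ndarray
    individuals: list
    dosage: np.ndarray
    global_ancestry: np.ndarray = None
    tracts: pd.DataFrame = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        ni, nl = self.dosage.shape
        if len(self.individuals) != ni or self.pos.shape != (nl,):
            raise DataError("dosage shape does not match individuals/loci")
        valid = np.isin(self.dosage, [-1, 0, 1, 2])
        if not np.all(valid):
            raise DataError("dosage values must be in {0,1,2} or -1 (missing)")
        if self.global_ancestry is None:
            masked = np.ma.masked_equal(self.dosage, -1)
            self.global_ancestry = np.asarray(masked.mean(axis=1) / 2.0)
        self.global_ancestry = np.asarray(self.global_ancestry, float)

    @property
    def n_individuals(self):
        return self.dosage.shape[0]

    @property
    def n_loci(self):
        return self.dosage.shape[1]

    def dosage_at(self, locus_index):
        """Dosage vector across individuals at one locus."""
        return self.dosage[:, locus_index]

    def subset_loci(self, index):
        return AncestryPanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            individuals=list(self.individuals),
            dosage=self.dosage[:, index],
            global_ancestry=self.global_ancestry,
            tracts=self.tracts,
        )


@dataclass
class ReporterCounts:
    """Reporter-assay (DNA/RNA x methylated/unmethylated) window counts.

    ``counts`` is (n_windows, n_samples); ``samples`` holds per-sample
    metadata with columns ``assay`` ("DNA"/"RNA"), ``condition``
    ("methylated"/"unmethylated") and ``replicate`` (the index pairing a
    DNA sample with its RNA sample within a condition). Windows are
    non-overlapping 500 bp intervals in 0-based half-open coordinates.
    """

    window_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    samples: pd.DataFrame
    counts: np.ndarray
    truth: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        nw, ns = self.counts.shape
        if len(self.samples) != ns:
            raise DataError("samples metadata does not match count columns")
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")
        if np.any(np.asarray(self.end) - np.asarray(self.start) != 500):
            raise DataError("windows must be exactly 500 bp")
        required = {"assay", "condition", "replicate"}
        if not required.issubset(self.samples.columns):
            raise DataError(f"samples must have columns {sorted(required)}")
        for cond in self.samples["condition"].unique():
            sub = self.samples[self.samples["condition"] == cond]
            dna = set(sub.loc[sub["assay"] == "DNA", "replicate"])
            rna = set(sub.loc[sub["assay"] == "RNA", "replicate"])
            if dna != rna:
                raise DataError(
                    f"replicate pairing is not a bijection in condition {cond!r}"
                )

    @property
    def n_windows(self):
        return self.counts.shape[0]

    def columns(self, assay, condition):
        """Column indices for one assay/condition, ordered by replicate."""
        m = (self.samples["assay"] == assay) & (self.samples["condition"] == condition)
        sub = self.samples[m].sort_values("replicate")
        return sub.index.to_numpy()

    def subset_windows(self, index):
        return ReporterCounts(
            window_id=np.asarray(self.window_id)[index],
            chrom=np.asarray(self.chrom)[index],
            start=np.asarray(self.start)[index],
            end=np.asarray(self.end)[index],
            samples=self.samples,
            counts=self.counts[index],
            truth=None if self.truth is None else self.truth.iloc[index].reset_index(drop=True),
        )
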
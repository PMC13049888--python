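"""Tests for CpG-island detection, context assignment and enrichment."""

import numpy as np
import pandas as pd
import pytest

from admixmeth.annotate import (
    assign_context,
    context_enrichment,
    expression_integration,
    find_cpg_islands,
    gene_windows,
)
from admixmeth.exceptions import AlignmentError
from test_species import _minlik_fisher_p


def brute_force_islands(seq, window=100, min_length=200):
    """Position-wise string-counting oracle for the island detector."""
    seq = str(seq).upper()
    L = len(seq)
    marked = [False] * L
    for i in range(L - window + 1):
        w = seq[i:i + window]
        n_c, n_g, n_cpg = w.count("C"), w.count("G"), w.count("CG")
        if (n_c + n_g) / window > 0.5 and n_c * n_g > 0 and \
                n_cpg * window / (n_c * n_g) > 0.6:
            for j in range(i, i + window):
                marked[j] = True
    islands, start = [], None
    for i, m in enumerate(marked + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > min_length:
                islands.append((start, i))
            start = None
    return islands


def random_sequence(rng, length, cpg_patches=0):
    bases = rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3])
    seq = "".join(bases)
    for _ in range(cpg_patches):
        start = int(rng.integers(0, length - 400))
        seq = seq[:start] + "CG" * 150 + seq[start + 300:]
    return seq


class TestIslandDetector:
    def test_poly_at_has_no_islands(self):
        islands, shores = find_cpg_islands("AT" * 5000)
        assert islands == [] and shores == []

    def test_embedded_cg_repeat_found(self):
        seq = "AT" * 2500 + "CG" * 150 + "AT" * 2350
        islands, shores = find_cpg_islands(seq)
        assert len(islands) == 1
        s, e = islands[0]
        assert abs(s - 5000) <= 100 and abs(e - 5300) <= 100
        assert len(shores) == 2

    def test_island_at_start_clips_left_shore(self):
        seq = "CG" * 200 + "AT" * 3000
        islands, shores = find_cpg_islands(seq)
        assert islands[0][0] == 0
        left = [sh for sh in shores if sh[1] <= islands[0][0] + 1]
        assert left == []  # no room for a left shore at the sequence start
        right = [sh for sh in shores if sh[0] >= islands[0][1]]
        assert right and right[0][1] - right[0][0] <= 2000

    def test_case_and_trailing_n_invariance(self, rng):
        seq = random_sequence(rng, 4000, cpg_patches=1)
        a, _ = find_cpg_islands(seq)
        b, _ = find_cpg_islands(seq.lower())
        c, _ = find_cpg_islands(seq + "N" * 500)
        assert a == b == c

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(95)
        for _ in range(5):
            seq = random_sequence(rng, 5000, cpg_patches=rng.integers(0, 3))
            fast, _ = find_cpg_islands(seq)
            assert fast == brute_force_islands(seq)

    def test_empty_sequence(self):
        islands, shores = find_cpg_islands("")
        assert islands == [] and shores == []


def _toy_annotation():
    genes = pd.DataFrame({
        "chrom": ["chr1"],
        "start": [50_000],
        "end": [80_000],
        "strand": ["+"],
        "gene_id": ["g1"],
    })
    exons = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [50_000, 70_000],
        "end": [52_000, 72_000],
    })
    enhancers = pd.DataFrame({"chrom": ["chr1"], "start": [90_000], "end": [91_000]})
    islands = pd.DataFrame({"chrom": ["chr1"], "start": [30_000], "end": [30_500]})
    shores = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [28_000, 30_500],
        "end": [30_000, 32_500],
    })
    return genes, exons, enhancers, islands, shores


class TestAssignContext:
    def test_promoter_exon_and_shore_flags(self):
        genes, exons, enhancers, islands, shores = _toy_annotation()
        cpgs = pd.DataFrame({
            "chrom": ["chr1"] * 5,
            # 5 kb upstream of TSS; inside exon 1; intron; enhancer; shore
            "pos": [45_001, 51_001, 60_001, 90_501, 31_001],
        })
        out = assign_context(cpgs, genes, exons, enhancers, islands, shores)
        assert out.loc[0, "promoter"] and not out.loc[0, "exon"]
        assert out.loc[1, "exon"] and not out.loc[1, "promoter"]
        assert out.loc[2, "intron_utr"]
        assert out.loc[3, "enhancer"]
        assert out.loc[4, "cpg_shore"] and not out.loc[4, "cpg_island"]

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        genes = pd.DataFrame({
            "chrom": ["chr1"], "start": [50_000], "end": [80_000],
            "strand": ["-"], "gene_id": ["g1"],
        })
        cpgs = pd.DataFrame({"chrom": ["chr1"], "pos": [85_001]})
        out = assign_context(cpgs, genes)
        assert out.loc[0, "promoter"].item()

    def test_chromosome_mismatch_raises(self):
        genes, *_ = _toy_annotation()
        cpgs = pd.DataFrame({"chrom": ["chrX"], "pos": [1000]})
        with pytest.raises(AlignmentError):
            assign_context(cpgs, genes)

    def test_gene_windows_widened_to_50kb(self):
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [100_000, 500_000],
            "end": [102_000, 600_000],  # short and long genes
            "strand": ["+", "+"],
            "gene_id": ["short", "long"],
        })
        gw = gene_windows(genes)
        assert gw.loc[0, "window_end"] - gw.loc[0, "window_start"] == 50_000
        assert gw.loc[1, "window_start"] == 490_000
        assert gw.loc[1, "window_end"] == 610_000


class TestContextEnrichment:
    def test_random_subsample_cis_cover_zero(self, rng):
        n = 2000
        contexts = pd.DataFrame({
            "promoter": rng.random(n) < 0.2,
            "exon": rng.random(n) < 0.3,
        })
        fg = rng.random(n) < 0.25
        res = context_enrichment(fg, contexts, context_cols=("promoter", "exon"))
        for _, row in res.iterrows():
            assert row.ci_lo <= 0.0 <= row.ci_hi

    def test_extreme_island_enrichment(self, rng):
        n = 1000
        island = np.zeros(n, dtype=bool)
        island[:200] = True
        fg = np.zeros(n, dtype=bool)
        fg[:100] = True  # foreground entirely inside islands
        contexts = pd.DataFrame({"cpg_island": island})
        res = context_enrichment(fg, contexts, context_cols=("cpg_island",))
        assert res.loc[0, "log2_or"] > 0
        assert res.loc[0, "p"] < 1e-10

    def test_fisher_matches_enumeration_on_reference_table(self):
        # foreground/background split giving the 2x2 table (10,90,50,850)
        fg = np.repeat([True, False], [100, 900])
        inc = np.zeros(1000, dtype=bool)
        inc[:10] = True
        inc[100:150] = True
        contexts = pd.DataFrame({"ctx": inc})
        res = context_enrichment(fg, contexts, context_cols=("ctx",))
        expected = _minlik_fisher_p([[10, 90], [50, 850]])
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-8)


class TestExpressionIntegration:
    @staticmethod
    def _tables(rng, couple):
        n_genes = 120
        genes = [f"g{i}" for i in range(n_genes)]
        expr = pd.DataFrame({
            "gene_id": genes,
            "expr_effect": rng.normal(0, 0.5, n_genes),
            "expr_significant": rng.random(n_genes) < 0.4,
        })
        rows = []
        for g in range(n_genes):
            for _ in range(5):
                if couple:
                    p_sig = 0.8 if abs(expr.loc[g, "expr_effect"]) > 0.5 else 0.1
                    sig = rng.random() < p_sig
                    eff = -np.sign(expr.loc[g, "expr_effect"]) * abs(rng.normal(0, 0.2))
                else:
                    sig = rng.random() < 0.3
                    eff = rng.normal(0, 0.2)
                rows.append((f"g{g}", sig, eff, True, False, False))
        cpgs = pd.DataFrame(
            rows, columns=["gene_id", "significant", "effect_allele",
                           "promoter", "exon", "intron_utr"])
        return cpgs, expr

    def test_coupled_simulation_detected(self):
        rng = np.random.default_rng(96)
        cpgs, expr = self._tables(rng, couple=True)
        res = expression_integration(cpgs, expr)
        prom = res[res["context"] == "promoter"].iloc[0]
        assert prom.logit_beta > 0 and prom.logit_p < 1e-4
        # methylation up -> expression down by construction
        assert prom.concordance_log2_or < 0

    def test_independent_simulation_null(self):
        rng = np.random.default_rng(97)
        cpgs, expr = self._tables(rng, couple=False)
        res = expression_integration(cpgs, expr)
        prom = res[res["context"] == "promoter"].iloc[0]
        assert prom.logit_p > 0.01

    def test_unassigned_cpgs_warn_and_return_empty(self, rng):
        cpgs, expr = self._tables(rng, couple=False)
        cpgs["gene_id"] = "nowhere"
        with pytest.warns(UserWarning):
            res = expression_integration(cpgs, expr)
        assert len(res) == 0

    def test_small_context_skipped_with_reason(self):
        rng = np.random.default_rng(98)
        cpgs, expr = self._tables(rng, couple=False)
        cpgs["exon"] = False
        cpgs.loc[:3, "exon"] = True
        res = expression_integration(cpgs, expr)
        exon = res[res["context"] == "exon"].iloc[0]
        assert exon.skip_reason == "too_few_cpgs"
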
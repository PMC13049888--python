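"""Tests for the synthetic-cohort generator against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import binomtest, chi2, chisquare

from admixmeth.exceptions import ParameterError
from admixmeth.simulate import (
    Genotypes,
    GroundTruth,
    ReporterConfig,
    SimConfig,
    simulate_ancestry,
    simulate_cohort,
    simulate_genotypes,
    simulate_methylation,
    simulate_parental_frequencies,
    simulate_reporter,
)


def hudson_fst(p1, p2):
    """Ratio-of-averages two-population F_ST estimator (the oracle)."""
    num = np.mean((p1 - p2) ** 2)
    den = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    return num / den


class TestParentalFrequencies:
    def test_no_drift_limit(self):
        f = simulate_parental_frequencies(10_000, 1e-6, seed=0)
        assert np.mean(np.abs(f.p_anubis - f.p_yellow)) < 0.01

    def test_fst_recovered_at_f_028(self):
        f = simulate_parental_frequencies(50_000, 0.28, seed=1)
        assert hudson_fst(f.p_yellow, f.p_anubis) == pytest.approx(0.28, abs=0.05)

    def test_aim_fraction_increases_with_divergence(self):
        fracs = [
            simulate_parental_frequencies(20_000, F, seed=3).is_aim.mean()
            for F in (0.05, 0.10, 0.20, 0.30)
        ]
        assert np.all(np.diff(fracs) > 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, np.nan, np.inf])
    def test_bad_divergence_rejected(self, bad):
        with pytest.raises(ParameterError):
            simulate_parental_frequencies(10, bad, seed=0)


class TestAncestry:
    def test_zero_alpha_all_yellow(self):
        cfg = SimConfig(n_individuals=20, n_snps=50, admix_alpha=0.0, seed=4)
        panel = simulate_ancestry(cfg)
        assert np.all(panel.dosage == 0)
        assert np.all(panel.global_ancestry == 0)

    def test_mean_global_ancestry_matches_alpha(self):
        cfg = SimConfig(n_individuals=200, n_snps=200, admix_alpha=0.37, seed=5)
        panel = simulate_ancestry(cfg)
        assert panel.global_ancestry.mean() == pytest.approx(0.37, abs=0.03)

    def test_mean_tract_length(self):
        cfg = SimConfig(
            n_individuals=40, n_snps=50, admix_alpha=0.3,
            chrom_length=50_000_000, mean_tract_bp=1_000_000.0, seed=6,
        )
        panel = simulate_ancestry(cfg)
        lengths = (panel.tracts["end"] - panel.tracts["start"]).to_numpy()
        assert len(lengths) >= 1000
        assert lengths.mean() == pytest.approx(1_000_000, rel=0.15)

    def test_global_ancestry_is_mean_dosage_over_two(self):
        cfg = SimConfig(n_individuals=30, n_snps=100, admix_alpha=0.5, seed=7)
        panel = simulate_ancestry(cfg)
        assert np.allclose(panel.global_ancestry, panel.dosage.mean(axis=1) / 2)


class TestGenotypes:
    @staticmethod
    def _panel(cfg):
        return simulate_ancestry(cfg)

    def test_monomorphic_frequencies_give_zero_genotypes(self):
        cfg = SimConfig(n_individuals=30, n_snps=20, admix_alpha=0.4, seed=8)
        panel = self._panel(cfg)
        freqs = simulate_parental_frequencies(20, 0.2, seed=8)
        freqs.p_yellow[:] = 0.0
        freqs.p_anubis[:] = 0.0
        geno = simulate_genotypes(panel, freqs, seed=8)
        assert np.all(geno.dosage == 0)

    def test_homozygous_yellow_subset_frequency_in_binomial_ci(self):
        cfg = SimConfig(n_individuals=500, n_snps=50, admix_alpha=0.3, seed=9)
        panel = self._panel(cfg)
        freqs = simulate_parental_frequencies(50, 0.25, seed=9)
        geno = simulate_genotypes(panel, freqs, seed=9)
        checked = 0
        for j in range(50):
            hom_y = panel.dosage[:, j] == 0
            n_hap = 2 * hom_y.sum()
            if n_hap < 100:
                continue
            alt = int(geno.dosage[hom_y, j].sum())
            ci = binomtest(alt, n_hap).proportion_ci(0.999)
            assert ci.low <= freqs.p_yellow[j] <= ci.high
            checked += 1
        assert checked > 20

    def test_hwe_within_ancestry_homozygous_subset(self):
        cfg = SimConfig(n_individuals=500, n_snps=30, admix_alpha=0.2, seed=10)
        panel = self._panel(cfg)
        freqs = simulate_parental_frequencies(30, 0.25, seed=10)
        freqs.p_yellow[:] = np.clip(freqs.p_yellow, 0.2, 0.8)
        geno = simulate_genotypes(panel, freqs, seed=10)
        for j in range(5):
            hom_y = panel.dosage[:, j] == 0
            g = geno.dosage[hom_y, j]
            if g.size < 400:
                continue
            p = g.mean() / 2
            expected = g.size * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            observed = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
            stat = np.sum((observed - expected) ** 2 / expected)
            # 1 df: frequency estimated from the data
            assert chi2.sf(stat, 1) > 0.001


def _two_allele_setup(n_ind, p_alt, m_ref, m_alt, coverage, phi, seed):
    """One CpG with a linked SNP in an unadmixed (all-yellow) cohort."""
    rng = np.random.default_rng(seed)
    hap = (rng.random((n_ind, 2, 1)) < p_alt).astype(np.int8)
    geno = Genotypes(
        chrom=np.array(["chr1"]), pos=np.array([1000]),
        individuals=[f"i{k}" for k in range(n_ind)], hap_alleles=hap,
    )
    base = 0.5 if m_ref in (0.0, 1.0) else m_ref
    truth = GroundTruth(
        baseline_logit=np.array([logit(base)]),
        m_ref=np.array([m_ref]),
        m_alt=np.array([m_alt]),
        is_disrupted=np.array([False]),
        linked_snp=np.array([0]),
        true_ancestry_effect=np.array([0.0]),
    )
    cfg = SimConfig(
        n_individuals=n_ind, n_snps=1, n_cpgs=1,
        mean_coverage=coverage, bb_dispersion=phi, seed=seed,
    )
    return simulate_methylation(
        geno, truth, cfg, np.array(["chr1"]), np.array([990]),
        np.array([10]), seed=seed,
    )


class TestMethylation:
    def test_all_unmethylated_alleles_give_zero_counts(self):
        counts, _ = _two_allele_setup(50, 0.5, 0.0, 0.0, 20, 0.05, seed=11)
        assert counts.meth.sum() == 0

    def test_worked_example_yellow_pool_mean(self):
        # one allele never methylated, the other at 0.5, frequency 0.25:
        # population mean methylation 12.5%
        counts, _ = _two_allele_setup(500, 0.25, 0.0, 0.5, 30, 0.0, seed=12)
        ratio = counts.meth.sum() / counts.total.sum()
        assert ratio == pytest.approx(0.125, abs=0.02)

    def test_zero_dispersion_counts_are_binomial(self):
        cfg = SimConfig(
            n_individuals=400, n_snps=20, n_cpgs=20,
            bb_dispersion=0.0, frac_meqtl=0.0, mean_coverage=25, seed=13,
        )
        cohort = simulate_cohort(cfg)
        pvals = []
        for j in range(cohort.counts.n_sites):
            k = cohort.counts.meth[j]
            n = cohort.counts.total[j]
            ok = n > 0
            k, n = k[ok], n[ok]
            p = k.sum() / n.sum()
            stat = np.sum((k - n * p) ** 2 / (n * p * (1 - p)))
            pvals.append(chi2.sf(stat, k.size - 1))
        assert np.min(pvals) > 0.001

    def test_positive_dispersion_inflates_variance(self):
        cfg = SimConfig(
            n_individuals=400, n_snps=20, n_cpgs=20,
            bb_dispersion=0.2, frac_meqtl=0.0, mean_coverage=25, seed=13,
        )
        cohort = simulate_cohort(cfg)
        j = 0
        k, n = cohort.counts.meth[j], cohort.counts.total[j]
        ok = n > 0
        k, n = k[ok], n[ok]
        p = k.sum() / n.sum()
        stat = np.sum((k - n * p) ** 2 / (n * p * (1 - p)))
        assert chi2.sf(stat, k.size - 1) < 1e-6

    def test_allele_specific_counts_partition_totals(self):
        cfg = SimConfig(n_individuals=60, n_snps=100, n_cpgs=100, seed=14)
        cohort = simulate_cohort(cfg)
        pc = cohort.pair_counts
        assert ((pc.meth_excl + pc.meth_ref + pc.meth_alt) == pc.meth).all()
        assert ((pc.total_excl + pc.total_ref + pc.total_alt) == pc.total).all()
        hets = pc[pc.genotype == 1]
        assert (hets.total_ref + hets.total_alt).sum() > 0
        homs = pc[pc.genotype != 1]
        assert (homs.total_ref + homs.total_alt).sum() == 0

    def test_meqtl_variance_closed_form(self):
        # cross-individual variance of expected methylation under HWE:
        # 2 p (1-p) ((m1 - m0)/2)^2
        n, p_alt, m0, m1 = 2000, 0.4, 0.2, 0.8
        counts, _ = _two_allele_setup(n, p_alt, m0, m1, 400, 0.0, seed=15)
        ratios = counts.meth[0] / np.maximum(counts.total[0], 1)
        expected = 2 * p_alt * (1 - p_alt) * ((m1 - m0) / 2) ** 2
        assert np.var(ratios) == pytest.approx(expected, rel=0.10)


class TestCohortDeterminism:
    def test_same_seed_is_bitwise_identical(self):
        cfg = SimConfig(n_individuals=40, n_snps=80, n_cpgs=80, seed=21)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.counts.meth, b.counts.meth)
        assert np.array_equal(a.counts.total, b.counts.total)
        assert np.array_equal(a.genotypes.hap_alleles, b.genotypes.hap_alleles)
        assert np.array_equal(a.panel.dosage, b.panel.dosage)
        pd.testing.assert_frame_equal(a.pair_counts, b.pair_counts)

    def test_different_seed_differs(self):
        a = simulate_cohort(SimConfig(n_individuals=40, n_snps=80, n_cpgs=80, seed=21))
        b = simulate_cohort(SimConfig(n_individuals=40, n_snps=80, n_cpgs=80, seed=22))
        assert not np.array_equal(a.counts.meth, b.counts.meth)

    def test_pair_distances_within_read_length(self):
        cohort = simulate_cohort(SimConfig(n_individuals=20, n_snps=200, n_cpgs=200, seed=23))
        assert cohort.pairs.distance.max() <= 100
        assert (cohort.pairs.distance[cohort.pairs.disrupted] <= 1).all()


class TestReporter:
    def test_no_active_windows_means_unit_multipliers(self):
        r = simulate_reporter(ReporterConfig(n_windows=300, frac_active=0.0,
                                             frac_meth_dependent=0.0, seed=31))
        assert not r.truth.is_active.any()
        assert np.all(r.truth.multiplier_methylated == 1.0)
        assert np.all(r.truth.multiplier_unmethylated == 1.0)

    def test_truth_label_counts(self):
        cfg = ReporterConfig(n_windows=1000, frac_active=0.08, frac_meth_dependent=0.05, seed=32)
        r = simulate_reporter(cfg)
        assert abs(int(r.truth.is_active.sum()) - 80) <= 1
        assert abs(int(r.truth.is_meth_dependent.sum()) - 50) <= 1
        assert r.truth.more_active_unmeth.sum() == round(0.87 * 50)

    def test_meth_dependent_rejects_exceeding_active(self):
        with pytest.raises(ParameterError):
            ReporterConfig(frac_active=0.01, frac_meth_dependent=0.02)

    def test_reporter_determinism(self):
        a = simulate_reporter(ReporterConfig(n_windows=200, seed=33))
        b = simulate_reporter(ReporterConfig(n_windows=200, seed=33))
        assert np.array_equal(a.counts, b.counts)
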
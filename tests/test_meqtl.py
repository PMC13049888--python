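"""Tests for allele-specific meQTL mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import kstest

from admixmeth.exceptions import ParameterError
from admixmeth.meqtl import (
    SnpCpgPair,
    build_pairs,
    disruption_regression,
    distance_effect,
    fit_meqtl,
    fit_pairs,
    map_meqtl,
    permutation_null,
)
from admixmeth.simulate import Genotypes, GroundTruth, SimConfig, simulate_methylation


def make_pair(seed, n=300, p_alt=0.4, m_ref=0.3, m_alt=0.3, coverage=20,
              phi=0.02, distance=10, pair_id="p0"):
    """One SNP-CpG pair generated by the read-level simulator."""
    rng = np.random.default_rng(seed)
    hap = (rng.random((n, 2, 1)) < p_alt).astype(np.int8)
    geno = Genotypes(
        chrom=np.array(["chr1"]), pos=np.array([1000]),
        individuals=[f"i{k}" for k in range(n)], hap_alleles=hap,
    )
    base = 0.5 if m_ref in (0.0, 1.0) else m_ref
    truth = GroundTruth(
        baseline_logit=np.array([logit(base)]),
        m_ref=np.array([m_ref]), m_alt=np.array([m_alt]),
        is_disrupted=np.array([False]), linked_snp=np.array([0]),
        true_ancestry_effect=np.array([0.0]),
    )
    cfg = SimConfig(n_individuals=n, n_snps=1, n_cpgs=1,
                    mean_coverage=coverage, bb_dispersion=phi, seed=seed)
    _, pc = simulate_methylation(
        geno, truth, cfg, np.array(["chr1"]), np.array([1000 - distance]),
        np.array([distance]), seed=seed + 1,
    )
    pc = pc.set_index("individual").reindex(geno.individuals)
    arr = lambda c: pc[c].to_numpy(dtype=np.int64)
    return SnpCpgPair(
        pair_id=pair_id, snp_chrom="chr1", snp_pos=1000, cpg_chrom="chr1",
        cpg_pos=1000 - distance, distance=distance, disrupted=distance <= 1,
        individuals=geno.individuals, genotype=arr("genotype"),
        meth=arr("meth"), total=arr("total"),
        meth_excl=arr("meth_excl"), total_excl=arr("total_excl"),
        meth_ref=arr("meth_ref"), total_ref=arr("total_ref"),
        meth_alt=arr("meth_alt"), total_alt=arr("total_alt"),
    )


class TestFitMeqtl:
    def test_worked_example_delta_recovered(self):
        # unmethylated reference allele vs 50%-methylated alternate:
        # per-allele proportion effect 0.5
        pair = make_pair(1, n=300, p_alt=0.4, m_ref=0.0, m_alt=0.5, coverage=20)
        entry = fit_meqtl(pair)
        assert entry["converged"]
        assert entry["delta"] == pytest.approx(0.5, abs=0.05)
        assert entry["p"] < 1e-10

    def test_null_betas_near_zero_p_uniformish(self):
        entries = [fit_meqtl(make_pair(100 + i, m_ref=0.3, m_alt=0.3, n=150))
                   for i in range(80)]
        betas = np.array([e["delta"] for e in entries])
        pvals = np.array([e["p"] for e in entries])
        assert abs(np.mean(betas)) < 0.02
        # conservative-to-uniform is acceptable; no excess of small p
        assert (pvals < 0.05).mean() <= 0.125

    def test_allele_specific_signal_alone_suffices(self):
        # destroy the individual-level signal by shuffling genotypes while
        # keeping heterozygotes' allele-specific counts intact
        rng = np.random.default_rng(7)
        pair = make_pair(2, n=200, p_alt=0.5, m_ref=0.2, m_alt=0.8,
                         coverage=40, distance=5)
        # relabel all non-assignable counts as if there were no genotype
        # effect: replace individual-level counts by constant-mean draws
        base = 0.5
        pair.meth_excl = rng.binomial(pair.total_excl, base)
        pair.meth = pair.meth_excl + pair.meth_ref + pair.meth_alt
        entry = fit_meqtl(pair)
        assert entry["p"] < 1e-6

    def test_individual_level_signal_alone_suffices(self):
        # a distant pair has no allele-assignable reads at all
        pair = make_pair(3, n=300, p_alt=0.4, m_ref=0.2, m_alt=0.6,
                         coverage=20, distance=100)
        assert pair.total_ref.sum() + pair.total_alt.sum() == 0
        entry = fit_meqtl(pair)
        assert not entry["has_allele_specific"]
        assert entry["p"] < 1e-6

    def test_no_heterozygotes_degrades_gracefully(self):
        pair = make_pair(4, n=120, p_alt=0.5, m_ref=0.2, m_alt=0.7)
        hom = pair.genotype != 1
        for attr in ("genotype", "meth", "total", "meth_excl", "total_excl",
                     "meth_ref", "total_ref", "meth_alt", "total_alt"):
            setattr(pair, attr, getattr(pair, attr)[hom])
        pair.individuals = [pair.individuals[i] for i in np.where(hom)[0]]
        entry = fit_meqtl(pair)
        assert not entry["has_allele_specific"]
        assert np.isfinite(entry["p"])


class TestPermutationNull:
    def test_marginals_preserved(self):
        pair = make_pair(5, n=80, m_ref=0.2, m_alt=0.7)
        before = (pair.meth.copy(), pair.total.copy(), pair.genotype.copy())
        permutation_null([pair], n_perm=3, seed=0)
        assert np.array_equal(pair.meth, before[0])
        assert np.array_equal(pair.total, before[1])
        assert np.array_equal(pair.genotype, before[2])

    def test_zero_permutations_rejected(self):
        pair = make_pair(6, n=40)
        with pytest.raises(ParameterError):
            permutation_null([pair], n_perm=0, seed=0)

    def test_null_pairs_rarely_discovered(self):
        pairs = [make_pair(200 + i, n=100, m_ref=0.4, m_alt=0.4)
                 for i in range(30)]
        res = map_meqtl(pairs, n_perm=10, seed=1)
        q = res.table["q"].dropna()
        assert (q < 0.1).mean() <= 0.02 + 1e-9

    def test_strong_pairs_survive_fdr(self):
        pairs = [make_pair(300 + i, n=150, m_ref=0.2, m_alt=0.7)
                 for i in range(10)]
        res = map_meqtl(pairs, n_perm=10, seed=2)
        assert (res.table["q"] < 0.1).all()


class TestDisruptedPairs:
    def test_disrupted_pairs_detected_with_negative_effect(self):
        # CpG-disrupting alleles force methylation toward zero: nearly all
        # such pairs with an intact-allele baseline >= 0.1 should map as
        # meQTL with delta < 0
        entries = []
        for i in range(20):
            rng = np.random.default_rng(400 + i)
            base = rng.uniform(0.15, 0.8)
            pair = make_pair(500 + i, n=300, p_alt=0.3, m_ref=base,
                             m_alt=0.01, distance=1)
            entries.append(fit_meqtl(pair))
        detected = [e for e in entries if e["p"] < 1e-4 and e["delta"] < 0]
        assert len(detected) >= 0.9 * len(entries)


class TestBuildPairs:
    @staticmethod
    def _inputs(p_alt=0.4, distance=10, n=60, seed=11):
        pair = make_pair(seed, n=n, p_alt=p_alt, m_ref=0.3, m_alt=0.6,
                         distance=distance)
        from conftest import make_counts

        counts = make_counts(pair.meth[None, :], pair.total[None, :],
                             individuals=pair.individuals)
        counts.pos = np.array([pair.cpg_pos])
        variants = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [pair.snp_pos], "ref": ["A"], "alt": ["T"],
             **{ind: [pair.genotype[i]] for i, ind in enumerate(pair.individuals)}}
        )
        read_pairs = pd.DataFrame({
            "snp_chrom": "chr1", "snp_pos": pair.snp_pos,
            "cpg_chrom": "chr1", "cpg_pos": pair.cpg_pos,
            "individual": pair.individuals,
            "meth": pair.meth, "total": pair.total,
            "meth_excl": pair.meth_excl, "total_excl": pair.total_excl,
            "meth_ref": pair.meth_ref, "total_ref": pair.total_ref,
            "meth_alt": pair.meth_alt, "total_alt": pair.total_alt,
        })
        return variants, counts, read_pairs

    def test_low_maf_excluded(self):
        variants, counts, rp = self._inputs(p_alt=0.01, n=200)
        pairs, log = build_pairs(variants, counts, rp)
        assert len(pairs) == 0 and log["maf"] == 1

    def test_distance_over_100_excluded(self):
        variants, counts, rp = self._inputs()
        rp["snp_pos"] += 101
        variants["pos"] += 101
        pairs, log = build_pairs(variants, counts, rp)
        assert len(pairs) == 0 and log["distance"] == 1

    def test_snp_at_cpg_plus_one_is_disrupted(self):
        variants, counts, rp = self._inputs(distance=1)
        pairs, _ = build_pairs(variants, counts, rp)
        assert len(pairs) == 1 and pairs[0].disrupted

    def test_good_pair_retained(self):
        variants, counts, rp = self._inputs()
        pairs, log = build_pairs(variants, counts, rp)
        assert log["retained"] == 1
        assert not pairs[0].disrupted


class TestDisruptionRegression:
    def test_perfect_composition(self, rng):
        deltas = rng.uniform(-0.8, -0.2, 50)
        dp = rng.uniform(-0.8, 0.8, 50)
        obs = deltas * dp
        res = disruption_regression(deltas, dp, obs)
        assert res["slope"] == pytest.approx(1.0, abs=1e-9)
        assert res["r"] == pytest.approx(1.0, abs=1e-9)

    def test_noisy_effects_keep_high_r(self, rng):
        deltas = rng.uniform(-0.9, -0.3, 200)
        dp = rng.uniform(-0.9, 0.9, 200)
        obs = deltas * dp + rng.normal(0, 0.05, 200)
        res = disruption_regression(deltas, dp, obs)
        assert 0.7 <= res["r"] <= 1.0

    def test_zero_divergence_degenerate(self):
        res = disruption_regression([-0.5, -0.4, -0.3], [0.0, 0.0, 0.0],
                                    [0.0, 0.01, -0.01])
        assert res["degenerate"]

    def test_too_few_points_flagged(self):
        res = disruption_regression([-0.5], [0.3], [-0.15])
        assert res["degenerate"]


class TestDistanceEffect:
    @staticmethod
    def _table(rng, n, decay):
        distance = rng.integers(2, 101, n)
        if decay:
            prob = np.clip(1.0 - distance / 120.0, 0.05, 0.95)
        else:
            prob = np.full(n, 0.5)
        detected = rng.random(n) < prob
        return pd.DataFrame({
            "distance": distance,
            "disrupted": False,
            "q": np.where(detected, 0.01, 0.5),
        })

    def test_no_decay_slope_not_significant(self, rng):
        res = distance_effect(self._table(rng, 400, decay=False))
        assert res["p"] > 0.01

    def test_decay_gives_negative_slope(self, rng):
        res = distance_effect(self._table(rng, 400, decay=True))
        assert res["slope"] < 0 and res["p"] < 0.01

    def test_empty_input_rejected(self):
        empty = pd.DataFrame({"distance": [], "disrupted": [], "q": []})
        with pytest.raises(ParameterError):
            distance_effect(empty)
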
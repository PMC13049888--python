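"""Tests for the local-ancestry methylation scan."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import kstest

from admixmeth.ancestry import effect_to_proportion_scale, filter_sites, scan
from admixmeth.ancestry import test_additivity as additivity_pvalues
from admixmeth.bbcore import BetaBinomFit
from admixmeth.containers import AncestryPanel, MethCountMatrix
from admixmeth.exceptions import AlignmentError, FitError, StateError
from conftest import make_counts, make_panel


def _balanced_panel(rng, n_ind, n_sites, p=0.5):
    dosage = rng.binomial(2, p, size=(n_ind, n_sites)).astype(np.int8)
    return make_panel(dosage)


class TestFilterSites:
    def test_hypermethylated_site_dropped(self, rng):
        n = 60
        total = np.full((1, n), 20)
        meth = (total * 0.95).astype(int)
        panel = _balanced_panel(rng, n, 1)
        assert filter_sites(make_counts(meth, total), panel).size == 0

    def test_sparse_ancestry_state_dropped(self):
        # 50 / 9 / 41 individuals per state: heterozygote count below 10
        dosage = np.array([0] * 50 + [1] * 9 + [2] * 41)[:, None]
        panel = make_panel(dosage)
        total = np.full((1, 100), 20)
        meth = (total * 0.5).astype(int)
        assert filter_sites(make_counts(meth, total), panel).size == 0

    def test_good_site_retained(self):
        dosage = np.array([0] * 20 + [1] * 20 + [2] * 20)[:, None]
        panel = make_panel(dosage)
        total = np.full((1, 60), 20)
        meth = (total * 0.5).astype(int)
        assert filter_sites(make_counts(meth, total), panel).tolist() == [0]

    def test_disjoint_individuals_raise(self, rng):
        panel = _balanced_panel(rng, 10, 1)
        counts = make_counts(
            np.full((1, 10), 5), np.full((1, 10), 10),
            individuals=[f"other{k}" for k in range(10)],
        )
        with pytest.raises(AlignmentError):
            filter_sites(counts, panel)


def _simulate_scan_data(rng, n_ind, n_sites, effect_state, base=0.35, phi=0.03,
                        coverage=20):
    """Counts with an additive per-dosage effect on the proportion scale."""
    dosage = rng.binomial(2, 0.5, size=(n_ind, n_sites)).astype(np.int8)
    total = rng.poisson(coverage, size=(n_sites, n_ind)) + 1
    eff = np.asarray(effect_state, float)
    if eff.ndim == 1:
        eff = eff[:, None]
    mean = base + (eff / 2.0) * dosage.T
    if phi > 0:
        s = (1 - phi) / phi
        mean = rng.beta(mean * s, (1 - mean) * s)
    meth = rng.binomial(total, mean)
    panel = make_panel(dosage, global_ancestry=rng.uniform(0.2, 0.6, n_ind))
    return make_counts(meth, total), panel


class TestScan:
    def test_worked_composition_scenario_detected(self):
        # per-allele meQTL effect 0.5 at parental frequencies 0.25 vs 1.0:
        # homozygous-state means 12.5% and 50%, ancestry effect 37.5%
        rng = np.random.default_rng(55)
        n = 300
        dosage = rng.binomial(2, 0.5, size=(n, 1)).astype(np.int8)
        p_T = np.where(dosage[:, 0] == 2, 1.0,
                       np.where(dosage[:, 0] == 1, 0.625, 0.25))
        # each of the individual's alleles is methylated at 0.5 if T, 0 if A;
        # read-level mean is p_T * 0.5
        total = rng.poisson(20, size=(1, n)) + 1
        meth = rng.binomial(total, (p_T * 0.5)[None, :])
        panel = make_panel(dosage, global_ancestry=rng.uniform(0.2, 0.6, n))
        counts = make_counts(meth, total)
        res = scan(counts, panel, n_perm=10, seed=0, test_global=False)
        row = res.table.iloc[0]
        assert row.q_local < 0.1
        assert row.effect_state == pytest.approx(0.375, abs=0.07)

    def test_null_scan_rarely_significant(self):
        rng = np.random.default_rng(56)
        counts, panel = _simulate_scan_data(rng, 120, 60, effect_state=0.0)
        res = scan(counts, panel, n_perm=10, seed=1, test_global=False)
        q = res.table["q_local"].dropna()
        assert (q < 0.1).mean() <= 0.02 + 1e-9

    def test_effect_recovery_correlates_with_truth(self):
        rng = np.random.default_rng(57)
        effects = rng.uniform(-0.3, 0.3, size=40)
        counts, panel = _simulate_scan_data(rng, 200, 40, effect_state=effects)
        res = scan(counts, panel, n_perm=2, seed=2, test_global=False)
        est = res.table["effect_state"].to_numpy()
        from scipy.stats import spearmanr

        assert spearmanr(est, effects).statistic > 0.9

    def test_constant_dosage_raises_rank_deficiency(self):
        counts = make_counts(np.full((1, 40), 8), np.full((1, 40), 20))
        panel = make_panel(np.full((40, 1), 1, dtype=np.int8))
        with pytest.raises(FitError):
            scan(counts, panel, n_perm=1, seed=0)

    def test_covariates_accepted(self, rng):
        counts, panel = _simulate_scan_data(rng, 80, 5, effect_state=0.0)
        cov = rng.normal(size=(80, 2))
        res = scan(counts, panel, covariates=cov, n_perm=2, seed=3,
                   test_global=False)
        assert len(res.table) == 5


class TestAdditivity:
    def test_additive_data_gives_uniform_p(self):
        rng = np.random.default_rng(58)
        counts, panel = _simulate_scan_data(rng, 150, 150, effect_state=0.2)
        p = additivity_pvalues(counts, panel)
        p = p[np.isfinite(p)]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_heterozygote_advantage_detected(self):
        rng = np.random.default_rng(59)
        n, n_sites = 300, 30
        dosage = rng.binomial(2, 0.5, size=(n, n_sites)).astype(np.int8)
        total = rng.poisson(25, size=(n_sites, n)) + 1
        # het mean displaced 0.2 above the homozygote midpoint
        mean = np.where(dosage.T == 1, 0.6, np.where(dosage.T == 2, 0.5, 0.3))
        meth = rng.binomial(total, mean)
        p = additivity_pvalues(make_counts(meth, total), make_panel(dosage))
        assert np.nanmedian(p) < 0.01

    def test_noiseless_additive_means_give_p_one(self):
        n = 90
        rng = np.random.default_rng(60)
        dosage = np.repeat([0, 1, 2], n // 3)[:, None].astype(np.int8)
        # deep coverage so count rounding is negligible
        total = np.full((1, n), 20_000)
        # additive on the model's logit scale so the 3-level fit adds nothing
        mean = expit(-0.5 + 0.3 * dosage[:, 0])
        meth = np.round(total[0] * mean).astype(int)[None, :]
        ga = rng.uniform(0.2, 0.6, n)
        p = additivity_pvalues(make_counts(meth, total),
                               make_panel(dosage, global_ancestry=ga))
        assert p[0] > 0.9


class TestEffectToProportionScale:
    @staticmethod
    def _fit(coefs):
        k = len(coefs)
        return BetaBinomFit(
            coefficients=np.asarray(coefs, float),
            standard_errors=np.ones(k),
            pvalues=np.ones(k),
            phi=0.0,
            log_likelihood=0.0,
            converged=True,
            n_used=100,
        )

    def test_zero_effect_gives_zero(self):
        fit = self._fit([0.3, 0.0, 0.1])
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5), np.zeros(10)])
        assert effect_to_proportion_scale(fit, X) == 0.0

    def test_worked_example_12p5_to_50(self):
        # intercept at logit(0.125); dosage effect chosen so the
        # homozygous-anubis mean is 0.5 -> state effect 0.375
        beta = (logit(0.5) - logit(0.125)) / 2.0
        fit = self._fit([logit(0.125), beta, 0.0])
        X = np.column_stack([np.ones(4), np.array([0, 1, 1, 2]), np.zeros(4)])
        assert effect_to_proportion_scale(fit, X) == pytest.approx(0.375, abs=1e-12)

    def test_matches_direct_prediction_oracle(self, rng):
        # brute-force check against explicit inverse-logit prediction
        for _ in range(20):
            coefs = rng.normal(size=3)
            fit = self._fit(coefs)
            gbar = rng.uniform(0, 1)
            X = np.column_stack(
                [np.ones(7), rng.integers(0, 3, 7), np.full(7, gbar)]
            )
            expected = expit(coefs[0] + 2 * coefs[1] + coefs[2] * X[:, 2].mean()) - expit(
                coefs[0] + coefs[2] * X[:, 2].mean()
            )
            assert effect_to_proportion_scale(fit, X) == pytest.approx(expected, abs=1e-10)

    def test_non_converged_fit_rejected(self):
        fit = self._fit([0.0, 1.0, 0.0])
        fit.converged = False
        with pytest.raises(StateError):
            effect_to_proportion_scale(fit, np.ones((5, 3)))
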
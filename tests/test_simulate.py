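"""Synthetic cohort generator: HWE/LD structure, stress item targets,
mediator paths, planted-effect wiring and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxewas import genoqc
from gxewas.simulate import (SimulationConfig, item_domain_mapping, plan_effects,
                             simulate_genotypes, simulate_mediators,
                             simulate_stress_items, simulate_study,
                             simulate_covariates)
from gxewas.stress import DOMAINS


def _cfg(**kw):
    base = dict(n_cohorts=1, n_subjects=(400,), stress_means=(0.4,),
                n_batches=(4,), n_snps=20, n_cpgs=15, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_snps=0)

    def test_domain_sizes_must_sum_to_items(self):
        with pytest.raises(ValueError):
            _cfg(domain_sizes=(10, 10, 10, 10))

    def test_unreachable_stress_mean_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            _cfg(stress_means=(5.0,))

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            _cfg(ld_copy_prob=1.5)


class TestGenotypes:
    def test_perfect_copying_makes_identical_block_columns(self):
        cfg = _cfg(ld_copy_prob=1.0, ld_block_size=5, n_snps=5)
        g = simulate_genotypes(cfg, 0)
        assert all(np.array_equal(g.calls[:, 0], g.calls[:, j]) for j in range(5))

    def test_no_copying_gives_independent_snps(self):
        cfg = _cfg(n_subjects=(2000,), ld_copy_prob=0.0, ld_block_size=5, n_snps=10)
        g = simulate_genotypes(cfg, 0)
        corr = np.corrcoef(g.calls, rowvar=False)
        off = np.abs(corr[~np.eye(10, dtype=bool)])
        assert off.max() < 0.1

    def test_symmetric_maf_recovered(self):
        cfg = _cfg(n_subjects=(2000,), maf_range=(0.5, 0.5), ld_block_size=1)
        g = simulate_genotypes(cfg, 0)
        assert np.all(np.abs(g.maf() - 0.5) < 0.05)

    def test_calls_in_hwe(self):
        cfg = _cfg(n_subjects=(3000,), ld_block_size=1, n_snps=30)
        g = simulate_genotypes(cfg, 0)
        pvals = []
        for j in range(g.n_snps):
            c = g.calls[:, j]
            pvals.append(genoqc.hwe_exact_test(int((c == 2).sum()), int((c == 1).sum()),
                                               int((c == 0).sum())))
        assert min(pvals) > 1e-5  # no gross HWE violation across 30 SNPs

    def test_shared_snp_metadata_across_cohorts(self):
        cfg = SimulationConfig(n_cohorts=2, n_subjects=(50, 60), stress_means=(0.4, 0.5),
                               n_batches=(3, 3), n_snps=12, n_cpgs=10, seed=2,
                               effect_registry_sizes={"g": 1, "e": 1, "gxe": 1, "mediated": 1})
        g0 = simulate_genotypes(cfg, 0)
        g1 = simulate_genotypes(cfg, 1)
        pd.testing.assert_frame_equal(g0.snps, g1.snps)
        assert not np.array_equal(g0.calls[:50], g1.calls[:50])


class TestStressItems:
    def test_no_missingness_when_rate_zero(self):
        items = simulate_stress_items(_cfg(missing_rate_items=0.0), 0)
        assert not items.isna().any().any()

    def test_missingness_rate_approximate(self):
        items = simulate_stress_items(_cfg(missing_rate_items=0.1), 0)
        assert items.isna().to_numpy().mean() == pytest.approx(0.1, abs=0.02)

    def test_cohort_means_hit_targets(self):
        cfg = SimulationConfig(n_cohorts=3, n_subjects=(1000, 1000, 1000),
                               stress_means=(0.36, 0.44, 0.51), n_batches=(3, 3, 3),
                               n_snps=5, n_cpgs=5, missing_rate_items=0.0, seed=7,
                               effect_registry_sizes={"g": 1, "e": 1, "gxe": 1, "mediated": 1})
        mapping = item_domain_mapping(cfg)
        for c, target in enumerate(cfg.stress_means):
            items = simulate_stress_items(cfg, c)
            total = sum(items[[i for i, d in mapping.items() if d == dom]].mean(axis=1)
                        for dom in DOMAINS)
            assert total.mean() == pytest.approx(target, abs=0.05)


class TestMediators:
    def test_smoking_correlates_with_stress_by_a_path(self):
        cfg = _cfg(n_subjects=(5000,), smoking_a_path=0.5)
        z = pd.Series(np.random.default_rng(1).standard_normal(5000),
                      index=[f"s{i}" for i in range(5000)])
        med = simulate_mediators(cfg, 0, z)
        r = np.corrcoef(z, med["smoking"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_null_a_path_gives_independence(self):
        cfg = _cfg(n_subjects=(5000,), smoking_a_path=0.0)
        z = pd.Series(np.random.default_rng(2).standard_normal(5000))
        med = simulate_mediators(cfg, 0, z)
        assert abs(np.corrcoef(z, med["smoking"])[0, 1]) < 0.05

    def test_constant_stress_gives_independent_smoking(self):
        cfg = _cfg(n_subjects=(500,))
        med = simulate_mediators(cfg, 0, pd.Series(np.zeros(500)))
        assert med["smoking"].std() > 0


class TestMethylation:
    def test_betas_bounded_and_registry_disjoint(self, small_study):
        _, cohorts, registry = small_study
        for c in cohorts:
            assert c.methylation.betas.min() >= 0 and c.methylation.betas.max() <= 1
        registry.validate_disjoint()
        cpgs = set()
        for c in cohorts:
            cpgs.update(c.methylation.probes["cpg"])
        assert set(registry.cpgs()) <= cpgs

    def test_effect_budget_guard(self):
        with pytest.raises(ValueError):
            _cfg(effect_r2=0.9)

    def test_too_many_planted_effects_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            _cfg(n_cpgs=5, effect_registry_sizes={"g": 3, "e": 3, "gxe": 3, "mediated": 3})

    def test_null_registry_yields_uniform_scan_p(self):
        # no planted effects -> Emodel p-values uniform over CpGs
        from gxewas.scan import ScanDesign, emodel_scan
        cfg = _cfg(n_subjects=(500,), n_cpgs=200, n_snps=5,
                   effect_registry_sizes={"g": 0, "e": 0, "gxe": 0, "mediated": 0},
                   missing_rate_items=0.0, seed=21)
        cohorts, _ = simulate_study(cfg)
        c = cohorts[0]
        d = ScanDesign(M=c.methylation.betas, cpg_ids=list(c.methylation.probes["cpg"]),
                       C=c.covariates.to_numpy(), E=c.stress_z.to_numpy())
        p = emodel_scan(d)["p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestReproducibility:
    def test_same_seed_identical_different_seed_different(self):
        cfg_a = _cfg(seed=13)
        cfg_b = _cfg(seed=13)
        cfg_c = _cfg(seed=14)
        ga, gb, gc = (simulate_genotypes(c, 0) for c in (cfg_a, cfg_b, cfg_c))
        assert np.array_equal(ga.calls, gb.calls)
        assert not np.array_equal(ga.calls, gc.calls)
        ia = simulate_stress_items(cfg_a, 0)
        ib = simulate_stress_items(cfg_b, 0)
        pd.testing.assert_frame_equal(ia, ib)

    def test_planted_effect_plan_deterministic(self):
        r1 = plan_effects(_cfg(seed=3))
        r2 = plan_effects(_cfg(seed=3))
        assert r1.planted_gxe == r2.planted_gxe

    def test_covariates_have_expected_columns(self):
        cov = simulate_covariates(_cfg(), 0)
        assert "sex" in cov and "pc5" in cov and "cell7" in cov
        cells = cov[[f"cell{k}" for k in range(1, 8)]].sum(axis=1)
        assert np.allclose(cells, 1.0)


class TestPlantedRecovery:
    def test_interaction_coefficients_rank_match_planted_magnitudes(self):
        # >=20 planted interactions at n=3000: logit-scale estimates must
        # rank-order like the planted magnitudes
        from gxewas.scan import ScanDesign, gxe_scan
        from scipy.special import logit
        cfg = SimulationConfig(
            n_cohorts=1, n_subjects=(3000,), stress_means=(0.4,), n_batches=(3,),
            n_snps=30, n_cpgs=40, ld_block_size=1, missing_rate_items=0.0,
            effect_registry_sizes={"g": 0, "e": 0, "gxe": 20, "mediated": 0}, seed=17)
        cohorts, registry = simulate_study(cfg)
        c = cohorts[0]
        dom = (c.genotypes.calls >= 1).astype(float)
        d = ScanDesign(M=logit(np.clip(c.methylation.betas, 1e-6, 1 - 1e-6)),
                       cpg_ids=list(c.methylation.probes["cpg"]),
                       C=c.covariates.to_numpy(), E=c.stress_z.to_numpy(),
                       G=dom, snp_ids=list(c.genotypes.snps["snp"]))
        table = gxe_scan(d).set_index(["snp", "cpg"])
        est, truth = [], []
        for snp, cpg, beta in registry.planted_gxe:
            est.append(abs(table.loc[(snp, cpg), "beta"]))
            truth.append(abs(beta))
        rho = stats.spearmanr(est, truth).statistic
        assert rho > 0.8
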
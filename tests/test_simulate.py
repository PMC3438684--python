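import numpy as np
import pytest

from pleiobayes.simulate import (
    SCENARIO_NAMES,
    CausalSpec,
    ScenarioConfig,
    class_genotype_freqs,
    draw_causal_specs,
    hwe_frequencies,
    scenario_presets,
    simulate_study,
)

from conftest import tiny_scenario


def _empirical_or(freq_affected, freq_ref, g_risk, g_ref):
    """Odds ratio between two genotype categories across two classes."""
    return (freq_affected[g_risk] / freq_affected[g_ref]) / (
        freq_ref[g_risk] / freq_ref[g_ref]
    )


class TestClassGenotypeFreqs:
    def test_or_one_is_hwe_everywhere(self):
        freqs = class_genotype_freqs(0.3, "B", "dominant", or_a=1.0, or_b=1.0)
        assert np.allclose(freqs, hwe_frequencies(0.3))
        assert np.allclose(hwe_frequencies(0.3), [0.49, 0.42, 0.09])

    def test_unaffected_classes_keep_hwe(self):
        freqs = class_genotype_freqs(0.2, "B", "recessive", or_a=3.0)
        # Da-only SNP: classes (1,1) and (1,2) untouched
        assert np.allclose(freqs[0], hwe_frequencies(0.2))
        assert np.allclose(freqs[1], hwe_frequencies(0.2))

    def test_dominant_carrier_odds_arithmetic(self):
        # HWE carrier probability 1/2 at maf = 1 - sqrt(1/2); OR=2 -> 2/3
        maf = 1.0 - np.sqrt(0.5)
        freqs = class_genotype_freqs(maf, "B", "dominant", or_a=2.0)
        carrier = freqs[2, 1] + freqs[2, 2]
        assert carrier == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("maf", [0.1, 0.25, 0.5])
    def test_additive_realizes_full_and_sqrt_or(self, maf):
        freqs = class_genotype_freqs(maf, "B", "additive", or_a=4.0)
        assert _empirical_or(freqs[2], freqs[0], 2, 0) == pytest.approx(4.0)
        assert _empirical_or(freqs[2], freqs[0], 1, 0) == pytest.approx(2.0)

    def test_disease_allele_a_mirrors_b(self):
        fb = class_genotype_freqs(0.3, "B", "dominant", or_a=2.0)
        fa = class_genotype_freqs(0.3, "A", "dominant", or_a=2.0)
        # with allele A at risk the protected genotype is BB instead of AA
        assert _empirical_or(fa[2], fa[0], 0, 2) == pytest.approx(
            _empirical_or(fb[2], fb[0], 2, 0)
        )

    def test_pleiotropic_weights_multiply_in_double_affected(self):
        f = class_genotype_freqs(0.3, "B", "recessive", or_a=2.0, or_b=3.0)
        assert _empirical_or(f[2], f[0], 2, 0) == pytest.approx(2.0)  # (2,1): Da only
        assert _empirical_or(f[1], f[0], 2, 0) == pytest.approx(3.0)  # (1,2): Db only
        assert _empirical_or(f[3], f[0], 2, 0) == pytest.approx(6.0)  # (2,2): both

    def test_rows_sum_to_one(self):
        f = class_genotype_freqs(0.17, "A", "additive", or_a=1.7, or_b=2.2)
        assert np.allclose(f.sum(axis=1), 1.0)

    def test_protective_or_rejected(self):
        with pytest.raises(ValueError, match="disease-allele"):
            class_genotype_freqs(0.3, "B", "dominant", or_a=0.5)


class TestDrawCausalSpecs:
    def test_degenerate_bounds_give_exact_or(self, rng):
        cfg = tiny_scenario(or_bounds_a=(2.0, 2.0), or_bounds_b=(2.0, 2.0))
        specs = draw_causal_specs(cfg, rng)
        assert all(s.or_a == 2.0 for s in specs if s.or_a is not None)

    def test_counts_per_target(self, rng):
        cfg = scenario_presets("set1_scenario1").at_scale(1000)
        specs = draw_causal_specs(cfg, rng)
        targets = [s.target for s in specs]
        assert targets.count("both") == 50
        assert targets.count("a") == 50
        assert targets.count("b") == 50

    def test_uniform_mode_and_allele_frequencies(self, rng):
        cfg = tiny_scenario(
            n_pleiotropic=10_000, n_da_only=0, n_db_only=0, n_snps_total=10_000
        )
        specs = draw_causal_specs(cfg, rng)
        modes = np.array([s.mode for s in specs])
        alleles = np.array([s.disease_allele for s in specs])
        for m in ("dominant", "recessive", "additive"):
            assert abs((modes == m).mean() - 1 / 3) < 0.02
        assert abs((alleles == "A").mean() - 0.5) < 0.02

    def test_empty_maf_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            draw_causal_specs(tiny_scenario(), rng, maf_pool=np.array([]))

    def test_maf_pool_must_exceed_threshold(self, rng):
        with pytest.raises(ValueError, match="0.05"):
            draw_causal_specs(tiny_scenario(), rng, maf_pool=np.array([0.01, 0.3]))


class TestSimulateStudy:
    def test_phenotype_counts_exact(self, tiny_study):
        p = tiny_study.discovery_phenotypes
        counts = np.bincount(p.joint_class(), minlength=4)
        assert counts.tolist() == [100, 100, 100, 100]

    def test_deterministic_given_seed(self):
        cfg = tiny_scenario()
        s1 = simulate_study(cfg, rng=123)
        s2 = simulate_study(cfg, rng=123)
        assert np.array_equal(
            s1.discovery_genotypes.genotypes, s2.discovery_genotypes.genotypes
        )
        assert np.array_equal(
            s1.validation_genotypes.genotypes, s2.validation_genotypes.genotypes
        )
        assert s1.specs == s2.specs

    def test_null_snps_match_hwe(self):
        cfg = ScenarioConfig(
            name="null",
            discovery_counts=(25000, 25000, 25000, 25000),
            validation_counts=(1, 1, 1, 1),
            or_bounds_a=(1.0, 1.0),
            or_bounds_b=(1.0, 1.0),
            n_pleiotropic=0,
            n_da_only=0,
            n_db_only=0,
            n_snps_total=30,
        )
        study = simulate_study(cfg, rng=3, maf_pool=np.array([0.3]))
        g = study.discovery_genotypes.genotypes
        emp = np.stack([(g == k).mean(axis=0) for k in range(3)], axis=1)
        assert np.all(np.abs(emp - hwe_frequencies(0.3)) < 0.01)

    def test_dominant_or_recovery(self):
        """Empirical case/control carrier OR within [1.9, 2.1] at 100k/class."""
        cfg = ScenarioConfig(
            name="one",
            discovery_counts=(100_000, 0, 100_000, 0),
            validation_counts=(1, 1, 1, 1),
            or_bounds_a=(2.0, 2.0),
            or_bounds_b=(1.0, 1.0),
            n_pleiotropic=0,
            n_da_only=1,
            n_db_only=0,
            n_snps_total=1,
        )
        spec = CausalSpec(0, "a", 0.3, "B", "dominant", or_a=2.0)
        study = simulate_study(cfg, specs=[spec], rng=9)
        g = study.discovery_genotypes.genotypes[:, 0]
        da = study.discovery_phenotypes.da
        carrier = g >= 1
        odds_case = carrier[da == 2].mean() / (1 - carrier[da == 2].mean())
        odds_ctrl = carrier[da == 1].mean() / (1 - carrier[da == 1].mean())
        assert 1.9 < odds_case / odds_ctrl < 2.1

    def test_truth_covers_exactly_causal_indices(self, tiny_study):
        truth = tiny_study.truth
        causal = [i for i, v in truth.items() if v is not None]
        assert sorted(causal) == sorted(s.snp_index for s in tiny_study.specs)
        assert len(truth) == tiny_study.config.n_snps_total

    def test_spec_mismatch_rejected(self, rng):
        cfg = tiny_scenario()
        with pytest.raises(ValueError, match="spec count"):
            simulate_study(cfg, specs=[], rng=rng)


class TestScenarioPresets:
    def test_all_sixteen_names_resolve(self):
        assert len(SCENARIO_NAMES) == 16
        for name in SCENARIO_NAMES:
            cfg = scenario_presets(name)
            assert cfg.n_snps_total == 500_150
            assert cfg.n_validation == 4000

    def test_set2_scenario5_or_ranges(self):
        cfg = scenario_presets("set2_scenario5")
        assert cfg.or_bounds_a == (2.0, 2.5)
        assert cfg.or_bounds_b == (1.5, 2.0)
        assert cfg.discovery_counts == (450, 450, 50, 50)
        assert cfg.validation_counts == (1800, 1800, 200, 200)

    def test_set4_scenario1(self):
        cfg = scenario_presets("set4_scenario1")
        assert cfg.n_discovery == 4000
        assert cfg.or_bounds_a == (1.1, 2.5)

    def test_set3_has_no_pleiotropy(self):
        cfg = scenario_presets("set3_moderate")
        assert (cfg.n_pleiotropic, cfg.n_da_only, cfg.n_db_only) == (0, 75, 75)
        assert cfg.or_bounds_a == (1.25, 2.0)

    def test_set1_sample_sizes_follow_names(self):
        # scenario names are authoritative: odd = 1.5k, even = 4k
        assert scenario_presets("set1_scenario5").n_discovery == 1500
        assert scenario_presets("set1_scenario6").n_discovery == 4000

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            scenario_presets("set9_scenario1")


class TestTypeIError:
    def test_null_snps_pass_chisq_screen_at_nominal_rate(self):
        """Non-causal SNPs show ~5% chi-square rejections at alpha=0.05."""
        from scipy.stats import chi2_contingency

        cfg = ScenarioConfig(
            name="null",
            discovery_counts=(1000, 1000, 1000, 1000),
            validation_counts=(1, 1, 1, 1),
            or_bounds_a=(1.0, 1.0),
            or_bounds_b=(1.0, 1.0),
            n_pleiotropic=0,
            n_da_only=0,
            n_db_only=0,
            n_snps_total=2500,
        )
        study = simulate_study(cfg, rng=17)
        g = study.discovery_genotypes.genotypes
        da = study.discovery_phenotypes.da
        rej = 0
        for j in range(g.shape[1]):
            table = np.stack(
                [np.bincount(g[da == k, j], minlength=3) for k in (1, 2)]
            )
            table = table[:, table.sum(axis=0) > 0]
            rej += chi2_contingency(table).pvalue < 0.05
        assert abs(rej / g.shape[1] - 0.05) < 0.01
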
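import numpy as np
import pytest

from pleiobayes.classify import (
    NestedClassifierSeries,
    build_series,
    decide,
    fit_cpt,
    joint_posterior,
    prediction_statistic,
    statistic_curves,
)
from pleiobayes.core import (
    AssociationModel,
    ContingencyTable,
    InheritanceMode,
    PhenotypeTable,
)
from pleiobayes.search import naive_scan, pleiotropic_scan


def _genotypic(counts, model):
    return ContingencyTable(
        np.asarray(counts, dtype=np.int64),
        AssociationModel(model),
        InheritanceMode.GENOTYPIC,
    )


def _series_from_cpts(cpt_rows, models, prior=None):
    """Hand-built 4-class series from per-SNP (q, 3) probability tables."""
    from pleiobayes.classify import SmoothedCPT, _expand_rows
    from pleiobayes.search import ModelAssignment

    assignments, cpts = [], []
    log_cpt = np.zeros((len(cpt_rows), 4, 4))
    for i, (probs, model) in enumerate(zip(cpt_rows, models)):
        model = AssociationModel(model)
        probs = np.asarray(probs, dtype=np.float64)
        assignments.append(
            ModelAssignment(i, f"s{i}", model, InheritanceMode.GENOTYPIC, 2.0, "a")
        )
        cpts.append(SmoothedCPT(probs=probs, av=4.0 / probs.shape[0], model=model))
        log_cpt[i, :, :3] = np.log(probs[_expand_rows(model, 4)])
    prior = np.full(4, 0.25) if prior is None else np.asarray(prior)
    return NestedClassifierSeries(assignments, cpts, prior, 4, log_cpt)


class TestSmoothedCPT:
    def test_empty_row_is_uniform(self):
        cpt = fit_cpt(_genotypic([[0, 0, 0], [0, 0, 0]], "Ma"))
        assert cpt.av == 2.0
        assert np.allclose(cpt.probs, 1 / 3)

    def test_q2_formula(self):
        cpt = fit_cpt(_genotypic([[10, 0, 0], [0, 0, 0]], "Ma"))
        assert np.allclose(cpt.probs[0], [0.75, 0.125, 0.125])

    def test_q4_symmetry(self):
        cpt = fit_cpt(_genotypic([[1, 1, 1]] * 4, "Mab"))
        assert cpt.av == 1.0
        assert np.allclose(cpt.probs, 1 / 3)

    def test_rows_sum_to_one_exactly(self, rng):
        counts = rng.integers(0, 30, size=(4, 3))
        cpt = fit_cpt(_genotypic(counts, "Mab"))
        assert np.allclose(cpt.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((cpt.probs > 0) & (cpt.probs < 1))

    def test_non_genotypic_rejected(self):
        t = ContingencyTable(
            np.zeros((2, 2), dtype=np.int64),
            AssociationModel.Ma,
            InheritanceMode.DOMINANT,
        )
        with pytest.raises(ValueError, match="genotypic"):
            fit_cpt(t)


class TestJointPosterior:
    def test_r0_returns_prior(self):
        s = _series_from_cpts([np.full((2, 3), 1 / 3)], ["Ma"], prior=[0.1, 0.2, 0.3, 0.4])
        assert np.allclose(joint_posterior([0], s, 0), [0.1, 0.2, 0.3, 0.4])

    def test_uniform_cpts_return_prior(self):
        s = _series_from_cpts(
            [np.full((2, 3), 1 / 3), np.full((4, 3), 1 / 3)], ["Ma", "Mab"]
        )
        assert np.allclose(joint_posterior([0, 2], s, 2), 0.25)

    def test_hand_enumeration_single_mab_snp(self):
        probs = np.array(
            [[0.8, 0.1, 0.1], [0.6, 0.2, 0.2], [0.2, 0.4, 0.4], [0.1, 0.45, 0.45]]
        )
        s = _series_from_cpts([probs], ["Mab"])
        post = joint_posterior([0], s, 1)  # observed genotype AA
        assert np.allclose(post, np.array([0.8, 0.6, 0.2, 0.1]) / 1.7)

    def test_normalization_at_every_r(self, rng):
        tables = [rng.dirichlet(np.ones(3), size=q) for q in (2, 2, 4, 2, 4)]
        models = ["Ma", "Mb", "Mab", "Ma", "Mab"]
        s = _series_from_cpts(tables, models)
        profile = rng.integers(0, 3, size=5)
        for r in range(6):
            assert joint_posterior(profile, s, r).sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_genotypes_skip_snp(self):
        probs = np.array([[0.9, 0.05, 0.05], [0.1, 0.45, 0.45]])
        s = _series_from_cpts([probs, probs], ["Ma", "Ma"])
        partial = joint_posterior([-1, 0], s, 2)
        only_second = joint_posterior([0], _series_from_cpts([probs], ["Ma"]), 1)
        assert np.allclose(partial, only_second)

    def test_r_out_of_range(self):
        s = _series_from_cpts([np.full((2, 3), 1 / 3)], ["Ma"])
        with pytest.raises(ValueError):
            joint_posterior([0], s, 2)


class TestPredictionStatistic:
    def _random_series(self, rng, models=("Ma", "Mab", "Mb", "Ma")):
        tables = [
            rng.dirichlet(np.ones(3), size=AssociationModel(m).q) for m in models
        ]
        return _series_from_cpts(tables, models)

    def test_r1_ensemble_equals_single(self, rng):
        s = self._random_series(rng)
        profile = rng.integers(0, 3, size=4)
        for kind in ("marginal", "conditional"):
            db = 2 if kind == "conditional" else None
            single = prediction_statistic(profile, s, 1, kind, "single", db)
            ens = prediction_statistic(profile, s, 1, kind, "ensemble", db)
            assert single.value == pytest.approx(ens.value, rel=1e-12)

    def test_uniform_series_statistic_is_one(self):
        s = _series_from_cpts([np.full((4, 3), 1 / 3)] * 3, ["Mab"] * 3)
        profile = np.array([0, 1, 2])
        for kind, db in (("marginal", None), ("conditional", 1)):
            for variant in ("single", "ensemble"):
                stat = prediction_statistic(profile, s, 3, kind, variant, db)
                assert stat.value == pytest.approx(1.0, rel=1e-12)

    def test_ma_only_series_conditional_equals_marginal(self, rng):
        """With no Mb/Mab SNPs and a uniform prior the posterior factorizes,
        so knowing Db cannot change the Da odds."""
        s = self._random_series(rng, models=("Ma", "Ma", "Ma"))
        profile = rng.integers(0, 3, size=3)
        marg = prediction_statistic(profile, s, 3, "marginal", "single")
        for db in (1, 2):
            cond = prediction_statistic(profile, s, 3, "conditional", "single", db)
            assert cond.value == pytest.approx(marg.value, rel=1e-10)

    def test_snp_order_invariance_single(self, rng):
        models = ["Ma", "Mab", "Mb"]
        tables = [rng.dirichlet(np.ones(3), size=AssociationModel(m).q) for m in models]
        profile = rng.integers(0, 3, size=3)
        perm = [2, 0, 1]
        s1 = _series_from_cpts(tables, models)
        s2 = _series_from_cpts([tables[i] for i in perm], [models[i] for i in perm])
        for kind, db in (("marginal", None), ("conditional", 2)):
            v1 = prediction_statistic(profile, s1, 3, kind, "single", db).value
            v2 = prediction_statistic(profile[perm], s2, 3, kind, "single", db).value
            assert v1 == pytest.approx(v2, rel=1e-10)

    def test_conditional_requires_db(self, rng):
        s = self._random_series(rng)
        with pytest.raises(ValueError, match="Db"):
            prediction_statistic([0, 0, 0, 0], s, 2, "conditional", "single")

    def test_decide_with_threshold_one_matches_posterior_half(self, rng):
        """With T=1 and a uniform prior, deciding class 2 is the same as the
        posterior probability of Da=2 exceeding 1/2."""
        for _ in range(20):
            s = self._random_series(rng)
            profile = rng.integers(0, 3, size=4)
            stat = prediction_statistic(profile, s, 4, "marginal", "single")
            post = joint_posterior(profile, s, 4)
            p_da2 = post[2] + post[3]
            assert (decide(stat) == 2) == (p_da2 > 0.5)


class TestDecide:
    @pytest.mark.parametrize(
        "c1,t,expected", [(1.5, 1.0, 2), (1.0, 1.0, 1), (0.2, 0.1, 2), (0.05, 0.1, 1)]
    )
    def test_strict_rule(self, c1, t, expected):
        assert decide(np.array([c1]), t)[0] == expected

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            decide(np.array([1.0]), 0.0)


class TestSeriesFromSearch:
    def test_naive_and_pleiotropic_series_curves(self, tiny_study):
        g, p = tiny_study.discovery_genotypes, tiny_study.discovery_phenotypes
        ranked = pleiotropic_scan(g, p)
        series = build_series(g, p, ranked, r_max=10)
        prof = tiny_study.validation_genotypes.genotypes[:, series.snp_indices]
        curves = statistic_curves(
            series, prof, "conditional", "single", tiny_study.validation_phenotypes.db
        )
        assert curves.shape == (prof.shape[0], series.r_avail)
        assert np.all(curves > 0) and np.all(np.isfinite(curves))
        ranked_n = naive_scan(g, PhenotypeTable(da=p.da))
        series_n = build_series(g, p, ranked_n, r_max=10, naive=True)
        prof_n = tiny_study.validation_genotypes.genotypes[:, series_n.snp_indices]
        naive_curves = statistic_curves(series_n, prof_n, "naive", "ensemble")
        assert naive_curves.shape[1] == series_n.r_avail

    def test_empirical_prior(self, tiny_study):
        g, p = tiny_study.discovery_genotypes, tiny_study.discovery_phenotypes
        ranked = pleiotropic_scan(g, p)
        series = build_series(g, p, ranked, r_max=5, prior="empirical")
        counts = np.bincount(p.joint_class(), minlength=4)
        assert np.allclose(series.prior, counts / counts.sum())
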
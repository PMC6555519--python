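"""Candidate log-log OLS models, AIC selection, and parameterization."""

import math

import numpy as np
import pytest

from beeallometry import allometry as al
from beeallometry import morphodata as md
from beeallometry import synthdata as sd


def simple_spec():
    return al.ModelSpec("proboscis", "none", "common_slope")


class TestBuildDesign:
    def test_it_only_design_is_intercept_plus_slope(self, six_family_means):
        X, y, names, used = al.build_design(simple_spec(), six_family_means[:3])
        assert X.shape == (3, 2)
        assert names == ["intercept", "ln_it"]
        assert np.allclose(X[:, 0], 1.0)

    def test_family_additive_has_seven_coefficients(self, six_family_means):
        X, _, names, _ = al.build_design(
            al.ModelSpec("proboscis", "family", "common_slope"), six_family_means
        )
        assert X.shape[1] == 7
        assert names.count("ln_it") == 1

    def test_family_interaction_has_twelve_coefficients(self, six_family_means):
        X, _, names, _ = al.build_design(
            al.ModelSpec("prementum", "family", "group_slope"), six_family_means
        )
        assert X.shape[1] == 12

    def test_single_family_grouping_is_rank_deficient(self, six_family_means):
        melittids = [m for m in six_family_means if m.family == "Melittidae"]
        with pytest.raises(al.FitError):
            al.build_design(
                al.ModelSpec("glossa", "family", "common_slope"), melittids
            )


class TestFitOLS:
    def test_worked_simple_regression(self):
        """x=(0,1,2), y=(0,1,3): closed-form slope 3/2, intercept -1/6, RSS 1/6."""
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        y = np.array([0.0, 1.0, 3.0])
        fit = al.fit_ols(X, y, simple_spec(), ["intercept", "ln_it"])
        assert fit.coefficients["ln_it"] == pytest.approx(1.5, abs=1e-12)
        assert fit.coefficients["intercept"] == pytest.approx(-1 / 6, abs=1e-12)
        assert fit.rss == pytest.approx(1 / 6, abs=1e-12)

    def test_worked_example_aic(self):
        """Gaussian-ML AIC with the variance counted: plugging rss=1/6, n=3,
        k=2 into -2*loglik + 2*(k+1) gives ~5.84."""
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        y = np.array([0.0, 1.0, 3.0])
        fit = al.fit_ols(X, y, simple_spec(), ["intercept", "ln_it"])
        n, rss = 3, 1 / 6
        loglik = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1)
        assert fit.loglik == pytest.approx(loglik, abs=1e-12)
        assert fit.aic == pytest.approx(-2 * loglik + 2 * 3, abs=1e-12)
        assert fit.aic == pytest.approx(5.84, abs=0.005)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 13))
            k = int(rng.integers(1, min(n - 1, 4) + 1))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
            y = rng.normal(size=n)
            fit = al.fit_ols(X, y, simple_spec())
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(list(fit.coefficients.values()), beta, atol=1e-8)
            assert fit.rss == pytest.approx(float(np.sum((y - X @ beta) ** 2)), abs=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        fit = al.fit_ols(X, y, simple_spec())
        res = sm.OLS(y, X).fit()
        assert np.allclose(list(fit.coefficients.values()), res.params, atol=1e-10)
        # statsmodels' OLS aic counts k (not k+1); same loglik convention
        assert fit.loglik == pytest.approx(res.llf, abs=1e-8)
        assert fit.aic == pytest.approx(res.aic + 2, abs=1e-8)

    def test_perfect_fit_reports_minus_inf_aic(self):
        X = np.column_stack([np.ones(4), [0.0, 1.0, 2.0, 3.0]])
        y = 2.0 + 0.5 * X[:, 1]
        fit = al.fit_ols(X, y, simple_spec())
        assert fit.aic == -math.inf
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_underdetermined_raises(self):
        X = np.ones((2, 2))
        with pytest.raises(al.FitError):
            al.fit_ols(X, np.zeros(2), simple_spec())


class TestCandidatesAndSelection:
    def test_seven_candidates_fit_on_valid_data(self, noisy_means):
        fits, failures = al.candidate_fits("proboscis", noisy_means)
        assert len(fits) == 7
        assert not failures
        assert len({f.n for f in fits}) == 1  # common species set

    def test_single_family_only_it_only_succeeds(self, noisy_means):
        melittids = [m for m in noisy_means if m.family == "Melittidae"]
        fits, failures = al.candidate_fits("glossa", melittids)
        assert [f.spec.grouping for f in fits] == ["none"]
        assert len(failures) == 6

    def test_select_best_is_argmin_aic(self, noisy_means):
        fits, _ = al.candidate_fits("glossa", noisy_means)
        best = al.select_best(fits)
        assert best.aic == min(f.aic for f in fits)

    def test_aic_tie_broken_by_fewer_coefficients(self):
        a = al.AllometryFit(al.ModelSpec("glossa", "family", "group_slope"),
                            20, 5, {}, 1.0, 0.0, 10.0, 0.9, 0.9)
        b = al.AllometryFit(al.ModelSpec("glossa", "family", "common_slope"),
                            20, 3, {}, 1.0, 0.0, 10.0, 0.9, 0.9)
        assert al.select_best([a, b]) is b

    def test_interaction_model_selected_when_generating(self):
        """Data generated with family-specific slopes should favour the
        interaction model (the prementum block's structure)."""
        wins = 0
        for seed in range(20):
            cfg = sd.SynthConfig(seed=300 + seed, n_specimens=1)
            means = md.aggregate_species_means(sd.gen_specimens(cfg))
            best = al.select_best(al.candidate_fits("prementum", means)[0])
            wins += best.spec == al.ModelSpec("prementum", "family", "group_slope")
        assert wins >= 16

    def test_adding_predictor_never_increases_rss(self, noisy_means):
        fits, _ = al.candidate_fits("proboscis", noisy_means)
        by_spec = {f.spec: f for f in fits}
        additive = by_spec[al.ModelSpec("proboscis", "family", "common_slope")]
        interaction = by_spec[al.ModelSpec("proboscis", "family", "group_slope")]
        family_only = by_spec[al.ModelSpec("proboscis", "family", "absent")]
        assert interaction.rss <= additive.rss <= family_only.rss + 1e-12

    def test_aic_ordering_invariant_to_response_shift(self, noisy_means):
        fits, _ = al.candidate_fits("glossa", noisy_means)
        order = [f.spec for f in sorted(fits, key=lambda f: f.aic)]
        shifted = [
            md.SpeciesTraitMeans(
                m.species, m.genus, m.family, m.n_specimens, m.mean_it_mm,
                mean_glossa_mm=m.mean_glossa_mm * math.e,  # +1 on the ln scale
            )
            for m in noisy_means
        ]
        fits2, _ = al.candidate_fits("glossa", shifted)
        order2 = [f.spec for f in sorted(fits2, key=lambda f: f.aic)]
        assert order == order2

    def test_additive_model_gives_parallel_lines(self, noisy_means):
        fit = al.fit_model(
            al.ModelSpec("proboscis", "family", "common_slope"), noisy_means
        )
        params = al.parameterize(fit)
        # predicted ln-length difference between two families is the intercept
        # difference, identical at any IT
        for it in (1.0, 2.5, 4.0):
            d = (params.intercepts["Apidae"] + params.slope * math.log(it)) - (
                params.intercepts["Melittidae"] + params.slope * math.log(it)
            )
            assert d == pytest.approx(
                params.intercepts["Apidae"] - params.intercepts["Melittidae"],
                abs=1e-12,
            )


class TestParameterize:
    def test_reference_plus_offset_sums(self):
        fit = al.AllometryFit(
            al.ModelSpec("proboscis", "family", "common_slope"), 111, 7,
            {"intercept": 1.06, "family[Melittidae]": 0.04, "family[Apidae]": 1.09,
             "family[Colletidae]": -0.20, "family[Halictidae]": 0.31,
             "family[Megachilidae]": 0.81, "ln_it": 0.96},
            1.0, 0.0, 0.0, 0.98, 0.98, reference_group="Andrenidae",
        )
        params = al.parameterize(fit)
        assert params.intercepts["Melittidae"] == pytest.approx(1.10)
        assert params.intercepts["Andrenidae"] == pytest.approx(1.06)
        assert params.intercepts["Apidae"] == pytest.approx(2.15)
        # common slope replicated for every family
        assert all(params.slope_for(f) == 0.96 for f in md.FAMILIES)

    def test_interaction_fit_yields_per_family_slopes(self, six_family_means):
        fit = al.fit_model(
            al.ModelSpec("prementum", "family", "group_slope"), six_family_means
        )
        params = al.parameterize(fit)
        assert params.slope is None
        # zero-noise fixture: recovers the generating per-family slopes
        gen = sd.SynthConfig(seed=0).coefficients["prementum"]
        for family in md.FAMILIES:
            assert params.slopes[family] == pytest.approx(
                gen.slopes[family], abs=1e-8
            )
            assert params.intercepts[family] == pytest.approx(
                gen.intercepts[family], abs=1e-8
            )

    def test_no_it_term_is_an_error(self, six_family_means):
        fit = al.fit_model(
            al.ModelSpec("glossa", "family", "absent"), six_family_means
        )
        with pytest.raises(al.FitError, match="power function"):
            al.parameterize(fit)


class TestSexSlope:
    def test_identical_sexes_give_f_zero_p_one(self):
        records = []
        for sex in ("male", "female"):
            for i, it in enumerate((1.0, 1.5, 2.0, 3.0, 4.0)):
                records.append(
                    md.SpecimenRecord(
                        specimen_id=f"{sex}{i}", species=f"sp{i % 2}", genus="G",
                        family="Melittidae", sex=sex, it_mm=it,
                        glossa_mm=0.5 * it + 0.3 + 0.01 * i,
                        prementum_mm=1.1 * it ** 0.8,
                    )
                )
        result = al.test_common_slope_by_sex(records)
        for response in al.RESPONSES:
            assert result[response]["F"] == pytest.approx(0.0, abs=1e-6)
            assert result[response]["p"] == pytest.approx(1.0, abs=1e-6)
            assert result[response]["slope_diff"] == pytest.approx(0.0, abs=1e-6)

    def test_missing_sex_raises(self):
        records = [
            md.SpecimenRecord(specimen_id=str(i), species="sp", genus="G",
                              family="Apidae", sex="female", it_mm=1.0 + i,
                              glossa_mm=1.0 + i, prementum_mm=1.0)
            for i in range(5)
        ]
        with pytest.raises(al.FitError, match="both sexes"):
            al.test_common_slope_by_sex(records, responses=("glossa",))

    def test_type_i_error_near_nominal(self):
        """Equal-slope generator: the sex-interaction F test should reject at
        ~alpha. 1000 replicates, alpha=0.05, band 0.05 +/- 0.02."""
        rejections = 0
        reps = 1000
        for seed in range(reps):
            cfg = sd.SynthConfig(seed=10_000 + seed, n_species={"Melittidae": 6},
                                 n_specimens=10)
            result = al.test_common_slope_by_sex(
                sd.gen_specimens(cfg), responses=("glossa",),
                include_species_intercepts=False,
            )
            rejections += result["glossa"]["p"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_slope_difference(self):
        """Male slope shifted by 0.5 at ~200 specimens: near-certain rejection."""
        rejections = 0
        reps = 60
        for seed in range(reps):
            cfg = sd.SynthConfig(seed=20_000 + seed, sex_slope_shift=0.5,
                                 n_species={"Melittidae": 10}, n_specimens=20)
            result = al.test_common_slope_by_sex(
                sd.gen_specimens(cfg), responses=("glossa",),
                include_species_intercepts=False,
            )
            rejections += result["glossa"]["p"] < 0.05
        assert rejections / reps > 0.9


def test_coefficient_recovery_within_three_se(noisy_means):
    """Fitting the generating additive model recovers the true glossa
    coefficients within 3 standard errors (single-replicate sanity check;
    the replicated version lives in the acceptance suite)."""
    fit = al.fit_model(al.ModelSpec("glossa", "family", "common_slope"), noisy_means)
    gen = sd.SynthConfig(seed=0).coefficients["glossa"]
    assert abs(fit.coefficients["ln_it"] - gen.slope) <= 3 * fit.stderr["ln_it"]
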
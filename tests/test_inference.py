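"""Frequentist analysis methods: Welch, ANOVA, GLMMs, LRT, dose-response."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

import wormassay as wa
from wormassay.errors import (
    ConfigError,
    InsufficientReplicationError,
    NotNestedError,
    ValidationError,
)

ZERO = wa.VarianceComponents()
DUNNETT = wa.ContrastSpec(control="control")


def dataset_from_props(groups: dict[str, list[float]], n=10) -> wa.AssayDataset:
    obs = []
    for s, props in groups.items():
        for i, p in enumerate(props):
            obs.append(
                wa.AssayObservation(s, f"d{i + 1}", f"{s}-p{i}", n, round(p * n))
            )
    return wa.AssayDataset(observations=obs, control_strain=list(groups)[0])


class TestWelch:
    def test_identical_groups_t0_p1(self):
        ds = dataset_from_props(
            {"control": [0.2, 0.3, 0.4], "g1": [0.2, 0.3, 0.4]}
        )
        fit = wa.welch_prop_test(ds, DUNNETT)
        c = fit.contrast("g1")
        assert c.statistic == pytest.approx(0.0)
        assert c.p_raw == pytest.approx(1.0)

    def test_zero_variance_degenerate_flag(self):
        ds = dataset_from_props({"control": [0, 0, 0], "g1": [1, 1, 1]})
        fit = wa.welch_prop_test(ds, DUNNETT)
        c = fit.contrast("g1")
        assert c.degenerate
        assert c.p_raw < 1e-6  # variance floor, not a crash

    def test_single_plate_rejected(self):
        ds = dataset_from_props({"control": [0.5], "g1": [0.2, 0.3]})
        with pytest.raises(InsufficientReplicationError):
            wa.welch_prop_test(ds, DUNNETT)

    def test_matches_scipy(self, small_dataset):
        fit = wa.welch_prop_test(small_dataset, DUNNETT)
        a = small_dataset.proportions("g1")
        b = small_dataset.proportions("control")
        ref = stats.ttest_ind(a, b, equal_var=False)
        c = fit.contrast("g1")
        assert c.statistic == pytest.approx(ref.statistic)
        assert c.p_raw == pytest.approx(ref.pvalue)

    def test_null_calibration(self):
        """Type-I of the Welch test on iid binomial plates is ~alpha."""
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.binomial(50, 0.5, size=6) / 50
            b = rng.binomial(50, 0.5, size=6) / 50
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        ds = dataset_from_props(
            {"control": [0.2, 0.35, 0.5], "g1": [0.3, 0.45, 0.6]}
        )
        fit = wa.anova_prop(ds, DUNNETT)
        a, b = ds.proportions("g1"), ds.proportions("control")
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert fit.diagnostics["F"] == pytest.approx(t**2)

    def test_all_equal_f0_p1(self):
        ds = dataset_from_props({"control": [0.4] * 3, "g1": [0.4] * 3})
        fit = wa.anova_prop(ds, DUNNETT)
        assert fit.diagnostics["F"] == 0.0
        assert fit.diagnostics["p_F"] == 1.0

    def test_single_strain_rejected(self):
        ds = dataset_from_props({"control": [0.2, 0.3]})
        with pytest.raises(InsufficientReplicationError):
            wa.anova_prop(ds, DUNNETT)

    def test_adjusted_at_least_raw(self, small_dataset):
        fit = wa.anova_prop(small_dataset, DUNNETT)
        for c in fit.contrasts:
            assert c.p_adj >= c.p_raw


class TestBinomialGLMM:
    def test_pooled_identity_without_random_terms(self, small_dataset):
        fit = wa.fit_binomial_glmm(small_dataset, random_terms=())
        for s in small_dataset.strains:
            assert fit.fixed_effects[s] == pytest.approx(
                logit(small_dataset.pooled_proportion(s)), abs=1e-8
            )

    def test_zero_variance_data_matches_pooled_glm(self):
        """Constant plates: variance estimates collapse and the fixed
        effects reproduce the pooled GLM logits."""
        obs = [
            wa.AssayObservation(s, f"d{d}", f"{s}p{d}{i}", 50, k)
            for s, k in (("control", 25), ("g1", 35))
            for d in range(3)
            for i in range(2)
        ]
        ds = wa.AssayDataset(observations=obs, control_strain="control")
        fit = wa.fit_binomial_glmm(ds)
        assert fit.fixed_effects["control"] == pytest.approx(0.0, abs=1e-6)
        assert fit.fixed_effects["g1"] == pytest.approx(logit(0.7), abs=1e-6)
        assert max(fit.variance_estimates.as_tuple()) < 1e-3

    def test_large_sample_recovery(self):
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0, "g1": 1.0},
            n_days=4,
            plates_per_group=200,
            animals_per_plate=100,
        )
        ds = wa.simulate_assay_dataset(scenario, ZERO, seed=11)
        fit = wa.fit_binomial_glmm(ds)
        assert 0.9 <= fit.contrast("g1").estimate <= 1.1
        assert max(fit.variance_estimates.as_tuple()) < 0.05

    def test_complete_separation_flagged_and_finite(self):
        ds = dataset_from_props(
            {"control": [0.4, 0.5, 0.6], "g1": [0.0, 0.0, 0.0]}, n=30
        )
        fit = wa.fit_binomial_glmm(ds)
        assert fit.diagnostics["separated"]
        assert np.isfinite(fit.contrast("g1").estimate)

    def test_matches_lme4_oracle(self, small_dataset, tmp_path):
        """Independent cross-check of the Laplace fit against R lme4."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        csv = tmp_path / "d.csv"
        wa.write_assay_table(small_dataset, csv)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- glmer(cbind(n_dauer, n_total - n_dauer) ~ 0 + strain
                           + (1 | day) + (1 | strain:day),
                           family = binomial, data = d)
                cat(fixef(m), sep = "\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = dict(
            zip(sorted(small_dataset.strains), map(float, out.stdout.split()))
        )
        fit = wa.fit_binomial_glmm(
            small_dataset, random_terms=("day", "history")
        )
        for s in small_dataset.strains:
            assert fit.fixed_effects[s] == pytest.approx(ref[s], abs=0.01)


class TestLRT:
    @staticmethod
    def _full_reduced(ds):
        full = wa.fit_binomial_glmm(ds, random_terms=())
        pooled_obs = [
            wa.AssayObservation(
                "control", o.day_id, o.plate_id, o.n_total, o.n_dauer
            )
            for o in ds.observations
        ]
        reduced_ds = wa.AssayDataset(
            observations=pooled_obs, control_strain="control"
        )
        reduced = wa.fit_binomial_glmm(reduced_ds, random_terms=())
        return full, reduced

    def test_identical_models(self, small_dataset):
        fit = wa.fit_binomial_glmm(small_dataset, random_terms=())
        stat, df, p = wa.lrt_nested(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_strong_effect_small_p(self):
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0, "g1": 2.0},
            n_days=5,
            plates_per_group=100,
            animals_per_plate=50,
        )
        ds = wa.simulate_assay_dataset(scenario, ZERO, seed=13)
        stat, df, p = wa.lrt_nested(*self._full_reduced(ds))
        assert df == 1
        assert p < 1e-4

    def test_null_distribution_chi2(self):
        """Under the null the LRT is chi-square(1): empirical 95th
        percentile near 3.84."""
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0, "g1": 0.0},
            n_days=2,
            plates_per_group=6,
            animals_per_plate=50,
        )
        stats_ = []
        for ssq in np.random.SeedSequence(17).spawn(300):
            ds = wa.simulate_assay_dataset(scenario, ZERO, ssq)
            stat, _, _ = wa.lrt_nested(*self._full_reduced(ds))
            stats_.append(stat)
        q95 = np.quantile(stats_, 0.95)
        assert q95 == pytest.approx(stats.chi2.ppf(0.95, 1), abs=1.0)

    def test_non_nested_rejected(self, small_dataset):
        full = wa.fit_binomial_glmm(small_dataset, random_terms=("day",))
        other = wa.fit_binomial_glmm(small_dataset, random_terms=("plate",))
        with pytest.raises(NotNestedError):
            wa.lrt_nested(full, other)

    def test_worse_full_model_flagged(self, small_dataset):
        full = wa.fit_binomial_glmm(small_dataset, random_terms=())
        worse = wa.fit_binomial_glmm(small_dataset, random_terms=())
        worse.loglik = full.loglik - 1.0
        worse.n_params = full.n_params + 1
        with pytest.raises(ValidationError, match="refit"):
            wa.lrt_nested(worse, full)


class TestPoissonGLMM:
    def test_single_group_intercept_is_log_mean(self):
        obs = wa.simulate_grid_counts(
            {"N2": 20.0}, ZERO, n_worms_per_day=50, n_days=1, seed=1
        )
        fit = wa.fit_poisson_glmm(obs, random_terms=())
        mean = np.mean([o.score for o in obs])
        assert fit.fixed_effects["N2"] == pytest.approx(math.log(mean), abs=1e-8)

    def test_identical_groups_ratio_one(self):
        obs = wa.simulate_grid_counts(
            {"a": 20.0, "b": 20.0}, ZERO, n_worms_per_day=200, n_days=3, seed=2
        )
        fit = wa.fit_poisson_glmm(
            obs, contrasts=wa.ContrastSpec(control="a")
        )
        ratio = fit.diagnostics["rate_ratios"]["b/a"]
        assert ratio == pytest.approx(1.0, abs=0.1)
        lo, hi = fit.contrast("b").ci95
        assert lo < 0.0 < hi

    def test_rate_ratio_recovery_with_day_variance(self):
        obs = wa.simulate_grid_counts(
            {"control": 20.0, "mut": 40.0},
            wa.VarianceComponents(sd_day=0.3),
            n_worms_per_day=120,
            n_days=3,
            seed=3,
        )
        fit = wa.fit_poisson_glmm(obs)
        assert 1.7 <= fit.diagnostics["rate_ratios"]["mut/control"] <= 2.3


class TestLmmLog10:
    @staticmethod
    def _frame(values_a, values_b):
        rows = []
        for i, v in enumerate(values_a):
            rows.append({"strain": "a", "day": f"d{i % 3}", "plate": f"p{i}", "value": v})
        for i, v in enumerate(values_b):
            rows.append({"strain": "b", "day": f"d{i % 3}", "plate": f"p{i}", "value": v})
        return pd.DataFrame(rows)

    def test_geometric_ratio_two(self):
        frame = self._frame([1, 2, 4, 1, 2, 4], [2, 4, 8, 2, 4, 8])
        fit = wa.fit_lmm_log10(frame, wa.ContrastSpec(control="a"))
        diff = fit.contrast("b").estimate
        assert diff == pytest.approx(math.log10(2), abs=1e-4)

    def test_identical_groups(self):
        frame = self._frame([1, 2, 4], [1, 2, 4])
        fit = wa.fit_lmm_log10(frame, wa.ContrastSpec(control="a"))
        assert fit.contrast("b").estimate == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_rejected(self):
        frame = self._frame([1.0, 0.0], [2.0, 1.0])
        with pytest.raises(ValidationError, match="non-positive"):
            wa.fit_lmm_log10(frame)

    def test_day_sd_recovery(self):
        """Median estimated day sd over replicates near the simulated 0.1."""
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(40):
            rows = []
            for d in range(12):
                day_eff = rng.normal(0, 0.1)
                for i in range(6):
                    rows.append(
                        {
                            "strain": "a",
                            "day": f"d{d}",
                            "plate": f"d{d}p{i}",
                            "value": 10 ** (1.0 + day_eff + rng.normal(0, 0.05)),
                        }
                    )
            fit = wa.fit_lmm_log10(
                pd.DataFrame(rows), wa.ContrastSpec(scheme="none"),
                random_terms=("day",),
            )
            estimates.append(fit.variance_estimates.sd_day)
        assert np.median(estimates) == pytest.approx(0.1, abs=0.03)


class TestDoseResponse:
    @staticmethod
    def _simulate(strain_logodds, slope=0.5, doses=(0, 2, 4, 6), plates=6,
                  n=50, seed=0):
        rng = np.random.default_rng(seed)
        obs = []
        for s, b0 in strain_logodds.items():
            for d in doses:
                for i in range(plates):
                    p = expit(b0 + slope * d)
                    obs.append(
                        wa.AssayObservation(
                            s, f"d{d}", f"{s}-{d}-{i}", n,
                            int(rng.binomial(n, p)), dose=float(d),
                        )
                    )
        return wa.AssayDataset(
            observations=obs, control_strain=list(strain_logodds)[0]
        )

    def test_identical_strains_odds_ratio_one(self):
        ds = self._simulate({"control": -2.0, "mut": -2.0}, seed=1)
        fit = wa.fit_dose_response_glm(ds)
        assert fit.diagnostics["odds_ratios"]["mut"] == pytest.approx(
            1.0, abs=0.35
        )

    def test_recovers_large_strain_offset(self):
        true_or = 21.3
        ds = self._simulate(
            {"control": -3.5, "mut": -3.5 + math.log(true_or)}, seed=2
        )
        fit = wa.fit_dose_response_glm(ds)
        assert 17.0 <= fit.diagnostics["odds_ratios"]["mut"] <= 27.0
        assert fit.diagnostics["wald_chi2_strain"]["mut"] > 50

    def test_null_dose_wald_p_uniform(self):
        """With no dose effect the dose Wald p-value is uniform."""
        rng = np.random.default_rng(3)
        ps = []
        for k in range(200):
            ds = self._simulate({"control": 0.0}, slope=0.0, seed=rng.integers(2**31))
            ps.append(wa.fit_dose_response_glm(ds).diagnostics["p_dose"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_single_dose_level_rank_deficient(self):
        ds = self._simulate({"control": 0.0}, doses=(2.0,), seed=4)
        with pytest.raises(ConfigError, match="dose"):
            wa.fit_dose_response_glm(ds)

    def test_quadratic_fit(self):
        rng = np.random.default_rng(6)
        dose = np.repeat([0.0, 1.0, 2.0, 4.0], 20)
        value = 3.0 + 2.0 * dose - 0.25 * dose**2 + rng.normal(0, 0.1, len(dose))
        frame = pd.DataFrame({"strain": "N2", "dose": dose, "value": value})
        fit = wa.fit_dose_response_glm(frame, model="quadratic")
        assert fit.diagnostics["dose_coef"] == pytest.approx(2.0, abs=0.15)
        assert fit.diagnostics["dose2_coef"] == pytest.approx(-0.25, abs=0.05)
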
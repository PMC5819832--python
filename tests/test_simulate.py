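"""Synthetic-data generators: moments, clustering structure, determinism."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import wormassay as wa
from wormassay.errors import ConfigError

ZERO = wa.VarianceComponents()


def big_null_dataset(n_plates=10_000, n=100, seed=0):
    scenario = wa.SimulationScenario(
        group_logits={"control": 0.0},
        n_days=1,
        plates_per_group=n_plates,
        animals_per_plate=n,
    )
    return wa.simulate_assay_dataset(scenario, ZERO, seed=seed)


class TestAssayGenerator:
    def test_pure_binomial_moments(self):
        """Zero variance components: plate-wise iid Binomial(100, 0.5)."""
        ds = big_null_dataset()
        props = np.array([o.proportion for o in ds.observations])
        assert abs(props.mean() - 0.5) < 0.005
        assert props.std() == pytest.approx(0.05, abs=0.005)

    def test_effect_size_on_logit_scale(self):
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0, "mut": 1.0},
            n_days=1,
            plates_per_group=2000,
            animals_per_plate=100,
        )
        ds = wa.simulate_assay_dataset(scenario, ZERO, seed=2)
        mut = ds.proportions("mut")
        assert mut.mean() == pytest.approx(expit(1.0), abs=0.01)

    def test_logit_variance_decomposition(self):
        """Empirical logit variance recovers sD^2+sP^2+sG^2 after removing
        the binomial sampling contribution (delta method)."""
        var = wa.VarianceComponents(1.0, 0.3, 0.3)
        n = 400
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0},
            n_days=3000,
            plates_per_group=3000,
            animals_per_plate=n,
        )
        ds = wa.simulate_assay_dataset(scenario, var, seed=3)
        props = np.clip(
            np.array([o.proportion for o in ds.observations]), 1e-4, 1 - 1e-4
        )
        v_emp = np.var(logit(props))
        # E[1/(n p(1-p))] over the mixing distribution, by simulation truth
        binom_term = np.mean(1.0 / (n * props * (1 - props)))
        target = 1.0**2 + 0.3**2 + 0.3**2
        assert v_emp - binom_term == pytest.approx(target, rel=0.12)

    def test_day_effects_shared_across_strains(self):
        """sD moves all strains on a day together: per-day strain means are
        positively correlated across days under pure day variance."""
        scenario = wa.SimulationScenario(
            group_logits={"a": 0.0, "b": 0.0},
            n_days=200,
            plates_per_group=200,
            animals_per_plate=200,
        )
        ds = wa.simulate_assay_dataset(
            scenario, wa.VarianceComponents(sd_day=1.0), seed=4
        )
        frame = ds.to_frame()
        day_means = frame.pivot_table(
            index="day", columns="strain", values="n_dauer", aggfunc="mean"
        )
        r = np.corrcoef(day_means["a"], day_means["b"])[0, 1]
        assert r > 0.8

    def test_history_effects_independent_across_strains(self):
        scenario = wa.SimulationScenario(
            group_logits={"a": 0.0, "b": 0.0},
            n_days=300,
            plates_per_group=300,
            animals_per_plate=200,
        )
        ds = wa.simulate_assay_dataset(
            scenario, wa.VarianceComponents(sd_history=1.0), seed=5
        )
        frame = ds.to_frame()
        day_means = frame.pivot_table(
            index="day", columns="strain", values="n_dauer", aggfunc="mean"
        )
        r = np.corrcoef(day_means["a"], day_means["b"])[0, 1]
        assert abs(r) < 0.25

    def test_unbalanced_allocation(self):
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0, "g1": 0.0, "g2": 0.0},
            balanced=False,
        )
        ds = wa.simulate_assay_dataset(scenario, ZERO, seed=6)
        frame = ds.to_frame()
        counts = frame.groupby(["strain", "day"]).size().unstack(fill_value=0)
        assert (counts.loc["control"] == 2).all()  # control on every day
        for g in ("g1", "g2"):
            assert (counts.loc[g] == 0).sum() == 1  # absent one day
            assert counts.loc[g].sum() == 6  # plates reallocated

    def test_bias_shifts_control_only(self):
        """With sD large and bias on, control means exceed test-group means
        on the biased days."""
        scenario = wa.SimulationScenario(
            group_logits={"control": 0.0, "g1": 0.0},
            n_days=3,
            plates_per_group=300,
            animals_per_plate=200,
            bias_fraction=1.0,  # every day biased, offset = +1 x sd_day
        )
        ds = wa.simulate_assay_dataset(
            scenario, wa.VarianceComponents(sd_day=0.5), seed=7
        )
        shift = logit(ds.pooled_proportion("control")) - logit(
            ds.pooled_proportion("g1")
        )
        assert shift == pytest.approx(0.5, abs=0.15)

    def test_determinism_and_independence(self):
        scenario = wa.SimulationScenario(group_logits={"c": 0.0, "m": 1.0})
        a = wa.simulate_assay_dataset(scenario, ZERO, seed=42).to_frame()
        b = wa.simulate_assay_dataset(scenario, ZERO, seed=42).to_frame()
        c = wa.simulate_assay_dataset(scenario, ZERO, seed=43).to_frame()
        assert a.equals(b)
        assert not a.equals(c)

    def test_zero_groups_rejected(self):
        with pytest.raises(ConfigError):
            wa.SimulationScenario(group_logits={})

    def test_chi_square_gof_against_binomial(self):
        """10,000 null plates pass a GOF test vs Binomial(100, 0.5)."""
        ds = big_null_dataset(seed=8)
        counts = np.array([o.n_dauer for o in ds.observations])
        edges = [-0.5, 39.5, 44.5, 47.5, 50.5, 53.5, 56.5, 60.5, 100.5]
        obs_freq, _ = np.histogram(counts, bins=edges)
        cdf = stats.binom.cdf(np.array(edges), 100, 0.5)
        exp_freq = np.diff(cdf) * len(counts)
        chi2 = ((obs_freq - exp_freq) ** 2 / exp_freq).sum()
        p = stats.chi2.sf(chi2, len(obs_freq) - 1)
        assert p > 0.01


class TestTrackGenerator:
    def test_frame_count_and_containment(self):
        cfg = wa.TrackSimConfig(duration_s=600.0, arena_radius_mm=5.0)
        tracks = wa.simulate_tracks(cfg, 3, seed=1)
        for tr in tracks:
            assert len(tr) == 1800
            assert np.all(np.hypot(tr.x_mm, tr.y_mm) <= 5.0 + 1e-9)

    def test_dwell_only_displacement(self):
        cfg = wa.TrackSimConfig(
            duration_s=200.0,
            state_transition_probs=((1.0, 0.0), (1.0, 0.0)),
            dwell_speed=(0.02, 0.0),
        )
        (tr,) = wa.simulate_tracks(cfg, 1, seed=2)
        steps = np.hypot(np.diff(tr.x_mm), np.diff(tr.y_mm))
        assert steps.mean() == pytest.approx(0.02 / 3.0, rel=1e-9)
        assert tr.true_state.sum() == 0

    def test_roam_only_straight_path(self):
        cfg = wa.TrackSimConfig(
            duration_s=100.0,
            state_transition_probs=((0.0, 1.0), (0.0, 1.0)),
            roam_speed=(0.15, 0.0),
            roam_turn_sd=0.0,
            arena_radius_mm=1000.0,  # no reflections
        )
        (tr,) = wa.simulate_tracks(cfg, 1, seed=3)
        total = np.hypot(np.diff(tr.x_mm), np.diff(tr.y_mm)).sum()
        assert total == pytest.approx(0.15 * 100.0, rel=0.01)
        av = wa.angular_velocity(tr)
        # arccos loses ~sqrt(eps) precision near zero turn
        assert np.nanmax(np.abs(av)) < 1e-4

    def test_symmetric_switching_occupancy(self):
        cfg = wa.TrackSimConfig(
            duration_s=5400.0,
            state_transition_probs=((0.99, 0.01), (0.01, 0.99)),
        )
        tracks = wa.simulate_tracks(cfg, 5, seed=4)
        occ = np.mean([tr.true_state.mean() for tr in tracks])
        assert occ == pytest.approx(0.5, abs=0.06)

    def test_default_stationary_occupancy(self):
        cfg = wa.TrackSimConfig()
        assert cfg.stationary_roam == pytest.approx(0.30)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ConfigError):
            wa.TrackSimConfig(state_transition_probs=((0.9, 0.2), (0.1, 0.9)))

    def test_worm_substreams_reproducible(self):
        cfg = wa.TrackSimConfig(duration_s=60.0)
        both = wa.simulate_tracks(cfg, 2, seed=9)
        again = wa.simulate_tracks(cfg, 2, seed=9)
        assert np.array_equal(both[1].x_mm, again[1].x_mm)


class TestGridGenerator:
    def test_poisson_moments(self):
        obs = wa.simulate_grid_counts(
            {"N2": 20.0}, ZERO, n_worms_per_day=1000, n_days=1, seed=1
        )
        scores = np.array([o.score for o in obs])
        assert scores.mean() == pytest.approx(20.0, abs=0.5)
        assert scores.var() / scores.mean() == pytest.approx(1.0, abs=0.15)

    def test_rate_ratio_preserved(self):
        obs = wa.simulate_grid_counts(
            {"a": 10.0, "b": 20.0}, ZERO, n_worms_per_day=2000, n_days=1, seed=2
        )
        means = {}
        for s in ("a", "b"):
            means[s] = np.mean([o.score for o in obs if o.strain_id == s])
        assert means["b"] / means["a"] == pytest.approx(2.0, abs=0.1)

    def test_day_variance_overdisperses(self):
        obs = wa.simulate_grid_counts(
            {"N2": 20.0},
            wa.VarianceComponents(sd_day=0.5),
            n_worms_per_day=200,
            n_days=60,
            seed=3,
        )
        scores = np.array([o.score for o in obs])
        # lognormal mixing: Var/mean = 1 + mu (e^{s^2} - 1) >> 1.2
        assert scores.var() / scores.mean() > 1.2

    def test_truncation_at_grid_capacity(self):
        obs = wa.simulate_grid_counts(
            {"N2": 5000.0}, ZERO, n_worms_per_day=10, n_days=1, seed=4
        )
        assert all(o.score <= 1880 for o in obs)

    def test_positive_rates_required(self):
        with pytest.raises(ConfigError):
            wa.simulate_grid_counts({"N2": 0.0}, ZERO, 5, 1, seed=0)
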
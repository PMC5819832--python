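"""Pre-registered study presets: calibration, recovery and error-rate runs.

These functions bundle the package's standard validation experiments at
fixed design sizes (the assay design they emulate is three groups with 6
plates over 3 days at ~50 animals per plate; tracking runs are 90 min at 3
frames/s).  Each returns a flat dict of named quantities so the same runs
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy import stats

from .core import VarianceComponents
from .comparison import ComparisonCondition, run_comparison
from .inference import fit_binomial_glmm, fit_bayes_binomial_glmm, fit_poisson_glmm
from .simulate import (
    SimulationScenario,
    TrackSimConfig,
    simulate_assay_dataset,
    simulate_grid_counts,
    simulate_tracks,
)
from .tracking import ClassifierConfig, Track, angular_velocity, bin_track, fraction_roaming, grid_entry_score, realize_grid
from .tracking import GridConfig

__all__ = [
    "simulator_calibration",
    "glmm_recovery",
    "bayes_coverage",
    "error_rate_study",
    "tracking_checks",
    "roam_dwell_recovery",
    "grid_scoring_checks",
    "poisson_recovery",
]


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulator_calibration(seed: int, n_plates: int = 10_000, n: int = 100) -> dict:
    """Null assay generator vs exact Binomial(n, 1/2): mean, sd, GOF."""
    scenario = SimulationScenario(
        group_logits={"control": 0.0},
        n_days=1,
        plates_per_group=n_plates,
        animals_per_plate=n,
    )
    ds = simulate_assay_dataset(scenario, VarianceComponents(), seed)
    counts = np.array([o.n_dauer for o in ds.observations])
    props = counts / n
    edges = np.array([-0.5, 39.5, 44.5, 47.5, 50.5, 53.5, 56.5, 60.5, n + 0.5])
    obs_freq, _ = np.histogram(counts, bins=edges)
    exp_freq = np.diff(stats.binom.cdf(edges, n, 0.5)) * n_plates
    chi2 = float(((obs_freq - exp_freq) ** 2 / exp_freq).sum())
    gof_p = float(stats.chi2.sf(chi2, len(obs_freq) - 1))
    return {
        "mean_proportion": float(props.mean()),
        "sd_proportion": float(props.std()),
        "gof_p": gof_p,
        "n_plates": n_plates,
    }


def glmm_recovery(
    seed: int, n_reps: int = 200, true_contrast: float = 1.0
) -> dict:
    """Frequentist GLMM on the 3-group/6-plate/3-day design, sD = 0.5."""
    scenario = SimulationScenario(
        group_logits={"control": 0.0, "g1": true_contrast, "g2": 0.0}
    )
    variance = VarianceComponents(sd_day=0.5)
    estimates, covered = [], 0
    for ssq in np.random.SeedSequence(seed).spawn(n_reps):
        ds = simulate_assay_dataset(scenario, variance, ssq)
        c = fit_binomial_glmm(ds).contrast("g1")
        estimates.append(c.estimate)
        covered += c.ci95[0] <= true_contrast <= c.ci95[1]
    return {
        "mean_estimate": float(np.mean(estimates)),
        "sd_estimate": float(np.std(estimates)),
        "wald_coverage_95": covered / n_reps,
        "n_reps": n_reps,
    }


def bayes_coverage(
    seed: int,
    n_reps: int = 50,
    true_contrast: float = 1.0,
    draws: int = 500,
    chains: int = 2,
) -> dict:
    """Bayesian GLMM credible-interval coverage at reduced draws, plus the
    strong-data agreement with the Laplace ML estimate."""
    scenario = SimulationScenario(
        group_logits={"control": 0.0, "g1": true_contrast, "g2": 0.0}
    )
    variance = VarianceComponents(sd_day=0.5)
    covered = n_conv = 0
    for ssq in np.random.SeedSequence(seed).spawn(n_reps):
        ds = simulate_assay_dataset(scenario, variance, ssq)
        fit = fit_bayes_binomial_glmm(
            ds, draws=draws, chains=chains, seed=_spawn_seed(ssq)
        )
        lo, hi = fit.contrast("g1").ci95
        covered += lo <= true_contrast <= hi
        n_conv += fit.converged
    big = SimulationScenario(
        group_logits={"control": 0.0, "g1": true_contrast},
        n_days=4,
        plates_per_group=200,
        animals_per_plate=100,
    )
    ds_big = simulate_assay_dataset(big, VarianceComponents(), seed + 1)
    ml = fit_binomial_glmm(ds_big).contrast("g1").estimate
    post = fit_bayes_binomial_glmm(
        ds_big, draws=draws, chains=chains, seed=seed + 2
    ).contrast("g1").estimate
    return {
        "credible_coverage_95": covered / n_reps,
        "n_converged": n_conv,
        "n_reps": n_reps,
        "strong_data_disagreement_logit": abs(post - ml),
    }


def error_rate_study(
    seed: int,
    n_reps: int = 200,
    methods: Iterable[str] = ("welch", "anova", "glmm", "bayes"),
) -> dict:
    """Per-comparison type-I error of the four methods under the stressed
    condition (high variance, unbalanced, control day-bias) and the benign
    one (zero variance, balanced)."""
    conds = [
        ComparisonCondition(
            variance="high",
            balanced=False,
            bias_fraction=1 / 3,
            scenario="null_all_equal",
            n_reps=n_reps,
            name="stressed",
        ),
        ComparisonCondition(
            variance="zero",
            balanced=True,
            scenario="null_all_equal",
            n_reps=n_reps,
            name="benign",
        ),
    ]
    result = run_comparison(conds, methods=methods, seed=seed)
    frame = result.to_frame()
    out: dict = {"n_reps": n_reps}
    for _, row in frame.iterrows():
        out[f"type1_{row['condition']}_{row['method']}"] = row["type_I_rate"]
        out[f"nconv_{row['condition']}_{row['method']}"] = row["n_converged"]
    out["mc_se"] = math.sqrt(0.05 * 0.95 / n_reps)
    return out


def _path_track(points, fps=3.0) -> Track:
    pts = np.asarray(points, dtype=float)
    return Track(
        worm_id="probe",
        fps=fps,
        t_s=np.arange(len(pts)) / fps,
        x_mm=pts[:, 0],
        y_mm=pts[:, 1],
    )


def tracking_checks() -> dict:
    """Exactness of the turn-angle computation and the 10-s binning."""
    probes = {
        0.0: [(0, 0), (1, 0), (2, 0)],
        90.0: [(0, 0), (1, 0), (1, 1)],
        180.0: [(0, 0), (1, 0), (0, 0)],
    }
    worst = 0.0
    for expected, pts in probes.items():
        got = angular_velocity(_path_track(pts))[0]
        worst = max(worst, abs(got - expected))
    heading = np.cumsum(np.full(40, math.radians(15.0)))
    steps = 0.05 * np.column_stack([np.cos(heading), np.sin(heading)])
    poly = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    got = angular_velocity(_path_track(poly))
    worst = max(worst, float(np.max(np.abs(got - 15.0))))
    (track,) = simulate_tracks(TrackSimConfig(), 1, seed=0)
    n_bins = len(bin_track(track))
    return {"max_angle_error_deg": worst, "bins_90min": n_bins}


def roam_dwell_recovery(seed: int, n_worms: int = 20) -> dict:
    """Two-state tracks at the default parameters (roam occupancy 0.30):
    roaming-fraction error and bin-label accuracy vs ground truth."""
    cfg = TrackSimConfig()
    clf = ClassifierConfig()
    tracks = simulate_tracks(cfg, n_worms, seed)
    nb = int(round(clf.bin_seconds * cfg.fps))
    all_bins = []
    agree = total = 0
    true_occ = []
    for tr in tracks:
        bins = bin_track(tr, clf)
        all_bins.extend(bins)
        true_occ.append(tr.true_state.mean())
        for k, b in enumerate(bins):
            if b.label == "undefined":
                continue
            truth = "roam" if tr.true_state[k * nb : (k + 1) * nb].mean() > 0.5 else "dwell"
            agree += b.label == truth
            total += 1
    est = fraction_roaming(all_bins)
    return {
        "roaming_fraction_estimate": float(est),
        "roaming_fraction_truth": cfg.stationary_roam,
        "bin_label_accuracy": agree / total,
        "n_worms": n_worms,
    }


def grid_scoring_checks() -> dict:
    """Constructed-path grid-entry scores and upsampling invariance."""
    cfg = GridConfig()
    s, _ = realize_grid(cfg)
    stationary = grid_entry_score(_path_track([(0.3, 0.2)] * 10), cfg).total
    xs = np.array([(-2 + k) * s + s / 4 for k in range(5)])
    row = np.column_stack([xs, np.full_like(xs, s / 4)])
    five = grid_entry_score(_path_track(row), cfg).total
    a, b = (s / 4, s / 4), (-s / 4, s / 4)
    osc = grid_entry_score(_path_track([a, b] * 15), cfg).total
    fine = []
    for p, q in zip(row[:-1], row[1:]):
        for t in np.linspace(0, 1, 10, endpoint=False):
            fine.append(p + t * (q - p))
    fine.append(row[-1])
    upsampled = grid_entry_score(_path_track(np.array(fine), fps=30.0), cfg).total
    return {
        "score_stationary": stationary,
        "score_five_cells": five,
        "score_oscillation_capped": osc,
        "upsampling_invariant": upsampled == five,
    }


def poisson_recovery(seed: int, n_worms_per_day: int = 100, n_days: int = 3) -> dict:
    """Poisson GLMM rate-ratio recovery on simulated grid counts."""
    obs = simulate_grid_counts(
        {"control": 20.0, "mut": 40.0},
        VarianceComponents(sd_day=0.3),
        n_worms_per_day=n_worms_per_day,
        n_days=n_days,
        seed=seed,
    )
    fit = fit_poisson_glmm(obs)
    return {
        "rate_ratio_estimate": fit.diagnostics["rate_ratios"]["mut/control"],
        "true_ratio": 2.0,
        "n_worms": n_worms_per_day * n_days * 2,
    }
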
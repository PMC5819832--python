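"""Synthetic-data generators for assay plates, exploration counts and tracks.

The assay generator draws clustered binomial outcomes on the logit scale:

    logit Pr(dauer) = beta_strain + d_day + g_strain.day + e_plate

with ``d ~ N(0, sd_day^2)`` shared by all strains on a day, ``g ~ N(0,
sd_history^2)`` independent per strain-by-day (culture-history batches push
strains in different directions on the same day), and ``e ~ N(0,
sd_plate^2)`` per plate.  An optional systematic-bias condition shifts the
control group's day effect on a subset of days, mimicking runs where control
plates drift together.

The track generator emulates the two locomotor states of adult worms on
food: roaming (fast, nearly straight) and dwelling (slow, high turning).
The hidden state follows a two-state Markov chain per frame; heading
performs a Gaussian random walk whose step size depends on state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .core import (
    AssayDataset,
    AssayObservation,
    GridCountObservation,
    VarianceComponents,
)
from .errors import ConfigError
from .tracking import Track

__all__ = [
    "SimulationScenario",
    "TrackSimConfig",
    "simulate_assay_dataset",
    "simulate_grid_counts",
    "simulate_tracks",
]


@dataclass
class SimulationScenario:
    """Design of one simulated dauer-assay dataset.

    ``group_logits`` maps strain name to its true log-odds of dauer entry;
    the first entry is the control.  With ``balanced=False`` the control is
    run on every day while each test group is absent on one day and its
    plates are reallocated evenly across the remaining days.  On
    ``ceil(bias_fraction * n_days)`` randomly chosen days the control day
    effect is shifted by ``bias_scale * sd_day`` (systematic control bias).
    """

    group_logits: Mapping[str, float]
    n_days: int = 3
    plates_per_group: int = 6
    balanced: bool = True
    bias_fraction: float = 0.0
    bias_scale: float = 1.0
    animals_per_plate: int | tuple[int, int] = 50

    def __post_init__(self) -> None:
        if len(self.group_logits) < 1:
            raise ConfigError("at least one group (the control) is required")
        if self.n_days < 1 or self.plates_per_group < 1:
            raise ConfigError("n_days and plates_per_group must be positive")
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ConfigError("bias_fraction must lie in [0, 1]")
        if self.balanced and self.plates_per_group % self.n_days:
            raise ConfigError(
                "balanced design needs plates_per_group divisible by n_days"
            )
        if self.n_days == 1 and not self.balanced:
            raise ConfigError("unbalanced design needs at least 2 days")

    @property
    def control(self) -> str:
        return next(iter(self.group_logits))


def _plate_sizes(
    scenario: SimulationScenario, rng: np.random.Generator, k: int
) -> np.ndarray:
    spec = scenario.animals_per_plate
    if isinstance(spec, tuple):
        lo, hi = spec
        return rng.integers(lo, hi + 1, size=k)
    return np.full(k, int(spec))


def _allocation(scenario: SimulationScenario) -> dict[str, list[int]]:
    """Per strain, the day index of each of its plates."""
    strains = list(scenario.group_logits)
    days = list(range(scenario.n_days))
    out: dict[str, list[int]] = {}
    for gi, strain in enumerate(strains):
        if scenario.balanced or gi == 0:
            per_day = scenario.plates_per_group // scenario.n_days
            rem = scenario.plates_per_group % scenario.n_days
            alloc = []
            for j in days:
                alloc.extend([j] * (per_day + (1 if j < rem else 0)))
        else:
            # test group gi is absent on one day; plates spread over the rest
            missing = (gi - 1) % scenario.n_days
            present = [j for j in days if j != missing]
            alloc = []
            for i in range(scenario.plates_per_group):
                alloc.append(present[i % len(present)])
            alloc.sort()
        out[strain] = alloc
    return out


def simulate_assay_dataset(
    scenario: SimulationScenario,
    variance: VarianceComponents,
    seed: int | np.random.SeedSequence,
) -> AssayDataset:
    """Draw one clustered-binomial assay dataset; deterministic given seed."""
    rng = np.random.default_rng(seed)
    strains = list(scenario.group_logits)
    n_days = scenario.n_days

    day_eff = rng.normal(0.0, variance.sd_day, size=n_days)
    hist_eff = {
        (s, j): rng.normal(0.0, variance.sd_history)
        for s in strains
        for j in range(n_days)
    }
    n_bias = math.ceil(scenario.bias_fraction * n_days)
    bias_days = (
        sorted(rng.choice(n_days, size=n_bias, replace=False).tolist())
        if n_bias
        else []
    )
    bias_offset = scenario.bias_scale * variance.sd_day

    alloc = _allocation(scenario)
    observations: list[AssayObservation] = []
    plate_counter: dict[int, int] = {j: 0 for j in range(n_days)}
    for strain in strains:
        days_here = alloc[strain]
        sizes = _plate_sizes(scenario, rng, len(days_here))
        for j, n_total in zip(days_here, sizes):
            eta = (
                scenario.group_logits[strain]
                + day_eff[j]
                + hist_eff[(strain, j)]
                + rng.normal(0.0, variance.sd_plate)
            )
            if strain == scenario.control and j in bias_days:
                eta += bias_offset
            n_dauer = int(rng.binomial(int(n_total), expit(eta)))
            plate_counter[j] += 1
            observations.append(
                AssayObservation(
                    strain_id=strain,
                    day_id=f"day{j + 1}",
                    plate_id=f"p{plate_counter[j]:03d}",
                    n_total=int(n_total),
                    n_dauer=n_dauer,
                )
            )
    truth = {
        "group_logits": dict(scenario.group_logits),
        "variance": variance.as_tuple(),
        "day_effects": day_eff.tolist(),
        "bias_days": bias_days,
        "bias_offset": bias_offset if bias_days else 0.0,
        "balanced": scenario.balanced,
    }
    return AssayDataset(
        observations=observations,
        control_strain=scenario.control,
        design_note="simulated",
        truth=truth,
    )


def simulate_grid_counts(
    rates: Mapping[str, float],
    variance: VarianceComponents,
    n_worms_per_day: int,
    n_days: int,
    seed: int | np.random.SeedSequence,
    cap_total: int = 188 * 10,
) -> list[GridCountObservation]:
    """Simulate grid-entry exploration scores.

    Each worm sits on its own plate, so the plate-level effect is drawn per
    worm: score ~ Poisson(exp(log rate + d_day + e_worm)), truncated at the
    maximum attainable grid score (cells x per-cell cap).
    """
    for s, r in rates.items():
        if r <= 0:
            raise ConfigError(f"rate for {s!r} must be positive")
    if n_worms_per_day < 1 or n_days < 1:
        raise ConfigError("n_worms_per_day and n_days must be positive")
    rng = np.random.default_rng(seed)
    day_eff = rng.normal(0.0, variance.sd_day, size=n_days)
    out: list[GridCountObservation] = []
    worm_counter = 0
    for strain, rate in rates.items():
        for j in range(n_days):
            e = rng.normal(0.0, variance.sd_plate, size=n_worms_per_day)
            lam = np.exp(math.log(rate) + day_eff[j] + e)
            scores = np.minimum(rng.poisson(lam), cap_total)
            for s in scores:
                worm_counter += 1
                out.append(
                    GridCountObservation(
                        strain_id=strain,
                        day_id=f"day{j + 1}",
                        worm_id=f"w{worm_counter:04d}",
                        score=int(s),
                    )
                )
    return out


@dataclass
class TrackSimConfig:
    """Parameters of the two-state locomotion generator.

    Defaults emulate the live-tracking assay: 90 min recorded at 3 frames/s
    on a 3.5 cm plate.  Transition probabilities are per frame; the default
    pair gives stationary roaming occupancy 0.30 with mean state durations of
    a few minutes.  Speeds are (mean, sd) in mm/s; turning is a per-frame
    Gaussian heading increment in degrees.
    """

    fps: float = 3.0
    duration_s: float = 5400.0
    #: rows: from-state (0=dwell, 1=roam); columns: to-state
    state_transition_probs: tuple[tuple[float, float], tuple[float, float]] = (
        (0.9985, 0.0015),
        (0.0035, 0.9965),
    )
    dwell_speed: tuple[float, float] = (0.02, 0.005)
    roam_speed: tuple[float, float] = (0.15, 0.02)
    dwell_turn_sd: float = 50.0
    roam_turn_sd: float = 5.0
    arena_radius_mm: float = 15.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigError("fps and duration_s must be positive")
        P = np.asarray(self.state_transition_probs, dtype=float)
        if P.shape != (2, 2) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ConfigError("state_transition_probs must be 2x2 row-stochastic")
        if min(self.dwell_speed[0], self.roam_speed[0]) < 0:
            raise ConfigError("speeds must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.state_transition_probs, dtype=float)

    @property
    def stationary_roam(self) -> float:
        """Stationary probability of the roaming state."""
        p_dr = self.matrix[0, 1]
        p_rd = self.matrix[1, 0]
        if p_dr + p_rd == 0:
            return 0.5
        return p_dr / (p_dr + p_rd)


def _simulate_one_track(
    config: TrackSimConfig, worm_id: str, rng: np.random.Generator
) -> Track:
    n_frames = int(math.floor(config.fps * config.duration_s))
    dt = 1.0 / config.fps
    P = config.matrix
    R = config.arena_radius_mm

    # hidden state path
    state = np.empty(n_frames, dtype=np.int8)
    state[0] = rng.random() < config.stationary_roam
    u = rng.random(n_frames - 1)
    for i in range(1, n_frames):
        state[i] = u[i - 1] < P[state[i - 1], 1]

    speed_mean = np.where(state, config.roam_speed[0], config.dwell_speed[0])
    speed_sd = np.where(state, config.roam_speed[1], config.dwell_speed[1])
    turn_sd = np.where(state, config.roam_turn_sd, config.dwell_turn_sd)

    steps = np.maximum(rng.normal(speed_mean, speed_sd), 0.0) * dt
    turns = np.deg2rad(rng.normal(0.0, turn_sd))

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    r0 = R * 0.5 * math.sqrt(rng.random())
    th0 = rng.uniform(0, 2 * math.pi)
    x[0], y[0] = r0 * math.cos(th0), r0 * math.sin(th0)
    heading = rng.uniform(0, 2 * math.pi)
    for i in range(1, n_frames):
        heading += turns[i]
        nx = x[i - 1] + steps[i] * math.cos(heading)
        ny = y[i - 1] + steps[i] * math.sin(heading)
        r = math.hypot(nx, ny)
        if r > R:  # fold radially back inside the arena
            scale = (2 * R - r) / r
            nx *= scale
            ny *= scale
            heading = math.atan2(ny - y[i - 1], nx - x[i - 1])
        x[i], y[i] = nx, ny
    t = np.arange(n_frames) * dt
    return Track(
        worm_id=worm_id,
        fps=config.fps,
        t_s=t,
        x_mm=x,
        y_mm=y,
        true_state=state.astype(int),
    )


def simulate_tracks(
    config: TrackSimConfig,
    n_worms: int,
    seed: int | np.random.SeedSequence,
) -> list[Track]:
    """Simulate two-state worm tracks with ground-truth state labels.

    Positions are folded back radially when a step would leave the circular
    arena.  Each worm uses an independent child stream of ``seed``, so worm k
    is reproducible in isolation.
    """
    if n_worms < 1:
        raise ConfigError("n_worms must be positive")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(n_worms)
    return [
        _simulate_one_track(config, f"worm{i + 1:03d}", np.random.default_rng(c))
        for i, c in enumerate(children)
    ]
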
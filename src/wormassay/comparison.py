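"""Simulation study comparing four analysis methods on clustered assays.

For each condition (variance preset x balance x control bias x scenario),
replicate datasets are drawn with three groups (a control and two test
genotypes, 6 plates over 3 days each) and analyzed with Welch t-tests,
ANOVA, the frequentist binomial GLMM and the Bayesian binomial GLMM, all
with control-vs-genotype contrasts.  Under the all-equal scenario the
fraction of rejected comparisons is the per-comparison type-I error; under
the one-effect scenario (one genotype shifted by 1 logit) the fraction of
replicates missing the shifted genotype is the type-II error.

Rejection is per-comparison by default (raw p < alpha for the frequentist
methods; the central (1 - alpha) credible interval excluding zero for the
Bayesian fit).  Family-wise (adjusted) rejections are logged alongside so
rates can be recomputed at any alpha without refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import VarianceComponents, VARIANCE_PRESETS
from .errors import ConfigError
from .inference import (
    ContrastSpec,
    anova_prop,
    fit_bayes_binomial_glmm,
    fit_binomial_glmm,
    welch_prop_test,
)
from .simulate import SimulationScenario, simulate_assay_dataset

__all__ = [
    "ComparisonCondition",
    "MethodComparisonResult",
    "run_comparison",
    "summarize_comparison",
    "METHODS",
]

METHODS = ("welch_t", "anova", "glmm_binomial", "bayes_glmm_binomial")
_ALIASES = {
    "welch": "welch_t",
    "glmm": "glmm_binomial",
    "bayes": "bayes_glmm_binomial",
}
EFFECT_LOGIT = 1.0  # the simulated genotype effect, on the log-odds scale


@dataclass
class ComparisonCondition:
    """One cell of the simulation-study grid."""

    variance: VarianceComponents | str = "low"
    balanced: bool = True
    bias_fraction: float = 0.0
    scenario: str = "null_all_equal"  # or "one_effect_logit1"
    n_reps: int = 1000
    alpha: float = 0.05
    animals_per_plate: int = 50
    baseline_logit: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.variance, str):
            if self.variance not in VARIANCE_PRESETS:
                raise ConfigError(f"unknown variance preset {self.variance!r}")
            self.variance = VARIANCE_PRESETS[self.variance]
        if self.scenario not in ("null_all_equal", "one_effect_logit1"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.n_reps < 1:
            raise ConfigError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if not self.name:
            v = self.variance
            self.name = (
                f"{self.scenario}|sD{v.sd_day:g}_sP{v.sd_plate:g}_sG{v.sd_history:g}"
                f"|{'bal' if self.balanced else 'unbal'}|bias{self.bias_fraction:g}"
            )

    def scenario_groups(self) -> dict[str, float]:
        b = self.baseline_logit
        eff = EFFECT_LOGIT if self.scenario == "one_effect_logit1" else 0.0
        return {"control": b, "g1": b + eff, "g2": b}


@dataclass
class MethodComparisonResult:
    """Error rates per condition and method, plus the replicate-level log."""

    rows: list[dict[str, Any]]
    log: pd.DataFrame
    seed: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def rates_at_alpha(
        self, alpha: float, family_wise: bool = False
    ) -> pd.DataFrame:
        """Recompute error rates from the stored log without refitting."""
        col = "p_family" if family_wise else "p_comparison"
        out = []
        for (cond, scen, method), g in self.log.groupby(
            ["condition", "scenario", "method"], sort=False
        ):
            g_ok = g[g["converged"]]
            if scen == "null_all_equal":
                rate = float((g_ok[col] < alpha).mean())
                kind = "type_I"
            else:
                eff = g_ok[g_ok["strain"] == "g1"]
                rate = float((eff[col] >= alpha).mean())
                kind = "type_II"
            out.append(
                {
                    "condition": cond,
                    "method": method,
                    "metric": kind,
                    "alpha": alpha,
                    "rate": rate,
                }
            )
        return pd.DataFrame(out)


def _canonical_methods(methods: Iterable[str]) -> list[str]:
    out = []
    for m in methods:
        m = _ALIASES.get(m, m)
        if m not in METHODS:
            raise ConfigError(f"unknown method {m!r}")
        out.append(m)
    if not out:
        raise ConfigError("at least one method is required")
    return out


def _fit_one(method: str, dataset, spec, bayes_draws, bayes_chains, rep_seed):
    if method == "welch_t":
        return welch_prop_test(dataset, spec)
    if method == "anova":
        return anova_prop(dataset, spec)
    if method == "glmm_binomial":
        return fit_binomial_glmm(dataset, contrasts=spec)
    return fit_bayes_binomial_glmm(
        dataset,
        draws=bayes_draws,
        chains=bayes_chains,
        seed=rep_seed,
        contrasts=spec,
    )


def run_comparison(
    conditions: Sequence[ComparisonCondition],
    methods: Iterable[str] = METHODS,
    seed: int = 0,
    bayes_draws: int = 500,
    bayes_chains: int = 2,
    max_failure_fraction: float = 0.10,
) -> MethodComparisonResult:
    """Run the full simulation study; deterministic given ``seed``.

    Each replicate draws one dataset (shared by all methods) from a child
    stream of ``seed``.  Replicates where a method fails to converge are
    excluded from that method's rates and counted in ``n_converged``.  A
    method crashing on more than ``max_failure_fraction`` of replicates
    aborts the study with diagnostics.
    """
    methods = _canonical_methods(methods)
    root = np.random.SeedSequence(seed)
    cond_streams = root.spawn(len(conditions))
    log_rows: list[dict[str, Any]] = []
    crash_info: dict[str, int] = {m: 0 for m in methods}

    for cond, stream in zip(conditions, cond_streams):
        scenario = SimulationScenario(
            group_logits=cond.scenario_groups(),
            n_days=3,
            plates_per_group=6,
            balanced=cond.balanced,
            bias_fraction=cond.bias_fraction,
            animals_per_plate=cond.animals_per_plate,
        )
        spec = ContrastSpec(scheme="dunnett_vs_control", control="control")
        rep_streams = stream.spawn(cond.n_reps)
        for rep, rep_stream in enumerate(rep_streams):
            data_ss, bayes_ss = rep_stream.spawn(2)
            dataset = simulate_assay_dataset(scenario, cond.variance, data_ss)
            bayes_seed = int(bayes_ss.generate_state(1)[0] % (2**31))
            for method in methods:
                try:
                    fit = _fit_one(
                        method, dataset, spec, bayes_draws, bayes_chains,
                        bayes_seed,
                    )
                except Exception as err:  # logged; hard failure if frequent
                    crash_info[method] += 1
                    if crash_info[method] > max_failure_fraction * cond.n_reps:
                        raise RuntimeError(
                            f"method {method} failed on >"
                            f"{max_failure_fraction:.0%} of replicates; "
                            f"last error: {err!r}"
                        ) from err
                    continue
                for c in fit.contrasts:
                    log_rows.append(
                        {
                            "condition": cond.name,
                            "scenario": cond.scenario,
                            "method": method,
                            "rep": rep,
                            "strain": c.strain_a,
                            "p_comparison": c.p_raw,
                            "p_family": c.p_adj,
                            "estimate": c.estimate,
                            "converged": fit.converged,
                            "degenerate": c.degenerate,
                        }
                    )

    log = pd.DataFrame(log_rows)
    rows = []
    for cond in conditions:
        sub = log[log["condition"] == cond.name]
        for method in methods:
            g = sub[sub["method"] == method]
            n_reps_seen = g["rep"].nunique()
            g_ok = g[g["converged"]]
            n_conv = g_ok["rep"].nunique()
            if cond.scenario == "null_all_equal":
                t1 = float((g_ok["p_comparison"] < cond.alpha).mean())
                t2 = math.nan
            else:
                eff = g_ok[g_ok["strain"] == "g1"]
                t2 = float((eff["p_comparison"] >= cond.alpha).mean())
                t1 = math.nan
            rows.append(
                {
                    "condition": cond.name,
                    "scenario": cond.scenario,
                    "method": method,
                    "type_I_rate": t1,
                    "type_II_rate": t2,
                    "mc_se_type_I": (
                        math.sqrt(max(t1 * (1 - t1), 0.0) / cond.n_reps)
                        if not math.isnan(t1)
                        else math.nan
                    ),
                    "mc_se_type_II": (
                        math.sqrt(max(t2 * (1 - t2), 0.0) / cond.n_reps)
                        if not math.isnan(t2)
                        else math.nan
                    ),
                    "n_reps": cond.n_reps,
                    "n_converged": n_conv,
                    "n_crashed": crash_info[method],
                    "n_degenerate": int(g["degenerate"].sum()),
                    "alpha": cond.alpha,
                }
            )
    return MethodComparisonResult(rows=rows, log=log, seed=seed)


def summarize_comparison(
    result: MethodComparisonResult,
    path: str | Path,
    heatmap: bool = False,
) -> pd.DataFrame:
    """Write the rates table as CSV (plus an optional heatmap figure)."""
    frame = result.to_frame()
    path = Path(path)
    frame.to_csv(path, index=False)
    if heatmap:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric in ("type_I_rate", "type_II_rate"):
            pivot = frame.pivot_table(
                index="condition", columns="method", values=metric
            ).dropna(how="all")
            if pivot.empty:
                continue
            fig, ax = plt.subplots(
                figsize=(2 + pivot.shape[1], 1 + 0.5 * pivot.shape[0])
            )
            im = ax.imshow(pivot.to_numpy(), cmap="viridis", aspect="auto")
            ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=30)
            ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
            fig.colorbar(im, label=metric)
            fig.tight_layout()
            fig.savefig(path.with_suffix(f".{metric}.png"), dpi=120)
            plt.close(fig)
    return frame
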
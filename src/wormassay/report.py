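"""End-to-end pipeline orchestration, manifests and report rendering.

A run is described by a single configuration mapping (YAML/JSON on disk):
requested stages execute in dependency order, every stochastic stage gets a
seed derived from the root seed, and a manifest records inputs, outputs
(with content hashes), per-stage timing and the hash of the merged
configuration, so identical config + seed reproduces identical manifests
for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    VarianceComponents,
    VARIANCE_PRESETS,
    config_hash,
    read_assay_table,
    write_assay_table,
    write_grid_table,
    write_results,
)
from .errors import ConfigError, WormAssayError
from .inference import (
    ContrastSpec,
    anova_prop,
    fit_bayes_binomial_glmm,
    fit_binomial_glmm,
    welch_prop_test,
)
from .comparison import (
    ComparisonCondition,
    run_comparison,
    summarize_comparison,
)
from .simulate import (
    SimulationScenario,
    TrackSimConfig,
    simulate_assay_dataset,
    simulate_grid_counts,
    simulate_tracks,
)
from .tracking import (
    ClassifierConfig,
    bin_track,
    fraction_roaming,
    read_track_table,
    write_track_table,
)

__all__ = ["run_pipeline", "render_report"]

STAGE_ORDER = (
    "simulate_assays",
    "simulate_tracks",
    "simulate_grid",
    "fit",
    "track_analyze",
    "compare_methods",
    "report",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _variance_from(cfg: Mapping[str, Any]) -> VarianceComponents:
    v = cfg.get("variance", "low")
    if isinstance(v, str):
        if v not in VARIANCE_PRESETS:
            raise ConfigError(f"unknown variance preset {v!r}")
        return VARIANCE_PRESETS[v]
    if isinstance(v, Mapping):
        return VarianceComponents(**v)
    sd, sp, sg = v
    return VarianceComponents(sd, sp, sg)


def _stage_simulate_assays(cfg, out_dir: Path, seed: int) -> list[Path]:
    scenario = SimulationScenario(
        group_logits=dict(cfg.get("groups", {"control": 0.0, "mutant": 1.0})),
        n_days=int(cfg.get("n_days", 3)),
        plates_per_group=int(cfg.get("plates_per_group", 6)),
        balanced=bool(cfg.get("balanced", True)),
        bias_fraction=float(cfg.get("bias_fraction", 0.0)),
        animals_per_plate=cfg.get("animals_per_plate", 50),
    )
    dataset = simulate_assay_dataset(scenario, _variance_from(cfg), seed)
    path = out_dir / "assays.csv"
    write_assay_table(dataset, path)
    return [path]


def _stage_simulate_tracks(cfg, out_dir: Path, seed: int) -> list[Path]:
    config = TrackSimConfig(
        fps=float(cfg.get("fps", 3.0)),
        duration_s=float(cfg.get("duration_s", 5400.0)),
        arena_radius_mm=float(cfg.get("arena_radius_mm", 15.0)),
    )
    tracks = simulate_tracks(config, int(cfg.get("n_worms", 5)), seed)
    path = out_dir / "tracks.csv"
    write_track_table(tracks, path)
    return [path]


def _stage_simulate_grid(cfg, out_dir: Path, seed: int) -> list[Path]:
    obs = simulate_grid_counts(
        rates=dict(cfg.get("rates", {"control": 20.0, "mutant": 40.0})),
        variance=_variance_from(cfg),
        n_worms_per_day=int(cfg.get("n_worms_per_day", 5)),
        n_days=int(cfg.get("n_days", 3)),
        seed=seed,
    )
    path = out_dir / "grid_counts.csv"
    write_grid_table(obs, path)
    return [path]


_FIT_METHODS = (
    "welch", "welch_t", "anova", "glmm", "glmm_binomial", "bayes",
    "bayes_glmm_binomial",
)


def _stage_fit(cfg, out_dir: Path, seed: int) -> list[Path]:
    method = cfg.get("method", "glmm")
    if method not in _FIT_METHODS:
        raise ConfigError(f"unknown fit method {method!r}")
    data_path = Path(cfg.get("data", out_dir / "assays.csv"))
    fmt = {}
    if cfg.get("control"):
        fmt["control_strain"] = cfg["control"]
    dataset = read_assay_table(data_path, fmt or None)
    spec = ContrastSpec(
        scheme=cfg.get("contrasts", "dunnett_vs_control"),
        control=dataset.control_strain,
    )
    if method in ("welch", "welch_t"):
        fit = welch_prop_test(dataset, spec)
    elif method == "anova":
        fit = anova_prop(dataset, spec)
    elif method in ("glmm", "glmm_binomial"):
        fit = fit_binomial_glmm(dataset, contrasts=spec)
    else:
        fit = fit_bayes_binomial_glmm(
            dataset,
            draws=int(cfg.get("draws", 1000)),
            chains=int(cfg.get("chains", 2)),
            seed=seed,
            contrasts=spec,
        )
    path = out_dir / f"fit_{method}.csv"
    write_results(fit, path)
    return [path, path.with_suffix(".csv.json")]


def _stage_track_analyze(cfg, out_dir: Path, seed: int) -> list[Path]:
    tracks = read_track_table(
        Path(cfg.get("tracks", out_dir / "tracks.csv")),
        fps=float(cfg.get("fps", 3.0)),
    )
    config = ClassifierConfig(
        slope=float(cfg.get("slope", 2.0)),
        bin_seconds=float(cfg.get("bin_seconds", 10.0)),
    )
    rows = []
    all_bins = []
    for tr in tracks:
        bins = bin_track(tr, config)
        all_bins.extend(bins)
        for b in bins:
            rows.append(
                {
                    "worm": tr.worm_id,
                    "t_start": b.t_start,
                    "mean_speed": b.mean_speed,
                    "mean_angular_velocity": b.mean_angular_velocity,
                    "label": b.label,
                }
            )
    bins_path = out_dir / "track_bins.csv"
    pd.DataFrame(rows).to_csv(bins_path, index=False)
    summary_path = out_dir / "roaming_summary.json"
    summary_path.write_text(
        json.dumps(
            {
                "n_worms": len(tracks),
                "n_bins": len(rows),
                "fraction_roaming": fraction_roaming(all_bins),
            },
            indent=1,
        )
    )
    return [bins_path, summary_path]


def _stage_compare_methods(cfg, out_dir: Path, seed: int) -> list[Path]:
    preset = cfg.get("preset", "s2table")
    reps = int(cfg.get("reps", 200))
    if preset == "s2table":
        conditions = []
        for var in ("low", "high"):
            for balanced in (True, False):
                for scenario in ("null_all_equal", "one_effect_logit1"):
                    conditions.append(
                        ComparisonCondition(
                            variance=var,
                            balanced=balanced,
                            bias_fraction=0.0 if balanced else 1 / 3,
                            scenario=scenario,
                            n_reps=reps,
                        )
                    )
    elif preset == "minimal":
        conditions = [
            ComparisonCondition(
                variance="zero", scenario="null_all_equal", n_reps=reps
            ),
            ComparisonCondition(
                variance="zero", scenario="one_effect_logit1", n_reps=reps
            ),
        ]
    else:
        raise ConfigError(f"unknown comparison preset {preset!r}")
    result = run_comparison(
        conditions,
        methods=cfg.get("methods", ("welch", "anova", "glmm", "bayes")),
        seed=seed,
        bayes_draws=int(cfg.get("bayes_draws", 500)),
        bayes_chains=int(cfg.get("bayes_chains", 2)),
    )
    path = out_dir / "method_comparison.csv"
    summarize_comparison(result, path, heatmap=bool(cfg.get("heatmap", False)))
    log_path = out_dir / "method_comparison_log.csv"
    result.log.to_csv(log_path, index=False)
    return [path, log_path]


_STAGES = {
    "simulate_assays": _stage_simulate_assays,
    "simulate_tracks": _stage_simulate_tracks,
    "simulate_grid": _stage_simulate_grid,
    "fit": _stage_fit,
    "track_analyze": _stage_track_analyze,
    "compare_methods": _stage_compare_methods,
}


def run_pipeline(config: Mapping[str, Any]) -> tuple[int, dict[str, Any]]:
    """Execute the requested stages; returns (exit status, manifest).

    Exit status 0 on success, 3 when a stage failed (partial outputs are
    retained and the failing stage is marked FAILED in the manifest).
    """
    out_dir = Path(config.get("out_dir", "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    root_seed = int(config.get("seed", 0))
    requested = list(config.get("stages", []))
    unknown = [s for s in requested if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}")
    ordered = [s for s in STAGE_ORDER if s in requested]

    manifest: dict[str, Any] = {
        "config": dict(config),
        "config_hash": config_hash(config),
        "seed": root_seed,
        "version": __version__,
        "stages": [],
    }
    status = 0
    ss = np.random.SeedSequence(root_seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGE_ORDER, ss.spawn(len(STAGE_ORDER)))
    }
    for name in ordered:
        if name == "report":
            continue  # rendered after the manifest is written
        t0 = time.perf_counter()
        entry: dict[str, Any] = {"name": name, "seed": stage_seeds[name]}
        try:
            outputs = _STAGES[name](
                config.get(name, {}), out_dir, stage_seeds[name]
            )
            entry["status"] = "ok"
            entry["outputs"] = {str(p): _sha256(Path(p)) for p in outputs}
        except WormAssayError:
            raise
        except Exception as err:
            entry["status"] = "FAILED"
            entry["error"] = repr(err)
            status = 3
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)
        if status:
            break
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    if "report" in ordered and status == 0:
        render_report(manifest_path)
    return status, manifest


def render_report(manifest_path: str | Path) -> Path:
    """Render a human-readable markdown summary (plus figures) of a run."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    out_dir = manifest_path.parent
    lines = [
        "# wormassay run report",
        "",
        f"- config hash: `{manifest['config_hash'][:16]}`",
        f"- root seed: {manifest['seed']}",
        "",
    ]
    stages = manifest.get("stages", [])
    if not stages:
        lines.append("No stages were executed.")
    for entry in stages:
        lines.append(f"## {entry['name']} ({entry['status']})")
        lines.append(f"- wall time: {entry.get('seconds', '?')} s")
        for path in entry.get("outputs", {}):
            lines.append(f"- output: `{path}`")
        lines.append("")
        if entry["status"] != "ok":
            lines.append(f"- error: {entry.get('error')}")
            continue
        for path in entry.get("outputs", {}):
            p = Path(path)
            if p.name.startswith("fit_") and p.suffix == ".csv":
                fig = _plot_fit(p, out_dir)
                if fig:
                    lines.append(f"![fit]({fig.name})")
            if p.name == "method_comparison.csv":
                frame = pd.read_csv(p)
                lines.append(frame.to_markdown(index=False))
            if p.name == "roaming_summary.json":
                lines.append(f"```\n{p.read_text()}\n```")
        lines.append("")
    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path


def _plot_fit(csv_path: Path, out_dir: Path) -> Path | None:
    """Per-strain scatter of plate proportions with 95%/75% interval bars."""
    sidecar = csv_path.with_suffix(".csv.json")
    if not sidecar.exists():
        return None
    meta = json.loads(sidecar.read_text())
    intervals = meta.get("intervals") or {}
    effects = meta.get("fixed_effects") or {}
    if not effects:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strains = list(effects)
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(strains), 3.2))
    for i, s in enumerate(strains):
        iv = intervals.get(s, {})
        if "95" in iv:
            ax.plot([i + 0.3] * 2, iv["95"], lw=1.5, color="0.6")
        if "75" in iv:
            ax.plot([i + 0.3] * 2, iv["75"], lw=4, color="0.75")
    ax.set_xticks(range(len(strains)), strains, rotation=30)
    ax.set_ylabel("response scale")
    ax.set_title(meta.get("method", "fit"))
    fig.tight_layout()
    out = out_dir / (csv_path.stem + ".png")
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
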
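"""Domain types and tabular I/O for plate-based assay data.

Dauer-formation assays produce clustered binomial data: each assay plate is a
cluster of animals, and the response is the count of dauers among animals
scored.  The unit row throughout the package is the plate; per-animal binary
rows are expanded internally only where a fitter requires them.

Variability among plates is described on the log-odds (logit) scale by three
standard deviations: day-to-day (``sd_day``), plate-to-plate (``sd_plate``)
and strain-culture-history (``sd_history``), the latter acting per strain and
day in independent directions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

__all__ = [
    "AssayObservation",
    "AssayDataset",
    "VarianceComponents",
    "GridCountObservation",
    "Contrast",
    "FitResult",
    "read_assay_table",
    "write_assay_table",
    "read_grid_table",
    "write_grid_table",
    "write_results",
    "read_results",
    "config_hash",
]

ASSAY_COLUMNS = ("strain", "day", "plate", "n_total", "n_dauer")
GRID_COLUMNS = ("strain", "day", "worm", "score")


@dataclass(frozen=True)
class AssayObservation:
    """One assay plate: dauers scored out of animals scored.

    ``dose`` is an optional pheromone concentration covariate used by the
    dose-response GLM; it is absent (None) for plain temperature assays.
    """

    strain_id: str
    day_id: str
    plate_id: str
    n_total: int
    n_dauer: int
    dose: float | None = None

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValidationError(
                f"plate {self.plate_id!r}: n_total must be >= 1, got {self.n_total}"
            )
        if not 0 <= self.n_dauer <= self.n_total:
            raise ValidationError(
                f"plate {self.plate_id!r}: n_dauer={self.n_dauer} outside "
                f"[0, n_total={self.n_total}]"
            )

    @property
    def proportion(self) -> float:
        return self.n_dauer / self.n_total


@dataclass
class AssayDataset:
    """A collection of assay plates with a designated control strain."""

    observations: list[AssayObservation]
    control_strain: str
    design_note: str = ""
    #: true generating parameters, attached by the simulator (None for real data)
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        strains = {o.strain_id for o in self.observations}
        if self.observations and self.control_strain not in strains:
            raise ValidationError(
                f"control strain {self.control_strain!r} absent from dataset"
            )
        seen: set[tuple[str, str]] = set()
        for o in self.observations:
            key = (o.day_id, o.plate_id)
            if key in seen:
                raise ValidationError(f"duplicate (day, plate) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def strains(self) -> list[str]:
        """Strains in first-appearance order, control first."""
        out = [self.control_strain]
        for o in self.observations:
            if o.strain_id not in out:
                out.append(o.strain_id)
        return out

    @property
    def days(self) -> list[str]:
        out: list[str] = []
        for o in self.observations:
            if o.day_id not in out:
                out.append(o.day_id)
        return out

    def pooled_proportion(self, strain: str | None = None) -> float:
        obs = [
            o
            for o in self.observations
            if strain is None or o.strain_id == strain
        ]
        tot = sum(o.n_total for o in obs)
        return sum(o.n_dauer for o in obs) / tot

    def proportions(self, strain: str) -> np.ndarray:
        return np.array(
            [o.proportion for o in self.observations if o.strain_id == strain]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strain": o.strain_id,
                "day": o.day_id,
                "plate": o.plate_id,
                "n_total": o.n_total,
                "n_dauer": o.n_dauer,
                **({"dose": o.dose} if o.dose is not None else {}),
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VarianceComponents:
    """Logit-scale standard deviations of the clustering structure."""

    sd_day: float = 0.0
    sd_plate: float = 0.0
    sd_history: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd_day", "sd_plate", "sd_history"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sd_day, self.sd_plate, self.sd_history)


#: presets used by the simulation study; the logit-scale magnitudes are the
#: package's own choices (low clustering vs clustering strong enough to break
#: naive plate-level tests)
VARIANCE_PRESETS = {
    "zero": VarianceComponents(0.0, 0.0, 0.0),
    "low": VarianceComponents(0.25, 0.25, 0.25),
    "high": VarianceComponents(1.0, 0.5, 0.5),
}


@dataclass(frozen=True)
class GridCountObservation:
    """One worm's grid-entry exploration score."""

    strain_id: str
    day_id: str
    worm_id: str
    score: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(
                f"worm {self.worm_id!r}: score must be non-negative"
            )


@dataclass
class Contrast:
    """A pairwise comparison between two strains on the link scale."""

    strain_a: str
    strain_b: str
    estimate: float
    se: float | None = None
    statistic: float | None = None
    df: float | None = None
    p_raw: float | None = None
    p_adj: float | None = None
    ci95: tuple[float, float] | None = None
    #: Bayesian: max(P(delta>0), P(delta<0)) from the posterior
    prob_direction: float | None = None
    #: Bayesian: 95% equal-tailed credible interval excludes zero
    excludes_zero: bool | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if (
            self.p_adj is not None
            and self.p_raw is not None
            and self.p_adj < self.p_raw - 1e-12
        ):
            raise ValidationError("adjusted p-value below raw p-value")


@dataclass
class FitResult:
    """Uniform result shape shared by every analysis method.

    ``fixed_effects`` are per-strain estimates on the model's link scale
    (logit for binomial fits, log for Poisson, identity for plate-proportion
    tests).  ``intervals`` maps strain -> {"95": (lo, hi), "75": (lo, hi)} on
    the response scale.  ``draws`` holds posterior draws for Bayesian fits
    (mapping name -> 1-D array) and is not serialized to the CSV row format.
    """

    method: str
    fixed_effects: dict[str, float] = field(default_factory=dict)
    variance_estimates: VarianceComponents | None = None
    contrasts: list[Contrast] = field(default_factory=list)
    intervals: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    converged: bool = True
    seed: int | None = None
    loglik: float | None = None
    n_params: int | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)
    draws: dict[str, np.ndarray] | None = None

    def contrast(self, strain_a: str, strain_b: str | None = None) -> Contrast:
        for c in self.contrasts:
            if c.strain_a == strain_a and (
                strain_b is None or c.strain_b == strain_b
            ):
                return c
        raise KeyError((strain_a, strain_b))


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def _resolve_columns(
    frame: pd.DataFrame, required: Sequence[str], format_spec: Mapping[str, str] | None
) -> dict[str, str]:
    spec = dict(format_spec or {})
    mapping = {}
    for name in required:
        col = spec.get(name, name)
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r} (for field {name!r})")
        mapping[name] = col
    return mapping


def read_assay_table(
    path: str | Path, format_spec: Mapping[str, str] | None = None
) -> AssayDataset:
    """Read a plate-level assay CSV into a validated :class:`AssayDataset`.

    Required columns: strain, day, plate, n_total, n_dauer (names remappable
    through ``format_spec``).  An optional ``dose`` column is carried through.
    The control strain defaults to the strain of the first row and can be set
    via ``format_spec["control_strain"]``.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")
    cols = _resolve_columns(frame, ASSAY_COLUMNS, format_spec)
    dose_col = (format_spec or {}).get("dose", "dose")
    has_dose = dose_col in frame.columns
    observations = []
    for idx, row in frame.iterrows():
        try:
            observations.append(
                AssayObservation(
                    strain_id=str(row[cols["strain"]]),
                    day_id=str(row[cols["day"]]),
                    plate_id=str(row[cols["plate"]]),
                    n_total=int(row[cols["n_total"]]),
                    n_dauer=int(row[cols["n_dauer"]]),
                    dose=float(row[dose_col]) if has_dose else None,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from None
    control = (format_spec or {}).get(
        "control_strain", observations[0].strain_id
    )
    return AssayDataset(observations=observations, control_strain=str(control))


def write_assay_table(dataset: AssayDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_grid_table(
    path: str | Path, format_spec: Mapping[str, str] | None = None
) -> list[GridCountObservation]:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if frame.empty:
        raise EmptyInputError(f"{path}: no data rows")
    cols = _resolve_columns(frame, GRID_COLUMNS, format_spec)
    out = []
    for idx, row in frame.iterrows():
        try:
            out.append(
                GridCountObservation(
                    strain_id=str(row[cols["strain"]]),
                    day_id=str(row[cols["day"]]),
                    worm_id=str(row[cols["worm"]]),
                    score=int(row[cols["score"]]),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from None
    return out


def write_grid_table(
    observations: Iterable[GridCountObservation], path: str | Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "strain": o.strain_id,
                "day": o.day_id,
                "worm": o.worm_id,
                "score": o.score,
            }
            for o in observations
        ]
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result serialization: flat CSV + JSON sidecar
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable SHA-256 of a configuration mapping (sorted-key canonical JSON)."""
    canon = json.dumps(_jsonable(dict(config)), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _result_rows(result: Any) -> pd.DataFrame:
    if isinstance(result, FitResult):
        rows = []
        for c in result.contrasts:
            rows.append(
                {
                    "method": result.method,
                    "strain_a": c.strain_a,
                    "strain_b": c.strain_b,
                    "estimate": c.estimate,
                    "se": c.se,
                    "statistic": c.statistic,
                    "df": c.df,
                    "p_raw": c.p_raw,
                    "p_adj": c.p_adj,
                    "prob_direction": c.prob_direction,
                    "excludes_zero": c.excludes_zero,
                    "degenerate": c.degenerate,
                }
            )
        return pd.DataFrame(rows)
    if hasattr(result, "to_frame"):  # MethodComparisonResult duck type
        return result.to_frame()
    raise TypeError(f"cannot serialize {type(result)!r}")


def write_results(result: Any, path: str | Path) -> None:
    """Write a result as a flat CSV plus a JSON sidecar with full metadata.

    Floats in the sidecar use Python's shortest round-trip representation, so
    re-reading reproduces every numeric field bit-exactly.
    """
    path = Path(path)
    frame = _result_rows(result)
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = _jsonable(
        {
            f.name: getattr(result, f.name)
            for f in dataclasses.fields(result)
            if f.name not in ("draws", "log")
        }
    )
    meta["__type__"] = type(result).__name__
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Read back a result written by :func:`write_results`."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return frame, meta
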
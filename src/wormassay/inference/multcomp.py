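"""Single-step multivariate-t multiple-comparison adjustment.

The Dunnett (each test strain vs control) and Tukey (all pairs) families
are adjusted with the single-step max-|T| rule: the adjusted p-value of
contrast i is

    p_adj_i = Pr(max_j |T_j| >= |t_i|)

where T follows a central multivariate t with the fit's residual degrees of
freedom and the correlation matrix of the contrast estimators (multivariate
normal in the Wald / infinite-df limit).  The rectangle probability is
evaluated with scipy's quasi-Monte-Carlo integrator under a fixed seed, so
adjusted p-values are reproducible to three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ..core import Contrast, FitResult
from ..errors import ConfigError, ValidationError

__all__ = ["ContrastSpec", "adjust_multcomp", "credible_intervals", "contrast_pairs"]

_QMC_SEED = 20180207  # fixed: adjusted p-values are part of the output contract


@dataclass(frozen=True)
class ContrastSpec:
    """Which pairwise comparisons form the family."""

    scheme: str = "dunnett_vs_control"  # or "tukey_all_pairs" or "none"
    control: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("dunnett_vs_control", "tukey_all_pairs", "none"):
            raise ConfigError(f"unknown contrast scheme {self.scheme!r}")
        if self.scheme == "dunnett_vs_control" and self.control is None:
            raise ConfigError("dunnett_vs_control requires a control strain")


def contrast_pairs(
    strains: Sequence[str], spec: ContrastSpec
) -> list[tuple[str, str]]:
    """(strain_a, strain_b) pairs of the family; b is the reference."""
    if spec.scheme == "none":
        return []
    if spec.scheme == "dunnett_vs_control":
        return [(s, spec.control) for s in strains if s != spec.control]
    pairs = []
    for i, a in enumerate(strains):
        for b in strains[:i]:
            pairs.append((a, b))
    return pairs


def _max_abs_tail(t_obs: float, corr: np.ndarray, df: float | None) -> float:
    """Pr(max_j |T_j| >= t_obs) under central mv-t(df, corr)."""
    k = corr.shape[0]
    lower = np.full(k, -abs(t_obs))
    upper = np.full(k, abs(t_obs))
    if df is None or not np.isfinite(df):
        inside = stats.multivariate_normal.cdf(
            upper,
            mean=np.zeros(k),
            cov=corr,
            lower_limit=lower,
            abseps=1e-7,
        )
    else:
        dist = stats.multivariate_t(
            loc=np.zeros(k), shape=corr, df=df, seed=_QMC_SEED
        )
        inside = dist.cdf(upper, lower_limit=lower)
    return float(min(max(1.0 - inside, 0.0), 1.0))


def adjust_multcomp(
    statistics: Sequence[float],
    corr: np.ndarray,
    df: float | None = None,
    raw_p: Sequence[float] | None = None,
) -> np.ndarray:
    """Single-step adjusted p-values for a family of |t| statistics.

    ``corr`` is the correlation matrix of the contrast estimators; ``df``
    the common residual degrees of freedom (None for the normal limit).
    Adjusted values never fall below the raw ones.
    """
    t = np.asarray(statistics, dtype=float)
    k = len(t)
    if raw_p is None:
        if df is None or not np.isfinite(df):
            raw_p = 2 * stats.norm.sf(np.abs(t))
        else:
            raw_p = 2 * stats.t.sf(np.abs(t), df)
    raw_p = np.asarray(raw_p, dtype=float)
    if k == 1:
        return raw_p.copy()
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ConfigError("correlation matrix does not match the family size")
    eigvals = np.linalg.eigvalsh((corr + corr.T) / 2)
    if eigvals.min() < -1e-8:
        raise ValidationError("contrast correlation matrix is not PSD")
    adj = np.array([_max_abs_tail(ti, corr, df) for ti in t])
    return np.maximum(adj, raw_p)


def apply_adjustment(fit: FitResult, corr: np.ndarray, df: float | None) -> None:
    """Fill ``p_adj`` on a fit's contrasts in place from their statistics."""
    if not fit.contrasts:
        return
    stats_ = [c.statistic for c in fit.contrasts]
    raw = [c.p_raw for c in fit.contrasts]
    adj = adjust_multcomp(stats_, corr, df, raw_p=raw)
    for c, a in zip(fit.contrasts, adj):
        c.p_adj = float(a)


def credible_intervals(
    fit: FitResult, levels: Sequence[float] = (0.95, 0.75)
) -> dict[str, dict[str, tuple[float, float]]]:
    """Equal-tailed response-scale posterior intervals per strain.

    Recomputed directly from the stored posterior draws; the 75% interval is
    nested inside the 95% one by quantile monotonicity.  A fit with fewer
    than 400 draws is flagged (``diagnostics["few_draws"]``) but still
    summarized.
    """
    if fit.draws is None:
        raise ConfigError("credible intervals require a fit with posterior draws")
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for strain, d in fit.draws.items():
        if not strain.startswith("response:"):
            continue
        name = strain.split(":", 1)[1]
        if len(d) < 400:
            fit.diagnostics["few_draws"] = True
        out[name] = {}
        for lv in levels:
            lo, hi = np.quantile(d, [(1 - lv) / 2, 1 - (1 - lv) / 2])
            out[name][f"{int(round(lv * 100))}"] = (float(lo), float(hi))
    return out
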
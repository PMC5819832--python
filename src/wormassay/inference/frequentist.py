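"""Plate-level tests that ignore the clustering structure.

These are the two "naive" members of the four-method comparison: Welch
t-tests and one-way ANOVA on per-plate dauer proportions.  Both treat the
plate proportion as the unit observation and omit day/plate/history random
effects, which is exactly why they misbehave under clustered variation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from ..core import AssayDataset, Contrast, FitResult
from ..errors import InsufficientReplicationError
from .multcomp import ContrastSpec, apply_adjustment, contrast_pairs

__all__ = ["welch_prop_test", "anova_prop"]

VAR_FLOOR = 1e-12  # variance floor for constant groups, flagged degenerate


def _welch_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, bool]:
    """Welch t, Welch-Satterthwaite df, two-sided p, degenerate flag."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    degenerate = va == 0.0 or vb == 0.0
    va, vb = max(va, VAR_FLOOR), max(vb, VAR_FLOOR)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), degenerate


def welch_prop_test(data: AssayDataset, contrasts: ContrastSpec) -> FitResult:
    """Pairwise Welch t-tests on plate proportions (no pooling, no
    multiplicity adjustment: the 'multiple t-tests' method reports raw
    p-values, so p_adj is the raw value)."""
    result = FitResult(method="welch_t")
    for s in data.strains:
        result.fixed_effects[s] = float(data.proportions(s).mean())
    pairs = contrast_pairs(data.strains, contrasts)
    for a_name, b_name in pairs:
        a, b = data.proportions(a_name), data.proportions(b_name)
        if len(a) < 2 or len(b) < 2:
            raise InsufficientReplicationError(
                f"Welch test needs >=2 plates per strain ({a_name} vs {b_name})"
            )
        t, df, p, degen = _welch_pair(a, b)
        result.contrasts.append(
            Contrast(
                strain_a=a_name,
                strain_b=b_name,
                estimate=float(a.mean() - b.mean()),
                se=float(math.sqrt(max(a.var(ddof=1), VAR_FLOOR) / len(a)
                                   + max(b.var(ddof=1), VAR_FLOOR) / len(b))),
                statistic=t,
                df=df,
                p_raw=p,
                p_adj=p,
                degenerate=degen,
            )
        )
    result.diagnostics["n_degenerate"] = sum(
        c.degenerate for c in result.contrasts
    )
    return result


def anova_prop(data: AssayDataset, contrasts: ContrastSpec) -> FitResult:
    """One-way ANOVA on plate proportions with pooled-variance post-hoc
    contrasts adjusted by the multivariate-t max-|T| rule."""
    strains = data.strains
    if len(strains) < 2:
        raise InsufficientReplicationError("ANOVA needs at least two strains")
    groups = [data.proportions(s) for s in strains]
    sizes = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    N, k = int(sizes.sum()), len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df1, df2 = k - 1, N - k
    if ss_within <= 1e-18 and ss_between <= 1e-18:
        F, p_f = 0.0, 1.0
    else:
        mse = max(ss_within / df2, VAR_FLOOR)
        F = (ss_between / df1) / mse
        p_f = float(stats.f.sf(F, df1, df2))
    mse = max(ss_within / df2, VAR_FLOOR)

    result = FitResult(method="anova")
    result.fixed_effects = {s: float(m) for s, m in zip(strains, means)}
    result.diagnostics.update({"F": float(F), "df1": df1, "df2": df2, "p_F": p_f})

    pairs = contrast_pairs(strains, contrasts)
    if not pairs:
        return result
    idx = {s: i for i, s in enumerate(strains)}
    C = np.zeros((len(pairs), k))
    for r, (a, b) in enumerate(pairs):
        C[r, idx[a]] = 1.0
        C[r, idx[b]] = -1.0
    cov = C @ np.diag(mse / sizes) @ C.T
    se = np.sqrt(np.diag(cov))
    corr = cov / np.outer(se, se)
    for (a, b), row, s_ in zip(pairs, C, se):
        est = float(row @ means)
        t = est / s_
        result.contrasts.append(
            Contrast(
                strain_a=a,
                strain_b=b,
                estimate=est,
                se=float(s_),
                statistic=float(t),
                df=float(df2),
                p_raw=float(2 * stats.t.sf(abs(t), df2)),
                degenerate=ss_within == 0.0,
            )
        )
    apply_adjustment(result, corr, df2)
    return result
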
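"""Mixed-model fits for dauer proportions, exploration counts and
fluorescence intensities, plus the likelihood-ratio test and the
dose-response GLM.

The binomial GLMM is the clustered model the assay design implies:

    logit Pr(dauer) = beta_strain + b_day + b_strain.day + b_plate

with independent random intercepts for day (sD), strain-by-day culture
history (sG) and plate (sP), fitted by Laplace-approximated maximum
likelihood.  With no random terms requested the fit reduces to an ordinary
binomial GLM (for a pure strain-indicator design, the estimates are exactly
the logits of the pooled per-strain proportions).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ..core import (
    AssayDataset,
    Contrast,
    FitResult,
    GridCountObservation,
    VarianceComponents,
)
from ..errors import (
    ConfigError,
    NotNestedError,
    ValidationError,
)
from ..laplace import GLMMData, fit_glmm_laplace
from .multcomp import ContrastSpec, apply_adjustment, contrast_pairs

__all__ = [
    "fit_binomial_glmm",
    "fit_poisson_glmm",
    "fit_lmm_log10",
    "lrt_nested",
    "fit_dose_response_glm",
]

VALID_TERMS = frozenset({"day", "plate", "history"})
_Z95 = stats.norm.ppf(0.975)
_Z75 = stats.norm.ppf(0.875)


def _codes(labels: Sequence) -> np.ndarray:
    return pd.Categorical(list(labels)).codes.astype(int)


def _assay_arrays(data: AssayDataset):
    strains = data.strains
    idx = {s: i for i, s in enumerate(strains)}
    obs = data.observations
    y = np.array([o.n_dauer for o in obs], dtype=float)
    trials = np.array([o.n_total for o in obs], dtype=float)
    X = np.zeros((len(obs), len(strains)))
    for r, o in enumerate(obs):
        X[r, idx[o.strain_id]] = 1.0
    blocks_all = {
        "day": _codes([o.day_id for o in obs]),
        "history": _codes([(o.strain_id, o.day_id) for o in obs]),
        "plate": np.arange(len(obs)),
    }
    return y, trials, X, strains, blocks_all


def _wald_intervals(
    strains: Sequence[str],
    beta: np.ndarray,
    cov: np.ndarray,
    link_inv,
) -> dict[str, dict[str, tuple[float, float]]]:
    out = {}
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    for i, s in enumerate(strains):
        out[s] = {
            "95": (
                float(link_inv(beta[i] - _Z95 * se[i])),
                float(link_inv(beta[i] + _Z95 * se[i])),
            ),
            "75": (
                float(link_inv(beta[i] - _Z75 * se[i])),
                float(link_inv(beta[i] + _Z75 * se[i])),
            ),
        }
    return out


def _wald_contrasts(
    result: FitResult,
    strains: Sequence[str],
    pairs: list[tuple[str, str]],
    beta: np.ndarray,
    cov: np.ndarray,
    degenerate: bool = False,
) -> None:
    if not pairs:
        return
    idx = {s: i for i, s in enumerate(strains)}
    k = len(strains)
    C = np.zeros((len(pairs), k))
    for r, (a, b) in enumerate(pairs):
        C[r, idx[a]] = 1.0
        C[r, idx[b]] = -1.0
    ccov = C @ cov @ C.T
    se = np.sqrt(np.clip(np.diag(ccov), 1e-300, None))
    corr = ccov / np.outer(se, se)
    est = C @ beta
    z = est / se
    for (a, b), e, s_, z_ in zip(pairs, est, se, z):
        p = float(2 * stats.norm.sf(abs(z_)))
        result.contrasts.append(
            Contrast(
                strain_a=a,
                strain_b=b,
                estimate=float(e),
                se=float(s_),
                statistic=float(z_),
                df=None,
                p_raw=p,
                ci95=(float(e - _Z95 * s_), float(e + _Z95 * s_)),
                degenerate=degenerate,
            )
        )
    apply_adjustment(result, corr, df=None)


def _fingerprint(y: np.ndarray, extra: float = 0.0) -> tuple:
    return (len(y), float(np.sum(y)), float(extra))


def fit_binomial_glmm(
    data: AssayDataset,
    random_terms: Iterable[str] = ("day", "plate", "history"),
    contrasts: ContrastSpec | None = None,
    ridge_on_separation: float = 0.01,
) -> FitResult:
    """Laplace ML fit of the clustered binomial model.

    A strain whose plates are all-0 or all-1 produces complete separation;
    the fit then adds a weak ridge penalty on the fixed effects (strength
    ``ridge_on_separation``) and flags the result degenerate.
    """
    terms = set(random_terms)
    if not terms <= VALID_TERMS:
        raise ConfigError(f"unknown random terms {terms - VALID_TERMS}")
    contrasts = contrasts or ContrastSpec(control=data.control_strain)
    y, trials, X, strains, blocks_all = _assay_arrays(data)

    separated = any(
        data.pooled_proportion(s) in (0.0, 1.0) for s in strains
    )
    ridge = ridge_on_separation if separated else 0.0

    if not terms:
        return _binomial_glm(data, y, trials, X, strains, contrasts, ridge)

    blocks = {k: blocks_all[k] for k in ("day", "history", "plate") if k in terms}
    gdata = GLMMData(y=y, X=X, blocks=blocks, family="binomial", trials=trials)
    fit = fit_glmm_laplace(gdata, ridge=ridge)

    sds = fit.sds
    result = FitResult(
        method="glmm_binomial",
        fixed_effects={s: float(b) for s, b in zip(strains, fit.beta)},
        variance_estimates=VarianceComponents(
            sd_day=sds.get("day", 0.0),
            sd_plate=sds.get("plate", 0.0),
            sd_history=sds.get("history", 0.0),
        ),
        converged=fit.converged,
        loglik=fit.loglik,
        n_params=fit.n_params,
    )
    result.intervals = _wald_intervals(
        strains, fit.beta, fit.cov_beta, stats.logistic.cdf
    )
    result.diagnostics.update(
        {
            "terms": sorted(terms),
            "separated": separated,
            "message": fit.message,
            "data_fingerprint": _fingerprint(y, trials.sum()),
        }
    )
    _wald_contrasts(
        result,
        strains,
        contrast_pairs(strains, contrasts),
        fit.beta,
        fit.cov_beta,
        degenerate=separated,
    )
    return result


def _binomial_glm(data, y, trials, X, strains, contrasts, ridge) -> FitResult:
    """No-random-terms limit: ordinary binomial GLM (statsmodels IRLS)."""
    endog = np.column_stack([y, trials - y])
    if ridge:
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        res = model.fit_regularized(alpha=ridge / len(y), L1_wt=0.0)
        beta = np.asarray(res.params)
        cov = np.linalg.pinv(
            (X.T * (trials * stats.logistic.pdf(X @ beta))) @ X
        )
        llf = float(
            sm.GLM(endog, X, family=sm.families.Binomial()).loglike(beta)
        )
        converged = True
    else:
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        llf = float(res.llf)
        converged = bool(res.converged)
    result = FitResult(
        method="glmm_binomial",
        fixed_effects={s: float(b) for s, b in zip(strains, beta)},
        variance_estimates=VarianceComponents(),
        converged=converged,
        loglik=llf,
        n_params=X.shape[1],
    )
    result.intervals = _wald_intervals(strains, beta, cov, stats.logistic.cdf)
    result.diagnostics.update(
        {
            "terms": [],
            "separated": bool(ridge),
            "data_fingerprint": _fingerprint(y, trials.sum()),
        }
    )
    _wald_contrasts(
        result,
        strains,
        contrast_pairs(strains, contrasts),
        beta,
        cov,
        degenerate=bool(ridge),
    )
    return result


def fit_poisson_glmm(
    data: Sequence[GridCountObservation],
    contrasts: ContrastSpec | None = None,
    bayes: bool = False,
    seed: int | None = None,
    random_terms: Iterable[str] = ("day", "plate"),
    **bayes_kwargs,
) -> FitResult:
    """Log-link Poisson mixed model for grid-entry counts.

    Each worm occupies its own plate in the exploration assay, so the plate
    random intercept is drawn per observation.  ``bayes=True`` delegates to
    the MCMC sampler and returns posterior summaries instead of Wald ones.
    """
    if bayes:
        from .bayes import fit_bayes_poisson_glmm

        return fit_bayes_poisson_glmm(
            data, contrasts=contrasts, seed=seed, random_terms=random_terms,
            **bayes_kwargs,
        )
    obs = list(data)
    if not obs:
        raise ValidationError("no observations")
    strains: list[str] = []
    for o in obs:
        if o.strain_id not in strains:
            strains.append(o.strain_id)
    idx = {s: i for i, s in enumerate(strains)}
    y = np.array([o.score for o in obs], dtype=float)
    X = np.zeros((len(obs), len(strains)))
    for r, o in enumerate(obs):
        X[r, idx[o.strain_id]] = 1.0
    all_zero = any(y[X[:, j] == 1].sum() == 0 for j in range(len(strains)))
    ridge = 0.01 if all_zero else 0.0
    contrasts = contrasts or ContrastSpec(control=strains[0])

    terms = set(random_terms)
    blocks = {}
    if "day" in terms:
        blocks["day"] = _codes([o.day_id for o in obs])
    if "plate" in terms:
        blocks["plate"] = np.arange(len(obs))

    if blocks:
        gdata = GLMMData(y=y, X=X, blocks=blocks, family="poisson")
        fit = fit_glmm_laplace(gdata, ridge=ridge)
        beta, cov, llf = fit.beta, fit.cov_beta, fit.loglik
        converged = fit.converged
        sds = fit.sds
        var = VarianceComponents(
            sd_day=sds.get("day", 0.0), sd_plate=sds.get("plate", 0.0)
        )
        n_params = fit.n_params
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        beta, cov, llf = np.asarray(res.params), np.asarray(res.cov_params()), float(res.llf)
        converged, var, n_params = bool(res.converged), VarianceComponents(), X.shape[1]

    result = FitResult(
        method="glmm_poisson",
        fixed_effects={s: float(b) for s, b in zip(strains, beta)},
        variance_estimates=var,
        converged=converged,
        loglik=llf,
        n_params=n_params,
        seed=seed,
    )
    result.intervals = _wald_intervals(strains, beta, cov, np.exp)
    result.diagnostics.update(
        {
            "terms": sorted(blocks),
            "all_zero_group": all_zero,
            "data_fingerprint": _fingerprint(y),
        }
    )
    _wald_contrasts(
        result, strains, contrast_pairs(strains, contrasts), beta, cov,
        degenerate=all_zero,
    )
    result.diagnostics["rate_ratios"] = {
        f"{c.strain_a}/{c.strain_b}": math.exp(c.estimate)
        for c in result.contrasts
    }
    return result


def fit_lmm_log10(
    data: pd.DataFrame,
    contrasts: ContrastSpec | None = None,
    random_terms: Iterable[str] = ("day", "plate"),
) -> FitResult:
    """Gaussian LMM on log10-transformed per-animal intensities.

    ``data`` columns: strain, day, plate, value (strictly positive; floor
    background-subtracted negatives upstream).  Group means are
    back-transformed (10**beta) for the response-scale intervals.
    """
    for col in ("strain", "day", "plate", "value"):
        if col not in data.columns:
            raise ValidationError(f"intensity table missing column {col!r}")
    if (data["value"] <= 0).any():
        bad = int((data["value"] <= 0).sum())
        raise ValidationError(
            f"{bad} non-positive intensities; floor them before the log10 fit"
        )
    y = np.log10(data["value"].to_numpy(dtype=float))
    strains = list(dict.fromkeys(data["strain"].astype(str)))
    idx = {s: i for i, s in enumerate(strains)}
    X = np.zeros((len(y), len(strains)))
    for r, s in enumerate(data["strain"].astype(str)):
        X[r, idx[s]] = 1.0
    contrasts = contrasts or ContrastSpec(control=strains[0])
    terms = set(random_terms)
    blocks = {}
    if "day" in terms:
        blocks["day"] = _codes(data["day"].astype(str))
    if "plate" in terms:
        blocks["plate"] = _codes(
            list(zip(data["day"].astype(str), data["plate"].astype(str)))
        )
    gdata = GLMMData(y=y, X=X, blocks=blocks, family="gaussian")
    fit = fit_glmm_laplace(gdata)
    sds = fit.sds
    result = FitResult(
        method="lmm_log10",
        fixed_effects={s: float(b) for s, b in zip(strains, fit.beta)},
        variance_estimates=VarianceComponents(
            sd_day=sds.get("day", 0.0), sd_plate=sds.get("plate", 0.0)
        ),
        converged=fit.converged,
        loglik=fit.loglik,
        n_params=fit.n_params,
    )
    result.intervals = _wald_intervals(
        strains, fit.beta, fit.cov_beta, lambda v: 10.0**v
    )
    result.diagnostics.update(
        {
            "terms": sorted(blocks),
            "residual_sd": fit.scale,
            "data_fingerprint": _fingerprint(y),
        }
    )
    _wald_contrasts(
        result, strains, contrast_pairs(strains, contrasts), fit.beta,
        fit.cov_beta,
    )
    return result


def lrt_nested(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: 2(l_full - l_reduced) ~ chi2.

    The chi-square reference uses df = difference in parameter count with no
    boundary correction, matching the df = 1 convention of single-term
    chromosome-effect tests (``boundary_correction=True`` on the module-level
    :func:`lrt_nested_corrected` halves the boundary mixture instead).
    """
    return _lrt(full, reduced, boundary_correction=False)


def lrt_nested_corrected(full: FitResult, reduced: FitResult):
    """Boundary-corrected variant (50:50 chi2 mixture) for variance terms."""
    return _lrt(full, reduced, boundary_correction=True)


def _lrt(full: FitResult, reduced: FitResult, boundary_correction: bool):
    if full.loglik is None or reduced.loglik is None:
        raise ConfigError("both fits must carry log-likelihoods")
    if not (full.converged and reduced.converged):
        raise ConfigError("both fits must have converged")
    t_full = set(full.diagnostics.get("terms", []))
    t_red = set(reduced.diagnostics.get("terms", []))
    fe_full = set(full.fixed_effects)
    fe_red = set(reduced.fixed_effects)
    if not (t_red <= t_full):
        raise NotNestedError("reduced model's random terms not a subset")
    if full.diagnostics.get("data_fingerprint") != reduced.diagnostics.get(
        "data_fingerprint"
    ):
        raise NotNestedError("fits are not on the same data")
    df = (full.n_params or 0) - (reduced.n_params or 0)
    if df < 0:
        raise NotNestedError("reduced model has more parameters than full")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ValidationError(
            f"full model fits worse than reduced (LRT={stat:.3g}); refit"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    if boundary_correction:
        p = 0.5 * p + 0.5 * float(stats.chi2.sf(stat, max(df - 1, 1e-300)))
    return float(stat), int(df), p


def fit_dose_response_glm(
    data: AssayDataset | pd.DataFrame,
    model: str = "logit_linear_dose",
) -> FitResult:
    """Dose-response fit across pheromone concentrations.

    ``logit_linear_dose``: binomial GLM with strain indicators plus a linear
    dose term on the logit scale; reports the strain odds ratio (vs the
    control) and a Wald chi-square per term.  ``quadratic``: ordinary least
    squares of a continuous response on strain + dose + dose^2 (for
    fluorescence-vs-dose curves); expects a frame with strain/dose/value.
    """
    if model == "quadratic":
        return _quadratic_dose(data)
    if model != "logit_linear_dose":
        raise ConfigError(f"unknown dose-response model {model!r}")
    if not isinstance(data, AssayDataset):
        raise ConfigError("logit_linear_dose expects an AssayDataset")
    doses = [o.dose for o in data.observations]
    if any(d is None for d in doses):
        raise ValidationError("every plate needs a dose covariate")
    if len(set(doses)) < 2:
        raise ConfigError(
            "dose term is rank-deficient with a single dose level"
        )
    y, trials, X, strains, _ = _assay_arrays(data)
    X = np.column_stack([X, np.asarray(doses, dtype=float)])
    res = sm.GLM(
        np.column_stack([y, trials - y]), X, family=sm.families.Binomial()
    ).fit()
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    result = FitResult(
        method="glm_dose",
        fixed_effects={s: float(b) for s, b in zip(strains, beta)},
        converged=bool(res.converged),
        loglik=float(res.llf),
        n_params=X.shape[1],
    )
    result.diagnostics["dose_slope"] = float(beta[-1])
    result.diagnostics["data_fingerprint"] = _fingerprint(y, trials.sum())
    result.diagnostics["terms"] = ["dose"]
    # per-strain odds ratio vs control, with Wald chi-square
    ctrl = strains.index(data.control_strain)
    wald = {}
    ors = {}
    for i, s in enumerate(strains):
        if i == ctrl:
            continue
        d = beta[i] - beta[ctrl]
        v = cov[i, i] + cov[ctrl, ctrl] - 2 * cov[i, ctrl]
        chi2 = d * d / v
        ors[s] = math.exp(d)
        wald[s] = float(chi2)
        result.contrasts.append(
            Contrast(
                strain_a=s,
                strain_b=data.control_strain,
                estimate=float(d),
                se=float(math.sqrt(v)),
                statistic=float(d / math.sqrt(v)),
                p_raw=float(stats.chi2.sf(chi2, 1)),
                p_adj=float(stats.chi2.sf(chi2, 1)),
            )
        )
    chi2_dose = beta[-1] ** 2 / cov[-1, -1]
    result.diagnostics.update(
        {
            "odds_ratios": ors,
            "wald_chi2_strain": wald,
            "wald_chi2_dose": float(chi2_dose),
            "p_dose": float(stats.chi2.sf(chi2_dose, 1)),
        }
    )
    return result


def _quadratic_dose(data: pd.DataFrame) -> FitResult:
    for col in ("strain", "dose", "value"):
        if col not in data.columns:
            raise ValidationError(f"quadratic fit missing column {col!r}")
    if data["dose"].nunique() < 3:
        raise ConfigError("quadratic dose model needs >= 3 dose levels")
    strains = list(dict.fromkeys(data["strain"].astype(str)))
    idx = {s: i for i, s in enumerate(strains)}
    X = np.zeros((len(data), len(strains) + 2))
    dose = data["dose"].to_numpy(dtype=float)
    for r, s in enumerate(data["strain"].astype(str)):
        X[r, idx[s]] = 1.0
    X[:, -2] = dose
    X[:, -1] = dose**2
    res = sm.OLS(data["value"].to_numpy(dtype=float), X).fit()
    result = FitResult(
        method="glm_dose",
        fixed_effects={s: float(res.params[idx[s]]) for s in strains},
        converged=True,
        loglik=float(res.llf),
        n_params=X.shape[1],
    )
    result.diagnostics.update(
        {
            "dose_coef": float(res.params[-2]),
            "dose2_coef": float(res.params[-1]),
            "r_squared": float(res.rsquared),
        }
    )
    return result
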
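"""Laplace-approximation fitting of GLMMs with independent random intercepts.

The model is

    g(E[y_i]) = x_i' beta + sum_k u_k[group_k(i)],   u_k ~ N(0, sd_k^2 I)

for binomial (logit link), Poisson (log link) or Gaussian (identity)
responses.  The marginal likelihood integrates the random intercepts out by
the Laplace approximation: with joint log-likelihood h(u) maximized at
u-hat and H the Hessian of -h at the mode,

    log L(beta, sd) ~= h(u-hat) - (1/2) log det H  (2 pi factors cancel)

which is exact for the Gaussian family.  A random-intercept block with one
level per observation (the plate effect in single-plate-per-row assay data,
or the per-worm effect in exploration counts) makes its Hessian block
diagonal; the Newton step and log-determinant are then computed through the
Schur complement on the remaining small blocks, so cost grows linearly in
the number of observations.

Variance parameters are optimized on the log-sd scale with a floor of
exp(-10); the fixed-effect covariance is the inverse Hessian of the
negative marginal log-likelihood in beta at the optimum, conditioning on
the fitted variance components (the standard mixed-model Wald convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln

from .errors import ConfigError

try:  # the JIT kernel is a speed-up only; semantics match the numpy path
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

__all__ = ["GLMMData", "GLMMFit", "fit_glmm_laplace", "marginal_nll"]

LOG_SD_FLOOR = -10.0


@dataclass
class GLMMData:
    """Response, fixed design and random-intercept grouping codes.

    ``blocks`` maps block name -> integer group codes per observation
    (0..q_k-1).  ``trials`` is required for the binomial family.
    """

    y: np.ndarray
    X: np.ndarray
    blocks: dict[str, np.ndarray]
    family: str
    trials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.family not in ("binomial", "poisson", "gaussian"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.family == "binomial":
            if self.trials is None:
                raise ConfigError("binomial family requires trials")
            self.trials = np.asarray(self.trials, dtype=float)
        self.blocks = {
            k: np.asarray(v, dtype=int) for k, v in self.blocks.items()
        }
        self.family_code = {"binomial": 0, "poisson": 1, "gaussian": 2}[
            self.family
        ]
        if self.family == "binomial":
            self.aux = self.trials
            self.nll_const = -float(
                (
                    gammaln(self.trials + 1)
                    - gammaln(self.y + 1)
                    - gammaln(self.trials - self.y + 1)
                ).sum()
            )
        elif self.family == "poisson":
            self.aux = np.zeros_like(self.y)
            self.nll_const = float(gammaln(self.y + 1).sum())
        else:
            self.aux = np.zeros_like(self.y)
            self.nll_const = 0.0
        self.block_sizes = {k: int(v.max()) + 1 for k, v in self.blocks.items()}
        n = len(self.y)
        # a block with one level per observation gets the O(n) fast path
        self.obs_block: str | None = None
        small = []
        for k, codes in self.blocks.items():
            if (
                self.obs_block is None
                and self.block_sizes[k] == n
                and np.array_equal(np.sort(codes), np.arange(n))
            ):
                self.obs_block = k
            else:
                small.append(k)
        self.small_names = small
        self.q_small = sum(self.block_sizes[k] for k in small)
        self.q = self.q_small + (n if self.obs_block else 0)
        Zs = np.zeros((n, self.q_small))
        off = 0
        self._offsets = {}
        for k in small:
            Zs[np.arange(n), off + self.blocks[k]] = 1.0
            self._offsets[k] = off
            off += self.block_sizes[k]
        self.Z_small = Zs

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    def small_sd_vector(self, log_sds: Mapping[str, float]) -> np.ndarray:
        out = np.empty(self.q_small)
        for k in self.small_names:
            off = self._offsets[k]
            size = self.block_sizes[k]
            out[off : off + size] = math.exp(max(log_sds[k], LOG_SD_FLOOR))
        return out


def _data_nll_parts(
    data: GLMMData, eta: np.ndarray, scale: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """(negative log-lik, dnll/deta, d2nll/deta2) of the observation model."""
    y = data.y
    if data.family == "binomial":
        n = data.trials
        eta = np.clip(eta, -30.0, 30.0)
        p = expit(eta)
        const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        ll = y * eta - n * np.logaddexp(0.0, eta) + const
        return -float(ll.sum()), -(y - n * p), n * p * (1 - p)
    if data.family == "poisson":
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        ll = y * eta - mu - gammaln(y + 1)
        return -float(ll.sum()), -(y - mu), mu
    r = y - eta
    v = scale * scale
    ll = -0.5 * r * r / v - 0.5 * math.log(2 * math.pi * v)
    return -float(ll.sum()), -r / v, np.full(len(y), 1.0 / v)


@njit(cache=True)
def _newton_core(y, aux, family, scale, xb, Zs, prec_s, prec_w, has_w, v0, w0):
    """Newton mode of the joint nll over random effects + Laplace log-det.

    The per-observation block (when present) has a diagonal Hessian block,
    so its update and determinant contribution are eliminated analytically
    through the Schur complement on the small blocks.  Returns the marginal
    negative log-likelihood without the observation-model constant.
    """
    n = y.shape[0]
    qs = Zs.shape[1]
    v = v0.copy()
    w = w0.copy()

    def parts(eta):
        base = 0.0
        g = np.empty(n)
        wt = np.empty(n)
        if family == 0:  # binomial; aux = trials
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                pe = 1.0 / (1.0 + math.exp(-e))
                if e > 0.0:
                    sp = e + math.log1p(math.exp(-e))
                else:
                    sp = math.log1p(math.exp(e))
                base += -y[i] * e + aux[i] * sp
                g[i] = -(y[i] - aux[i] * pe)
                wt[i] = aux[i] * pe * (1.0 - pe)
        elif family == 1:  # poisson
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                mu = math.exp(e)
                base += -y[i] * e + mu
                g[i] = -(y[i] - mu)
                wt[i] = mu
        else:  # gaussian with residual sd = scale
            invv = 1.0 / (scale * scale)
            lognorm = 0.5 * math.log(2.0 * math.pi * scale * scale)
            for i in range(n):
                r = y[i] - eta[i]
                base += 0.5 * r * r * invv + lognorm
                g[i] = -r * invv
                wt[i] = invv
        return base, g, wt

    def objective(v_, w_):
        eta = xb.copy()
        if qs > 0:
            eta = eta + Zs @ v_
        if has_w:
            eta = eta + w_
        base, g, wt = parts(eta)
        pen = 0.0
        for j in range(qs):
            pen += 0.5 * prec_s[j] * v_[j] * v_[j]
        if has_w:
            for i in range(n):
                pen += 0.5 * prec_w * w_[i] * w_[i]
        return base + pen, eta, g, wt

    current, eta, g, wt = objective(v, w)
    for _ in range(50):
        if has_w:
            grad_w = g + prec_w * w
            c = wt + prec_w
            if qs > 0:
                grad_v = Zs.T @ g + prec_s * v
                ratio = wt - wt * wt / c
                S = Zs.T @ (Zs * ratio.reshape(n, 1))
                for j in range(qs):
                    S[j, j] += prec_s[j]
                rhs = grad_v - Zs.T @ (wt / c * grad_w)
                dv = np.linalg.solve(S, rhs)
                dw = (grad_w - wt * (Zs @ dv)) / c
            else:
                dv = np.zeros(0)
                dw = grad_w / c
        else:
            grad_v = Zs.T @ g + prec_s * v
            S = Zs.T @ (Zs * wt.reshape(n, 1))
            for j in range(qs):
                S[j, j] += prec_s[j]
            dv = np.linalg.solve(S, grad_v)
            dw = np.zeros(n)
        t = 1.0
        new = current
        v_new = v
        w_new = w
        eta_new = eta
        g_new = g
        wt_new = wt
        for _ in range(30):
            v_try = v - t * dv
            if has_w:
                w_try = w - t * dw
            else:
                w_try = w
            obj, eta_t, g_t, wt_t = objective(v_try, w_try)
            if obj <= current + 1e-12:
                new = obj
                v_new = v_try
                w_new = w_try
                eta_new = eta_t
                g_new = g_t
                wt_new = wt_t
                break
            t *= 0.5
        moved = abs(current - new)
        v, w, current, eta, g, wt = v_new, w_new, new, eta_new, g_new, wt_new
        gmax = 0.0
        if qs > 0:
            gv = Zs.T @ g + prec_s * v
            for j in range(qs):
                if abs(gv[j]) > gmax:
                    gmax = abs(gv[j])
        if has_w:
            for i in range(n):
                gw = g[i] + prec_w * w[i]
                if abs(gw) > gmax:
                    gmax = abs(gw)
        if moved < 1e-9 and gmax < 1e-7:
            break
    # log-determinants at the mode
    logdet = 0.0
    if has_w:
        c = wt + prec_w
        for i in range(n):
            logdet += math.log(c[i])
        if qs > 0:
            ratio = wt - wt * wt / c
            S = Zs.T @ (Zs * ratio.reshape(n, 1))
            for j in range(qs):
                S[j, j] += prec_s[j]
            L = np.linalg.cholesky(S)
            for j in range(qs):
                logdet += 2.0 * math.log(L[j, j])
    else:
        S = Zs.T @ (Zs * wt.reshape(n, 1))
        for j in range(qs):
            S[j, j] += prec_s[j]
        L = np.linalg.cholesky(S)
        for j in range(qs):
            logdet += 2.0 * math.log(L[j, j])
    logdet_D = 0.0
    for j in range(qs):
        logdet_D += -math.log(prec_s[j])
    if has_w:
        logdet_D += -n * math.log(prec_w)
    nll_marg = current + 0.5 * logdet_D + 0.5 * logdet
    return nll_marg, v, w


def marginal_nll(
    data: GLMMData,
    beta: np.ndarray,
    log_sds: Mapping[str, float],
    scale: float = 1.0,
    warm: dict | None = None,
    ridge: float = 0.0,
) -> float:
    """Negative Laplace-approximated marginal log-likelihood.

    ``warm`` is an optional mutable dict carrying the previous random-effect
    mode between calls, which makes repeated evaluation along an optimizer
    or MCMC path cheap.  ``ridge`` adds (ridge/2)*||beta||^2 (separation
    stabilization).
    """
    beta = np.asarray(beta, dtype=float)
    if data.q == 0:
        nll, _, _ = _data_nll_parts(data, data.X @ beta, scale)
        return nll + 0.5 * ridge * float(beta @ beta)
    n = len(data.y)
    sd_s = data.small_sd_vector(log_sds)
    prec_s = 1.0 / (sd_s * sd_s)
    has_w = data.obs_block is not None
    if has_w:
        sd_w = math.exp(max(log_sds[data.obs_block], LOG_SD_FLOOR))
        prec_w = 1.0 / (sd_w * sd_w)
    else:
        prec_w = 0.0
    v0 = np.zeros(data.q_small)
    w0 = np.zeros(n)
    if warm is not None:
        if warm.get("v") is not None and len(warm["v"]) == data.q_small:
            v0 = warm["v"]
        if has_w and warm.get("w") is not None and len(warm["w"]) == n:
            w0 = warm["w"]
    nll, v, w = _newton_core(
        data.y,
        data.aux,
        data.family_code,
        float(scale),
        data.X @ beta,
        data.Z_small,
        prec_s,
        float(prec_w),
        has_w,
        v0,
        w0,
    )
    if warm is not None:
        warm["v"] = v
        warm["w"] = w if has_w else None
    return nll + data.nll_const + 0.5 * ridge * float(beta @ beta)

@dataclass
class GLMMFit:
    """Raw output of the Laplace maximum-likelihood fit."""

    beta: np.ndarray
    log_sds: dict[str, float]
    loglik: float
    cov_beta: np.ndarray
    converged: bool
    message: str
    scale: float | None = None
    n_params: int = 0

    @property
    def sds(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.log_sds.items()}


def _beta_hessian(
    data: GLMMData,
    beta: np.ndarray,
    log_sds: Mapping[str, float],
    scale: float,
    ridge: float,
    step: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference Hessian of the marginal nll in beta."""
    p = len(beta)
    warm: dict = {}
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            bpp = beta.copy(); bpp[i] += step; bpp[j] += step
            bpm = beta.copy(); bpm[i] += step; bpm[j] -= step
            bmp = beta.copy(); bmp[i] -= step; bmp[j] += step
            bmm = beta.copy(); bmm[i] -= step; bmm[j] -= step
            fpp = marginal_nll(data, bpp, log_sds, scale, warm, ridge)
            fpm = marginal_nll(data, bpm, log_sds, scale, warm, ridge)
            fmp = marginal_nll(data, bmp, log_sds, scale, warm, ridge)
            fmm = marginal_nll(data, bmm, log_sds, scale, warm, ridge)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step * step)
    return H


def fit_glmm_laplace(
    data: GLMMData,
    start_beta: np.ndarray | None = None,
    start_log_sd: float = math.log(0.3),
    ridge: float = 0.0,
    gtol: float = 1e-8,
) -> GLMMFit:
    """Maximum-likelihood fit of all parameters by L-BFGS-B on the marginal.

    The Gaussian family carries an extra residual log-sd parameter.  Variance
    parameters are bounded below at log-sd = -10 (an effective zero).
    """
    p = data.n_fixed
    names = list(data.blocks)
    m = len(names)
    gaussian = data.family == "gaussian"

    if start_beta is None:
        start_beta = _default_start(data)
    theta0 = np.concatenate(
        [
            start_beta,
            np.full(m, start_log_sd),
            [math.log(max(np.std(data.y), 1e-3))] if gaussian else [],
        ]
    )
    warm: dict = {}

    def unpack(theta: np.ndarray):
        beta = theta[:p]
        log_sds = dict(zip(names, theta[p : p + m]))
        scale = math.exp(theta[p + m]) if gaussian else 1.0
        return beta, log_sds, scale

    def objective(theta: np.ndarray) -> float:
        beta, log_sds, scale = unpack(theta)
        return marginal_nll(data, beta, log_sds, scale, warm, ridge)

    bounds = (
        [(None, None)] * p
        + [(LOG_SD_FLOOR, 3.0)] * m
        + ([(-12.0, 6.0)] if gaussian else [])
    )
    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
    )
    beta, log_sds, scale = unpack(res.x)
    # boundary polish: a variance component whose profile is flat down to
    # the floor is snapped there (L-BFGS can stall on the flat shoulder)
    nll_cur = marginal_nll(data, beta, log_sds, scale, warm, ridge)
    for k in names:
        if log_sds[k] <= LOG_SD_FLOOR:
            continue
        trial = dict(log_sds)
        trial[k] = LOG_SD_FLOOR
        nll_floor = marginal_nll(data, beta, trial, scale, warm, ridge)
        if nll_floor <= nll_cur + 1e-8:
            log_sds = trial
            nll_cur = nll_floor
    if any(v <= LOG_SD_FLOOR for v in log_sds.values()):
        res_b = optimize.minimize(
            lambda b: marginal_nll(data, b, log_sds, scale, warm, ridge),
            beta,
            method="BFGS",
            options={"gtol": 1e-10},
        )
        if res_b.fun <= nll_cur + 1e-10:
            beta = res_b.x
    try:
        H = _beta_hessian(data, beta, log_sds, scale, ridge)
        cov_beta = np.linalg.inv(H)
        if np.any(np.diag(cov_beta) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_beta = np.linalg.pinv(
            _beta_hessian(data, beta, log_sds, scale, ridge, step=1e-3)
        )
    loglik = -marginal_nll(data, beta, log_sds, scale, warm, ridge=0.0)
    converged = bool(res.success) or float(np.abs(res.jac).max()) < 1e-3
    return GLMMFit(
        beta=beta,
        log_sds={k: float(v) for k, v in log_sds.items()},
        loglik=float(loglik),
        cov_beta=cov_beta,
        converged=converged,
        message=str(res.message),
        scale=scale if gaussian else None,
        n_params=p + m + (1 if gaussian else 0),
    )


def _default_start(data: GLMMData) -> np.ndarray:
    """Start fixed effects from link-transformed cell means when X is an
    indicator design, else zeros."""
    X, y = data.X, data.y
    p = X.shape[1]
    beta0 = np.zeros(p)
    is_indicator = np.all((X == 0) | (X == 1)) and np.all(X.sum(axis=1) == 1)
    if not is_indicator:
        return beta0
    for j in range(p):
        mask = X[:, j] == 1
        if not mask.any():
            continue
        if data.family == "binomial":
            tot = data.trials[mask].sum()
            prop = (y[mask].sum() + 0.5) / (tot + 1.0)
            beta0[j] = math.log(prop / (1 - prop))
        elif data.family == "poisson":
            beta0[j] = math.log(max(float(y[mask].mean()), 1e-3))
        else:
            beta0[j] = float(y[mask].mean())
    return beta0
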
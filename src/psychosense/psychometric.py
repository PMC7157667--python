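"""Weibull 2AFC psychometric fitting by maximum likelihood.

The psychometric function is P(correct | x) = gamma + (1 - gamma - lapse) *
(1 - exp(-(x / alpha)^beta)) with guess rate gamma fixed at 0.5 (2AFC),
scale alpha (% contrast), shape beta, and a lapse rate bounded at 5%.
Thresholds are read off the full performance scale: the 75% threshold is
the contrast at which P(correct) = 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

GUESS_2AFC = 0.5
LAPSE_MAX = 0.05
BETA_BOUNDS = (0.5, 10.0)
_EPS = 1e-12


@dataclass
class PsychFit:
    """A fitted Weibull psychometric function and its derived measures."""

    alpha: float
    beta: float
    gamma: float
    lapse: float
    threshold75: float
    slope_at_threshold: float
    loglik: float
    converged: bool
    n_trials: int


def weibull_p(contrast, alpha, beta, gamma=GUESS_2AFC, lapse=0.0):
    """P(correct) under the Weibull 2AFC model; vectorised in contrast."""
    contrast = np.asarray(contrast, dtype=float)
    if np.any(contrast < 0):
        raise ValueError("contrast must be >= 0")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if not (0 <= lapse <= 1 - gamma):
        raise ValueError("lapse outside [0, 1 - gamma]")
    F = 1.0 - np.exp(-((contrast / alpha) ** beta))
    return gamma + (1.0 - gamma - lapse) * F


def threshold_at(fit_or_params, p: float = 0.75) -> float:
    """Contrast at which P(correct) = p, by exact inversion of weibull_p.

    Accepts a PsychFit or an (alpha, beta, gamma, lapse) tuple.
    """
    if isinstance(fit_or_params, PsychFit):
        alpha, beta, gamma, lapse = (
            fit_or_params.alpha,
            fit_or_params.beta,
            fit_or_params.gamma,
            fit_or_params.lapse,
        )
    else:
        alpha, beta, gamma, lapse = fit_or_params
    if not (gamma < p < 1.0 - lapse):
        raise ValueError(f"p={p} not attainable with gamma={gamma}, lapse={lapse}")
    q = (p - gamma) / (1.0 - gamma - lapse)
    return alpha * (-np.log1p(-q)) ** (1.0 / beta)


def slope_at(fit_or_params, p: float = 0.75) -> float:
    """dP/d(log10 contrast) evaluated at the p-threshold (closed form)."""
    if isinstance(fit_or_params, PsychFit):
        alpha, beta, gamma, lapse = (
            fit_or_params.alpha,
            fit_or_params.beta,
            fit_or_params.gamma,
            fit_or_params.lapse,
        )
    else:
        alpha, beta, gamma, lapse = fit_or_params
    x = threshold_at((alpha, beta, gamma, lapse), p)
    u = (x / alpha) ** beta
    # dP/dx = (1-g-l) * exp(-u) * beta * u / x ; chain rule for log10 x
    return (1.0 - gamma - lapse) * np.exp(-u) * beta * u * np.log(10.0)


def _nll_and_grad(params, contrasts, n_correct, n_total, gamma):
    """Negative Bernoulli log-likelihood and its gradient in
    (log alpha, beta, lapse) coordinates."""
    log_alpha, beta, lapse = params
    ratio = contrasts / np.exp(log_alpha)
    u = ratio**beta
    eu = np.exp(-u)
    F = 1.0 - eu
    scale = 1.0 - gamma - lapse
    p = np.clip(gamma + scale * F, _EPS, 1.0 - _EPS)
    nll = -np.sum(n_correct * np.log(p) + (n_total - n_correct) * np.log1p(-p))
    # dnll/dp, then chain through p(log_alpha, beta, lapse)
    dldp = -(n_correct / p - (n_total - n_correct) / (1.0 - p))
    dp_dloga = scale * eu * (-beta * u)
    dp_dbeta = scale * eu * u * np.log(ratio)
    dp_dlapse = -F
    grad = np.array(
        [
            np.sum(dldp * dp_dloga),
            np.sum(dldp * dp_dbeta),
            np.sum(dldp * dp_dlapse),
        ]
    )
    return nll, grad


def _coarse_grid_start(contrasts, n_correct, n_total, gamma, alpha_lo, alpha_hi):
    """Best point of a small deterministic (alpha, beta, lapse) grid,
    used as extra optimiser starts so multimodal likelihoods (shallow
    data, lapse/shape trade-offs) cannot trap the fit."""
    alphas = np.geomspace(alpha_lo, alpha_hi, 48)
    betas = np.linspace(BETA_BOUNDS[0], BETA_BOUNDS[1], 24)
    lapses = np.array([0.0, 0.0125, 0.025, 0.0375, 0.05])
    a, b, l = np.meshgrid(alphas, betas, lapses, indexing="ij")
    a, b, l = a.ravel(), b.ravel(), l.ravel()
    F = 1.0 - np.exp(-((contrasts[:, None] / a[None, :]) ** b[None, :]))
    p = np.clip(gamma + (1.0 - gamma - l[None, :]) * F, _EPS, 1.0 - _EPS)
    ll = (
        n_correct[:, None] * np.log(p)
        + (n_total - n_correct)[:, None] * np.log1p(-p)
    ).sum(axis=0)
    # one start per beta band: the likelihood can be multimodal in shape
    # (shallow data trade steepness against lapse), and clustered top
    # points would all fall in one basin
    edges = np.linspace(BETA_BOUNDS[0], BETA_BOUNDS[1], 4)
    starts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (b >= lo) & (b <= hi)
        i = np.flatnonzero(mask)[np.argmax(ll[mask])]
        starts.append((np.log(a[i]), b[i], l[i]))
    return starts


def fit_psychometric(
    contrasts,
    n_correct,
    n_total,
    gamma: float = GUESS_2AFC,
) -> PsychFit:
    """Fit (alpha, beta, lapse) to per-contrast correct/total counts by MLE.

    Bounds: alpha in [min contrast / 10, max contrast * 10], beta in
    [0.5, 10], lapse in [0, 0.05]. Five deterministic multi-starts on a
    log-spaced alpha grid; ties in likelihood break toward the lowest
    alpha. Fully saturated data (all correct or all incorrect) cannot
    identify alpha: a boundary estimate is returned with converged=False
    and a warning.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if len(np.unique(contrasts)) < 2:
        raise ValueError("need >= 2 distinct contrast levels to fit")
    if np.any(n_total < 1) or np.any(n_correct < 0) or np.any(n_correct > n_total):
        raise ValueError("invalid counts")
    if np.any(contrasts <= 0):
        raise ValueError("contrasts must be positive")

    alpha_lo, alpha_hi = contrasts.min() / 10.0, contrasts.max() * 10.0
    bounds = [(np.log(alpha_lo), np.log(alpha_hi)), BETA_BOUNDS, (0.0, LAPSE_MAX)]

    degenerate = bool(
        np.all(n_correct == n_total) or np.all(n_correct == 0)
    )

    starts = [(np.log(a0), 2.0, 0.02) for a0 in np.geomspace(alpha_lo * 1.5, alpha_hi / 1.5, 5)]
    starts.extend(
        _coarse_grid_start(contrasts, n_correct, n_total, gamma, alpha_lo, alpha_hi)
    )
    best = None
    for x0 in starts:
        res = minimize(
            _nll_and_grad,
            x0=x0,
            args=(contrasts, n_correct, n_total, gamma),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9 and res.x[0] < best.x[0]
        ):
            best = res

    alpha = float(np.exp(best.x[0]))
    beta = float(best.x[1])
    lapse = float(best.x[2])
    converged = bool(best.success) and not degenerate
    if degenerate:
        warnings.warn(
            "saturated response data: psychometric scale is unidentified, "
            "returning boundary estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    fit = PsychFit(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        lapse=lapse,
        threshold75=threshold_at((alpha, beta, gamma, lapse), 0.75),
        slope_at_threshold=slope_at((alpha, beta, gamma, lapse), 0.75),
        loglik=-float(best.fun),
        converged=converged,
        n_trials=int(n_total.sum()),
    )
    return fit


def grid_loglik_oracle(
    contrasts,
    n_correct,
    n_total,
    gamma: float = GUESS_2AFC,
    n_alpha: int = 200,
    n_beta: int = 100,
    n_lapse: int = 6,
) -> float:
    """Best log-likelihood over an exhaustive (alpha, beta, lapse) grid.

    Independent brute-force check of fit_psychometric; shares only the
    model equation, not the optimiser.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    alphas = np.geomspace(contrasts.min() / 10.0, contrasts.max() * 10.0, n_alpha)
    betas = np.linspace(BETA_BOUNDS[0], BETA_BOUNDS[1], n_beta)
    lapses = np.linspace(0.0, LAPSE_MAX, n_lapse)
    a, b, l = np.meshgrid(alphas, betas, lapses, indexing="ij")
    x = contrasts[:, None]
    F = 1.0 - np.exp(-((x / a.ravel()[None, :]) ** b.ravel()[None, :]))
    p = gamma + (1.0 - gamma - l.ravel()[None, :]) * F
    p = np.clip(p, _EPS, 1.0 - _EPS)
    ll = (
        np.asarray(n_correct, float)[:, None] * np.log(p)
        + (np.asarray(n_total, float) - np.asarray(n_correct, float))[:, None]
        * np.log1p(-p)
    ).sum(axis=0)
    return float(ll.max())
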
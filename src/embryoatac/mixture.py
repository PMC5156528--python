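"""Exponential + Gaussian mixture model for ATAC insert-length distributions.

ATAC libraries are a superposition of short inserts from nucleosome-free DNA
(approximately exponential in length) and longer, nucleosome-protected inserts
(approximately Gaussian around mono-, di-, ... nucleosome spans). Fitting this
mixture by maximum likelihood gives a principled length cutoff for the
open-chromatin fraction: the crossover where the first nucleosomal component
starts to dominate the sub-nucleosomal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["LengthMixtureFit", "MixtureConvergenceError", "fit_length_mixture", "crossover_scan"]


@dataclass
class LengthMixtureFit:
    """Maximum-likelihood parameters of the exponential/Gaussian length mixture.

    ``weights[0]`` belongs to the exponential component, ``weights[1:]`` to the
    Gaussians in increasing-mean order. ``crossover`` is the smallest length at
    which the weighted first-Gaussian density exceeds the weighted exponential
    density, or ``None`` if the densities never cross below the first Gaussian
    mean.
    """

    exp_rate: float
    gaussian_means: np.ndarray
    gaussian_sds: np.ndarray
    weights: np.ndarray
    crossover: float | None
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def component_densities(self, x) -> np.ndarray:
        """Weighted per-component densities, shape (1 + n_gaussians, len(x))."""
        x = np.asarray(x, dtype=float)
        dens = [self.weights[0] * stats.expon.pdf(x, scale=1.0 / self.exp_rate)]
        for w, m, s in zip(self.weights[1:], self.gaussian_means, self.gaussian_sds):
            dens.append(w * stats.norm.pdf(x, loc=m, scale=s))
        return np.vstack(dens)

    def pdf(self, x) -> np.ndarray:
        return self.component_densities(x).sum(axis=0)


class MixtureConvergenceError(RuntimeError):
    """EM failed to converge; carries the last fit for inspection."""

    def __init__(self, fit: LengthMixtureFit):
        self.fit = fit
        super().__init__(f"EM did not converge after {fit.n_iter} iterations")


def _analytic_crossover(w_exp, rate, w_g, mu, sigma) -> float | None:
    """Smallest x in (0, mu) where w_g*N(x; mu, sigma) >= w_exp*Exp(x; rate).

    The log-density difference is a downward parabola in x; the lower root is
    the first crossing.
    """
    if w_g <= 0 or w_exp <= 0:
        return None
    a = 1.0 / (2.0 * sigma**2)
    c_const = np.log(w_g / (sigma * np.sqrt(2 * np.pi))) - np.log(w_exp * rate)
    # a*x^2 - (2*a*mu + rate)*x + (a*mu^2 - c_const) = 0
    b = 2 * a * mu + rate
    c = a * mu**2 - c_const
    disc = b**2 - 4 * a * c
    if disc < 0:
        return None
    x1 = (b - np.sqrt(disc)) / (2 * a)
    if 0 < x1 < mu:
        return float(x1)
    if x1 <= 0:
        # Gaussian already dominates at arbitrarily small lengths
        return 0.0 if c_const >= 0 else None
    return None


def crossover_scan(fit: LengthMixtureFit, resolution: float = 1.0) -> float | None:
    """Grid-scan crossover at fixed resolution (independent of the analytic root)."""
    mu1 = float(fit.gaussian_means[0])
    grid = np.arange(resolution, mu1, resolution)
    if grid.size == 0 or fit.weights[1] <= 0:
        return None
    dens = fit.component_densities(grid)
    above = dens[1] >= dens[0]
    idx = np.flatnonzero(above)
    return float(grid[idx[0]]) if idx.size else None


def fit_length_mixture(
    lengths,
    n_gaussians: int = 2,
    max_iter: int = 500,
    tol: float = 1e-8,
    min_lengths: int = 1000,
) -> LengthMixtureFit:
    """Fit a 1-exponential + ``n_gaussians``-Gaussian mixture by EM.

    Initialization: exponential rate from the mean of lengths < 100 bp,
    Gaussian means at 200, 400, ... bp with 50 bp spread, weights from the
    empirical mass near each component. Convergence is declared when the
    relative log-likelihood change falls below ``tol``; non-convergence after
    ``max_iter`` iterations raises :class:`MixtureConvergenceError` carrying
    the last fit.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < min_lengths:
        raise ValueError(f"need >= {min_lengths} lengths for a stable fit, got {x.size}")
    if n_gaussians < 1:
        raise ValueError("n_gaussians must be >= 1")
    if (x <= 0).any():
        raise ValueError("lengths must be strictly positive")

    short = x[x < 100]
    rate = 1.0 / max(short.mean() if short.size else 50.0, 1.0)
    means = 200.0 * np.arange(1, n_gaussians + 1)
    sds = np.full(n_gaussians, 50.0)
    w_exp0 = np.clip(short.size / x.size, 0.05, 0.95)
    weights = np.concatenate(([w_exp0], np.full(n_gaussians, (1 - w_exp0) / n_gaussians)))

    n = x.size
    loglik_trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = np.vstack(
            [weights[0] * rate * np.exp(-rate * x)]
            + [
                weights[k + 1] * stats.norm.pdf(x, loc=means[k], scale=sds[k])
                for k in range(n_gaussians)
            ]
        )
        total = dens.sum(axis=0)
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        loglik_trace.append(ll)
        resp = dens / total  # responsibilities, shape (K+1, n)

        nk = resp.sum(axis=1)
        weights = nk / n
        if nk[0] > 0:
            rate = nk[0] / float(resp[0] @ x)
        for k in range(n_gaussians):
            if nk[k + 1] <= 1e-12:
                continue
            mu = float(resp[k + 1] @ x) / nk[k + 1]
            var = float(resp[k + 1] @ (x - mu) ** 2) / nk[k + 1]
            means[k] = mu
            sds[k] = np.sqrt(max(var, 1.0))
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

    order = np.argsort(means)
    means = means[order]
    sds = sds[order]
    weights = np.concatenate(([weights[0]], weights[1:][order]))

    crossover = _analytic_crossover(weights[0], rate, weights[1], means[0], sds[0])
    fit = LengthMixtureFit(
        exp_rate=float(rate),
        gaussian_means=means,
        gaussian_sds=sds,
        weights=weights,
        crossover=crossover,
        loglik=loglik_trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=np.asarray(loglik_trace),
    )
    if not converged:
        raise MixtureConvergenceError(fit)
    return fit
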
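"""Adaptive random-walk Metropolis engine and convergence diagnostics.

Small general-purpose MCMC machinery shared by the censored-residue model and
the dichotomous dose-response fits.  Chains are independent random-walk
Metropolis samplers whose multivariate-normal proposal covariance is adapted
(Haario-style) during warmup only and frozen afterwards, so the retained draws
come from a valid time-homogeneous Markov chain.

Log-posterior callables must be vectorized: they receive an array of shape
``(m, ndim)`` and return ``(m,)`` log densities (``-inf`` outside support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["McmcSettings", "McmcResult", "run_metropolis", "compute_rhat"]


@dataclass
class McmcSettings:
    """MCMC run configuration.

    Parameters
    ----------
    n_chains : int
        Number of independent chains (>= 2 so R-hat is defined).
    n_iter : int
        Iterations per chain, including warmup.
    warmup_fraction : float
        Fraction of each chain discarded as warmup; the retained draws are
        the last ``(1 - warmup_fraction)`` of every chain.
    seed : int
        Seed for the chain-specific random generators.
    rhat_threshold : float
        Gelman-Rubin threshold below which a run is declared converged.
    """

    n_chains: int = 4
    n_iter: int = 25_000
    warmup_fraction: float = 0.5
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.n_iter < 10:
            raise ValueError("n_iter too small")

    @property
    def n_warmup(self) -> int:
        return int(self.n_iter * self.warmup_fraction)


@dataclass
class McmcResult:
    """Draws and diagnostics from a Metropolis run.

    ``chains`` has shape ``(n_chains, n_retained, ndim)`` (post-warmup only);
    ``rhat`` one value per parameter; ``accept_rate`` per chain.
    """

    chains: np.ndarray
    rhat: np.ndarray
    accept_rate: np.ndarray
    param_names: list[str] = field(default_factory=list)

    @property
    def draws(self) -> np.ndarray:
        """All retained draws pooled across chains, shape (n, ndim)."""
        return self.chains.reshape(-1, self.chains.shape[-1])

    def converged(self, threshold: float = 1.1) -> bool:
        return bool(np.all(np.isfinite(self.rhat)) and self.rhat.max() < threshold)


def compute_rhat(chain_draws: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    Parameters
    ----------
    chain_draws : array, shape (n_chains, n_iter)
        Post-warmup draws of a scalar parameter, one row per chain.

    Returns
    -------
    float
        The classic (non-split) PSRF
        ``sqrt(((n-1)/n * W + B/n) / W)`` with ``W`` the mean within-chain
        variance and ``B`` the between-chain variance.  ``inf`` when the
        chains are internally constant but disagree; 1.0 when everything is
        constant.
    """
    draws = np.asarray(chain_draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("chain_draws must be 2-D (n_chains, n_iter)")
    m, n = draws.shape
    if m < 2:
        raise ValueError("at least 2 chains are required for R-hat")
    if n < 4:
        raise ValueError("at least 4 draws per chain are required")
    chain_means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0.0:
        return 1.0 if b == 0.0 else float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _adapt_cov(history: np.ndarray) -> np.ndarray:
    """Regularized empirical covariance of warmup history (n, ndim)."""
    ndim = history.shape[1]
    cov = np.cov(history, rowvar=False).reshape(ndim, ndim)
    return cov + 1e-10 * np.eye(ndim)


def run_metropolis(
    log_prob: Callable[[np.ndarray], np.ndarray],
    initial: np.ndarray,
    settings: McmcSettings,
    param_names: list[str] | None = None,
) -> McmcResult:
    """Sample a log density with independent adaptive Metropolis chains.

    Parameters
    ----------
    log_prob : callable
        Vectorized log density, ``(m, ndim) -> (m,)``.
    initial : array, shape (n_chains, ndim)
        Starting point of each chain; must have finite log density.
    settings : McmcSettings
        Chains, iterations, warmup and seed.

    Returns
    -------
    McmcResult
        Post-warmup chains, per-parameter R-hat and acceptance rates.
    """
    initial = np.atleast_2d(np.asarray(initial, dtype=float))
    n_chains, ndim = initial.shape
    if n_chains != settings.n_chains:
        raise ValueError("initial must supply one row per chain")
    lp0 = np.asarray(log_prob(initial), dtype=float)
    if not np.all(np.isfinite(lp0)):
        raise ValueError("initial points must have finite log probability")

    rng = np.random.default_rng(settings.seed)
    n_iter, n_warm = settings.n_iter, settings.n_warmup
    scale = 2.38**2 / ndim

    current = initial.copy()
    current_lp = lp0
    # per-chain proposal Cholesky factors, start isotropic at a guessed scale
    spread = np.maximum(np.abs(current).mean(axis=0), 1.0) * 0.1
    chol = np.broadcast_to(np.diag(spread * np.sqrt(scale)), (n_chains, ndim, ndim)).copy()

    out = np.empty((n_chains, n_iter, ndim))
    accepts = np.zeros(n_chains)
    # adaptation checkpoints, warmup only; more frequent early on
    step = max(100, n_warm // 20)
    adapt_at = set(range(step, n_warm, step))

    for t in range(n_iter):
        z = rng.standard_normal((n_chains, ndim))
        prop = current + np.einsum("cij,cj->ci", chol, z)
        prop_lp = np.asarray(log_prob(prop), dtype=float)
        logu = np.log(rng.random(n_chains))
        accept = logu < (prop_lp - current_lp)
        current[accept] = prop[accept]
        current_lp[accept] = prop_lp[accept]
        out[:, t, :] = current
        if t >= n_warm:
            accepts += accept
        if t in adapt_at:
            for c in range(n_chains):
                cov = _adapt_cov(out[c, t // 2 : t + 1, :])
                try:
                    chol[c] = np.linalg.cholesky(scale * cov)
                except np.linalg.LinAlgError:
                    pass  # keep previous proposal

    retained = out[:, n_warm:, :]
    rhat = np.array([compute_rhat(retained[:, :, k]) for k in range(ndim)])
    return McmcResult(
        chains=retained,
        rhat=rhat,
        accept_rate=accepts / (n_iter - n_warm),
        param_names=list(param_names or [f"p{k}" for k in range(ndim)]),
    )
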
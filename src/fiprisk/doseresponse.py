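"""Bayesian benchmark-dose modelling for dichotomous (quantal) endpoints.

Fits the eight standard dichotomous dose-response models (Logistic,
LogLogistic, Probit, LogProbit, Quantal Linear, Multistage 2nd order,
Weibull, Dichotomous Hill) to incidence data by MCMC with non-informative
(wide uniform) priors, inverts each fitted curve for the benchmark dose (BMD)
at a given benchmark response (BMR, extra risk), and combines the per-model
BMD posteriors into a model-averaged posterior using posterior model weights.

Extra risk at dose d is (p(d) - p(0)) / (1 - p(0)); the BMD solves
extra_risk(BMD) = BMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr, ndtri

from .mcmc import McmcResult, McmcSettings, run_metropolis

__all__ = [
    "DoseResponseData",
    "FIPRONIL_CONVULSION",
    "DichotomousModel",
    "MODELS",
    "ModelFit",
    "BmdPosterior",
    "model_probability",
    "bmd_from_params",
    "bmd_numeric",
    "fit_dichotomous_model",
    "fit_all_models",
    "compute_model_weights",
    "model_average_bmd",
    "load_dose_response",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DoseResponseData:
    """Quantal dose-response table: dose (mg/kg/day), group size, incidence."""

    doses: np.ndarray
    n: np.ndarray
    incidence: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        n = np.asarray(self.n, dtype=int)
        inc = np.asarray(self.incidence, dtype=int)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "incidence", inc)
        if not (d.size == n.size == inc.size):
            raise ValueError("doses, n and incidence must have equal length")
        if d[0] != 0:
            raise ValueError("first dose must be the control (0)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(inc < 0) or np.any(inc > n):
            raise ValueError("incidence must lie in [0, n]")


# The fipronil convulsion data (male SD rats) driving the reference dose.
FIPRONIL_CONVULSION = DoseResponseData(
    doses=np.array([0.0, 0.019, 0.059, 1.27, 12.68]),
    n=np.array([50, 50, 50, 50, 50]),
    incidence=np.array([0, 0, 3, 1, 5]),
)


class DichotomousModel:
    """Base class: a named curve family with a uniform box prior.

    ``prob`` is vectorized over parameter rows: params (m, d), doses (k,)
    -> probabilities (m, k).  ``bmd`` returns the closed-form BMD per row
    (nan where the curve admits no root, e.g. zero slope).
    """

    name: str = ""
    param_names: tuple[str, ...] = ()
    bounds: tuple[tuple[float, float], ...] = ()

    def prob(self, params: np.ndarray, doses: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def bmd(self, params: np.ndarray, bmr: float) -> np.ndarray:
        raise NotImplementedError

    def init_point(self, data: DoseResponseData) -> np.ndarray:
        raise NotImplementedError

    @property
    def ndim(self) -> int:
        return len(self.param_names)

    def in_bounds(self, params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(params)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.all((params >= lo) & (params <= hi), axis=1)

    def log_prior_volume(self) -> float:
        return float(np.sum([np.log(hi - lo) for lo, hi in self.bounds]))


def _bg(data: DoseResponseData) -> float:
    """Smoothed control incidence used to initialize chains."""
    return (data.incidence[0] + 0.5) / (data.n[0] + 1.0)


class Logistic(DichotomousModel):
    name = "Logistic"
    param_names = ("a", "b")
    bounds = ((-50.0, 50.0), (0.0, 100.0))

    def prob(self, params, doses):
        a, b = params[:, 0:1], params[:, 1:2]
        return expit(a + b * doses[None, :])

    def bmd(self, params, bmr):
        a, b = params[:, 0], params[:, 1]
        p0 = expit(a)
        pd_ = p0 + bmr * (1.0 - p0)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = (logit(pd_) - a) / b
        return np.where(b > 0, out, np.nan)

    def init_point(self, data):
        return np.array([logit(_bg(data)), 0.05])


class Probit(DichotomousModel):
    name = "Probit"
    param_names = ("a", "b")
    bounds = ((-50.0, 50.0), (0.0, 100.0))

    def prob(self, params, doses):
        a, b = params[:, 0:1], params[:, 1:2]
        return ndtr(a + b * doses[None, :])

    def bmd(self, params, bmr):
        a, b = params[:, 0], params[:, 1]
        p0 = ndtr(a)
        pd_ = p0 + bmr * (1.0 - p0)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = (ndtri(pd_) - a) / b
        return np.where(b > 0, out, np.nan)

    def init_point(self, data):
        return np.array([ndtri(_bg(data)), 0.05])


class QuantalLinear(DichotomousModel):
    name = "QuantalLinear"
    param_names = ("g", "b")
    bounds = ((0.0, 1.0), (0.0, 100.0))

    def prob(self, params, doses):
        g, b = params[:, 0:1], params[:, 1:2]
        return g + (1.0 - g) * (-np.expm1(-b * doses[None, :]))

    def bmd(self, params, bmr):
        b = params[:, 1]
        with np.errstate(divide="ignore"):
            out = -np.log1p(-bmr) / b
        return np.where(b > 0, out, np.nan)

    def init_point(self, data):
        return np.array([_bg(data), 0.01])


class Multistage2(DichotomousModel):
    name = "Multistage2"
    param_names = ("g", "b1", "b2")
    bounds = ((0.0, 1.0), (0.0, 100.0), (0.0, 100.0))

    def prob(self, params, doses):
        g, b1, b2 = params[:, 0:1], params[:, 1:2], params[:, 2:3]
        d = doses[None, :]
        return g + (1.0 - g) * (-np.expm1(-b1 * d - b2 * d * d))

    def bmd(self, params, bmr):
        b1, b2 = params[:, 1], params[:, 2]
        A = -np.log1p(-bmr)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            quad = (-b1 + np.sqrt(b1 * b1 + 4.0 * b2 * A)) / (2.0 * b2)
            lin = A / b1
        out = np.where(b2 > 0, quad, lin)
        return np.where((b1 > 0) | (b2 > 0), out, np.nan)

    def init_point(self, data):
        return np.array([_bg(data), 0.01, 0.001])


class Weibull(DichotomousModel):
    name = "Weibull"
    param_names = ("g", "b", "k")
    bounds = ((0.0, 1.0), (0.0, 50.0), (1.0, 15.0))

    def __init__(self, restricted: bool = True):
        if not restricted:
            self.bounds = ((0.0, 1.0), (0.0, 50.0), (0.0, 15.0))

    def prob(self, params, doses):
        g, b, k = params[:, 0:1], params[:, 1:2], params[:, 2:3]
        d = doses[None, :]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            dk = np.where(d > 0, np.power(np.maximum(d, _EPS), k), 0.0)
        return g + (1.0 - g) * (-np.expm1(-b * dk))

    def bmd(self, params, bmr):
        b, k = params[:, 1], params[:, 2]
        A = -np.log1p(-bmr)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = np.power(A / b, 1.0 / k)
        return np.where((b > 0) & (k > 0), out, np.nan)

    def init_point(self, data):
        return np.array([_bg(data), 0.01, 1.0])


class LogLogistic(DichotomousModel):
    name = "LogLogistic"
    param_names = ("g", "a", "b")
    bounds = ((0.0, 1.0), (-50.0, 50.0), (1.0, 15.0))

    def __init__(self, restricted: bool = True):
        # restricted keeps the log-dose slope >= 1 (standard plausible-shape bound)
        if not restricted:
            self.bounds = ((0.0, 1.0), (-50.0, 50.0), (0.0, 15.0))

    def prob(self, params, doses):
        g, a, b = params[:, 0:1], params[:, 1:2], params[:, 2:3]
        d = doses[None, :]
        with np.errstate(divide="ignore"):
            frac = np.where(d > 0, expit(a + b * np.log(np.maximum(d, _EPS))), 0.0)
        return g + (1.0 - g) * frac

    def bmd(self, params, bmr):
        a, b = params[:, 1], params[:, 2]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = np.exp((logit(bmr) - a) / b)
        return np.where(b > 0, out, np.nan)

    def init_point(self, data):
        return np.array([_bg(data), -3.0, 1.0])


class LogProbit(DichotomousModel):
    name = "LogProbit"
    param_names = ("g", "a", "b")
    bounds = ((0.0, 1.0), (-50.0, 50.0), (1.0, 15.0))

    def __init__(self, restricted: bool = True):
        if not restricted:
            self.bounds = ((0.0, 1.0), (-50.0, 50.0), (0.0, 15.0))

    def prob(self, params, doses):
        g, a, b = params[:, 0:1], params[:, 1:2], params[:, 2:3]
        d = doses[None, :]
        with np.errstate(divide="ignore"):
            frac = np.where(d > 0, ndtr(a + b * np.log(np.maximum(d, _EPS))), 0.0)
        return g + (1.0 - g) * frac

    def bmd(self, params, bmr):
        a, b = params[:, 1], params[:, 2]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = np.exp((ndtri(bmr) - a) / b)
        return np.where(b > 0, out, np.nan)

    def init_point(self, data):
        return np.array([_bg(data), -3.0, 1.0])


class DichotomousHill(DichotomousModel):
    name = "DichotomousHill"
    param_names = ("g", "v", "a", "b")
    bounds = ((0.0, 1.0), (0.0, 1.0), (-50.0, 50.0), (1.0, 15.0))

    def __init__(self, restricted: bool = True):
        if not restricted:
            self.bounds = ((0.0, 1.0), (0.0, 1.0), (-50.0, 50.0), (0.0, 15.0))

    def prob(self, params, doses):
        g, v = params[:, 0:1], params[:, 1:2]
        a, b = params[:, 2:3], params[:, 3:4]
        d = doses[None, :]
        with np.errstate(divide="ignore"):
            frac = np.where(d > 0, expit(a + b * np.log(np.maximum(d, _EPS))), 0.0)
        return g * v + (v - g * v) * frac

    def bmd(self, params, bmr):
        g, v = params[:, 0], params[:, 1]
        a, b = params[:, 2], params[:, 3]
        p0 = g * v
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            q = bmr * (1.0 - p0) / np.maximum(v * (1.0 - g), _EPS)
            out = np.exp((logit(q) - a) / b)
        ok = (b > 0) & (q < 1.0) & (v > 0) & (g < 1.0)
        return np.where(ok, out, np.nan)

    def init_point(self, data):
        return np.array([_bg(data), 0.5, -2.0, 1.0])


def make_models(restricted: bool = True) -> dict[str, DichotomousModel]:
    """The eight standard dichotomous models, in the canonical order."""
    return {
        m.name: m
        for m in [
            Logistic(),
            LogLogistic(restricted),
            Probit(),
            LogProbit(restricted),
            QuantalLinear(),
            Multistage2(),
            Weibull(restricted),
            DichotomousHill(restricted),
        ]
    }


MODELS: dict[str, DichotomousModel] = make_models()


def model_probability(model: DichotomousModel | str, params: np.ndarray, dose: float) -> float:
    """Response probability of one model at one dose; validates bounds."""
    model = MODELS[model] if isinstance(model, str) else model
    params = np.atleast_2d(np.asarray(params, dtype=float))
    if not model.in_bounds(params).all():
        raise ValueError(f"{model.name}: parameters outside prior bounds")
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    return float(model.prob(params, np.array([dose]))[0, 0])


def bmd_from_params(model: DichotomousModel | str, params: np.ndarray, bmr: float = 0.10) -> float:
    """Closed-form BMD at ``bmr`` extra risk for one parameter vector."""
    model = MODELS[model] if isinstance(model, str) else model
    params = np.atleast_2d(np.asarray(params, dtype=float))
    out = float(model.bmd(params, bmr)[0])
    if not np.isfinite(out) or out <= 0:
        raise ValueError(f"{model.name}: no positive BMD at these parameters (flat curve?)")
    return out


def bmd_numeric(
    model: DichotomousModel | str,
    params: np.ndarray,
    bmr: float = 0.10,
    hi: float = 1e8,
) -> float:
    """Bracketed root-finder BMD, used as an independent check on closed forms."""
    model = MODELS[model] if isinstance(model, str) else model
    params = np.atleast_2d(np.asarray(params, dtype=float))
    p0 = model.prob(params, np.array([0.0]))[0, 0]

    def extra_risk(d: float) -> float:
        pd_ = model.prob(params, np.array([d]))[0, 0]
        return (pd_ - p0) / (1.0 - p0) - bmr

    lo = 1e-12
    if extra_risk(hi) < 0:
        raise ValueError("curve never reaches the benchmark response")
    return float(brentq(extra_risk, lo, hi, xtol=1e-14, rtol=1e-12))


@dataclass
class ModelFit:
    """Posterior of one dichotomous model: parameter and BMD draws."""

    model: DichotomousModel
    data: DoseResponseData
    param_draws: np.ndarray
    bmd_draws: np.ndarray
    pointwise_loglik: np.ndarray  # (n_draws, n_dose_groups)
    rhat: np.ndarray
    converged: bool

    @property
    def loglik_draws(self) -> np.ndarray:
        return self.pointwise_loglik.sum(axis=1)

    @property
    def bmd_median(self) -> float:
        return float(np.nanmedian(self.bmd_draws))


def _binom_loglik(model: DichotomousModel, params: np.ndarray, data: DoseResponseData) -> np.ndarray:
    """Pointwise binomial log likelihood, shape (m, n_groups)."""
    p = np.clip(model.prob(np.atleast_2d(params), data.doses), _EPS, 1.0 - _EPS)
    return data.incidence * np.log(p) + (data.n - data.incidence) * np.log1p(-p)


def fit_dichotomous_model(
    data: DoseResponseData,
    model: DichotomousModel | str,
    mcmc: McmcSettings | None = None,
) -> ModelFit:
    """Fit one dichotomous model by MCMC under its uniform box prior."""
    model = MODELS[model] if isinstance(model, str) else model
    if mcmc is None:
        mcmc = McmcSettings(n_chains=3, n_iter=50_000, warmup_fraction=0.5, seed=76_316)

    lo = np.array([b[0] for b in model.bounds])
    hi = np.array([b[1] for b in model.bounds])

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        ok = model.in_bounds(theta)
        lp = np.full(len(theta), -np.inf)
        if ok.any():
            lp[ok] = _binom_loglik(model, theta[ok], data).sum(axis=1)
        return lp

    rng = np.random.default_rng(mcmc.seed + 1)
    center = model.init_point(data)
    span = np.minimum(0.05 * (hi - lo), 0.5)
    init = np.clip(
        center[None, :] + span * rng.standard_normal((mcmc.n_chains, model.ndim)),
        lo + 1e-6 * (hi - lo),
        hi - 1e-6 * (hi - lo),
    )
    result: McmcResult = run_metropolis(log_prob, init, mcmc, list(model.param_names))

    draws = result.draws
    bmd = model.bmd(draws, 0.10)
    return ModelFit(
        model=model,
        data=data,
        param_draws=draws,
        bmd_draws=bmd,
        pointwise_loglik=_binom_loglik(model, draws, data),
        rhat=result.rhat,
        converged=result.converged(mcmc.rhat_threshold),
    )


def fit_all_models(
    data: DoseResponseData,
    mcmc: McmcSettings | None = None,
    bmr: float = 0.10,
) -> dict[str, ModelFit]:
    """Fit all eight dichotomous models (per-model seeds offset from the base)."""
    fits = {}
    for i, (name, model) in enumerate(MODELS.items()):
        settings = mcmc or McmcSettings(n_chains=3, n_iter=50_000, warmup_fraction=0.5, seed=76_316)
        settings = McmcSettings(
            n_chains=settings.n_chains,
            n_iter=settings.n_iter,
            warmup_fraction=settings.warmup_fraction,
            seed=settings.seed + 1000 * i,
            rhat_threshold=settings.rhat_threshold,
        )
        fit = fit_dichotomous_model(data, model, settings)
        if bmr != 0.10:
            fit.bmd_draws = model.bmd(fit.param_draws, bmr)
        fits[name] = fit
    return fits


def _log_marginal_likelihood_bridge(
    fit: ModelFit,
    n_proposal: int = 4000,
    max_posterior: int = 4000,
    seed: int = 0,
    tol: float = 1e-10,
) -> float:
    """Bridge-sampling estimate of one model's log marginal likelihood.

    Uses a multivariate-normal proposal matched to the posterior draws and
    the optimal-bridge iteration of Meng & Wong; the unnormalized posterior
    is binomial likelihood times the uniform box prior density.
    """
    model, data = fit.model, fit.data
    draws = fit.param_draws
    if len(draws) > max_posterior:
        step = len(draws) // max_posterior
        draws = draws[::step][:max_posterior]

    def log_post(theta: np.ndarray) -> np.ndarray:
        lp = np.full(len(theta), -np.inf)
        ok = model.in_bounds(theta)
        if ok.any():
            lp[ok] = _binom_loglik(model, theta[ok], data).sum(axis=1) - model.log_prior_volume()
        return lp

    mu = draws.mean(axis=0)
    cov = np.cov(draws, rowvar=False).reshape(model.ndim, model.ndim)
    cov += 1e-10 * np.diag(np.maximum(np.diag(cov), 1e-8))
    rng = np.random.default_rng(seed)
    prop = rng.multivariate_normal(mu, cov, size=n_proposal, method="cholesky")

    from scipy.stats import multivariate_normal

    g = multivariate_normal(mu, cov, allow_singular=True)
    l1 = log_post(draws) - g.logpdf(draws)  # posterior draws
    l2 = log_post(prop) - g.logpdf(prop)  # proposal draws
    n1, n2 = len(l1), len(l2)
    s1, s2 = n1 / (n1 + n2), n2 / (n1 + n2)

    lstar = np.median(l1)
    e1 = np.exp(l1 - lstar)
    e2 = np.exp(np.clip(l2 - lstar, -700, 700))
    r = 1.0
    for _ in range(1000):
        num = np.mean(e2 / (s1 * e2 + s2 * r))
        den = np.mean(1.0 / (s1 * e1 + s2 * r))
        r_new = num / den
        if abs(r_new - r) <= tol * abs(r):
            r = r_new
            break
        r = r_new
    return float(np.log(r) + lstar)


def compute_model_weights(
    fits: dict[str, ModelFit], scheme: str = "bic", seed: int = 0
) -> dict[str, float]:
    """Posterior model weights over the fitted models.

    ``bic`` (default): marginal likelihoods approximated by the Schwarz
    criterion, ``max log-lik - (d/2) log(n)`` with n the total number of
    animals; weights are the normalized approximate marginal likelihoods.
    This approximation is insensitive to the (arbitrarily wide) flat prior
    boxes, which otherwise dominate exact Bayes factors.

    ``pseudo_bma``: weights proportional to exp(WAIC elpd) computed from the
    pointwise (per dose group) posterior log likelihoods.

    ``bridge``: normalized marginal likelihoods estimated by bridge sampling
    under each model's uniform box prior; offered for comparison (weakly
    identified models escape the Occam penalty under wide flat boxes and can
    swamp the weights).
    """
    if not fits:
        raise ValueError("no fits supplied")
    names = list(fits)
    log_scores = np.empty(len(names))
    for i, name in enumerate(names):
        fit = fits[name]
        if scheme == "bic":
            n_animals = int(fit.data.n.sum())
            log_scores[i] = float(fit.loglik_draws.max()) - 0.5 * fit.model.ndim * np.log(n_animals)
        elif scheme == "bridge":
            log_scores[i] = _log_marginal_likelihood_bridge(fit, seed=seed + i)
        elif scheme == "pseudo_bma":
            ll = fit.pointwise_loglik
            m = ll.max(axis=0)
            lppd = np.log(np.exp(ll - m).mean(axis=0)) + m
            p_waic = ll.var(axis=0, ddof=1)
            log_scores[i] = float((lppd - p_waic).sum())
        else:
            raise ValueError(f"unknown weight scheme: {scheme}")
    w = np.exp(log_scores - log_scores.max())
    w /= w.sum()
    return dict(zip(names, w))


@dataclass
class BmdPosterior:
    """Model-averaged BMD posterior with the weights that produced it."""

    averaged_draws: np.ndarray
    model_weights: dict[str, float]
    per_model_draws: dict[str, np.ndarray] = field(default_factory=dict)
    bmr: float = 0.10
    seed: int = 0

    def percentile_table(self) -> dict[str, float]:
        """Protection-direction summary (lower-tail percentiles)."""
        d = self.averaged_draws
        return {
            "median": float(np.median(d)),
            "p90_protective": float(np.percentile(d, 10)),
            "p95_protective": float(np.percentile(d, 5)),
            "p99_protective": float(np.percentile(d, 1)),
            "mean": float(np.mean(d)),
            "sd": float(np.std(d, ddof=1)),
        }


def model_average_bmd(
    fits: dict[str, ModelFit],
    weights: dict[str, float] | None = None,
    n_draws: int = 30_000,
    seed: int = 0,
    weight_scheme: str = "bic",
) -> BmdPosterior:
    """Mixture-sample the averaged BMD posterior: pick a model by weight,
    then a BMD draw from that model's posterior (invalid draws excluded)."""
    if weights is None:
        weights = compute_model_weights(fits, scheme=weight_scheme)
    names = list(fits)
    w = np.array([weights[n] for n in names])
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be a simplex over the fitted models")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(names), size=n_draws, p=w)
    out = np.empty(n_draws)
    per_model = {}
    for i, name in enumerate(names):
        valid = fits[name].bmd_draws
        valid = valid[np.isfinite(valid) & (valid > 0)]
        if valid.size == 0:
            raise ValueError(f"{name}: no admissible BMD draws")
        per_model[name] = valid
        mask = idx == i
        out[mask] = rng.choice(valid, size=int(mask.sum()), replace=True)
    return BmdPosterior(
        averaged_draws=out,
        model_weights=dict(zip(names, w)),
        per_model_draws=per_model,
        seed=seed,
    )


def load_dose_response(path: str | Path) -> DoseResponseData:
    df = pd.read_csv(path)
    return DoseResponseData(
        doses=df["dose"].to_numpy(float),
        n=df["n"].to_numpy(int),
        incidence=df["incidence"].to_numpy(int),
    )
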
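"""Maximum-likelihood estimation of founder switch rates.

The ``2**(K+1)`` per-founder switch rates are optimised with L-BFGS on a
logit transform of the log-scaled rate box, using central finite-difference
gradients.  Admixture proportions are read off the fitted rates as the
stationary frequencies of each founder's two-state ancestry chain; by the
invariance principle of ML these proportions are themselves ML estimates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import PhasedGenome, SiteTable
from .hmm import FounderModel, loglikelihood
from .ac import n_founders

__all__ = ["FitOptions", "FitResult", "rates_to_proportions", "fit_ml"]


@dataclasses.dataclass
class FitOptions:
    """Optimiser configuration (all defaults are deliberate choices, the
    source method reports none)."""

    restarts: int = 3
    rate_lo: float = 1e-10
    rate_hi: float = 1e-4
    fd_step: float = 1e-4          # central-difference step, transformed scale
    gtol: float = 1e-5
    ftol: float = 1e-7
    maxiter: int = 500
    seed: int | None = None
    engine: str = "auto"


@dataclasses.dataclass
class FitResult:
    model_hat: FounderModel
    m0_hat: np.ndarray
    loglik: float
    n_evals: int
    converged: bool
    restarts: list
    trace: list

    def to_dict(self) -> dict:
        return {
            "K": self.model_hat.K,
            "m0_hat": [float(x) for x in self.m0_hat],
            "rateAB": [float(x) for x in self.model_hat.rateAB],
            "rateBA": [float(x) for x in self.model_hat.rateBA],
            "pp": float(self.model_hat.pp),
            "loglik": float(self.loglik),
            "n_evals": int(self.n_evals),
            "converged": bool(self.converged),
            "restart_logliks": [float(ll) for ll, _ in self.restarts],
        }


def rates_to_proportions(model: FounderModel) -> np.ndarray:
    """Stationary population-A proportion of each founder's ancestry chain."""
    return model.m0


def _rates_from_x(x: np.ndarray, opt: FitOptions) -> np.ndarray:
    lo, hi = np.log(opt.rate_lo), np.log(opt.rate_hi)
    return np.exp(lo + expit(x) * (hi - lo))


def _x_from_rates(rates: np.ndarray, opt: FitOptions) -> np.ndarray:
    lo, hi = np.log(opt.rate_lo), np.log(opt.rate_hi)
    u = (np.log(np.clip(rates, opt.rate_lo, opt.rate_hi)) - lo) / (hi - lo)
    return logit(np.clip(u, 1e-12, 1 - 1e-12))


def fit_ml(genome: PhasedGenome, sites: SiteTable, K: int, pp: float,
           options: FitOptions | None = None) -> FitResult:
    """Fit founder switch rates by maximising the HMM likelihood.

    Multi-start L-BFGS over the ``2 * 2**K`` logit-transformed rates; the
    phase-switch rate ``pp`` is a known constant, not a parameter.  Returns
    the best restart; ``converged=False`` (never an exception) marks runs
    that hit the iteration cap.
    """
    opt = options or FitOptions()
    if K not in (1, 2, 3):
        raise ValueError(f"K must be 1, 2 or 3, got {K}")
    if np.all(sites.freqA == sites.freqB):
        raise ValueError("degenerate data: freqA == freqB at every site, "
                         "no ancestry information")
    nf = n_founders(K)
    rng = np.random.default_rng(opt.seed)
    n_evals = 0
    trace: list[float] = []

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        rates = _rates_from_x(x, opt)
        model = FounderModel(K, rates[:nf], rates[nf:], pp=pp)
        ll = loglikelihood(genome, sites, model, engine=opt.engine)
        return -ll if np.isfinite(ll) else 1e300

    def gradient(x: np.ndarray) -> np.ndarray:
        g = np.empty_like(x)
        for i in range(x.shape[0]):
            xp, xm = x.copy(), x.copy()
            xp[i] += opt.fd_step
            xm[i] -= opt.fd_step
            g[i] = (objective(xp) - objective(xm)) / (2 * opt.fd_step)
        return g

    restarts: list[tuple[float, FounderModel]] = []
    best = None
    for _ in range(max(1, opt.restarts)):
        m0 = rng.uniform(0.1, 0.9, size=nf)
        total = np.exp(rng.uniform(np.log(opt.rate_lo * 10), np.log(opt.rate_hi / 10),
                                   size=nf))
        x0 = _x_from_rates(np.concatenate([(1 - m0) * total, m0 * total]), opt)

        def callback(xk, _trace=trace):
            _trace.append(-objective(xk))

        res = minimize(objective, x0, jac=gradient, method="L-BFGS-B",
                       callback=callback,
                       options={"maxiter": opt.maxiter, "ftol": opt.ftol,
                                "gtol": opt.gtol})
        rates = _rates_from_x(res.x, opt)
        model = FounderModel(K, rates[:nf], rates[nf:], pp=pp)
        restarts.append((-res.fun, model))
        if best is None or -res.fun > best[0]:
            best = (-res.fun, model, bool(res.success))

    loglik, model_hat, converged = best
    return FitResult(
        model_hat=model_hat,
        m0_hat=rates_to_proportions(model_hat),
        loglik=float(loglik),
        n_evals=n_evals,
        converged=converged,
        restarts=restarts,
        trace=trace,
    )
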
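"""Full empirical-Bayes gamma-Poisson shrinker (MGPS).

The observed count a for each drug–event pair is modelled as Poisson with
mean λ·E, where E is the count expected under independence and λ is the
relative reporting rate.  λ carries a two-component gamma mixture prior

    λ ~ w · Gamma(α₁, β₁) + (1−w) · Gamma(α₂, β₂)      (shape, rate)

whose five hyperparameters are fitted by maximising the marginal likelihood
of the observed counts — a mixture of negative binomials.  The posterior of
λ given (a, E) is again a gamma mixture; EBGM is the geometric mean
exp(E[ln λ]) and EBGM05 the posterior 5th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .signal_stats import ContingencyTable


class MgpsConvergenceError(RuntimeError):
    """Prior optimisation failed; carries the best prior found and the trace."""

    def __init__(self, message: str, best_prior: "MgpsPrior", trace: list[float]):
        super().__init__(message)
        self.best_prior = best_prior
        self.trace = trace


@dataclass(frozen=True)
class MgpsPrior:
    """Hyperparameters of the two-component gamma mixture prior on λ."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.w < 1:
            raise ValueError("mixture weight must lie in (0, 1)")


#: conventional starting point for the hyperparameter search
_INIT = MgpsPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, w=1 / 3)


def _mixture_logpmf(a: np.ndarray, E: np.ndarray, p: MgpsPrior) -> np.ndarray:
    """log marginal pmf of counts under the negative-binomial mixture."""
    lp1 = stats.nbinom.logpmf(a, p.alpha1, p.beta1 / (p.beta1 + E))
    lp2 = stats.nbinom.logpmf(a, p.alpha2, p.beta2 / (p.beta2 + E))
    return np.logaddexp(np.log(p.w) + lp1, np.log1p(-p.w) + lp2)


def mgps_fit(tables: Sequence[ContingencyTable], init: MgpsPrior = _INIT) -> MgpsPrior:
    """Fit the prior by maximum marginal likelihood over all tables at a level.

    Requires at least 20 tables for a stable five-parameter fit.  Raises
    :class:`MgpsConvergenceError` (carrying the best prior found and the
    objective trace) if the optimiser reports failure.
    """
    if len(tables) < 20:
        raise ValueError(f"need >= 20 tables to fit the MGPS prior, got {len(tables)}")
    a = np.array([t.a for t in tables], dtype=float)
    E = np.array([t.expected for t in tables], dtype=float)
    trace: list[float] = []

    def unpack(x: np.ndarray) -> MgpsPrior:
        return MgpsPrior(
            alpha1=float(np.exp(x[0])), beta1=float(np.exp(x[1])),
            alpha2=float(np.exp(x[2])), beta2=float(np.exp(x[3])),
            w=float(special.expit(x[4])),
        )

    def nll(x: np.ndarray) -> float:
        p = unpack(x)
        val = -float(_mixture_logpmf(a, E, p).sum())
        trace.append(val)
        return val

    x0 = np.array([
        np.log(init.alpha1), np.log(init.beta1),
        np.log(init.alpha2), np.log(init.beta2),
        special.logit(init.w),
    ])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    prior = unpack(res.x)
    if not res.success:
        raise MgpsConvergenceError(f"MGPS prior fit did not converge: {res.message}", prior, trace)
    return prior


def _posterior(a: float, E: float, p: MgpsPrior):
    """Posterior mixture: weights Q and per-component gamma (shape, rate)."""
    lq1 = np.log(p.w) + stats.nbinom.logpmf(a, p.alpha1, p.beta1 / (p.beta1 + E))
    lq2 = np.log1p(-p.w) + stats.nbinom.logpmf(a, p.alpha2, p.beta2 / (p.beta2 + E))
    norm = np.logaddexp(lq1, lq2)
    q1 = float(np.exp(lq1 - norm))
    return (
        (q1, p.alpha1 + a, p.beta1 + E),
        (1.0 - q1, p.alpha2 + a, p.beta2 + E),
    )


def ebgm_full(t: ContingencyTable, prior: MgpsPrior) -> tuple[float, float]:
    """Posterior geometric mean of λ and its 5th percentile for one table."""
    comps = _posterior(t.a, t.expected, prior)
    mean_log = sum(q * (special.digamma(s) - np.log(r)) for q, s, r in comps)
    ebgm = float(np.exp(mean_log))

    def cdf(lam: float) -> float:
        return sum(q * stats.gamma.cdf(lam, s, scale=1 / r) for q, s, r in comps)

    lo, hi = 1e-12, 1.0
    while cdf(hi) < 0.05:
        hi *= 2
        if hi > 1e12:  # pragma: no cover - pathological prior
            raise RuntimeError("EBGM05 bracket search failed")
    ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12))
    return ebgm, ebgm05
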
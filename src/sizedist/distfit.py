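"""Maximum-likelihood fitting of right-skewed size distributions.

Cell-size values are strictly positive and right-skewed, so the candidate
families are gamma, lognormal, Weibull and (as a complexity check) the
three-parameter generalized gamma.  Parameterizations:

* gamma: density ``f(x) = rate^shape x^(shape-1) exp(-rate x) / Gamma(shape)``
  — mean ``shape/rate``.
* lognormal: ``ln x ~ Normal(mu, sigma^2)`` with the MLE convention
  ``sigma^2 = mean((ln x - mu)^2)`` (divisor ``n``).
* Weibull: ``f(x) = (k/lam) (x/lam)^(k-1) exp(-(x/lam)^k)``.
* generalized gamma: ``f(x) ∝ x^(shape*power - 1) exp(-(rate x)^power)``,
  which reduces exactly to the gamma at ``power = 1``.

The gamma MLE solves the profile score ``ln(a) - psi(a) = ln(mean) -
mean(ln x)`` by Newton iteration from the Minka closed-form initializer;
the rate follows as ``shape/mean``, so the fitted mean equals the sample
mean exactly.  The Weibull MLE uses the analogous Newton iteration on its
profile score.  The generalized gamma is fitted by a nested search: for
each power ``p`` the transformed values ``x^p`` are gamma-distributed, so
the inner problem reuses the gamma profile and only the outer 1-D search
over ``p`` needs numerical optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .histogram_io import CellSample, ValidationError

FAMILIES = ("gamma", "lognormal", "weibull", "gengamma")

#: free-parameter count per family (for AIC/BIC)
N_PARAMS = {"gamma": 2, "lognormal": 2, "weibull": 2, "gengamma": 3}

MIN_FIT_N = 8


class FitError(ValueError):
    """A sample cannot be fitted (degenerate or out of domain)."""


@dataclass(frozen=True)
class FitResult:
    """Fitted family, parameter estimates and information criteria."""

    family: str
    params: dict[str, float]
    loglik: float
    n: int
    converged: bool
    iterations: int = 0
    message: str = ""

    @property
    def k(self) -> int:
        return N_PARAMS[self.family]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.n)

    def frozen(self):
        """The fitted distribution as a frozen scipy object (for cdf/rvs)."""
        p = self.params
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=1.0 / p["rate"])
        if self.family == "lognormal":
            return stats.lognorm(p["sdlog"], scale=math.exp(p["meanlog"]))
        if self.family == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        if self.family == "gengamma":
            return stats.gengamma(p["shape"], p["power"], scale=1.0 / p["rate"])
        raise ValueError(self.family)

    def cdf(self, x):
        return self.frozen().cdf(x)


def _values(sample: CellSample | np.ndarray) -> np.ndarray:
    x = sample.values if isinstance(sample, CellSample) else np.asarray(sample, float)
    if x.size < MIN_FIT_N:
        raise FitError(f"need at least {MIN_FIT_N} values to fit, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise FitError("values must be finite and > 0")
    if np.all(x == x[0]):
        raise FitError("degenerate sample: all values equal")
    return x


# ---------------------------------------------------------------------------
# gamma


def minka_initial_shape(s):
    """Closed-form starting value for the gamma shape given
    ``s = ln(mean) - mean(ln x) > 0``."""
    s = np.asarray(s, float)
    return (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)


def gamma_shape_from_s(s, tol: float = 1e-10, max_iter: int = 100):
    """Solve ``ln(a) - psi(a) = s`` by Newton iteration (vectorized).

    Returns ``(shape, converged, iterations)``; ``shape`` has the shape of
    ``s``.  The profile score is strictly decreasing in ``a`` so the Newton
    step from the Minka initializer converges in a handful of iterations.
    """
    s = np.asarray(s, float)
    if np.any(s <= 0):
        raise FitError("degenerate sample: ln(mean) - mean(ln x) must be > 0")
    a = minka_initial_shape(s)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        f = np.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        a = np.where(a_new > 0, a_new, a / 2.0)
        if np.all(np.abs(f) < tol):
            converged = True
            break
    return a, converged, it


def gamma_loglik(x: np.ndarray, shape: float, rate: float) -> float:
    n = x.size
    return float(
        n * shape * math.log(rate)
        + (shape - 1.0) * np.sum(np.log(x))
        - rate * np.sum(x)
        - n * special.gammaln(shape)
    )


def fit_gamma(sample: CellSample | np.ndarray) -> FitResult:
    """Gamma MLE; the fitted mean ``shape/rate`` equals the sample mean."""
    x = _values(sample)
    s = math.log(x.mean()) - np.log(x).mean()
    shape, converged, it = gamma_shape_from_s(s)
    shape = float(shape)
    rate = shape / float(x.mean())
    return FitResult(
        family="gamma",
        params={"shape": shape, "rate": rate},
        loglik=gamma_loglik(x, shape, rate),
        n=x.size,
        converged=converged,
        iterations=it,
        message="" if converged else "Newton iteration did not reach tolerance",
    )


# ---------------------------------------------------------------------------
# lognormal


def fit_lognormal(sample: CellSample | np.ndarray) -> FitResult:
    """Closed-form lognormal MLE on the log values (sd with divisor n)."""
    x = _values(sample)
    logx = np.log(x)
    mu = float(logx.mean())
    sigma = float(np.sqrt(np.mean((logx - mu) ** 2)))
    if sigma <= 0:
        raise FitError("degenerate sample: zero variance on the log scale")
    n = x.size
    ll = float(-n * math.log(sigma) - n / 2.0 * math.log(2 * math.pi) - logx.sum() - n / 2.0)
    return FitResult(
        family="lognormal",
        params={"meanlog": mu, "sdlog": sigma},
        loglik=ll,
        n=n,
        converged=True,
        iterations=0,
    )


# ---------------------------------------------------------------------------
# Weibull


def _weibull_profile_scale(x: np.ndarray, k: float) -> float:
    return float(np.mean(x**k) ** (1.0 / k))


def weibull_loglik(x: np.ndarray, k: float, lam: float) -> float:
    n = x.size
    z = (x / lam) ** k
    return float(n * math.log(k) - n * k * math.log(lam) + (k - 1.0) * np.sum(np.log(x)) - z.sum())


def fit_weibull(sample: CellSample | np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> FitResult:
    """Weibull MLE by Newton iteration on the shape profile score."""
    x = _values(sample)
    logx = np.log(x)
    sd = logx.std()
    if sd <= 0:
        raise FitError("degenerate sample on the log scale")
    k = math.pi / (sd * math.sqrt(6.0))  # moment-of-logs initializer
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        xk = x**k
        s0, s1, s2 = xk.sum(), (xk * logx).sum(), (xk * logx**2).sum()
        g = 1.0 / k + logx.mean() - s1 / s0
        gp = -1.0 / k**2 - (s2 * s0 - s1**2) / s0**2
        k_new = k - g / gp
        k = k_new if k_new > 0 else k / 2.0
        if abs(g) < tol:
            converged = True
            break
    lam = _weibull_profile_scale(x, k)
    return FitResult(
        family="weibull",
        params={"shape": float(k), "scale": lam},
        loglik=weibull_loglik(x, float(k), lam),
        n=x.size,
        converged=converged,
        iterations=it,
        message="" if converged else "Newton iteration did not reach tolerance",
    )


# ---------------------------------------------------------------------------
# generalized gamma


def _gengamma_profile(x: np.ndarray, logx: np.ndarray, p: float):
    """Profile log-likelihood over (shape, rate) at fixed power ``p``.

    For fixed ``p`` the variable ``z = x^p`` is gamma(shape, rate^p), so the
    inner problem reduces to the gamma profile; the Jacobian term
    ``n ln p + (p-1) sum(ln x)`` converts the likelihood back to ``x``.
    Returns ``(loglik, shape, rate)`` or ``(-inf, nan, nan)`` when the
    transformed sample is degenerate.
    """
    n = x.size
    logz = p * logx
    # log of mean(z) computed stably through logsumexp
    log_mean_z = special.logsumexp(logz) - math.log(n)
    s = log_mean_z - logz.mean()
    if not np.isfinite(s) or s <= 0:
        return -np.inf, math.nan, math.nan
    shape, _, _ = gamma_shape_from_s(s)
    shape = float(shape)
    log_rate_z = math.log(shape) - log_mean_z
    ll_z = (
        n * shape * log_rate_z
        + (shape - 1.0) * logz.sum()
        - shape * n  # rate_z * sum(z) = n*shape at the profile optimum
        - n * special.gammaln(shape)
    )
    ll = float(ll_z) + n * math.log(p) + (p - 1.0) * logx.sum()
    rate = math.exp(log_rate_z / p)
    return ll, shape, rate


def fit_gengamma(
    sample: CellSample | np.ndarray,
    power_bounds: tuple[float, float] = (0.2, 6.0),
) -> FitResult:
    """Generalized-gamma MLE by an outer 1-D search on the power parameter.

    The log-likelihood is guaranteed to be at least the gamma log-likelihood
    (the gamma is the ``power = 1`` boundary of the search and is always
    evaluated).
    """
    x = _values(sample)
    logx = np.log(x)

    def neg(p: float) -> float:
        return -_gengamma_profile(x, logx, p)[0]

    grid = np.concatenate([np.geomspace(power_bounds[0], power_bounds[1], 25), [1.0]])
    lls = np.array([-neg(p) for p in grid])
    if not np.any(np.isfinite(lls)):
        raise FitError("generalized-gamma profile degenerate on the whole power grid")
    p0 = grid[int(np.nanargmax(lls))]
    lo = max(power_bounds[0], p0 / 1.6)
    hi = min(power_bounds[1], p0 * 1.6)
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6})
    candidates = [(float(res.x)), 1.0, float(p0)]
    best_p = max(candidates, key=lambda p: _gengamma_profile(x, logx, p)[0])
    ll, shape, rate = _gengamma_profile(x, logx, best_p)
    converged = bool(res.success) and np.isfinite(ll)
    return FitResult(
        family="gengamma",
        params={"shape": shape, "rate": rate, "power": best_p},
        loglik=ll,
        n=x.size,
        converged=converged,
        iterations=int(res.nfev) if hasattr(res, "nfev") else 0,
        message="" if converged else "outer power search did not converge",
    )


def gengamma_power_ci(
    sample: CellSample | np.ndarray,
    fit: FitResult | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Wald interval for the power parameter from the profile curvature.

    The standard error comes from a central finite-difference second
    derivative of the profile log-likelihood at the fitted power.
    """
    x = _values(sample)
    logx = np.log(x)
    fit = fit or fit_gengamma(sample)
    p_hat = fit.params["power"]
    h = 1e-3 * max(1.0, p_hat)
    ll = lambda p: _gengamma_profile(x, logx, p)[0]
    d2 = (ll(p_hat + h) - 2.0 * ll(p_hat) + ll(p_hat - h)) / h**2
    if not np.isfinite(d2) or d2 >= 0:
        return (-np.inf, np.inf)
    se = 1.0 / math.sqrt(-d2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (p_hat - z * se, p_hat + z * se)


# ---------------------------------------------------------------------------
# model selection

_FITTERS = {
    "gamma": fit_gamma,
    "lognormal": fit_lognormal,
    "weibull": fit_weibull,
    "gengamma": fit_gengamma,
}


@dataclass
class ModelSelection:
    """Per-family fits with information criteria and EDF statistics."""

    fits: dict[str, FitResult]
    edf: dict[str, tuple[float, float, float]]  # family -> (A2, D, W2)
    errors: dict[str, str] = field(default_factory=dict)

    def table(self):
        import pandas as pd

        rows = []
        for fam, fr in self.fits.items():
            ad, ks, cvm = self.edf.get(fam, (math.nan, math.nan, math.nan))
            rows.append(
                {
                    "family": fam,
                    "loglik": fr.loglik,
                    "aic": fr.aic,
                    "bic": fr.bic,
                    "ad": ad,
                    "ks": ks,
                    "cvm": cvm,
                    "converged": fr.converged,
                    **{f"param_{k}": v for k, v in fr.params.items()},
                }
            )
        return pd.DataFrame(rows).sort_values("ad").reset_index(drop=True)

    def best(self, criterion: str = "ad") -> str:
        """Winning family by lowest AD/KS/CvM statistic or AIC/BIC."""
        if criterion in ("ad", "ks", "cvm"):
            idx = ("ad", "ks", "cvm").index(criterion)
            return min(self.edf, key=lambda fam: self.edf[fam][idx])
        if criterion in ("aic", "bic"):
            return min(self.fits, key=lambda fam: getattr(self.fits[fam], criterion))
        raise ValueError(f"unknown criterion {criterion!r}")


def model_select(
    sample: CellSample | np.ndarray,
    families: Sequence[str] = FAMILIES,
) -> ModelSelection:
    """Fit the requested families and attach EDF goodness-of-fit statistics.

    Fit failures in one family are recorded and do not abort the others.
    """
    from . import gof  # deferred: gof depends on this module for bootstrap refits

    x = _values(sample)
    fits: dict[str, FitResult] = {}
    edf: dict[str, tuple[float, float, float]] = {}
    errors: dict[str, str] = {}
    for fam in families:
        if fam not in _FITTERS:
            raise ValueError(f"unknown family {fam!r}")
        try:
            fr = _FITTERS[fam](x)
            fits[fam] = fr
            edf[fam] = gof.edf_statistics(x, fr.cdf)
        except (FitError, ValidationError) as exc:
            errors[fam] = str(exc)
    if not fits:
        raise FitError(f"all families failed: {errors}")
    return ModelSelection(fits=fits, edf=edf, errors=errors)
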
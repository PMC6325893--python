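"""Normality and goodness-of-fit statistics with calibrated p-values.

Three empirical-distribution-function (EDF) statistics are computed from
the probability-integral transforms ``u_(i) = F(x_(i))`` of the sorted
sample:

* Anderson-Darling ``A^2 = -n - (1/n) sum (2i-1)[ln u_(i) + ln(1-u_(n+1-i))]``
  (tail-weighted; the workhorse statistic of the screen),
* Kolmogorov-Smirnov ``D = max_i max(i/n - u_(i), u_(i) - (i-1)/n)``,
* Cramér-von Mises ``W^2 = sum (u_(i) - (2i-1)/(2n))^2 + 1/(12n)``.

Two null regimes need different calibrations:

* **composite null** — the gamma parameters are estimated from the tested
  sample itself; the A² distribution is then parameter-estimation dependent
  and is calibrated by parametric bootstrap (draw from the fitted gamma,
  refit, recompute A²; default B=999).
* **fully specified null** — shape and rate are given a priori (e.g. the
  averaged wild-type reference); the classical asymptotic A² distribution
  applies, evaluated through the Marsaglia & Marsaglia (2004)
  approximation with its finite-n correction, with a bootstrap fallback
  for small samples.

``u`` values are clamped to ``[1e-12, 1-1e-12]`` before logs so extreme
observations cannot overflow; clamping is reported through ``warnings``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special, stats

from . import distfit
from .histogram_io import CellSample, ValidationError

U_CLAMP = 1e-12


class ContractError(ValueError):
    """A supplied cdf violated its contract (values outside [0, 1])."""


@dataclass(frozen=True)
class GoFResult:
    """A goodness-of-fit statistic with its null specification and p-value."""

    statistic_name: str  # one of SW, AD, KS, CvM
    statistic: float
    null_spec: dict
    p_value: float | None
    calibration: dict = field(default_factory=lambda: {"method": "none"})


def _values(sample) -> np.ndarray:
    if isinstance(sample, CellSample):
        return sample.values
    return np.asarray(sample, float)


# ---------------------------------------------------------------------------
# EDF statistics


def _clamped_u(u: np.ndarray) -> np.ndarray:
    if np.any(u < 0) or np.any(u > 1) or not np.all(np.isfinite(u)):
        raise ContractError("cdf returned values outside [0, 1]")
    n_clamped = int(np.sum((u < U_CLAMP) | (u > 1 - U_CLAMP)))
    if n_clamped:
        warnings.warn(f"{n_clamped} probability-integral value(s) clamped to avoid log overflow", stacklevel=3)
    return np.clip(u, U_CLAMP, 1 - U_CLAMP)


def edf_statistics(sample, cdf: Callable[[np.ndarray], np.ndarray]) -> tuple[float, float, float]:
    """Return ``(A2, D, W2)`` for a sample against an evaluable cdf."""
    x = np.sort(_values(sample))
    n = x.size
    u = _clamped_u(np.asarray(cdf(x), float))
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))
    d = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    w2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1.0 / (12 * n))
    return float(a2), d, w2


def _ad_from_sorted_u(u: np.ndarray) -> np.ndarray:
    """Vectorized A² over rows of already-sorted probability transforms."""
    u = np.clip(u, U_CLAMP, 1 - U_CLAMP)
    n = u.shape[-1]
    i = np.arange(1, n + 1)
    return -n - ((2 * i - 1) * (np.log(u) + np.log1p(-u[..., ::-1]))).mean(-1)


# ---------------------------------------------------------------------------
# Shapiro-Wilk normality


def shapiro_wilk(sample) -> GoFResult:
    """Shapiro-Wilk W and p-value (Royston's algorithm, 3 <= n <= 5000)."""
    x = _values(sample)
    if x.size < 3:
        raise ValidationError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValidationError(f"Shapiro-Wilk p-value approximation limited to n <= 5000, got {x.size}")
    if np.unique(x).size < x.size:
        warnings.warn("ties present in Shapiro-Wilk input (expected for bin-center resampling)", stacklevel=2)
    w, p = stats.shapiro(x)
    return GoFResult(
        statistic_name="SW",
        statistic=float(w),
        null_spec={"family": "normal", "composite": True},
        p_value=float(p),
        calibration={"method": "analytic"},
    )


def lognormality_check(sample) -> GoFResult:
    """Shapiro-Wilk normality test applied to the log-transformed values.

    Lognormal data have normally distributed logs, so rejection here argues
    against lognormality.
    """
    x = _values(sample)
    if np.any(x <= 0):
        raise ValidationError("log transform requires positive values")
    res = shapiro_wilk(np.log(x))
    null_spec = dict(res.null_spec, transform="log")
    return GoFResult(res.statistic_name, res.statistic, null_spec, res.p_value, res.calibration)


# ---------------------------------------------------------------------------
# fixed-null asymptotic AD distribution (Marsaglia & Marsaglia 2004)


def _adinf(z: float) -> float:
    if z <= 0:
        return 0.0
    if z < 2.0:
        return (math.exp(-1.2337141 / z) / math.sqrt(z)) * (
            2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z
        )
    return math.exp(
        -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
    )


def _errfix(n: int, x: float) -> float:
    if x > 0.8:
        return (-130.2137 + (745.2337 - (1705.091 - (1950.646 - (1116.360 - 255.7844 * x) * x) * x) * x) * x) / n
    c = 0.01265 + 0.1757 / n
    if x < c:
        t = x / c
        return (0.0037 / n**3 + 0.00078 / n**2 + 0.00006 / n) * math.sqrt(t) * (1 - t) * (49 * t - 102)
    t = (x - c) / (0.8 - c)
    return (0.04213 / n + 0.01365 / n**2) * (
        -0.00022633 + (6.54034 - (14.6538 - (14.458 - (8.259 - 1.91864 * t) * t) * t) * t) * t
    )


def ad_pvalue_fixed_null(a2: float, n: int) -> float:
    """Upper-tail p-value of A² under a fully specified null."""
    cdf = _adinf(a2)
    cdf = min(1.0, max(0.0, cdf + _errfix(n, cdf)))
    return min(1.0, max(np.finfo(float).tiny, 1.0 - cdf))


# ---------------------------------------------------------------------------
# AD tests against gamma nulls


def _bootstrap_gamma_ad(shape: float, rate: float, n: int, B: int, seed: int, refit: bool) -> np.ndarray:
    """A² null distribution from B gamma(n) resamples, optionally refitting."""
    rng = np.random.default_rng(seed)
    x = rng.gamma(shape, 1.0 / rate, (B, n))
    if refit:
        mean = x.mean(axis=1)
        s = np.log(mean) - np.log(x).mean(axis=1)
        a, _, _ = distfit.gamma_shape_from_s(s)
        r = a / mean
    else:
        a = np.full(B, shape)
        r = np.full(B, rate)
    xs = np.sort(x, axis=1)
    u = special.gammainc(a[:, None], r[:, None] * xs)
    return _ad_from_sorted_u(u)


def ad_test_fitted_gamma(sample, B: int = 999, seed: int = 0) -> GoFResult:
    """Composite-null AD test: gamma parameters estimated from the sample.

    The p-value is calibrated by parametric bootstrap — ``B`` resamples of
    size n from the fitted gamma, each refitted before its A² is computed —
    giving ``p = (1 + #{A²_b >= A²_obs}) / (B + 1)``, bit-reproducible for
    fixed ``(B, seed)``.
    """
    if B < 99:
        raise ValidationError(f"B >= 99 required for a calibrated p-value, got {B}")
    x = _values(sample)
    fit = distfit.fit_gamma(x)
    a2, _, _ = edf_statistics(x, fit.cdf)
    null_a2 = _bootstrap_gamma_ad(fit.params["shape"], fit.params["rate"], x.size, B, seed, refit=True)
    p = (1.0 + np.sum(null_a2 >= a2)) / (B + 1.0)
    return GoFResult(
        statistic_name="AD",
        statistic=a2,
        null_spec={"family": "gamma", "params": dict(fit.params), "composite": True},
        p_value=float(p),
        calibration={"method": "bootstrap", "B": B, "seed": int(seed)},
    )


def ad_test_fixed(
    sample,
    shape: float,
    rate: float,
    method: str = "auto",
    B: int = 999,
    seed: int = 0,
) -> GoFResult:
    """AD test against a fully specified gamma(shape, rate) null.

    ``method="auto"`` uses the asymptotic distribution for n >= 50 and the
    (no-refit) parametric bootstrap below that; both can be forced.
    """
    if shape <= 0 or rate <= 0:
        raise ValidationError("null shape and rate must be > 0")
    x = _values(sample)
    null = stats.gamma(shape, scale=1.0 / rate)
    a2, _, _ = edf_statistics(x, null.cdf)
    if method == "auto":
        method = "asymptotic" if x.size >= 50 else "bootstrap"
    if method == "asymptotic":
        p = ad_pvalue_fixed_null(a2, x.size)
        calibration = {"method": "analytic"}
    elif method == "bootstrap":
        if B < 99:
            raise ValidationError(f"B >= 99 required for a calibrated p-value, got {B}")
        null_a2 = _bootstrap_gamma_ad(shape, rate, x.size, B, seed, refit=False)
        p = float((1.0 + np.sum(null_a2 >= a2)) / (B + 1.0))
        calibration = {"method": "bootstrap", "B": B, "seed": int(seed)}
    else:
        raise ValueError(f"unknown method {method!r}")
    return GoFResult(
        statistic_name="AD",
        statistic=a2,
        null_spec={"family": "gamma", "params": {"shape": shape, "rate": rate}, "composite": False},
        p_value=p,
        calibration=calibration,
    )
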
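"""Numerical helpers: confluent hypergeometric evaluation and alpha-quadrature.

Two primitives recur throughout the package:

* Kummer's confluent hypergeometric function M(a, b, z), needed by the
  closed-form effect-size marginal and the limiting compatibility Bayes
  factor.  For negative arguments the Kummer transformation
  ``M(a, b, -z) = exp(-z) M(b - a, b, z)`` is applied before calling
  ``scipy.special.hyp1f1``; for |z| > 700 (where exp overflows in double
  precision) the integral representation is evaluated in log space.

* The marginal likelihood of the replication estimate under a
  Beta(x, y)-mixed power prior,
  ``int_0^1 N(theta_hat_r | theta_hat_o, se_r^2 + se_o^2/alpha) Be(alpha | x, y) dalpha``.
  The integrand vanishes like sqrt(alpha) at the origin; the integral is
  split at 1e-4 with the substitution u = sqrt(alpha) on the lower piece so
  adaptive Gauss-Kronrod converges quickly.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, special, stats


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""


_SPLIT = 1e-4
_RTOL = 1e-8
_OVERFLOW_Z = 700.0


def _log_kummer_quad(a: float, b: float, z: float) -> float:
    """log M(a, b, z) via the integral representation, stable for large |z|.

    M(a, b, z) = [int_0^1 exp(z t) t^(a-1) (1-t)^(b-a-1) dt] / B(a, b-a),
    valid for b > a > 0.  The integrand's log is maximized and shifted out
    before exponentiating.
    """
    if not (b > a > 0):
        raise ValueError("integral representation requires b > a > 0")

    def logf(t: float) -> float:
        return z * t + (a - 1.0) * math.log(t) + (b - a - 1.0) * math.log1p(-t)

    # locate the maximum of the log-integrand on a coarse grid, refine once
    ts = np.linspace(1e-12, 1.0 - 1e-12, 2001)
    logs = z * ts + (a - 1.0) * np.log(ts) + (b - a - 1.0) * np.log1p(-ts)
    m = float(np.max(logs))
    val, err = integrate.quad(lambda t: math.exp(logf(t) - m), 0.0, 1.0, limit=200)
    if val <= 0:
        raise QuadratureError(f"log-space Kummer quadrature degenerate (err={err})")
    return m + math.log(val) - special.betaln(a, b - a)


def kummer_m(a: float, b: float, z: float) -> float:
    """Confluent hypergeometric function M(a, b, z) with stable branches."""
    if z == 0.0:
        return 1.0
    if z > 0:
        if z < _OVERFLOW_Z:
            return float(special.hyp1f1(a, b, z))
        return math.exp(_log_kummer_quad(a, b, z))
    # z < 0: Kummer transform to a positive argument
    zp = -z
    if zp < _OVERFLOW_Z:
        return math.exp(-zp) * float(special.hyp1f1(b - a, b, zp))
    return math.exp(-zp + _log_kummer_quad(b - a, b, zp))


def kummer_m_vec(a: float, b: float, z: np.ndarray) -> np.ndarray:
    """Vectorized :func:`kummer_m` over an array of arguments."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < _OVERFLOW_Z
    zn = z[small]
    neg = zn < 0
    res = np.empty_like(zn)
    if np.any(~neg):
        res[~neg] = special.hyp1f1(a, b, zn[~neg])
    if np.any(neg):
        res[neg] = np.exp(zn[neg]) * special.hyp1f1(b - a, b, -zn[neg])
    out[small] = res
    for i in np.flatnonzero(~small):
        out.flat[i] = kummer_m(a, b, float(z.flat[i]))
    return out


def marginal_alpha_integral(
    theta_r: float,
    sigma_r: float,
    theta_o: float,
    sigma_o: float,
    x: float,
    y: float,
) -> float:
    """int_0^1 N(theta_r | theta_o, sigma_r^2 + sigma_o^2/alpha) Be(alpha | x, y) dalpha."""
    so2, sr2 = sigma_o**2, sigma_r**2
    d2 = (theta_r - theta_o) ** 2
    log_beta_norm = special.betaln(x, y)
    log_2pi = math.log(2.0 * math.pi)

    def gauss(alpha: float) -> float:
        v = sr2 + so2 / alpha
        return math.exp(-0.5 * (log_2pi + math.log(v)) - 0.5 * d2 / v)

    if min(x, y) < 0.1:
        # nearly all beta mass hugs an endpoint within e^(-1/shape); integrate
        # against the beta CDF instead: int g dBe = int_0^1 g(F^-1(p)) dp
        def by_cdf(p: float) -> float:
            a = float(stats.beta.ppf(p, x, y))
            a = min(max(a, 1e-300), 1.0)
            return gauss(a)

        val, err = integrate.quad(by_cdf, 0.0, 1.0, epsrel=_RTOL, limit=200)
        if not math.isfinite(val) or val <= 0:
            raise QuadratureError(
                f"alpha-quadrature (CDF route) failed: value={val!r}, error={err:g}"
            )
        return val

    def integrand(alpha: float) -> float:
        alpha = min(alpha, 1.0 - 1e-16)  # keep log1p finite at the endpoint
        # beta-kernel terms guarded so shape = 1 never multiplies log(0)
        lx = 0.0 if x == 1.0 else (x - 1.0) * math.log(alpha)
        ly = 0.0 if y == 1.0 else (y - 1.0) * math.log1p(-alpha)
        return gauss(alpha) * math.exp(lx + ly - log_beta_norm)

    # lower piece with u = sqrt(alpha): alpha = u^2, dalpha = 2 u du
    u_hi = math.sqrt(_SPLIT)
    lo, err_lo = integrate.quad(
        lambda u: integrand(u * u) * 2.0 * u, 0.0, u_hi,
        epsrel=_RTOL, epsabs=0.0, limit=200,
    )
    # sharply concentrated beta priors need interior break points so the
    # adaptive rule does not step over the spike
    pts = None
    if max(x, y) > 50.0:
        q = stats.beta.ppf([1e-6, 0.01, 0.5, 0.99, 1.0 - 1e-6], x, y)
        pts = [float(v) for v in q if _SPLIT < v < 1.0]
    hi, err_hi = integrate.quad(
        integrand, _SPLIT, 1.0, epsrel=_RTOL, epsabs=0.0, limit=200, points=pts
    )
    val = lo + hi
    err = err_lo + err_hi
    if not math.isfinite(val) or val <= 0:
        raise QuadratureError(
            f"alpha-quadrature failed: value={val!r}, abs error estimate={err:g}"
        )
    if err > max(1e-280, 1e-5 * val):
        raise QuadratureError(
            f"alpha-quadrature did not converge: achieved abs tolerance {err:g} "
            f"for value {val:g}"
        )
    return val
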
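"""Normal hierarchical (random-effects) model and its power-prior correspondence.

The two-study hierarchical model places study-specific effects
``theta_i ~ N(theta_*, tau^2)`` around an overall effect with a flat prior,
and estimates ``hat_theta_i ~ N(theta_i, se_i^2)``.  For fixed parameters
the replication-specific posterior matches the fixed-alpha power-prior
posterior exactly under the parameter maps

    alpha = se_o^2 / (2 tau^2 + se_o^2)        tau^2 = (1/alpha - 1) se_o^2 / 2
    alpha = (1 - I^2) / (1 + I^2)              I^2   = tau^2 / (tau^2 + se_o^2)

and the correspondence extends to random parameters: a Beta(x, y) prior on
alpha is equivalent to the change-of-variables-matched prior on tau^2 (a
generalized F law whose scale is tied to se_o^2/2) or on I^2 (a generalized
beta law, free of se_o).  The same machinery reconstructs all three
power-prior Bayes factors as hierarchical marginal-likelihood ratios, and
supplies the inverse-gamma heterogeneity prior that repairs the
compatibility test's inconsistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from ._special import QuadratureError
from .models import (
    BayesFactorResult,
    BetaParams,
    IGParams,
    NormalParams,
    ReplicationPair,
)

INFINITE_HETEROGENEITY = float("inf")


# --------------------------------------------------------------------------
# parameter maps
# --------------------------------------------------------------------------

def alpha_from_tau2(tau2: float, sigma_o: float) -> float:
    """alpha = se_o^2 / (2 tau^2 + se_o^2); tau^2 = inf maps to alpha = 0."""
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2!r}")
    if math.isinf(tau2):
        return 0.0
    so2 = sigma_o**2
    return so2 / (2.0 * tau2 + so2)


def tau2_from_alpha(alpha: float, sigma_o: float) -> float:
    """tau^2 = (1/alpha - 1) se_o^2 / 2; alpha = 0 maps to infinite heterogeneity."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha!r}")
    if alpha == 0.0:
        return INFINITE_HETEROGENEITY
    return (1.0 / alpha - 1.0) * sigma_o**2 / 2.0


def alpha_from_I2(I2: float) -> float:
    """alpha = (1 - I^2) / (1 + I^2)."""
    if not 0.0 <= I2 < 1.0:
        raise ValueError(f"I2 must lie in [0, 1), got {I2!r}")
    return (1.0 - I2) / (1.0 + I2)


def I2_from_alpha(alpha: float) -> float:
    """I^2 = (1 - alpha) / (1 + alpha); same functional form as its inverse."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha!r}")
    return (1.0 - alpha) / (1.0 + alpha)


@dataclass(frozen=True)
class HeterogeneityParams:
    """Absolute (tau^2) and relative (I^2) heterogeneity for a reference se_o."""

    tau2: float
    I2: float

    @classmethod
    def from_alpha(cls, alpha: float, sigma_o: float) -> "HeterogeneityParams":
        return cls(tau2_from_alpha(alpha, sigma_o), I2_from_alpha(alpha))


# --------------------------------------------------------------------------
# posteriors
# --------------------------------------------------------------------------

def hier_replication_posterior(pair: ReplicationPair, tau2: float) -> NormalParams:
    """Posterior of the replication-specific effect for fixed heterogeneity.

    Mean and precision combine the replication estimate with the original
    estimate discounted through the chain variance 2 tau^2 + se_o^2.
    Identical to the fixed-alpha power-prior posterior at
    alpha = se_o^2/(2 tau^2 + se_o^2).
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be >= 0, got {tau2!r}")
    o, r = pair.original, pair.replication
    w = 2.0 * tau2 + o.variance
    prec = 1.0 / r.variance + 1.0 / w
    mean = (r.estimate / r.variance + o.estimate / w) / prec
    return NormalParams(mean, 1.0 / prec)


# --------------------------------------------------------------------------
# matched heterogeneity priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchedPriorSpec:
    """Heterogeneity prior matched to a Beta(x, y) prior on alpha.

    Constructed via the change of variables alpha = se_o^2/(2 tau^2 + se_o^2);
    on the tau^2 scale this is a generalized F law GF(y, x) with scale tied
    to se_o^2/2, and on the I^2 scale a generalized beta law independent of
    se_o.  (The two notations are aliases for the same constructive density.)
    """

    family: str  # "GF_on_tau2" | "GBe_on_I2" | "Beta_on_alpha"
    shape1: float
    shape2: float
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("GF_on_tau2", "GBe_on_I2", "Beta_on_alpha"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.shape1 > 0 and self.shape2 > 0):
            raise ValueError("shape parameters must be > 0")


def matched_tau2_prior(prior: BetaParams, sigma_o: float) -> MatchedPriorSpec:
    """The GF-family spec for the tau^2 prior matched to Be(x, y) on alpha."""
    return MatchedPriorSpec("GF_on_tau2", prior.y, prior.x, scale=sigma_o**2 / 2.0)


def matched_tau2_prior_density(
    tau2: float | np.ndarray, prior: BetaParams, sigma_o: float
) -> float | np.ndarray:
    """Density on tau^2 matched to a Beta(x, y) prior on alpha.

    f(tau^2) = Be(se_o^2/(2 tau^2 + se_o^2) | x, y) * 2 se_o^2/(2 tau^2 + se_o^2)^2.
    The uniform alpha prior gives 2 se_o^2/(2 tau^2 + se_o^2)^2, akin to the
    classical "uniform shrinkage" prior.
    """
    tau2 = np.asarray(tau2, dtype=float)
    if np.any(tau2 < 0):
        raise ValueError("tau2 must be >= 0")
    so2 = sigma_o**2
    w = 2.0 * tau2 + so2
    val = stats.beta.pdf(so2 / w, prior.x, prior.y) * 2.0 * so2 / w**2
    return float(val) if np.ndim(val) == 0 else val


def matched_I2_prior_density(
    I2: float | np.ndarray, prior: BetaParams
) -> float | np.ndarray:
    """Density on I^2 matched to a Beta(x, y) prior on alpha (free of se_o).

    f(I^2) = Be((1 - I^2)/(1 + I^2) | x, y) * 2/(1 + I^2)^2.
    """
    I2 = np.asarray(I2, dtype=float)
    if np.any(I2 < 0) or np.any(I2 > 1):
        raise ValueError("I2 must lie in [0, 1]")
    val = stats.beta.pdf((1.0 - I2) / (1.0 + I2), prior.x, prior.y) * 2.0 / (1.0 + I2) ** 2
    return float(val) if np.ndim(val) == 0 else val


# --------------------------------------------------------------------------
# marginal likelihoods and tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PointMass:
    """Degenerate prior at a fixed value (tau^2 = v or theta_* = v)."""

    value: float


class OriginalUpdated:
    """Marker: theta_* | tau^2 ~ N(th_o, se_o^2 + tau^2).

    The overall-effect prior obtained by updating a flat prior for theta_*
    with the original study's likelihood in the hierarchical model.
    """


def _tau2_quad(integrand, sigma_o2: float, prior_quantiles=None) -> float:
    """Integrate over tau^2 in [0, inf) via u = tau^2/(tau^2 + c), c = sigma_o2.

    ``prior_quantiles`` (tau^2 values) become interior break points on the
    u scale, so sharply concentrated heterogeneity priors are resolved.
    """
    c = sigma_o2

    def g(u: float) -> float:
        t = c * u / (1.0 - u)
        jac = c / (1.0 - u) ** 2
        return integrand(t) * jac

    pts = None
    if prior_quantiles is not None:
        pts = sorted(
            float(t / (t + c))
            for t in prior_quantiles
            if math.isfinite(t) and 0.0 < t / (t + c) < 1.0
        )
    val, err = integrate.quad(
        g, 0.0, 1.0, epsrel=1e-10, epsabs=0.0, limit=400, points=pts
    )
    if not math.isfinite(val):
        raise QuadratureError(f"tau^2 quadrature failed (err={err!r})")
    return val


def hier_marginal_likelihood(
    pair: ReplicationPair,
    theta_star_prior: PointMass | NormalParams | OriginalUpdated,
    tau2_prior: PointMass | BetaParams | IGParams,
) -> float:
    """Marginal likelihood of the replication estimate in the hierarchical model.

    ``int N(th_r | theta_*, se_r^2 + tau^2) f(theta_*, tau^2 | H) dtheta_* dtau^2``.
    The theta_* layer integrates analytically (normal-normal); the tau^2
    layer is a point mass, the Beta-matched heterogeneity prior
    (:func:`matched_tau2_prior_density`), or an inverse-gamma law, handled by
    quadrature in the latter two cases.
    """
    o, r = pair.original, pair.replication

    def cond(tau2: float) -> float:
        base_var = r.variance + tau2
        if isinstance(theta_star_prior, PointMass):
            return stats.norm.pdf(r.estimate, theta_star_prior.value, math.sqrt(base_var))
        if isinstance(theta_star_prior, NormalParams):
            return stats.norm.pdf(
                r.estimate,
                theta_star_prior.mean,
                math.sqrt(base_var + theta_star_prior.variance),
            )
        if isinstance(theta_star_prior, OriginalUpdated):
            return stats.norm.pdf(
                r.estimate, o.estimate, math.sqrt(base_var + o.variance + tau2)
            )
        raise ValueError(f"unsupported theta_star prior {theta_star_prior!r}")

    qs = [1e-6, 0.01, 0.5, 0.99, 1.0 - 1e-6]
    if isinstance(tau2_prior, PointMass):
        return float(cond(tau2_prior.value))
    if isinstance(tau2_prior, BetaParams):
        dens = lambda t: matched_tau2_prior_density(t, tau2_prior, o.se)
        alpha_q = stats.beta.ppf(qs, tau2_prior.x, tau2_prior.y)
        quantiles = [(1.0 / a - 1.0) * o.variance / 2.0 for a in alpha_q if a > 0]
    elif isinstance(tau2_prior, IGParams):
        dens = lambda t: stats.invgamma.pdf(t, tau2_prior.q, scale=tau2_prior.r)
        quantiles = list(stats.invgamma.ppf(qs, tau2_prior.q, scale=tau2_prior.r))
    else:
        raise ValueError(f"unsupported tau2 prior {tau2_prior!r}")
    return _tau2_quad(lambda t: cond(t) * dens(t), o.variance, quantiles)


def bfdc_ig(pair: ReplicationPair, ig: IGParams) -> BayesFactorResult:
    """Heterogeneity test with an inverse-gamma prior: H_d: tau^2 ~ IG(q, r) vs H_c: tau^2 = 0.

    Unlike the Beta-on-alpha compatibility test, this test is consistent:
    the Bayes factor tends to zero (resp. infinity) as both standard errors
    shrink when the true effects agree (resp. differ).
    """
    o, r = pair.original, pair.replication

    def integrand(t: float) -> float:
        return stats.norm.pdf(
            r.estimate, o.estimate, math.sqrt(r.variance + o.variance + 2.0 * t)
        ) * stats.invgamma.pdf(t, ig.q, scale=ig.r)

    quantiles = stats.invgamma.ppf([1e-6, 0.01, 0.5, 0.99, 1.0 - 1e-6], ig.q, scale=ig.r)
    num = _tau2_quad(integrand, max(o.variance, ig.r), list(quantiles))
    den = stats.norm.pdf(r.estimate, o.estimate, math.sqrt(r.variance + o.variance))
    return BayesFactorResult(
        float(num / den),
        f"H_d: tau^2 ~ IG({ig.q:g}, {ig.r:g})",
        "H_c: tau^2 = 0",
    )


def bfdc_ig_limit(
    theta_r_true: float, theta_o_true: float, ig: IGParams
) -> tuple[str, float]:
    """Limiting behavior of :func:`bfdc_ig` as both standard errors vanish.

    Returns ``(limit_class, prefactor)`` where limit_class is ``"zero"``
    when the true effects agree (evidence for H_c accumulates without bound)
    and ``"infinite"`` otherwise; the prefactor
    Gamma(q + 1/2) {r + (th_r - th_o)^2/4}^(-(q + 1/2)) / sqrt(4 pi)
    is reported for diagnostics.
    """
    delta2 = (theta_r_true - theta_o_true) ** 2
    pref = (
        special.gamma(ig.q + 0.5)
        * (ig.r + delta2 / 4.0) ** -(ig.q + 0.5)
        / math.sqrt(4.0 * math.pi)
    )
    limit_class = "zero" if theta_r_true == theta_o_true else "infinite"
    return limit_class, float(pref)


def ig_implied_alpha_prior(
    alpha: float | np.ndarray, ig: IGParams, sigma_o: float
) -> float | np.ndarray:
    """Prior on alpha implied by tau^2 ~ IG(q, r) through the parameter map.

    f(alpha) = r^q/Gamma(q) * alpha^(q-1)/(1-alpha)^(q+1) * (2/se_o^2)^q
               * exp{-2 r alpha / (se_o^2 (1 - alpha))}.

    Depends on se_o: the smaller the original standard error, the more mass
    is pushed toward alpha = 0 — this "unscaling" is what makes the
    resulting compatibility test consistent.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 1):
        raise ValueError("alpha must lie in (0, 1)")
    so2 = sigma_o**2
    q, r_ = ig.q, ig.r
    log_val = (
        q * math.log(r_)
        - special.gammaln(q)
        + (q - 1.0) * np.log(alpha)
        - (q + 1.0) * np.log1p(-alpha)
        + q * math.log(2.0 / so2)
        - 2.0 * r_ * alpha / (so2 * (1.0 - alpha))
    )
    val = np.exp(log_val)
    return float(val) if np.ndim(val) == 0 else val
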
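"""Bayes factor tests for the effect size and for study compatibility.

Four tests, all operating on a pair of normal effect estimates:

* ``bf01_effect`` — H0: theta = 0 against H1: theta != 0, with the
  alternative prior being the power prior built from the original study
  (either mixed over alpha ~ Be(x, y), or with alpha fixed at 1, which
  recovers the replication Bayes factor under normality).
* ``bfdc_point`` — complete discounting (alpha = 0) against complete
  pooling (alpha = 1), both hypotheses starting from a proper
  unit-information initial prior N(0, kappa^2).
* ``bfdc_partial`` — partial discounting (alpha ~ Be(1, y)) against
  complete pooling (alpha = 1), no initial prior for theta needed.
* ``bfdc_*_limit`` — the positive constants the two compatibility Bayes
  factors converge to as the replication standard error shrinks to zero:
  the compatibility tests are inconsistent, and these limits quantify the
  maximal attainable evidence.

Orientation: values > 1 favor the first-named (numerator) hypothesis, i.e.
H0 for the effect test and H_d (discounting) for the compatibility tests.
"""

from __future__ import annotations

import math

from scipy import special, stats

from ._special import kummer_m
from .models import (
    BayesFactorResult,
    BetaParams,
    ReplicationPair,
    StudySummary,
    UnitInformation,
    UNIFORM_ALPHA_PRIOR,
    shrinkage_factor,
)
from ._special import marginal_alpha_integral


def bf01_effect(
    pair: ReplicationPair,
    alternative: BetaParams | str = UNIFORM_ALPHA_PRIOR,
) -> BayesFactorResult:
    """Test H0: theta = 0 against the power-prior alternative.

    ``alternative`` is either a :class:`BetaParams` prior for alpha under H1
    or the string ``"point_alpha_1"`` for a point mass at alpha = 1 (the
    replication Bayes factor under normality).  Values > 1 favor H0.
    """
    o, r = pair.original, pair.replication
    log_num = stats.norm.logpdf(r.estimate, 0.0, r.se)
    if isinstance(alternative, str):
        if alternative != "point_alpha_1":
            raise ValueError(f"unknown alternative {alternative!r}")
        log_den = stats.norm.logpdf(
            r.estimate, o.estimate, math.sqrt(o.variance + r.variance)
        )
        h1 = "H1: theta ~ N(theta_o_hat, se_o^2) (alpha = 1)"
    else:
        log_den = math.log(
            marginal_alpha_integral(
                r.estimate, r.se, o.estimate, o.se, alternative.x, alternative.y
            )
        )
        h1 = (
            f"H1: theta | alpha ~ N(theta_o_hat, se_o^2/alpha), "
            f"alpha ~ Be({alternative.x:g}, {alternative.y:g})"
        )
    return BayesFactorResult.from_log(float(log_num - log_den), "H0: theta = 0", h1)


def bfdc_point(
    pair: ReplicationPair, unit: UnitInformation = UnitInformation()
) -> BayesFactorResult:
    """Complete discounting (alpha = 0) vs complete pooling (alpha = 1).

    Both hypotheses start from the unit-information prior N(0, kappa^2);
    under pooling it is updated by the full original likelihood, shrinking
    the original estimate by s = 1/(1 + se_o^2/kappa^2).  Values > 1 favor
    H_d (discounting).
    """
    o, r = pair.original, pair.replication
    s = shrinkage_factor(o.se, unit.kappa2)
    log_num = stats.norm.logpdf(r.estimate, 0.0, math.sqrt(r.variance + unit.kappa2))
    log_den = stats.norm.logpdf(
        r.estimate, s * o.estimate, math.sqrt(r.variance + s * o.variance)
    )
    return BayesFactorResult.from_log(
        float(log_num - log_den),
        "H_d: alpha = 0 (complete discounting)",
        "H_c: alpha = 1 (complete pooling)",
    )


def bfdc_partial(pair: ReplicationPair, y: float = 2.0) -> BayesFactorResult:
    """Partial discounting (alpha ~ Be(1, y)) vs complete pooling (alpha = 1).

    Values > 1 favor H_d (partial discounting).
    """
    if not y > 0:
        raise ValueError(f"y must be > 0, got {y!r}")
    o, r = pair.original, pair.replication
    log_num = math.log(
        marginal_alpha_integral(r.estimate, r.se, o.estimate, o.se, 1.0, y)
    )
    log_den = stats.norm.logpdf(
        r.estimate, o.estimate, math.sqrt(r.variance + o.variance)
    )
    return BayesFactorResult.from_log(
        float(log_num - log_den),
        f"H_d: alpha ~ Be(1, {y:g}) (partial discounting)",
        "H_c: alpha = 1 (complete pooling)",
    )


def bfdc_point_limit(
    theta_r_true: float,
    original: StudySummary,
    unit: UnitInformation = UnitInformation(),
) -> BayesFactorResult:
    """Limit of :func:`bfdc_point` as the replication SE shrinks to zero.

    sqrt(1 - s) * exp[-1/2 {theta_r^2/kappa^2 - (theta_r - s th_o)^2/(s se_o^2)}].
    Minimized (most pro-pooling) at theta_r equal to the original estimate.
    """
    s = shrinkage_factor(original.se, unit.kappa2)
    log_bf = 0.5 * math.log1p(-s) - 0.5 * (
        theta_r_true**2 / unit.kappa2
        - (theta_r_true - s * original.estimate) ** 2 / (s * original.variance)
    )
    return BayesFactorResult.from_log(
        float(log_bf),
        "H_d: alpha = 0 (complete discounting), se_r -> 0",
        "H_c: alpha = 1 (complete pooling), se_r -> 0",
    )


def bfdc_partial_limit(
    theta_r_true: float, original: StudySummary, y: float = 2.0
) -> BayesFactorResult:
    """Limit of :func:`bfdc_partial` as the replication SE shrinks to zero.

    B(3/2, y)/B(1, y) * M(y, y + 3/2, (theta_r - th_o)^2 / (2 se_o^2)).
    Bounded below by B(3/2, y)/B(1, y) > 0: the test cannot accumulate
    unbounded evidence for pooling even from a perfect replication.
    """
    if not y > 0:
        raise ValueError(f"y must be > 0, got {y!r}")
    z = (theta_r_true - original.estimate) ** 2 / (2.0 * original.variance)
    pref = math.exp(special.betaln(1.5, y) - special.betaln(1.0, y))
    val = pref * kummer_m(y, y + 1.5, z)
    return BayesFactorResult(
        val,
        f"H_d: alpha ~ Be(1, {y:g}) (partial discounting), se_r -> 0",
        "H_c: alpha = 1 (complete pooling), se_r -> 0",
    )
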
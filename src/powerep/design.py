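"""Bayes-factor design of replication studies.

Planning a replication amounts to choosing a standard error sigma_r (hence a
sample size) so that the compatibility Bayes factor ``bfdc_point`` will,
with high probability, cross an evidence threshold gamma under the
hypothesis one expects to hold.  Because the success region
{BF_dc <= gamma} is a quadratic set in the future estimate th_r, and th_r is
normal under either hypothesis, the probability of replication success has a
closed form in terms of a non-central chi-squared distribution:

    Pr(BF_dc <= gamma | H_i) = Pr(chi^2_{1, lambda_i} <= X / v_i)

with (m_i, v_i) the predictive mean and variance of th_r under hypothesis
i in {d, c}, X the squared half-width of the success region, and lambda_i
the non-centrality of the shifted estimate.  The closed form is validated
against Monte Carlo simulation in :mod:`powerep.simulation`.

Standard errors translate to total sample sizes through the standardized
mean difference approximation ``n ~= 4 / sigma_r^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .models import StudySummary, UnitInformation, shrinkage_factor


class InfeasibleTargetError(ValueError):
    """The requested success probability lies above the attainable asymptote."""

    def __init__(self, message: str, asymptote: float):
        super().__init__(message)
        self.asymptote = asymptote


@dataclass(frozen=True)
class DesignSpec:
    """A replication-design question: original study, threshold and direction.

    ``hypothesis`` is the truth assumed when computing the success
    probability; ``direction`` says whether success means evidence for
    compatibility (BF_dc <= gamma, gamma < 1 conventionally) or for
    discounting (BF_dc >= gamma, gamma > 1).
    """

    original: StudySummary
    unit: UnitInformation = UnitInformation()
    gamma: float = 0.1
    hypothesis: str = "compatible"
    direction: str = "evidence_for_c"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma!r}")
        if self.hypothesis not in ("compatible", "discount"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.direction not in ("evidence_for_c", "evidence_for_d"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class DesignResult:
    """Closed-form success probability with its intermediate quantities."""

    X: float
    m_i: float
    v_i: float
    lambda_i: float
    probability: float


def success_threshold_X(
    original: StudySummary,
    sigma_r: float,
    unit: UnitInformation = UnitInformation(),
    gamma: float = 0.1,
) -> float:
    """Squared half-width X of the success region {BF_dc <= gamma}.

    The region equals {(th_r - th_o (sigma_r^2 + kappa^2)/kappa^2)^2 <= X};
    a negative X means no future estimate can push the Bayes factor below
    gamma.
    """
    if not sigma_r > 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r!r}")
    k2 = unit.kappa2
    s = shrinkage_factor(original.se, k2)
    so2, sr2 = original.variance, sigma_r**2
    a = sr2 + k2
    b = sr2 + s * so2
    if k2 <= s * so2:
        raise ValueError(
            "degenerate geometry: unit-information variance kappa^2 must exceed "
            "the shrunken original variance s*se_o^2"
        )
    return (a * b / (k2 - s * so2)) * (
        math.log(gamma**2) - math.log(b / a) + s**2 * original.estimate**2 / (k2 - s * so2)
    )


def predictive_moments(
    original: StudySummary,
    sigma_r: float,
    unit: UnitInformation = UnitInformation(),
    hypothesis: str = "compatible",
) -> tuple[float, float]:
    """Predictive mean and variance of the future replication estimate.

    Under H_d (alpha = 0) th_r ~ N(0, sigma_r^2 + kappa^2); under H_c
    (alpha = 1) th_r ~ N(s th_o, sigma_r^2 + s se_o^2), with s the
    unit-information shrinkage factor.
    """
    if not sigma_r > 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r!r}")
    k2 = unit.kappa2
    if hypothesis == "discount":
        return 0.0, sigma_r**2 + k2
    if hypothesis == "compatible":
        s = shrinkage_factor(original.se, k2)
        return s * original.estimate, sigma_r**2 + s * original.variance
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def _prob_bf_below(
    original: StudySummary,
    sigma_r: float,
    unit: UnitInformation,
    gamma: float,
    hypothesis: str,
) -> DesignResult:
    x_val = success_threshold_X(original, sigma_r, unit, gamma)
    m_i, v_i = predictive_moments(original, sigma_r, unit, hypothesis)
    center = original.estimate * (sigma_r**2 + unit.kappa2) / unit.kappa2
    lam = (m_i - center) ** 2 / v_i
    if x_val < 0:
        prob = 0.0
    else:
        prob = float(stats.ncx2.cdf(x_val / v_i, df=1, nc=lam))
    return DesignResult(x_val, m_i, v_i, lam, prob)


def replication_success_probability(spec: DesignSpec, sigma_r: float) -> DesignResult:
    """Closed-form probability of replication success at standard error sigma_r.

    ``evidence_for_c``: Pr(BF_dc <= gamma | hypothesis).
    ``evidence_for_d``: Pr(BF_dc >= gamma | hypothesis), computed as the
    complement of the closed form at the same gamma (no second derivation).
    """
    res = _prob_bf_below(spec.original, sigma_r, spec.unit, spec.gamma, spec.hypothesis)
    if spec.direction == "evidence_for_c":
        return res
    return DesignResult(res.X, res.m_i, res.v_i, res.lambda_i, 1.0 - res.probability)


def find_replication_se(
    spec: DesignSpec,
    target_probability: float,
    bracket: tuple[float, float] = (1e-4, 1.0),
) -> tuple[float, float]:
    """Largest standard error whose success probability reaches the target.

    The success probability is monotone in sigma_r (non-increasing for
    evidence-for-c as sigma_r grows), so the feasible set is an interval
    (0, sigma_r*]; the boundary sigma_r* — the cheapest adequate study — is
    located by bisection on a log grid followed by root refinement.  Returns
    ``(sigma_r, achieved_probability)``.

    Raises :class:`InfeasibleTargetError` when the probability levels off at
    an asymptote below the target even for vanishing standard error.
    """
    if not (0.0 < target_probability < 1.0):
        raise ValueError("target probability must be in (0, 1)")
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")

    def prob(sr: float) -> float:
        return replication_success_probability(spec, sr).probability

    p_lo = prob(lo)
    if p_lo < target_probability:
        # estimate the asymptote by pushing the SE an order of magnitude lower
        asymptote = prob(lo / 10.0)
        raise InfeasibleTargetError(
            f"target probability {target_probability:g} is unattainable: the "
            f"success probability levels off near {asymptote:.4f} as sigma_r -> 0",
            asymptote,
        )
    if prob(hi) >= target_probability:
        return hi, prob(hi)
    # monotone bisection on a log grid to bracket the crossing
    grid = np.geomspace(lo, hi, 64)
    probs = np.array([prob(float(s)) for s in grid])
    idx = int(np.argmax(probs < target_probability))  # first failure
    a, b = float(grid[idx - 1]), float(grid[idx])
    root = optimize.brentq(lambda s: prob(s) - target_probability, a, b, xtol=1e-10)
    # step back inside the feasible side if refinement landed a hair below
    achieved = prob(root)
    if achieved < target_probability:
        root = math.nextafter(root, 0.0)
        while prob(root) < target_probability - 1e-9:
            root *= 0.999999
        achieved = prob(root)
    return float(root), float(achieved)


def sample_size_from_se(sigma_r: float) -> int:
    """Total sample size for a standardized mean difference: n = ceil(4/sigma_r^2)."""
    if not sigma_r > 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r!r}")
    # tolerance keeps exact integers stable under se -> n -> se roundtrips
    return int(math.ceil(4.0 / sigma_r**2 - 1e-9))


def se_from_sample_size(n: float) -> float:
    """Standard error implied by a total sample size: sigma_r = sqrt(4/n)."""
    if not n > 0:
        raise ValueError(f"n must be > 0, got {n!r}")
    return math.sqrt(4.0 / n)


def design_curve(
    original: StudySummary,
    unit: UnitInformation = UnitInformation(),
    gamma_c: float = 0.1,
    gamma_d: float = 10.0,
    sigma_r_grid: np.ndarray | None = None,
):
    """Success-probability curves over a grid of replication standard errors.

    Returns a DataFrame with columns sigma_r, rel_sample_size
    (sigma_o^2 / sigma_r^2, i.e. n_r/n_o under the SMD approximation),
    prob_under_c and prob_under_d for the evidence-for-c criterion at
    gamma_c, plus prob_d_under_c / prob_d_under_d for the evidence-for-d
    criterion at gamma_d.
    """
    import pandas as pd

    if sigma_r_grid is None:
        sigma_r_grid = np.geomspace(original.se / 10.0, original.se * 3.0, 50)
    rows = []
    for sr in np.asarray(sigma_r_grid, dtype=float):
        row = {"sigma_r": sr, "rel_sample_size": original.variance / sr**2}
        for hyp, tag in (("compatible", "c"), ("discount", "d")):
            spec_c = DesignSpec(original, unit, gamma_c, hyp, "evidence_for_c")
            spec_d = DesignSpec(original, unit, gamma_d, hyp, "evidence_for_d")
            row[f"prob_under_{tag}"] = replication_success_probability(
                spec_c, float(sr)
            ).probability
            row[f"prob_d_under_{tag}"] = replication_success_probability(
                spec_d, float(sr)
            ).probability
        rows.append(row)
    return pd.DataFrame(rows)
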
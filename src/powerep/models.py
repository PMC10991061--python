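"""Domain types and prior/likelihood densities for power-prior replication analysis.

The setting is the standard meta-analytic normal approximation: each study
reports an effect estimate ``theta_hat`` whose likelihood is
``N(theta, se^2)`` with known standard error ``se``.  A power prior for the
effect size is built by raising the original study's likelihood to a power
``alpha`` in [0, 1] (0 = discard the original data, 1 = pool completely) and
renormalizing.  Everything downstream (posteriors, Bayes factors, design,
the hierarchical-model correspondence) composes the types and densities
defined here.

Effect sizes are treated as generic reals on a single scale (standardized
mean differences by default); callers transform non-normal effect measures
(e.g. log odds ratios) before constructing :class:`StudySummary`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class ImproperPriorError(ValueError):
    """Raised when a requested prior is improper and unusable for the operation."""


@dataclass(frozen=True)
class StudySummary:
    """One study's effect estimate and its (known) standard error."""

    estimate: float
    se: float
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise ValueError(f"estimate must be finite, got {self.estimate!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be finite and > 0, got {self.se!r}")

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class ReplicationPair:
    """Ordered original + replication study summaries; the universal input."""

    original: StudySummary
    replication: StudySummary


@dataclass(frozen=True)
class BetaParams:
    """Beta(x, y) hyperparameters for the prior on the power parameter alpha."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (self.x > 0 and self.y > 0):
            raise ValueError(f"beta shapes must be > 0, got x={self.x}, y={self.y}")


#: Uniform Be(1, 1) prior on alpha, the conventional default.
UNIFORM_ALPHA_PRIOR = BetaParams(1.0, 1.0)


@dataclass(frozen=True)
class IGParams:
    """Inverse-gamma IG(q, r) hyperparameters (shape q, scale r) for tau^2."""

    q: float
    r: float

    def __post_init__(self) -> None:
        if not (self.q > 0 and self.r > 0):
            raise ValueError(f"IG parameters must be > 0, got q={self.q}, r={self.r}")


@dataclass(frozen=True)
class UnitInformation:
    """Variance kappa^2 of one effective observation (unit-information prior).

    The default kappa^2 = 2 comes from the standardized-mean-difference
    approximation Var(theta_hat) = 4/n with the minimal n = 2 (one
    observation per group).
    """

    kappa2: float = 2.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kappa2) and self.kappa2 > 0):
            raise ValueError(f"kappa2 must be finite and > 0, got {self.kappa2!r}")


@dataclass(frozen=True)
class NormalParams:
    """Mean/variance of a (possibly degenerate) normal distribution."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"variance must be >= 0, got {self.variance!r}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class Interval:
    """Credible interval [lower, upper] at the stated level."""

    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower endpoint exceeds upper endpoint")
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"level must be in (0, 1), got {self.level!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class DensityGrid:
    """Tabulated univariate density on strictly increasing abscissae.

    Carrier for marginal posteriors: supports normalization, trapezoid
    moments, tail probabilities and HPD computation downstream.
    """

    points: np.ndarray
    density: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.points.ndim != 1 or self.points.shape != self.density.shape:
            raise ValueError("points and density must be 1-D arrays of equal length")
        if self.points.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(self.density < 0) or not np.all(np.isfinite(self.density)):
            raise ValueError("density must be finite and non-negative")
        if self.normalized and abs(self.integral() - 1.0) > 1e-6:
            raise ValueError("grid flagged normalized but trapezoid integral is not 1")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.points))

    def normalize(self) -> "DensityGrid":
        z = self.integral()
        if z <= 0:
            raise ValueError("cannot normalize a grid with zero total mass")
        return DensityGrid(self.points, self.density / z, normalized=True)

    def mean(self) -> float:
        g = self if self.normalized else self.normalize()
        return float(np.trapezoid(g.points * g.density, g.points))

    def argmax(self) -> float:
        return float(self.points[int(np.argmax(self.density))])

    def mass_above(self, threshold: float) -> float:
        """Trapezoid mass on {points > threshold}, interpolating the cut point."""
        g = self if self.normalized else self.normalize()
        p, d = g.points, g.density
        if threshold <= p[0]:
            return g.integral()
        if threshold >= p[-1]:
            return 0.0
        i = int(np.searchsorted(p, threshold, side="right"))
        d_cut = float(np.interp(threshold, p, d))
        pp = np.concatenate(([threshold], p[i:]))
        dd = np.concatenate(([d_cut], d[i:]))
        return float(np.trapezoid(dd, pp))


@dataclass(frozen=True)
class BayesFactorResult:
    """A Bayes factor with explicit hypothesis descriptors and orientation.

    ``value`` > 1 favors the numerator hypothesis.  For values below one the
    conventional reciprocal reading ("1/19") is exposed via
    :attr:`reciprocal_display`.  ``log_value`` is authoritative when the
    linear value under- or overflows double precision (evidence can be
    astronomically one-sided for precise, conflicting studies).
    """

    value: float
    numerator_hypothesis: str
    denominator_hypothesis: str
    log_value: float | None = None

    def __post_init__(self) -> None:
        if self.log_value is None:
            if not self.value > 0:
                raise ValueError(f"Bayes factor must be > 0, got {self.value!r}")
            object.__setattr__(self, "log_value", math.log(self.value))
        elif not math.isfinite(self.log_value):
            raise ValueError(f"log Bayes factor must be finite, got {self.log_value!r}")

    @classmethod
    def from_log(
        cls, log_value: float, numerator_hypothesis: str, denominator_hypothesis: str
    ) -> "BayesFactorResult":
        if log_value > 709.0:
            value = float("inf")
        elif log_value < -745.0:
            value = 0.0
        else:
            value = math.exp(log_value)
        return cls(value, numerator_hypothesis, denominator_hypothesis, log_value)

    @property
    def reciprocal_display(self) -> str:
        if self.value == 0.0 or math.isinf(self.value):
            exponent = self.log_value / math.log(10.0)
            return f"10^{exponent:.0f}"
        if self.value < 1.0:
            return f"1/{1.0 / self.value:.3g}"
        return f"{self.value:.3g}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BF[{self.numerator_hypothesis} vs {self.denominator_hypothesis}] "
            f"= {self.reciprocal_display}"
        )


def conditional_power_prior(
    original: StudySummary,
    alpha: float,
    initial: str = "flat",
    unit: UnitInformation | None = None,
) -> NormalParams:
    """Power prior for the effect size conditional on a fixed alpha.

    With a flat initial prior the result is ``N(theta_hat_o, se_o^2/alpha)``;
    with a unit-information initial prior ``N(0, kappa^2)`` the update by the
    alpha-powered original likelihood gives mean
    ``alpha*theta_hat_o / (alpha + se_o^2/kappa^2)`` and variance
    ``1 / (1/kappa^2 + alpha/se_o^2)``.

    Parameters
    ----------
    initial
        ``"flat"`` (improper, requires alpha > 0) or ``"unit_information"``.
    unit
        Unit-information variance; defaults to ``UnitInformation()`` when
        ``initial="unit_information"``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(
            f"alpha must lie in [0, 1], got {alpha!r}; power parameters above 1 "
            "(relative-precision extension) are not supported"
        )
    so2 = original.variance
    if initial == "flat":
        if alpha == 0.0:
            raise ImproperPriorError(
                "alpha = 0 with a flat initial prior leaves the power prior "
                "improper; use initial='unit_information' for a proper prior"
            )
        return NormalParams(original.estimate, so2 / alpha)
    if initial == "unit_information":
        kappa2 = (unit or UnitInformation()).kappa2
        mean = alpha * original.estimate / (alpha + so2 / kappa2)
        variance = 1.0 / (1.0 / kappa2 + alpha / so2)
        return NormalParams(mean, variance)
    raise ValueError(f"unknown initial prior {initial!r}")


def power_prior_joint_density(
    theta: float | np.ndarray,
    alpha: float | np.ndarray,
    pair: ReplicationPair,
    prior: BetaParams = UNIFORM_ALPHA_PRIOR,
) -> float | np.ndarray:
    """Joint prior density f(theta, alpha) = N(theta | theta_hat_o, se_o^2/alpha) Be(alpha | x, y)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in (0, 1]")
    o = pair.original
    val = stats.norm.pdf(theta, o.estimate, np.sqrt(o.variance / alpha)) * stats.beta.pdf(
        alpha, prior.x, prior.y
    )
    return float(val) if np.ndim(val) == 0 else val


def shrinkage_factor(sigma_o: float, kappa2: float = 2.0) -> float:
    """Shrinkage s = 1/(1 + se_o^2/kappa^2) of the original estimate toward zero.

    This is the weight the unit-information initial prior leaves on the
    original estimate after a full-power (alpha = 1) update.
    """
    if not (sigma_o > 0 and kappa2 > 0):
        raise ValueError("sigma_o and kappa2 must be > 0")
    return 1.0 / (1.0 + sigma_o**2 / kappa2)
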
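"""CSV input, full-analysis orchestration and JSON report assembly."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from . import __version__
from .bayes_factors import bf01_effect, bfdc_partial, bfdc_point
from .estimation import (
    alpha_marginal_posterior,
    empirical_bayes_alpha,
    marginal_likelihood,
    theta_marginal_posterior,
)
from .hierarchy import bfdc_ig, hier_replication_posterior, tau2_from_alpha
from .models import (
    BayesFactorResult,
    BetaParams,
    IGParams,
    ReplicationPair,
    StudySummary,
    UnitInformation,
)

_CONFIG_KEYS = {
    "x",
    "y",
    "kappa2",
    "y_discount",
    "level",
    "grid_size",
    "seed",
    "ig_q",
    "ig_r",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Defaults for a full analysis; every field is echoed into the report."""

    x: float = 1.0
    y: float = 1.0
    kappa2: float = 2.0
    y_discount: float = 2.0
    level: float = 0.95
    grid_size: int = 2001
    seed: int = 0
    ig_q: float | None = None
    ig_r: float | None = None

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "AnalysisConfig":
        unknown = sorted(set(mapping) - _CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**mapping)


def read_studies_csv(path: str | Path) -> ReplicationPair:
    """Read a two-row study CSV (header ``label,estimate,se``).

    Row order defines the original (first) then the replication (second).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != [
            "label",
            "estimate",
            "se",
        ]:
            raise ValueError(
                f"{path}: expected header 'label,estimate,se', got {reader.fieldnames!r}"
            )
        studies = []
        for lineno, row in enumerate(reader, start=2):
            try:
                study = StudySummary(
                    float(row["estimate"]), float(row["se"]), row["label"]
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            studies.append(study)
    if len(studies) != 2:
        raise ValueError(
            f"{path}: expected exactly 2 data rows (original, replication), "
            f"got {len(studies)}"
        )
    return ReplicationPair(*studies)


def _bf_dict(bf: BayesFactorResult) -> dict[str, Any]:
    return {
        "value": bf.value,
        "display": bf.reciprocal_display,
        "numerator_hypothesis": bf.numerator_hypothesis,
        "denominator_hypothesis": bf.denominator_hypothesis,
    }


def run_full_analysis(
    pair: ReplicationPair, config: AnalysisConfig = AnalysisConfig()
) -> dict[str, Any]:
    """Posterior summaries, the four Bayes factors and the hierarchy block.

    Deterministic given (pair, config); the returned dict is
    JSON-serializable and echoes every default for auditability.
    """
    prior = BetaParams(config.x, config.y)
    unit = UnitInformation(config.kappa2)
    apost = alpha_marginal_posterior(pair, prior, config.grid_size, config.level)
    tpost = theta_marginal_posterior(pair, prior, config.grid_size, config.level)
    eb = empirical_bayes_alpha(pair)
    tau2_eb = tau2_from_alpha(eb, pair.original.se) if eb > 0 else float("inf")
    report: dict[str, Any] = {
        "inputs": {
            "original": {
                "label": pair.original.label,
                "estimate": pair.original.estimate,
                "se": pair.original.se,
            },
            "replication": {
                "label": pair.replication.label,
                "estimate": pair.replication.estimate,
                "se": pair.replication.se,
            },
        },
        "config": {
            "x": config.x,
            "y": config.y,
            "kappa2": config.kappa2,
            "y_discount": config.y_discount,
            "level": config.level,
            "grid_size": config.grid_size,
            "seed": config.seed,
        },
        "alpha_posterior": {
            "mode": apost.mode,
            "hpd": [apost.hpd.lower, apost.hpd.upper],
            "mean": apost.mean,
        },
        "theta_posterior": {
            "mode": tpost.mode,
            "hpd": [tpost.hpd.lower, tpost.hpd.upper],
            "mean": tpost.mean,
        },
        "marginal_likelihood": marginal_likelihood(pair, prior),
        "eb_alpha": eb,
        "bayes_factors": {
            "bf01_beta": _bf_dict(bf01_effect(pair, prior)),
            "bf01_point": _bf_dict(bf01_effect(pair, "point_alpha_1")),
            "bfdc_point": _bf_dict(bfdc_point(pair, unit)),
            "bfdc_partial": _bf_dict(bfdc_partial(pair, config.y_discount)),
        },
        "hierarchy": {
            "eb_alpha_tau2": tau2_eb,
            "eb_alpha_I2": (1.0 - eb) / (1.0 + eb),
            "posterior_at_eb_alpha": {
                "mean": hier_replication_posterior(pair, tau2_eb).mean
                if eb > 0
                else None,
                "variance": hier_replication_posterior(pair, tau2_eb).variance
                if eb > 0
                else None,
            },
        },
        "version": __version__,
        "seed": config.seed,
    }
    if config.ig_q is not None and config.ig_r is not None:
        report["bayes_factors"]["bfdc_ig"] = _bf_dict(
            bfdc_ig(pair, IGParams(config.ig_q, config.ig_r))
        )
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write an analysis report as JSON."""
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def load_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
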
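"""Synthetic patient cohorts for the post-splenectomy thrombosis analysis.

Real portal-hypertension cohorts with per-patient CTA geometry and Doppler
velocities are not publicly available, so the analysis is exercised on
synthetic patients whose anatomical and flow covariates are drawn from
truncated normal distributions chosen to be plausible for splenomegalic
portal hypertension. Thrombosis labels come from a known logistic risk
model on the true ALWSS, which makes recovery of the score's predictive
power a testable property rather than an act of faith.

The study cohort the analysis emulates (15 patients, 6 of whom developed
post-splenectomy portal venous thrombosis) ships as a small packaged
summary record for prevalence bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import ConfigError, ValidationError

#: Odds-ratio slope of the default label model: 30 cm² of extra ALWSS
#: triples the odds of thrombosis.
DEFAULT_BETA1 = float(np.log(3.0) / 30.0)  # per cm²
#: Intercept calibrated once so the default cohort has ≈40% prevalence
#: (default-cohort ALWSS ≈ 39 ± 13 cm² at n=1000, seed 0); frozen.
DEFAULT_BETA0 = -1.85


@dataclass(frozen=True)
class DistributionSpec:
    """Truncated normal sampling spec (SI units)."""

    mean: float
    sd: float
    low: float
    high: float
    family: str = "truncnorm"

    def __post_init__(self) -> None:
        if self.family != "truncnorm":
            raise ConfigError(f"unsupported distribution family {self.family!r}")
        if not self.sd > 0:
            raise ConfigError("sd must be > 0")
        if not self.low < self.high:
            raise ConfigError("truncation bounds must satisfy low < high")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


#: Default covariate distributions: plausibility choices for splenomegalic
#: portal hypertension, all config-exposed. SI units.
DEFAULT_DISTRIBUTIONS: dict[str, DistributionSpec] = {
    "pv_velocity": DistributionSpec(0.15, 0.04, 0.06, 0.30),  # m/s
    "pv_diameter": DistributionSpec(0.013, 0.002, 0.009, 0.018),  # m
    "sv_diameter": DistributionSpec(0.012, 0.003, 0.007, 0.020),  # m
    "sv_length": DistributionSpec(0.100, 0.025, 0.050, 0.180),  # m
    "sv_tortuosity": DistributionSpec(1.3, 0.2, 1.0, 2.0),
    "spleen_max_diameter": DistributionSpec(0.16, 0.03, 0.10, 0.25),  # m
}

DEFAULT_ANATOMY_PROBABILITIES = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class CohortPatient:
    """One synthetic patient (SI units; label optional)."""

    id: str
    pv_velocity: float
    pv_diameter: float
    sv_diameter: float
    sv_length: float
    sv_tortuosity: float
    anatomy_type: int
    spleen_max_diameter: float
    label: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "pv_velocity",
            "pv_diameter",
            "sv_diameter",
            "sv_length",
            "spleen_max_diameter",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.sv_tortuosity >= 1.0:
            raise ValidationError("sv_tortuosity must be >= 1")
        if self.anatomy_type not in (1, 2, 3):
            raise ValidationError("anatomy_type must be 1, 2 or 3")
        if self.label not in (None, 0, 1):
            raise ValidationError("label must be 0, 1 or None")


@dataclass(frozen=True)
class CohortConfig:
    """Sampling configuration for a synthetic cohort."""

    n: int = 15
    seed: int = 0
    distributions: dict[str, DistributionSpec] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS)
    )
    anatomy_probabilities: tuple[float, float, float] = DEFAULT_ANATOMY_PROBABILITIES
    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1  # per cm² of ALWSS

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("cohort size must be >= 1")
        probs = self.anatomy_probabilities
        if len(probs) != 3 or any(p < 0 for p in probs):
            raise ConfigError("anatomy_probabilities needs 3 non-negative entries")
        if abs(sum(probs) - 1.0) > 1.0e-9:
            raise ConfigError("anatomy_probabilities must sum to 1")
        missing = set(DEFAULT_DISTRIBUTIONS) - set(self.distributions)
        if missing:
            raise ConfigError(f"missing distribution specs: {sorted(missing)}")


def sample_cohort(config: CohortConfig) -> list[CohortPatient]:
    """Draw a deterministic synthetic cohort from ``config``."""
    rng = np.random.default_rng(config.seed)
    draws = {
        name: spec.sample(config.n, rng)
        for name, spec in sorted(config.distributions.items())
    }
    types = rng.choice([1, 2, 3], size=config.n, p=list(config.anatomy_probabilities))
    return [
        CohortPatient(
            id=f"synthetic-{i + 1:04d}",
            pv_velocity=float(draws["pv_velocity"][i]),
            pv_diameter=float(draws["pv_diameter"][i]),
            sv_diameter=float(draws["sv_diameter"][i]),
            sv_length=float(draws["sv_length"][i]),
            sv_tortuosity=float(draws["sv_tortuosity"][i]),
            anatomy_type=int(types[i]),
            spleen_max_diameter=float(draws["spleen_max_diameter"][i]),
        )
        for i in range(config.n)
    ]


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def generate_labels(
    alwss_values: Sequence[float], beta0: float, beta1: float, seed: int
) -> np.ndarray:
    """Bernoulli thrombosis labels from the logistic risk model on ALWSS.

    P(thrombosis) = logistic(β0 + β1·ALWSS[cm²]); deterministic given seed.
    """
    a = np.asarray(alwss_values, dtype=float)
    if not (np.isfinite(beta0) and np.isfinite(beta1)) or not np.all(np.isfinite(a)):
        raise ValidationError("label model inputs must be finite")
    p = logistic(beta0 + beta1 * a)
    rng = np.random.default_rng(seed)
    return (rng.random(a.shape) < p).astype(int)


@dataclass(frozen=True)
class CohortSummary:
    """Headline bookkeeping of the emulated clinical cohort."""

    n: int
    positives: int
    males: int
    females: int
    age_mean: float
    age_sd: float

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.n


def fixture_cohort() -> CohortSummary:
    """Packaged summary of the emulated 15-patient clinical cohort."""
    text = resources.files("portalwss").joinpath("data/cohort_summary.json").read_text()
    raw = json.loads(text)
    return CohortSummary(**raw)
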
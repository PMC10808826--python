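"""The ALWSS score: area of wall below 20% of the space-averaged WSS.

The risk score is patient specific: first the space-averaged wall shear
stress of the whole portal venous surface is computed (area-weighted),
then the low-WSS threshold is set to 20% of that average, and finally
ALWSS is the total wall area whose stress is strictly below the
threshold. Stresses are in Pa; areas are reported in cm².
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, DomainError
from .hemodynamics import WSSField

M2_TO_CM2 = 1.0e4
DEFAULT_LOW_WSS_FRACTION = 0.2


@dataclass(frozen=True)
class MetricsResult:
    """Per-patient WSS summary (stresses in Pa, areas in cm²)."""

    mean_wss: float
    threshold: float
    alwss: float
    total_area: float


def space_averaged_wss(field: WSSField) -> float:
    """Area-weighted mean wall shear stress Σ(τ_i·A_i)/Σ(A_i) in Pa."""
    if not field.strips:
        raise DomainError("cannot average an empty WSS field")
    total_area = sum(strip.area for strip, _ in field.strips)
    if not total_area > 0:
        raise DomainError("total surface area must be > 0")
    weighted = sum(tau * strip.area for strip, tau in field.strips)
    return weighted / total_area


def low_wss_threshold(
    mean_wss: float, fraction: float = DEFAULT_LOW_WSS_FRACTION
) -> float:
    """Patient-specific low-WSS threshold: ``fraction`` of the mean WSS."""
    if mean_wss < 0:
        raise DomainError("mean WSS must be >= 0")
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"low-WSS fraction must lie in (0, 1), got {fraction}")
    return fraction * mean_wss


def alwss(field: WSSField, threshold: float) -> float:
    """Area (cm²) of wall strips with τ_w strictly below ``threshold``.

    Ties at the threshold are excluded ("lower than" is strict), so a
    threshold of zero always yields zero area even on stagnant walls.
    """
    if threshold < 0:
        raise DomainError("threshold must be >= 0")
    area_m2 = sum(strip.area for strip, tau in field.strips if tau < threshold)
    return area_m2 * M2_TO_CM2


def total_area_cm2(field: WSSField) -> float:
    return sum(strip.area for strip, _ in field.strips) * M2_TO_CM2


def compute_metrics(
    field: WSSField, fraction: float = DEFAULT_LOW_WSS_FRACTION
) -> MetricsResult:
    """Mean WSS, threshold and ALWSS of one postoperative surface field."""
    mean = space_averaged_wss(field)
    thr = low_wss_threshold(mean, fraction)
    return MetricsResult(
        mean_wss=mean,
        threshold=thr,
        alwss=alwss(field, thr),
        total_area=total_area_cm2(field),
    )
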
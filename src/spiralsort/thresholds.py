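"""Focusing-threshold models TM1-TM4 and the density-coefficient calibration.

A particle focuses when ``a / x >= 0.07`` where ``x`` is a characteristic
channel length: hydraulic diameter ``D`` (TM1), channel height ``h`` (TM2),
or ``(D + 3h) / 4`` (TM3).  TM4 keeps ``x = D`` but scales the criterion by a
density coefficient ``c >= 1`` that grows linearly with particle density
(in g/ml): ``c = 0.127 * rho + 0.867`` over 1.05-2.75 g/ml.

Density enters these formulas in g/ml; conversion from SI happens at this
module's boundary and nowhere else.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DomainError
from .geometry_flow import RectChannel, hydraulic_diameter

#: the size-to-channel ratio above which inertial lift dominates
FOCUSING_RATIO_CRITERION = 0.07

#: default absolute tolerance (m) when comparing a diameter to a threshold;
#: half the 0.1-um reporting granularity of measured diameters
FOCUS_COMPARISON_ATOL = 0.05e-6


class ThresholdModel(str, enum.Enum):
    TM1 = "TM1"
    TM2 = "TM2"
    TM3 = "TM3"
    TM4 = "TM4"


@dataclass(frozen=True)
class DensityCoefficientModel:
    """Linear model ``c(rho) = slope * rho + intercept`` with rho in g/ml.

    Predictions are clamped below at 1 (the coefficient never shrinks the
    threshold); densities outside ``valid_range`` trigger a warning, not an
    error.
    """

    slope: float = 0.127
    intercept: float = 0.867
    valid_range: tuple[float, float] = (1.05, 2.75)

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if lo >= hi:
            raise CalibrationError("valid_range must be an increasing interval")

    def predict(self, density_g_per_ml: float) -> float:
        return density_coefficient(density_g_per_ml, self)


def density_coefficient(
    density_g_per_ml: float, model: DensityCoefficientModel | None = None
) -> float:
    """Density coefficient ``c`` for a particle density in g/ml, clamped >= 1."""
    if density_g_per_ml <= 0:
        raise DomainError(f"density must be positive, got {density_g_per_ml} g/ml")
    model = model or DensityCoefficientModel()
    lo, hi = model.valid_range
    if not lo <= density_g_per_ml <= hi:
        warnings.warn(
            f"density {density_g_per_ml} g/ml is outside the calibrated range "
            f"[{lo}, {hi}] g/ml; extrapolating",
            stacklevel=2,
        )
    c = model.slope * density_g_per_ml + model.intercept
    return max(c, 1.0)


def characteristic_length(model: ThresholdModel | str, channel: RectChannel) -> float:
    """The length ``x`` the focusing criterion ``a/x >= 0.07`` is taken against."""
    model = ThresholdModel(model)
    d = hydraulic_diameter(channel)
    if model is ThresholdModel.TM1 or model is ThresholdModel.TM4:
        return d
    if model is ThresholdModel.TM2:
        return channel.height
    if model is ThresholdModel.TM3:
        return (d + 3.0 * channel.height) / 4.0
    raise DomainError(f"unknown threshold model {model!r}")  # pragma: no cover


def threshold_diameter(
    model: ThresholdModel | str, channel: RectChannel, c: float = 1.0
) -> float:
    """Smallest focused diameter (m): ``0.07*x`` for TM1-TM3, ``0.07*c*D`` for TM4.

    TM4 with ``c = 1`` coincides with TM1 exactly.
    """
    model = ThresholdModel(model)
    x = characteristic_length(model, channel)
    if model is ThresholdModel.TM4:
        if c < 1.0:
            raise DomainError(f"TM4 density coefficient must be >= 1, got {c}")
        return FOCUSING_RATIO_CRITERION * c * x
    return FOCUSING_RATIO_CRITERION * x


def calibrate_density_model(
    anchors: list[tuple[float, float]],
) -> DensityCoefficientModel:
    """Least-squares line through ``(density g/ml, c)`` anchor pairs.

    Two anchors interpolate exactly.  The validity range is the anchor span.
    """
    if len(anchors) < 2:
        raise CalibrationError("need at least 2 anchor points")
    rho = np.asarray([a[0] for a in anchors], dtype=float)
    c = np.asarray([a[1] for a in anchors], dtype=float)
    if len(np.unique(rho)) < 2:
        raise CalibrationError("anchor densities must include at least 2 distinct values")
    slope, intercept = np.polyfit(rho, c, deg=1)
    return DensityCoefficientModel(
        slope=float(slope),
        intercept=float(intercept),
        valid_range=(float(rho.min()), float(rho.max())),
    )


def coefficient_from_threshold(threshold: float, channel: RectChannel) -> float:
    """Invert TM4: the coefficient implied by an observed threshold diameter."""
    if threshold <= 0:
        raise DomainError("threshold diameter must be positive")
    return threshold / (FOCUSING_RATIO_CRITERION * hydraulic_diameter(channel))


def is_focused(
    diameter: float,
    model: ThresholdModel | str,
    channel: RectChannel,
    density_g_per_ml: float | None = None,
    dcm: DensityCoefficientModel | None = None,
    atol: float = FOCUS_COMPARISON_ATOL,
) -> bool:
    """Whether a particle of ``diameter`` (m) meets the model's criterion.

    The comparison allows ``atol`` of slack (default 0.05 um) so diameters
    quoted at reporting granularity are not rejected by sub-resolution
    differences; pass ``atol=0`` for a strict comparison.
    """
    model = ThresholdModel(model)
    c = 1.0
    if model is ThresholdModel.TM4:
        if density_g_per_ml is None:
            raise DomainError("TM4 requires the particle density (g/ml)")
        c = density_coefficient(density_g_per_ml, dcm)
    return diameter >= threshold_diameter(model, channel, c) - atol


# --- human-readable rounding -------------------------------------------------

def round_to_micron(length: float) -> float:
    """Nearest whole micron, returned in metres."""
    return round(length * 1e6) * 1e-6


def round_to_half_micron(length: float) -> float:
    """Nearest 0.5 um, returned in metres."""
    return round(length * 2e6) / 2.0 * 1e-6


def tm3_rounded_chain(channel: RectChannel) -> float:
    """TM3 threshold computed from the micron-rounded TM1/TM2 thresholds.

    ``(round(0.07 D) + 3 round(0.07 h)) / 4`` in metres — a display convention
    in which the component thresholds are rounded before averaging, as opposed
    to :func:`threshold_diameter` which applies 0.07 to ``(D + 3h)/4`` at full
    precision.
    """
    t1 = round_to_micron(threshold_diameter(ThresholdModel.TM1, channel))
    t2 = round_to_micron(threshold_diameter(ThresholdModel.TM2, channel))
    return (t1 + 3.0 * t2) / 4.0
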
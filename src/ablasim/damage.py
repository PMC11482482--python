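"""Thermal-damage models: Arrhenius kinetics and critical-temperature necrosis.

The Arrhenius damage integral treats cell death as a first-order rate
process with temperature-dependent rate A*exp(-Ea/(R*(T + 273.15))), T in
degC.  The accumulated exposure

    Omega(t) = integral_0^t A exp(-Ea / (R (T(t') + 273.15))) dt'

maps to a completed damage fraction 1 - exp(-Omega); Omega = 1 corresponds
to 63% completion and is the necrosis threshold.  The default constants
(A = 7.39e39 1/s, Ea = 2.577e5 J/mol) are the standard liver-tissue pair.
The critical-temperature model declares necrosis wherever the tissue reaches
60 degC (either ever, or at the final time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bioheat import ZERO_C, TemperatureHistory

__all__ = [
    "DamageParams",
    "DamageField",
    "arrhenius_integral",
    "damage_fraction",
    "arrhenius_mask",
    "critical_temp_mask",
]

GAS_CONSTANT = 8.3145  # J/(mol K)


@dataclass(frozen=True)
class DamageParams:
    frequency_factor: float = 7.39e39  # 1/s
    activation_energy: float = 2.577e5  # J/mol
    omega_threshold: float = 1.0
    critical_temperature: float = 60.0  # degC
    critical_mode: str = "max_over_time"  # or "final_time"

    def __post_init__(self) -> None:
        if self.frequency_factor <= 0 or self.activation_energy <= 0:
            raise ValueError("A and Ea must be > 0")
        if self.omega_threshold <= 0:
            raise ValueError("omega threshold must be > 0")
        if self.critical_mode not in ("max_over_time", "final_time"):
            raise ValueError("critical_mode must be 'max_over_time' or 'final_time'")

    def rate(self, temperature_celsius: np.ndarray) -> np.ndarray:
        """Damage rate A*exp(-Ea/(R*(T+273.15))) for T in degC."""
        t_abs = np.asarray(temperature_celsius, dtype=float) + ZERO_C
        return self.frequency_factor * np.exp(
            -self.activation_energy / (GAS_CONSTANT * t_abs)
        )


@dataclass
class DamageField:
    """Accumulated Arrhenius exposure per cell."""

    omega: np.ndarray  # (nr, nz), dimensionless, >= 0

    @property
    def fraction(self) -> np.ndarray:
        """Completed damage fraction 1 - exp(-Omega), in [0, 1)."""
        return -np.expm1(-self.omega)


def arrhenius_integral(history: TemperatureHistory, params: DamageParams | None = None) -> DamageField:
    """Trapezoidal accumulation of the damage integral over the snapshots.

    The integrand is evaluated at the snapshot cadence, so steep temperature
    ramps need a commensurately fine cadence.
    """
    params = params or DamageParams()
    times = history.times
    if np.any(np.diff(times) <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    if len(times) < 2:
        return DamageField(omega=np.zeros_like(history.fields[0]))
    rates = params.rate(history.fields - ZERO_C)  # fields are K
    omega = np.zeros_like(rates[0])
    dt = np.diff(times)
    for n in range(len(dt)):
        omega += 0.5 * dt[n] * (rates[n] + rates[n + 1])
    return DamageField(omega=omega)


def damage_fraction(omega: float | np.ndarray) -> float | np.ndarray:
    """Completed fraction 1 - exp(-omega) of the damage process."""
    if np.any(np.asarray(omega) < 0):
        raise ValueError("omega must be >= 0")
    return -np.expm1(-omega)


def arrhenius_mask(damage: DamageField, params: DamageParams | None = None) -> np.ndarray:
    """Binary necrosis mask: Omega strictly greater than the threshold."""
    params = params or DamageParams()
    if not np.isfinite(damage.omega).all():
        raise ValueError("damage field contains non-finite values")
    return damage.omega > params.omega_threshold


def critical_temp_mask(history: TemperatureHistory, params: DamageParams | None = None) -> np.ndarray:
    """Binary necrosis mask from the critical-temperature model.

    ``max_over_time`` uses the running maximum field (necrosis is
    irreversible); ``final_time`` uses the end-time isoline.
    """
    params = params or DamageParams()
    if len(history.times) == 0:
        raise ValueError("empty temperature history")
    stat = history.max_field if params.critical_mode == "max_over_time" else history.final
    return (stat - ZERO_C) >= params.critical_temperature
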
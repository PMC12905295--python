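"""Transition-state-theory (Eyring) conversion between barriers and rates.

    k = kappa * (k_B T / h) * exp(-dG / (R T))

with dG in kcal/mol and k in 1/s.  The prefactor k_B T / h is about
6.21e12 1/s at 298.15 K.  The transmission coefficient kappa defaults
to 1 (no recrossing correction).

A unit-conversion caveat worth knowing when comparing against published
numbers: printed rate↔barrier conversions in the literature are sometimes
made at standard temperature (298.15 K) even when the system of interest
runs hotter; this module takes the temperature explicitly everywhere so the
choice is always visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log

from .constants import BOLTZMANN, PLANCK, R_KCAL

__all__ = ["RateBarrier", "eyring_rate", "eyring_barrier", "STANDARD_TEMPERATURE"]

STANDARD_TEMPERATURE = 298.15  # K


def _check_temperature(temperature: float) -> None:
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")


def eyring_rate(dg: float, temperature: float, transmission_coefficient: float = 1.0) -> float:
    """Rate constant (1/s) for a free-energy barrier ``dg`` (kcal/mol)."""
    _check_temperature(temperature)
    prefactor = BOLTZMANN * temperature / PLANCK
    return transmission_coefficient * prefactor * exp(-dg / (R_KCAL * temperature))


def eyring_barrier(rate: float, temperature: float, transmission_coefficient: float = 1.0) -> float:
    """Free-energy barrier (kcal/mol) for a rate constant ``rate`` (1/s).

    Exact inverse of :func:`eyring_rate`.
    """
    _check_temperature(temperature)
    if rate <= 0:
        raise ValueError("rate must be positive (1/s)")
    prefactor = BOLTZMANN * temperature / PLANCK
    return -R_KCAL * temperature * log(rate / (transmission_coefficient * prefactor))


@dataclass(frozen=True)
class RateBarrier:
    """A mutually consistent (barrier, rate) pair at a stated temperature."""

    dg: float
    rate: float
    temperature: float
    transmission_coefficient: float = 1.0

    @classmethod
    def from_barrier(cls, dg: float, temperature: float, transmission_coefficient: float = 1.0):
        return cls(dg, eyring_rate(dg, temperature, transmission_coefficient),
                   temperature, transmission_coefficient)

    @classmethod
    def from_rate(cls, rate: float, temperature: float, transmission_coefficient: float = 1.0):
        return cls(eyring_barrier(rate, temperature, transmission_coefficient), rate,
                   temperature, transmission_coefficient)

    def __post_init__(self):
        _check_temperature(self.temperature)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        implied = eyring_rate(self.dg, self.temperature, self.transmission_coefficient)
        if abs(implied - self.rate) > 1e-9 * max(abs(implied), abs(self.rate)):
            raise ValueError("dg and rate are not Eyring-consistent at this temperature")
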
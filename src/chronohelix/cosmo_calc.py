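"""Closed-form back-of-envelope calculators.

Pure, deterministic helpers: photon energy, wave period, the linearized
cosmological frequency drift Δf = f0 * H0 * Δt, unit conversions, and the
energy-accumulation time under the additive-antenna assumption (every
nucleotide absorbs independently and the contributions add).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._constants import E_CHARGE, H_PLANCK, HBAR, hubble_rate

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class PhysicalConstants:
    h: float = H_PLANCK
    hbar: float = HBAR
    e_charge: float = E_CHARGE
    h0: float = hubble_rate(70.0)

    def __post_init__(self) -> None:
        if min(self.h, self.hbar, self.e_charge, self.h0) <= 0:
            raise ValueError("all constants must be positive")


def photon_energy(f: float) -> tuple[float, float]:
    """Photon energy E = h*f, returned as (joules, eV)."""
    if f < 0:
        raise ValueError("frequency must be >= 0")
    joules = H_PLANCK * f
    return joules, joules / E_CHARGE


def wave_period(f: float) -> float:
    """Period T = 1/f in seconds."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return 1.0 / f


def redshift_drift(f0: float, delta_t: float, h0: float | None = None) -> float:
    """Linearized cosmological frequency drift Δf = f0 * H0 * Δt (Hz)."""
    if f0 < 0 or delta_t < 0:
        raise ValueError("inputs must be >= 0")
    if h0 is None:
        h0 = hubble_rate(70.0)
    return f0 * h0 * delta_t


def ev_to_joules(energy_ev: float) -> float:
    return energy_ev * E_CHARGE


def accumulation_time(
    activation_energy_j: float, flux_per_nt: float, n_nucleotides: int
) -> dict[str, float]:
    """Time to accumulate an activation energy from per-nucleotide flux.

    Under the additive-antenna assumption the total absorbed power is
    flux_per_nt * n; t = activation_energy / total_flux.  Returns seconds,
    days and the intermediate total flux.
    """
    if flux_per_nt <= 0:
        raise ValueError("flux must be positive")
    if n_nucleotides < 1:
        raise ValueError("need at least one nucleotide")
    total_flux = flux_per_nt * n_nucleotides
    seconds = activation_energy_j / total_flux
    return {
        "total_flux_j_per_s": total_flux,
        "seconds": seconds,
        "days": seconds / SECONDS_PER_DAY,
    }
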
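"""Physical constants shared across modules.

All propagation happens in SI units; energies are specified in eV at the API
surface and converted exactly once, at the propagation boundary, to joules.
"""

# CODATA exact value (SI redefinition); also the eV -> J conversion factor.
EV_TO_J: float = 1.602176634e-19

# Reduced Planck constant, J*s (value used throughout the simulations).
HBAR: float = 1.0545718e-34

# Planck constant, J*s (CODATA exact).
H_PLANCK: float = 6.62607015e-34

# Elementary charge, C.
E_CHARGE: float = 1.6021766e-19

# Proton mass, kg.
PROTON_MASS: float = 1.6726219e-27

# Megaparsec in metres.
MPC_M: float = 3.0856775814913673e22


def hubble_rate(h0_km_s_mpc: float = 70.0) -> float:
    """Hubble parameter in s^-1 from the conventional km/s/Mpc figure."""
    return h0_km_s_mpc * 1e3 / MPC_M
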
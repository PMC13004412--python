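"""Nucleotide-to-qubit encodings.

Two representations are used downstream:

* a per-base qubit state (2-component complex unit vector) used to build
  density matrices — A maps to |0>, T to |1>, C to the equal superposition
  (|0>+|1>)/sqrt(2), and G to an erasure/"vacuum" placeholder contributing no
  projector;
* a site-basis complex amplitude alpha(b) per sequence position, assembled
  into a unit-norm state vector for Hamiltonian dynamics, with
  alpha(A)=1, alpha(T)=i, alpha(C)=(1+i)/sqrt(2), alpha(G)=0.

A Bloch-parameterised generalisation cos(theta/2)|0> + e^{i phi} sin(theta/2)|1>
is exposed for configurable encodings; its defaults reproduce the discrete map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

_SQRT2_INV = 1.0 / math.sqrt(2.0)

#: Site-basis scalar embedding used for Schroedinger evolution.
SITE_ALPHA: dict[str, complex] = {
    "A": 1.0 + 0.0j,
    "T": 0.0 + 1.0j,
    "C": (1.0 + 1.0j) * _SQRT2_INV,
    "G": 0.0 + 0.0j,
}


class UnencodableSiteError(ValueError):
    """Raised for letters with no qubit image (anything outside ACGT)."""


@dataclass(frozen=True)
class QubitVector:
    """A qubit state, or the vacuum placeholder (zero components)."""

    components: tuple[complex, complex]
    vacuum: bool = False

    def __post_init__(self) -> None:
        norm = abs(self.components[0]) ** 2 + abs(self.components[1]) ** 2
        if self.vacuum:
            if norm != 0.0:
                raise ValueError("vacuum state must carry zero components")
        elif abs(norm - 1.0) > 1e-12:
            raise ValueError(f"qubit norm^2 = {norm}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array(self.components, dtype=complex)

    def projector(self) -> np.ndarray:
        """|v><v| — the zero matrix for the vacuum state."""
        v = self.as_array()
        return np.outer(v, v.conj())


_DISCRETE: dict[str, QubitVector] = {
    "A": QubitVector((1.0, 0.0)),
    "T": QubitVector((0.0, 1.0)),
    "C": QubitVector((_SQRT2_INV, _SQRT2_INV)),
    "G": QubitVector((0.0, 0.0), vacuum=True),
}


def encode_qubit(base: str) -> QubitVector:
    """Discrete qubit image of one nucleotide letter.

    Raises :class:`UnencodableSiteError` for N or any other letter; the caller
    decides whether to drop the site or abort.
    """
    try:
        return _DISCRETE[base]
    except KeyError:
        raise UnencodableSiteError(f"no qubit encoding for base {base!r}") from None


@dataclass(frozen=True)
class BlochParams:
    """Per-base Bloch angles (theta in [0, pi], phi in [0, 2*pi))."""

    angles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # Defaults reproduce the discrete mapping (G handled as vacuum
            # by encode_qubit; here it gets the |0> pole as a placeholder).
            "A": (0.0, 0.0),
            "T": (math.pi, 0.0),
            "C": (math.pi / 2.0, 0.0),
            "G": (0.0, 0.0),
        }
    )

    def __post_init__(self) -> None:
        missing = set("ACGT") - set(self.angles)
        if missing:
            raise ValueError(f"BlochParams missing bases: {sorted(missing)}")
        for b, (theta, _phi) in self.angles.items():
            if not 0.0 <= theta <= math.pi:
                raise ValueError(f"theta for {b} outside [0, pi]: {theta}")


def encode_bloch(base: str, params: BlochParams) -> QubitVector:
    """Bloch-sphere qubit cos(theta/2)|0> + e^{i phi} sin(theta/2)|1>."""
    if base not in params.angles:
        raise UnencodableSiteError(f"no Bloch angles for base {base!r}")
    theta, phi = params.angles[base]
    c0 = math.cos(theta / 2.0)
    c1 = complex(math.cos(phi), math.sin(phi)) * math.sin(theta / 2.0)
    return QubitVector((c0, c1))


@dataclass(frozen=True)
class SiteAmplitudeVector:
    """Unit-norm complex amplitudes, one per sequence position."""

    amplitudes: np.ndarray
    n_unencodable: int = 0

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.amplitudes))
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"site amplitude vector norm = {norm}, expected 1")

    def __len__(self) -> int:
        return len(self.amplitudes)


def encode_site_amplitudes(sequence: str) -> SiteAmplitudeVector:
    """Map a sequence to the normalized site-basis state vector psi(0).

    G sites carry amplitude 0 by the vacuum rule; N (or other) sites also get
    amplitude 0 with a warning, which keeps positions aligned with genome
    coordinates.  An all-zero encoding (e.g. all-G) is an error.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    amps = np.zeros(len(sequence), dtype=complex)
    n_unknown = 0
    for i, base in enumerate(sequence):
        alpha = SITE_ALPHA.get(base)
        if alpha is None:
            n_unknown += 1
        else:
            amps[i] = alpha
    if n_unknown:
        warnings.warn(
            f"{n_unknown} unencodable site(s) assigned zero amplitude",
            stacklevel=2,
        )
    norm = np.linalg.norm(amps)
    if norm == 0.0:
        raise ValueError("zero-norm encoding: sequence has no non-G, non-N base")
    return SiteAmplitudeVector(amplitudes=amps / norm, n_unencodable=n_unknown)
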
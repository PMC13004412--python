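"""Tight-binding Hamiltonians and time-dependent Schroedinger propagation.

A DNA segment is modelled as a chain of sites with random on-site binding
energies (uniform in a configured eV range), constant nearest-neighbour
coupling, and an optional single boundary coupling g joining a non-coding
block to a coding block.  A weak diagonal drive lambda*cos(2*pi*f(t)*t) with
linearly chirped frequency f(t) = f0 + k*t acts on the non-coding block only;
an antenna-gain factor 10^(dBi/10) rescales the drive amplitude.

Energies are specified in eV and converted to joules exactly once, inside
:func:`propagate`; hbar is taken in J*s, so all phases are in SI radians.

With the headline parameter set (site energies up to ~0.05 eV, dt = 1e-13 s)
the per-step phase E*dt/hbar exceeds pi, i.e. the dynamics are undersampled;
:func:`propagate` emits a warning when that happens rather than silently
aliasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from ._constants import EV_TO_J, HBAR
from .qubit_encoding import SiteAmplitudeVector


@dataclass(frozen=True)
class HamiltonianSpec:
    """Chain sizes and energy parameters (all energies in eV)."""

    n_nc: int
    n_c: int
    diag_energy_range: tuple[float, float] = (0.01, 0.05)
    neighbor_coupling: float = 0.025
    boundary_coupling: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.diag_energy_range
        if lo > hi:
            raise ValueError(f"diagonal energy range has lo > hi: ({lo}, {hi})")
        if self.n_nc < 0 or self.n_c < 0 or self.n_nc + self.n_c < 1:
            raise ValueError("need at least one site across the two blocks")


@dataclass(frozen=True)
class DriveSpec:
    """Diagonal chirped drive on the non-coding block (amplitude in eV)."""

    amplitude: float = 1e-4
    base_frequency: float = 34e9
    chirp_rate: float = 0.0
    gain_dBi: float = 0.0
    target: Literal["noncoding_block", "all"] = "noncoding_block"
    integrated_phase: bool = False

    def __post_init__(self) -> None:
        if self.base_frequency < 0:
            raise ValueError("base_frequency must be >= 0")

    @property
    def gain_linear(self) -> float:
        return 10.0 ** (self.gain_dBi / 10.0)

    def instantaneous_value(self, t: float) -> float:
        """lambda * gain * cos(phase(t)), in eV.

        The default phase is the literal 2*pi*(f0 + k*t)*t; with
        ``integrated_phase`` the conventional integrated chirp
        2*pi*(f0*t + k*t^2/2) is used instead.
        """
        if self.integrated_phase:
            phase = 2.0 * np.pi * (self.base_frequency * t + 0.5 * self.chirp_rate * t * t)
        else:
            phase = 2.0 * np.pi * (self.base_frequency + self.chirp_rate * t) * t
        return self.amplitude * self.gain_linear * float(np.cos(phase))


@dataclass
class TrajectoryRecord:
    """Recorded amplitudes/phases plus the pre-renormalization norm log."""

    times: np.ndarray        # (T,) seconds
    amplitudes: np.ndarray   # (T, N) |psi_i|
    phases: np.ndarray       # (T, N) arg psi_i in (-pi, pi]
    norm_log: np.ndarray     # (T,) state norm before any renormalization
    n_nc: int
    n_c: int


def build_region_hamiltonian(
    n: int, spec: HamiltonianSpec, rng: np.random.Generator
) -> np.ndarray:
    """Real symmetric tridiagonal block Hamiltonian for one region (eV).

    Diagonal entries are i.i.d. uniform in ``spec.diag_energy_range``; the
    super/sub-diagonals are the constant nearest-neighbour coupling.
    """
    if n < 1:
        raise ValueError("region must have at least one site")
    lo, hi = spec.diag_energy_range
    h = np.diag(rng.uniform(lo, hi, size=n))
    if n > 1:
        off = np.full(n - 1, spec.neighbor_coupling)
        h += np.diag(off, 1) + np.diag(off, -1)
    return h


def build_total_hamiltonian(
    h_nc: np.ndarray, h_c: np.ndarray, g: complex
) -> np.ndarray:
    """Block-diagonal embedding of the two region Hamiltonians plus the
    boundary coupling g between the last non-coding and first coding site."""
    n_nc, n_c = h_nc.shape[0], h_c.shape[0]
    if n_c == 0:
        if g != 0:
            raise ValueError("boundary coupling supplied with empty coding block")
        return h_nc.copy()
    dtype = complex if np.iscomplexobj(h_nc) or np.iscomplexobj(h_c) or np.iscomplex(g) else float
    total = np.zeros((n_nc + n_c, n_nc + n_c), dtype=dtype)
    total[:n_nc, :n_nc] = h_nc
    total[n_nc:, n_nc:] = h_c
    if n_nc > 0:
        total[n_nc - 1, n_nc] = g
        total[n_nc, n_nc - 1] = np.conj(g)
    return total


def drive_term(
    t: float, spec: DriveSpec, n_nc: int, n_total: int
) -> np.ndarray:
    """Diagonal drive matrix at time t (eV)."""
    diag = np.zeros(n_total)
    value = spec.instantaneous_value(t)
    if spec.target == "all":
        diag[:] = value
    else:
        diag[:n_nc] = value
    return np.diag(diag)


def propagate(
    psi0: SiteAmplitudeVector,
    h_base: np.ndarray,
    drive: Optional[DriveSpec],
    dt: float,
    steps: int,
    method: Literal["exact_step", "euler"] = "exact_step",
    record_every: int = 1,
    n_nc: Optional[int] = None,
    renormalize: bool = True,
) -> TrajectoryRecord:
    """Propagate a site-amplitude state under H(t) = H_base + H_drive(t).

    ``exact_step`` applies the one-step unitary exp(-i H(t_n) dt / hbar)
    (frozen Hamiltonian per step, via Hermitian eigendecomposition);
    ``euler`` applies the first-order update psi <- psi - (i dt/hbar) H psi
    followed by renormalization (the explicit update alone does not conserve
    the norm; set ``renormalize=False`` to observe the drift).

    ``h_base`` and the drive amplitude are in eV; dt in seconds.  The state
    norm is recorded *before* any renormalization at every recorded step.
    """
    psi = psi0.amplitudes.astype(complex).copy()
    n = len(psi)
    if h_base.shape != (n, n):
        raise ValueError(
            f"Hamiltonian shape {h_base.shape} does not match state length {n}"
        )
    if dt <= 0 or steps < 1:
        raise ValueError("need dt > 0 and steps >= 1")
    if n_nc is None:
        n_nc = n

    h_base_j = h_base * EV_TO_J
    scale = np.max(np.abs(h_base_j)) * dt / HBAR
    if scale > np.pi:
        warnings.warn(
            f"per-step phase {scale:.2f} rad exceeds pi: the chosen dt "
            "undersamples the dynamics (aliasing)",
            stacklevel=2,
        )

    # Static Hamiltonian: one eigendecomposition serves every step.
    static = drive is None or drive.amplitude == 0.0
    if static and method == "exact_step":
        evals, evecs = np.linalg.eigh(h_base_j)
        u_static = (evecs * np.exp(-1j * evals * dt / HBAR)) @ evecs.conj().T

    n_records = steps // record_every + 1
    times = np.empty(n_records)
    amplitudes = np.empty((n_records, n))
    phases = np.empty((n_records, n))
    norm_log = np.empty(n_records)

    def record(idx: int, t: float, state: np.ndarray, norm: float) -> None:
        times[idx] = t
        amplitudes[idx] = np.abs(state)
        phases[idx] = np.angle(state)
        norm_log[idx] = norm

    record(0, 0.0, psi, float(np.linalg.norm(psi)))
    rec_idx = 1
    for step in range(steps):
        t = step * dt
        if static:
            h_t = h_base_j
        else:
            h_t = h_base_j + drive_term(t, drive, n_nc, n) * EV_TO_J
        if method == "exact_step":
            if static:
                psi = u_static @ psi
            else:
                evals, evecs = np.linalg.eigh(h_t)
                psi = (evecs * np.exp(-1j * evals * dt / HBAR)) @ evecs.conj().T @ psi
        elif method == "euler":
            psi = psi - (1j * dt / HBAR) * (h_t @ psi)
        else:
            raise ValueError(f"unknown method {method!r}")
        norm = float(np.linalg.norm(psi))
        if not np.isfinite(norm) or norm == 0.0:
            raise FloatingPointError(
                f"non-finite state at step {step + 1} (method={method})"
            )
        if method == "euler" and renormalize:
            psi = psi / norm
        if (step + 1) % record_every == 0:
            record(rec_idx, (step + 1) * dt, psi, norm)
            rec_idx += 1
    return TrajectoryRecord(
        times=times[:rec_idx],
        amplitudes=amplitudes[:rec_idx],
        phases=phases[:rec_idx],
        norm_log=norm_log[:rec_idx],
        n_nc=n_nc,
        n_c=n - n_nc,
    )


def region_series(
    traj: TrajectoryRecord,
) -> dict[str, np.ndarray]:
    """Per-block mean amplitude and mean unwrapped phase time series.

    Phases are unwrapped along time per site before averaging, which keeps
    the block mean meaningful across branch cuts.
    """
    n_nc, n_c = traj.n_nc, traj.n_c
    out: dict[str, np.ndarray] = {"times": traj.times}
    blocks = []
    if n_nc > 0:
        blocks.append(("nc", slice(0, n_nc)))
    if n_c > 0:
        blocks.append(("c", slice(n_nc, n_nc + n_c)))
    if not blocks:
        raise ValueError("trajectory has no non-empty block")
    for name, sl in blocks:
        out[f"amplitude_{name}"] = traj.amplitudes[:, sl].mean(axis=1)
        unwrapped = np.unwrap(traj.phases[:, sl], axis=0)
        out[f"phase_{name}"] = unwrapped.mean(axis=1)
    return out
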
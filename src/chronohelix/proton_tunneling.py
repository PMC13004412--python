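"""Driven, noisy proton wavepacket in a quartic double well per base pair.

Each base pair is modelled by a one-dimensional effective proton coordinate x
along the hydrogen bond, in the symmetric quartic double well

    V(x) = V0 [ (x/a)^4 - 2 (x/a)^2 + 1 ]

with minima at +-a and barrier height V0 at x = 0.  Barrier heights follow
the pair class: 0.065 eV for A-T/T-A and 0.108 eV for G-C/C-G, with
a = 1e-10 m for both.  A weak time-dependent tilt

    V_ext(x, t) = (lambda_pert + xi(t)) * cos(2*pi*f(t)*t) * (x/a)

drives the system, where lambda_pert = e*E0*a*10^(gain_dBi/10) and xi(t) is
zero-mean Gaussian noise redrawn i.i.d. each step with standard deviation
noise_amplitude * lambda_pert (the stochastic-resonance ingredient: noise
occasionally carries the system over threshold where the weak drive alone
cannot).  The drive frequency is either statically shifted (f0 + delta_f) or
linearly chirped (f0 + k*t).

Propagation is Strang split-operator: half kinetic step in momentum space
(FFT), full potential step in position space, half kinetic step — unitary and
second-order accurate in dt.  The right-well probability P_R(t) integrates
|psi|^2 over x >= 0 with half weight at the x = 0 grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from ._constants import EV_TO_J, HBAR, E_CHARGE, PROTON_MASS

BasePair = Literal["AT", "TA", "GC", "CG"]

#: Barrier heights (eV) per base-pair class; complements share parameters.
PAIR_BARRIERS_EV: dict[str, float] = {
    "AT": 0.065,
    "TA": 0.065,
    "GC": 0.108,
    "CG": 0.108,
}

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def base_to_pair(base: str) -> BasePair:
    """Base-pair label for one strand letter via Watson-Crick pairing."""
    if base not in _COMPLEMENT:
        raise ValueError(f"cannot pair base {base!r}")
    return base + _COMPLEMENT[base]  # type: ignore[return-value]


@dataclass(frozen=True)
class GridSpec:
    """Uniform spatial grid; power-of-two size for the spectral kinetic step."""

    n_points: int = 512
    x_min: float = -5e-10
    x_max: float = 5e-10

    def __post_init__(self) -> None:
        if self.n_points < 8 or self.n_points & (self.n_points - 1):
            raise ValueError("n_points must be a power of two (>= 8)")
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.n_points

    @property
    def x(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.n_points)

    @property
    def k(self) -> np.ndarray:
        """Angular wavenumbers matching numpy's FFT ordering."""
        return 2.0 * np.pi * np.fft.fftfreq(self.n_points, d=self.dx)


@dataclass(frozen=True)
class PotentialSpec:
    v0_ev: float
    a: float = 1e-10

    def __post_init__(self) -> None:
        if self.v0_ev <= 0 or self.a <= 0:
            raise ValueError("V0 and a must be positive")


@dataclass(frozen=True)
class TunnelDriveSpec:
    """External drive/noise parameters for the double-well simulation."""

    e0: float = 1e-6               # electric field amplitude, V/m
    gain_dBi: float = 1.7
    f0: float = 34e9
    delta_f: float = 0.0008        # static frequency shift, Hz
    chirp_rate: Optional[float] = None  # Hz/s; replaces delta_f when set
    noise_amplitude: float = 0.05  # xi std as a fraction of lambda_pert
    noise_absolute: Optional[float] = None  # xi std in joules, overrides
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")

    def lambda_pert(self, a: float) -> float:
        """Drive amplitude e*E0*a scaled by the linear antenna gain (J)."""
        return E_CHARGE * self.e0 * a * 10.0 ** (self.gain_dBi / 10.0)

    def noise_std(self, a: float) -> float:
        if self.noise_absolute is not None:
            return self.noise_absolute
        return self.noise_amplitude * self.lambda_pert(a)

    def frequency(self, t: float) -> float:
        if self.chirp_rate is not None:
            return self.f0 + self.chirp_rate * t
        return self.f0 + self.delta_f


@dataclass
class Wavefunction:
    values: np.ndarray
    grid: GridSpec

    def norm(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2) * self.grid.dx)


@dataclass
class TunnelingTrace:
    times: np.ndarray
    p_right: np.ndarray
    base_pair: str
    seed: int


def quartic_potential(grid: GridSpec, spec: PotentialSpec) -> np.ndarray:
    """Double-well potential evaluated on the grid, in joules."""
    u = grid.x / spec.a
    return spec.v0_ev * EV_TO_J * (u**4 - 2.0 * u**2 + 1.0)


def gaussian_packet(grid: GridSpec, x0: float, sigma: float) -> Wavefunction:
    """Normalized Gaussian wavepacket (1/(pi sigma^2))^(1/4) exp(-(x-x0)^2/(2 sigma^2))."""
    if not grid.x_min <= x0 <= grid.x_max:
        raise ValueError(f"x0={x0} outside the grid")
    if sigma <= 2.0 * grid.dx:
        raise ValueError(f"sigma={sigma} under-resolved (dx={grid.dx})")
    psi = (np.pi * sigma**2) ** -0.25 * np.exp(-((grid.x - x0) ** 2) / (2.0 * sigma**2))
    psi = psi.astype(complex)
    psi /= np.sqrt(np.sum(np.abs(psi) ** 2) * grid.dx)
    return Wavefunction(values=psi, grid=grid)


def external_potential(
    t: float,
    grid: GridSpec,
    drive: TunnelDriveSpec,
    a: float,
    noise_draw: float = 0.0,
) -> np.ndarray:
    """Linear tilt (lambda_pert + xi) cos(2 pi f(t) t) (x/a), in joules."""
    envelope = (drive.lambda_pert(a) + noise_draw) * np.cos(
        2.0 * np.pi * drive.frequency(t) * t
    )
    return envelope * grid.x / a


def split_operator_step(
    psi: Wavefunction, v_total: np.ndarray, dt: float, mass: float = PROTON_MASS
) -> Wavefunction:
    """One Strang step exp(-iT dt/2) exp(-iV dt) exp(-iT dt/2) (V in joules)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    grid = psi.grid
    kin_half = np.exp(-1j * HBAR * grid.k**2 * dt / (4.0 * mass))
    pot = np.exp(-1j * v_total * dt / HBAR)
    values = np.fft.ifft(kin_half * np.fft.fft(psi.values))
    values = pot * values
    values = np.fft.ifft(kin_half * np.fft.fft(values))
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite wavefunction after split-operator step")
    return Wavefunction(values=values, grid=grid)


def right_well_probability(psi: Wavefunction) -> float:
    """P_R = integral over x >= 0 of |psi|^2, half weight at the x=0 point."""
    norm = psi.norm()
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"wavefunction norm {norm} deviates from 1")
    grid = psi.grid
    density = np.abs(psi.values) ** 2 * grid.dx
    weights = np.where(grid.x > 0, 1.0, 0.0)
    at_zero = np.isclose(grid.x, 0.0, atol=grid.dx * 1e-9)
    weights[at_zero] = 0.5
    return float(np.sum(density * weights) / norm)


def _pair_seed(root_seed: int, index: int, pair: str) -> int:
    """Per-base-pair noise seed, independent of the region label."""
    pair_class = 0 if pair in ("AT", "TA") else 1
    ss = np.random.SeedSequence([root_seed, index, pair_class])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_base_pair(
    pair: BasePair,
    drive: Optional[TunnelDriveSpec],
    grid: GridSpec,
    dt: float,
    steps: int,
    record_every: int = 1,
    sigma: float = 5e-11,
) -> TunnelingTrace:
    """Full P_R(t) trace for one simulated base pair.

    The packet starts in the left well (x0 = -a); noise xi(t) is drawn
    i.i.d. Gaussian per step from the drive's seeded generator, so the same
    spec reproduces a bit-identical trace.
    """
    if pair not in PAIR_BARRIERS_EV:
        raise ValueError(f"unknown base pair {pair!r}")
    pot_spec = PotentialSpec(v0_ev=PAIR_BARRIERS_EV[pair])
    v_static = quartic_potential(grid, pot_spec)
    psi = gaussian_packet(grid, x0=-pot_spec.a, sigma=sigma)
    seed = drive.seed if drive is not None else 0
    rng = np.random.default_rng(seed)

    n_records = steps // record_every + 1
    times = np.empty(n_records)
    p_right = np.empty(n_records)
    times[0] = 0.0
    p_right[0] = right_well_probability(psi)
    rec = 1
    for step in range(steps):
        t = step * dt
        if drive is None:
            v_total = v_static
        else:
            std = drive.noise_std(pot_spec.a)
            xi = rng.normal(0.0, std) if std > 0 else 0.0
            v_total = v_static + external_potential(t, grid, drive, pot_spec.a, xi)
        psi = split_operator_step(psi, v_total, dt)
        if (step + 1) % record_every == 0:
            times[rec] = (step + 1) * dt
            p_right[rec] = right_well_probability(psi)
            rec += 1
    return TunnelingTrace(
        times=times[:rec], p_right=p_right[:rec], base_pair=pair, seed=seed
    )


@dataclass
class RegionTunnelingResult:
    """Per-base mean P_R values and the region-level comparisons."""

    per_base: dict[str, np.ndarray]  # keys: nc / c per-base time-averaged P_R
    welch: dict[str, float]
    paired_t: Optional[float]
    paired_p: Optional[float]
    condition: str


def _segment_traces(
    segment: str,
    drive_template: Optional[TunnelDriveSpec],
    grid: GridSpec,
    dt: float,
    steps: int,
    root_seed: int,
) -> np.ndarray:
    """Time-averaged P_R per base of a segment (noise seeded per base index)."""
    values = []
    cache: dict[tuple[str, int], float] = {}
    for idx, base in enumerate(segment):
        pair = base_to_pair(base)
        if drive_template is None:
            key = (pair, -1)  # deterministic: identical pairs share a trace
            seed = 0
            drive = None
        else:
            seed = _pair_seed(root_seed, idx, pair)
            key = (pair, seed)
            drive = TunnelDriveSpec(
                e0=drive_template.e0,
                gain_dBi=drive_template.gain_dBi,
                f0=drive_template.f0,
                delta_f=drive_template.delta_f,
                chirp_rate=drive_template.chirp_rate,
                noise_amplitude=drive_template.noise_amplitude,
                noise_absolute=drive_template.noise_absolute,
                seed=seed,
            )
        if key not in cache:
            trace = simulate_base_pair(pair, drive, grid, dt, steps)
            cache[key] = float(trace.p_right.mean())
        values.append(cache[key])
    return np.array(values)


def region_tunneling_experiment(
    real_segments: tuple[str, str],
    control_segments: tuple[str, str],
    drive: Optional[TunnelDriveSpec] = None,
    grid: Optional[GridSpec] = None,
    dt: float = 1e-15,
    steps: int = 2000,
    seed: int = 0,
) -> dict[str, RegionTunnelingResult]:
    """Coding-vs-non-coding tunneling comparison for real and control pairs.

    ``real_segments``/``control_segments`` are (noncoding, coding) sequence
    pairs.  Per base pair the time-averaged P_R is computed; regions are
    compared by Welch's t-test and, when the segments have equal length, by
    a paired t-test over base index.  Noise seeds depend only on (seed, base
    index, pair type), so a control built from a duplicated sequence yields
    exactly zero paired differences.
    """
    import scipy.stats

    if grid is None:
        grid = GridSpec(n_points=256)
    out: dict[str, RegionTunnelingResult] = {}
    for condition, (seg_nc, seg_c) in (
        ("real", real_segments),
        ("control", control_segments),
    ):
        if not seg_nc or not seg_c:
            raise ValueError(f"{condition}: empty segment")
        p_nc = _segment_traces(seg_nc, drive, grid, dt, steps, seed)
        p_c = _segment_traces(seg_c, drive, grid, dt, steps, seed)
        if np.var(p_nc) == 0 and np.var(p_c) == 0:
            welch = {"welch_t": 0.0 if np.mean(p_nc) == np.mean(p_c) else np.inf,
                     "t_pvalue": float("nan")}
        else:
            t, p = scipy.stats.ttest_ind(p_nc, p_c, equal_var=False)
            welch = {"welch_t": float(t), "t_pvalue": float(p)}
        paired_t = paired_p = None
        if len(p_nc) == len(p_c):
            diff = p_nc - p_c
            if np.allclose(diff, 0.0):
                paired_t, paired_p = 0.0, float("nan")
            else:
                t, p = scipy.stats.ttest_rel(p_nc, p_c)
                paired_t, paired_p = float(t), float(p)
        out[condition] = RegionTunnelingResult(
            per_base={"nc": p_nc, "c": p_c},
            welch=welch,
            paired_t=paired_t,
            paired_p=paired_p,
            condition=condition,
        )
    return out
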
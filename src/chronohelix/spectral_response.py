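"""Detrending, power spectra, band power and the power-ratio statistic.

The spectral convention is fixed and documented here once: for a length-n
real series x with sampling interval dt, the one-sided power spectrum is

    P_0 = 0 (the mean is removed),
    P_j = w_j |X_j|^2 / n   for j = 1 .. n//2,

where X = rfft(x - mean(x)) and w_j doubles every interior bin (w_j = 2,
except w = 1 at the Nyquist bin when n is even).  With this normalization
Parseval's identity reads sum_j P_j = n * var(x) (biased variance), which is
asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import scipy.signal
import scipy.stats


@dataclass(frozen=True)
class SpectrumResult:
    frequencies: np.ndarray  # Hz, non-negative half-spectrum
    power: np.ndarray
    dt: float
    n: int

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt


@dataclass(frozen=True)
class BandPowerReport:
    band: tuple[float, float]
    power_nc: float
    power_c: float
    replicate_id: int
    condition: Literal["real", "control"]

    @property
    def ratio(self) -> float:
        if self.power_c <= 0:
            raise ZeroDivisionError(
                f"replicate {self.replicate_id}: coding band power is zero"
            )
        return self.power_nc / self.power_c


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (output mean ~ 0)."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 points to detrend")
    return scipy.signal.detrend(series, type="linear")


def power_spectrum(series: np.ndarray, dt: float) -> SpectrumResult:
    """One-sided power spectrum under the module's documented convention."""
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("need at least 4 points for a spectrum")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(series)):
        raise ValueError("non-finite values in input series")
    n = series.size
    x = np.fft.rfft(series - series.mean())
    power = np.abs(x) ** 2 / n
    weights = np.full(power.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    power *= weights
    freqs = np.fft.rfftfreq(n, d=dt)
    return SpectrumResult(frequencies=freqs, power=power, dt=dt, n=n)


def band_power(spec: SpectrumResult, f_lo: float, f_hi: float) -> float:
    """Sum of spectral power over bins with f_lo <= f <= f_hi (inclusive)."""
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"invalid band ({f_lo}, {f_hi})")
    if f_hi > spec.nyquist * (1 + 1e-12):
        raise ValueError(
            f"band edge {f_hi} Hz exceeds the Nyquist frequency {spec.nyquist} Hz"
        )
    mask = (spec.frequencies >= f_lo) & (spec.frequencies <= f_hi)
    return float(spec.power[mask].sum())


def doppler_band(
    f0: float, chirp_rate: float, total_time: float, bin_width: float
) -> tuple[float, float]:
    """Band swept by the chirped drive, padded by one spectral bin per side."""
    f_end = f0 + chirp_rate * total_time
    lo = max(0.0, min(f0, f_end) - bin_width)
    hi = max(f0, f_end) + bin_width
    return lo, hi


def compare_distributions(
    a: np.ndarray, b: np.ndarray
) -> dict[str, float]:
    """Welch t-test and Mann-Whitney U between two samples (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            t_stat, t_p = 0.0, float("nan")
        else:
            raise ValueError("zero variance in both samples: t undefined")
    else:
        t_stat, t_p = scipy.stats.ttest_ind(a, b, equal_var=False)
    u_stat, u_p = scipy.stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic"
    )
    return {
        "welch_t": float(t_stat),
        "t_pvalue": float(t_p),
        "mannwhitney_U": float(u_stat),
        "U_pvalue": float(u_p),
    }


def power_ratio_experiment(
    replicates: list[BandPowerReport],
) -> dict[str, object]:
    """Per-condition summary of non-coding/coding band-power ratios.

    Returns the mean and standard deviation of the ratio for the ``real``
    and ``control`` conditions plus the two-sample comparison between the
    two sets of ratios (when both are present with >= 2 replicates each).
    """
    by_cond: dict[str, list[float]] = {}
    for rep in replicates:
        by_cond.setdefault(rep.condition, []).append(rep.ratio)
    summary: dict[str, object] = {}
    for cond, ratios in by_cond.items():
        if len(ratios) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        arr = np.array(ratios)
        summary[f"mean_ratio_{cond}"] = float(arr.mean())
        summary[f"sd_ratio_{cond}"] = float(arr.std(ddof=1))
        summary[f"n_{cond}"] = len(ratios)
    if "real" in by_cond and "control" in by_cond:
        summary["comparison"] = compare_distributions(
            np.array(by_cond["real"]), np.array(by_cond["control"])
        )
    return summary


def phase_band_power_ratio(
    phase_nc: np.ndarray,
    phase_c: np.ndarray,
    dt: float,
    band: tuple[float, float],
    replicate_id: int = 0,
    condition: Literal["real", "control"] = "real",
) -> BandPowerReport:
    """Detrend both block phase series and report in-band powers."""
    spec_nc = power_spectrum(detrend(phase_nc), dt)
    spec_c = power_spectrum(detrend(phase_c), dt)
    return BandPowerReport(
        band=band,
        power_nc=band_power(spec_nc, *band),
        power_c=band_power(spec_c, *band),
        replicate_id=replicate_id,
        condition=condition,
    )
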
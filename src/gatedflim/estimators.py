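"""Lifetime, photon-efficiency and FRET estimators for the two-gate scheme.

The central estimator turns a background-subtracted pair of gate counts into
a lifetime, ``tau = T / ln((N0 - B0) / (N1 - B1))``.  Invalid logarithm
arguments are *censored*, never clamped: clamping would bias the spread
statistics that feed the F-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SaturationError",
    "GatePair",
    "LifetimeEstimate",
    "FretEstimate",
    "FValueResult",
    "pileup_correct",
    "two_gate_lifetime",
    "lifetime_series",
    "empirical_f_value",
    "predicted_rel_error",
    "fret_efficiencies",
    "gate_scan_lifetime",
]


class SaturationError(ValueError):
    """A measured count reached full-scale; no lifetime can be assigned."""


# Censoring reason codes for two_gate_lifetime.
CENSOR_NONPOS_GATE0 = "nonpositive_gate0_signal"
CENSOR_NONPOS_GATE1 = "nonpositive_gate1_signal"
CENSOR_NEGATIVE_RATE = "negative_rate"
CENSOR_NAN = "nan_input"


@dataclass(frozen=True)
class GatePair:
    """Corrected photon counts for one gate pair (possibly frame-averaged)."""

    n0: float
    n1: float
    b0: float = 0.0
    b1: float = 0.0
    gate_separation: float = 2.5  # T, ns

    def __post_init__(self) -> None:
        if self.gate_separation <= 0:
            raise ValueError("gate separation T must be positive")


@dataclass(frozen=True)
class LifetimeEstimate:
    """A lifetime with its photon budget and censoring status.

    ``n_photons`` is the number of available photons, 2 x N0 summed over the
    frames used.  ``rel_error`` is the predicted shot-noise relative error
    F/sqrt(N) when an F-value was supplied.
    """

    tau: float  # ns; NaN when censored
    n_photons: float
    censored: bool = False
    censor_reason: Optional[str] = None
    rel_error: Optional[float] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.censored and not self.tau > 0:
            raise ValueError("non-censored estimate requires tau > 0")


@dataclass(frozen=True)
class FretEstimate:
    """Lifetime- and intensity-based FRET efficiencies for one molecule.

    Values may be slightly negative under noise and are reported as-is.
    """

    e_lifetime: float
    e_intensity: float
    tau_da: float
    tau_d: float
    n_da: float
    n_d: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FValueResult:
    f: float
    n_used: int
    n_censored: int


def pileup_correct(n_measured, bit_depth: int):
    """Invert the q-bit single-photon saturation law.

    A q-bit frame is the sum of ``2**q - 1`` one-bit exposures, each of which
    registers at most one photon, so the measured count under-reports the
    true rate.  The inverse is ``-ln(1 - N/(2^q - 1)) * (2^q - 1)``.

    Accepts scalars or arrays.  Raises :class:`SaturationError` on
    full-scale input and ``ValueError`` on negative input.
    """
    m = 2 ** bit_depth - 1
    arr = np.asarray(n_measured, dtype=float)
    if np.any(arr < 0):
        raise ValueError("measured counts must be non-negative")
    if np.any(arr >= m):
        raise SaturationError(
            f"count at or above full scale {m}; lifetime cannot be assigned"
        )
    out = -np.log1p(-arr / m) * m
    if np.isscalar(n_measured) or arr.ndim == 0:
        return float(out)
    return out


def two_gate_lifetime(pair: GatePair) -> LifetimeEstimate:
    """Rapid lifetime determination from a pair of gate counts.

    ``tau = T / ln((N0 - B0)/(N1 - B1))``.  Censors (with a reason code)
    when either background-subtracted signal is non-positive or the late
    gate outweighs the early gate.
    """
    n = 2.0 * pair.n0
    s0 = pair.n0 - pair.b0
    s1 = pair.n1 - pair.b1
    if math.isnan(s0) or math.isnan(s1):
        return LifetimeEstimate(math.nan, n, censored=True, censor_reason=CENSOR_NAN)
    if s0 <= 0:
        return LifetimeEstimate(
            math.nan, n, censored=True, censor_reason=CENSOR_NONPOS_GATE0
        )
    if s1 <= 0:
        return LifetimeEstimate(
            math.nan, n, censored=True, censor_reason=CENSOR_NONPOS_GATE1
        )
    if s0 <= s1:
        return LifetimeEstimate(
            math.nan, n, censored=True, censor_reason=CENSOR_NEGATIVE_RATE
        )
    tau = pair.gate_separation / math.log(s0 / s1)
    return LifetimeEstimate(tau, n)


def lifetime_series(
    n0: np.ndarray,
    n1: np.ndarray,
    b0: float,
    b1: float,
    gate_separation: float,
) -> tuple[np.ndarray, int]:
    """Vectorized two-gate lifetimes; NaN marks censored samples.

    Returns ``(tau, n_censored)``.
    """
    if gate_separation <= 0:
        raise ValueError("gate separation T must be positive")
    s0 = np.asarray(n0, dtype=float) - b0
    s1 = np.asarray(n1, dtype=float) - b1
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (s0 > 0) & (s1 > 0) & (s0 > s1)
        tau = np.where(valid, gate_separation / np.log(s0 / s1), np.nan)
    return tau, int(np.size(tau) - np.count_nonzero(valid))


def empirical_f_value(
    tau_samples: Sequence[float], n_per_sample: float
) -> FValueResult:
    """Photon-normalized lifetime spread, ``F = sqrt(N) * std(tau)/mean(tau)``.

    Uses the sample standard deviation (ddof=1).  NaN samples count as
    censored and are excluded.
    """
    if n_per_sample <= 0:
        raise ValueError("n_per_sample must be positive")
    arr = np.asarray(tau_samples, dtype=float)
    good = arr[np.isfinite(arr)]
    n_censored = arr.size - good.size
    if good.size < 2:
        raise ValueError("need at least 2 non-censored lifetime samples")
    f = math.sqrt(n_per_sample) * float(np.std(good, ddof=1)) / float(np.mean(good))
    return FValueResult(f=f, n_used=good.size, n_censored=n_censored)


def predicted_rel_error(f: float, n_photons: float) -> float:
    """Shot-noise-limited relative lifetime error, ``F / sqrt(N)``."""
    if f <= 0:
        raise ValueError("F must be positive")
    if n_photons <= 0:
        raise ValueError("n_photons must be positive")
    return f / math.sqrt(n_photons)


def fret_efficiencies(
    tau_da: float, tau_d: float, n_da: float, n_d: float, flags: tuple[str, ...] = ()
) -> FretEstimate:
    """FRET efficiency from lifetimes and from first-gate intensities.

    ``E_lifetime = 1 - tau_DA/tau_D`` and ``E_intensity = 1 - N_DA/N_D``.
    Noise can push either slightly negative; values are not clipped.
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    if n_d <= 0:
        raise ValueError("n_d must be positive")
    return FretEstimate(
        e_lifetime=1.0 - tau_da / tau_d,
        e_intensity=1.0 - n_da / n_d,
        tau_da=tau_da,
        tau_d=tau_d,
        n_da=n_da,
        n_d=n_d,
        flags=flags,
    )


def gate_scan_lifetime(delays: Sequence[float], counts: Sequence[float]) -> float:
    """Reference lifetime from a multi-delay gate scan.

    Weighted least-squares fit of ``ln(counts)`` against gate delay; the
    slope is ``-1/tau``.  Weights are proportional to the counts (the
    log-transform of a Poisson variate has variance ~ 1/counts).  Points
    with non-positive counts are dropped; fewer than 3 usable points is an
    error.  Equal gate widths cancel in the slope, so no width correction
    is applied.
    """
    d = np.asarray(delays, dtype=float)
    c = np.asarray(counts, dtype=float)
    if d.shape != c.shape:
        raise ValueError("delays and counts must have the same length")
    keep = c > 0
    d, c = d[keep], c[keep]
    if d.size < 3:
        raise ValueError("need at least 3 usable (positive-count) gate positions")
    if np.ptp(d) <= 0:
        raise ValueError("gate delays must span a positive range")
    # np.polyfit minimizes sum (w_i * resid_i)^2 -> w_i = sqrt(counts_i)
    slope, _ = np.polyfit(d, np.log(c), 1, w=np.sqrt(c))
    if slope >= 0:
        raise ValueError("counts do not decay with delay; no lifetime")
    return -1.0 / slope
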
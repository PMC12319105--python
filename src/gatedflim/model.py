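"""Statistical model of gated photon collection from mono-exponential emitters.

A pulsed source excites a molecule whose emission decays exponentially with
lifetime ``tau``.  The camera opens two square detection gates of equal width
``W`` per laser period, at delays ``delay0`` (early gate, catching nearly the
whole decay) and ``delay1 = delay0 + T`` (late gate, rejecting early photons).
Everything downstream — simulator, estimators, design theory — is phrased in
terms of the per-pulse capture fractions defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

__all__ = [
    "AcquisitionConfig",
    "EmitterTruth",
    "BackgroundModel",
    "expected_gate_fraction",
    "expected_counts",
]

#: Default laser repetition period in ns (26 MHz repetition rate).
DEFAULT_REPETITION_PERIOD_NS = 1e3 / 26.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Gate geometry, timing and digitization of one acquisition.

    Times are in ns, exposure in ms.  ``gate_delays`` holds the opening
    delays of gate 0 and gate 1 relative to the excitation pulse; their
    difference is the lifetime-estimation delay ``T``.
    """

    repetition_period: float = DEFAULT_REPETITION_PERIOD_NS
    gate_width: float = 10.0
    gate_delays: tuple[float, float] = (0.0, 2.5)
    bit_depth: int = 8
    exposure_ms: float = 20.0
    n_frame_pairs: int = 100
    pixel_size_nm: float = 100.0
    sensor_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.gate_width <= 0:
            raise ValueError("gate_width must be positive")
        d0, d1 = self.gate_delays
        if d0 < 0:
            raise ValueError("gate delays must be non-negative")
        if d1 <= d0:
            raise ValueError("gate 1 delay must exceed gate 0 delay (T > 0)")
        if d1 + self.gate_width > self.repetition_period:
            raise ValueError(
                "gate 1 window extends beyond the laser repetition period"
            )
        if not (1 <= self.bit_depth <= 16):
            raise ValueError("bit_depth must be in 1..16")
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be positive")
        if self.n_frame_pairs < 0:
            raise ValueError("n_frame_pairs must be non-negative")

    @property
    def gate_separation(self) -> float:
        """Delay difference T = delay1 - delay0 (ns)."""
        d0, d1 = self.gate_delays
        return d1 - d0

    @property
    def max_count(self) -> int:
        """Largest representable q-bit count, 2**q - 1."""
        return 2 ** self.bit_depth - 1

    @property
    def field_of_view_um(self) -> tuple[float, float]:
        """Field-of-view side lengths in micrometres."""
        return tuple(n * self.pixel_size_nm / 1e3 for n in self.sensor_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gate_delays"] = list(self.gate_delays)
        d["sensor_shape"] = list(self.sensor_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown acquisition keys: {sorted(unknown)}")
        d = dict(d)
        if "gate_delays" in d:
            d["gate_delays"] = tuple(d["gate_delays"])
        if "sensor_shape" in d:
            d["sensor_shape"] = tuple(d["sensor_shape"])
        return cls(**d)


@dataclass(frozen=True)
class EmitterTruth:
    """Ground truth for one simulated molecule.

    ``brightness`` is the expected number of signal photons per first-gate
    frame (integrated over the point-spread function).  ``lifetime`` is the
    active lifetime from frame 0; if ``t_acceptor_bleach`` and
    ``lifetime_post_step`` are set, the lifetime switches at that frame pair
    and the brightness rises by ``lifetime_post_step / lifetime`` (pure
    dynamic quenching: the radiative rate is unchanged, so intensity scales
    with lifetime).  ``t_bleach`` is the frame pair at which emission stops.
    """

    position: tuple[float, float]  # (row, col) in px, sub-pixel
    lifetime: float  # ns
    brightness: float  # expected signal photons / first-gate frame
    t_bleach: int  # frame-pair index of final (donor) photobleach
    lifetime_post_step: Optional[float] = None  # ns, after acceptor bleach
    t_acceptor_bleach: Optional[int] = None  # frame-pair index
    psf_sigma: float = 1.0  # px

    def __post_init__(self) -> None:
        if self.lifetime <= 0:
            raise ValueError("lifetime must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be non-negative")
        if self.t_bleach < 0:
            raise ValueError("t_bleach must be non-negative")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if (self.t_acceptor_bleach is None) != (self.lifetime_post_step is None):
            raise ValueError(
                "t_acceptor_bleach and lifetime_post_step must be set together"
            )
        if self.t_acceptor_bleach is not None:
            if self.lifetime_post_step <= 0:
                raise ValueError("lifetime_post_step must be positive")
            if not self.t_acceptor_bleach < self.t_bleach:
                raise ValueError("acceptor bleach must precede donor bleach")

    def active_lifetime(self, frame_pair: int) -> Optional[float]:
        """Lifetime in effect at ``frame_pair``; None once bleached."""
        if frame_pair >= self.t_bleach:
            return None
        if self.t_acceptor_bleach is not None and frame_pair >= self.t_acceptor_bleach:
            return self.lifetime_post_step
        return self.lifetime

    def active_brightness(self, frame_pair: int) -> float:
        """Expected first-gate signal photons per frame at ``frame_pair``."""
        if frame_pair >= self.t_bleach:
            return 0.0
        if self.t_acceptor_bleach is not None and frame_pair >= self.t_acceptor_bleach:
            return self.brightness * self.lifetime_post_step / self.lifetime
        return self.brightness


@dataclass(frozen=True)
class BackgroundModel:
    """Expected background photons per frame.

    ``b0`` / ``b1`` are per trace box (the 5x5 px summation region), for the
    first and second gate; they may differ if the background itself is
    fluorescent.  ``spatial_density`` is the per-pixel per-frame rate used by
    the simulator.
    """

    b0: float = 0.0
    b1: float = 0.0
    spatial_density: float = 0.0

    def __post_init__(self) -> None:
        if self.b0 < 0 or self.b1 < 0 or self.spatial_density < 0:
            raise ValueError("background rates must be non-negative")

    @classmethod
    def from_density(cls, density: float, box_area: int = 25) -> "BackgroundModel":
        """Time-constant background: equal in both gates, ``density`` per px."""
        b = density * box_area
        return cls(b0=b, b1=b, spatial_density=density)

    @property
    def sbr(self) -> Optional[float]:
        return None  # SBR is a property of emitter + background; see callers


def expected_gate_fraction(lifetime: float, gate_delay: float, gate_width: float) -> float:
    """Fraction of emitted photons per pulse falling inside a square gate.

    For a mono-exponential decay with time constant ``lifetime``, the
    probability that a photon arrives within ``[gate_delay, gate_delay +
    gate_width]`` is ``exp(-delay/tau) - exp(-(delay+width)/tau)``.
    ``gate_width`` may be ``math.inf``.
    """
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    if gate_width <= 0:
        raise ValueError("gate_width must be positive")
    if gate_delay < 0:
        raise ValueError("gate_delay must be non-negative")
    lo = math.exp(-gate_delay / lifetime)
    if math.isinf(gate_width):
        return lo
    return lo - math.exp(-(gate_delay + gate_width) / lifetime)


def expected_counts(
    emitter: EmitterTruth,
    cfg: AcquisitionConfig,
    background: BackgroundModel,
    frame_pair: int,
    gate_index: int,
) -> float:
    """Expected photons per frame in one trace box for one gate.

    Before the final bleach the signal in gate ``g`` is the active brightness
    scaled by the ratio of the gate-``g`` capture fraction to the gate-0
    capture fraction (so gate 0 carries exactly the configured brightness and
    gate 1 carries ``S * exp(-T/tau)`` for equal-width gates).  After the
    bleach only background remains.
    """
    if frame_pair < 0:
        raise ValueError("frame index must be non-negative")
    if gate_index not in (0, 1):
        raise ValueError("gate_index must be 0 or 1")
    bg = background.b0 if gate_index == 0 else background.b1
    tau = emitter.active_lifetime(frame_pair)
    if tau is None:
        return bg
    s = emitter.active_brightness(frame_pair)
    if s == 0.0:
        return bg
    w = cfg.gate_width
    f0 = expected_gate_fraction(tau, cfg.gate_delays[0], w)
    fg = expected_gate_fraction(tau, cfg.gate_delays[gate_index], w)
    return s * fg / f0 + bg
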
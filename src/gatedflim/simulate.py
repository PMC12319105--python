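"""Synthetic two-gate frame-stack generator.

Emulates the acquisition end-to-end: mono-exponential emitters rendered
through a pixel-integrated Gaussian PSF, constant background, warm pixels,
stochastic photobleaching, and the q-bit single-photon digitization in which
each frame is the sum of ``2**q - 1`` one-bit exposures.  Per-pixel counts
are drawn as ``Binomial(2**q - 1, 1 - exp(-lambda / (2**q - 1)))``, which is
exactly the saturation law that the pile-up correction inverts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf

from .model import AcquisitionConfig, BackgroundModel, EmitterTruth, expected_gate_fraction

__all__ = [
    "ScenePlan",
    "GatedFrameStack",
    "simulate_stack",
    "simulate_dark_stack",
    "fret_scene",
    "render_psf_patch",
]

#: Dark count rate of a normal (non-warm) pixel, counts per frame.
BASE_DARK_RATE = 1e-3

#: PSF support truncation radius in units of sigma.
PSF_TRUNCATION_SIGMAS = 4.0


@dataclass
class ScenePlan:
    """Everything needed to synthesize one acquisition, seed included."""

    config: AcquisitionConfig
    emitters: list[EmitterTruth] = field(default_factory=list)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    warm_pixel_fraction: float = 0.0
    warm_pixel_rate: float = 0.0  # expected dark counts / pixel / frame
    base_dark_rate: float = BASE_DARK_RATE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.warm_pixel_fraction <= 0.05):
            raise ValueError("warm_pixel_fraction must be in [0, 0.05]")
        if self.warm_pixel_rate < 0 or self.base_dark_rate < 0:
            raise ValueError("dark rates must be non-negative")
        h, w = self.config.sensor_shape
        for e in self.emitters:
            r, c = e.position
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"emitter at {e.position} outside sensor {self.config.sensor_shape}")


@dataclass
class GatedFrameStack:
    """Alternating-gate q-bit image sequence with its acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W) unsigned integer
    gate_index: np.ndarray  # (n_frames,) of 0/1, strictly alternating
    config: AcquisitionConfig
    plan: Optional[ScenePlan] = None  # ground truth, when simulated
    saturated: bool = False  # any pixel at full scale (set by readers)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.gate_index = np.asarray(self.gate_index)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        n = self.frames.shape[0]
        if n % 2 != 0:
            raise ValueError("frame count must be even (alternating gate pairs)")
        if self.gate_index.shape != (n,):
            raise ValueError("gate_index length must match frame count")
        if n and not np.array_equal(self.gate_index, np.arange(n) % 2):
            raise ValueError("gates must strictly alternate starting with gate 0")
        if n and self.frames.max(initial=0) > self.config.max_count:
            raise ValueError("pixel values exceed the q-bit range")

    @property
    def n_pairs(self) -> int:
        return self.frames.shape[0] // 2

    def gate_frames(self, gate: int) -> np.ndarray:
        """View of the frames of one gate, shape (n_pairs, H, W)."""
        if gate not in (0, 1):
            raise ValueError("gate must be 0 or 1")
        return self.frames[gate::2]


def render_psf_patch(
    position: tuple[float, float], sigma: float, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Pixel-integrated 2D Gaussian, truncated at 4 sigma.

    Returns row/col slices into the sensor and the weight patch; weights sum
    to the PSF mass inside the truncation window (< 1, but > 0.9999 for the
    default truncation), so the emitter brightness is conserved.
    """
    r0, c0 = position
    rad = PSF_TRUNCATION_SIGMAS * sigma
    rlo = max(int(math.floor(r0 - rad)), 0)
    rhi = min(int(math.ceil(r0 + rad)) + 1, shape[0])
    clo = max(int(math.floor(c0 - rad)), 0)
    chi = min(int(math.ceil(c0 + rad)) + 1, shape[1])
    rows = np.arange(rlo, rhi)
    cols = np.arange(clo, chi)
    s = math.sqrt(2.0) * sigma
    # integral of the unit Gaussian over each pixel [i - 0.5, i + 0.5]
    wr = 0.5 * (erf((rows + 0.5 - r0) / s) - erf((rows - 0.5 - r0) / s))
    wc = 0.5 * (erf((cols + 0.5 - c0) / s) - erf((cols - 0.5 - c0) / s))
    return slice(rlo, rhi), slice(clo, chi), np.outer(wr, wc)


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, max_count: int) -> np.ndarray:
    """q-bit counts from per-pixel expected rates via the binary-frame model."""
    p = -np.expm1(-lam / max_count)
    return rng.binomial(max_count, p)


def simulate_stack(plan: ScenePlan, n_pairs: Optional[int] = None) -> GatedFrameStack:
    """Generate the alternating-gate stack for a scene plan.

    Fully reproducible from ``plan.rng_seed``; a single generator drives the
    warm-pixel layout and every frame draw.  Warns when the expected rate
    exceeds half of the q-bit full scale anywhere (the regime where pile-up
    correction starts to distort).
    """
    cfg = plan.config
    if n_pairs is None:
        n_pairs = cfg.n_frame_pairs
    shape = tuple(cfg.sensor_shape)
    m = cfg.max_count
    rng = np.random.default_rng(plan.rng_seed)

    dark = np.full(shape, plan.base_dark_rate)
    if plan.warm_pixel_fraction > 0:
        warm = rng.random(shape) < plan.warm_pixel_fraction
        dark = np.where(warm, plan.warm_pixel_rate, dark)

    static = dark + plan.background.spatial_density

    # per-emitter static PSF patch and per-gate capture-fraction ratios
    patches = [render_psf_patch(e.position, e.psf_sigma, shape) for e in plan.emitters]
    w = cfg.gate_width
    gate_ratio = []  # (ratio_gate0, ratio_gate1) per lifetime in play, per emitter
    for e in plan.emitters:
        ratios = {}
        for tau in {e.lifetime, e.lifetime_post_step} - {None}:
            f0 = expected_gate_fraction(tau, cfg.gate_delays[0], w)
            f1 = expected_gate_fraction(tau, cfg.gate_delays[1], w)
            ratios[tau] = (1.0, f1 / f0)
        gate_ratio.append(ratios)

    frames = np.empty((2 * n_pairs, *shape), dtype=np.uint8 if cfg.bit_depth <= 8 else np.uint16)
    peak_rate = float(static.max(initial=0.0))
    for t in range(n_pairs):
        for g in (0, 1):
            lam = static.copy()
            for e, (rs, cs, patch), ratios in zip(plan.emitters, patches, gate_ratio):
                tau = e.active_lifetime(t)
                if tau is None:
                    continue
                amp = e.active_brightness(t) * ratios[tau][g]
                lam[rs, cs] += amp * patch
            peak_rate = max(peak_rate, float(lam.max(initial=0.0)))
            frames[2 * t + g] = _draw_counts(rng, lam, m)

    if peak_rate > 0.5 * m:
        warnings.warn(
            f"expected rate {peak_rate:.1f} exceeds half of full scale ({m}); "
            "pile-up correction will be inaccurate",
            stacklevel=2,
        )
    gates = np.arange(2 * n_pairs) % 2
    return GatedFrameStack(frames=frames, gate_index=gates, config=cfg, plan=plan)


def simulate_dark_stack(plan: ScenePlan, n_frames: int) -> GatedFrameStack:
    """Dark-calibration stack: no emitters, no background, only dark counts.

    Warm pixels fire at ``warm_pixel_rate``; normal pixels at the base dark
    rate.  ``n_frames`` must be even and at least 10.
    """
    if n_frames < 10:
        raise ValueError("dark calibration needs at least 10 frames")
    if n_frames % 2 != 0:
        raise ValueError("frame count must be even")
    cfg = plan.config
    shape = tuple(cfg.sensor_shape)
    m = cfg.max_count
    rng = np.random.default_rng(plan.rng_seed)
    dark = np.full(shape, plan.base_dark_rate)
    if plan.warm_pixel_fraction > 0:
        warm = rng.random(shape) < plan.warm_pixel_fraction
        dark = np.where(warm, plan.warm_pixel_rate, dark)
    frames = np.empty((n_frames, *shape), dtype=np.uint8 if cfg.bit_depth <= 8 else np.uint16)
    for i in range(n_frames):
        frames[i] = _draw_counts(rng, dark, m)
    return GatedFrameStack(
        frames=frames, gate_index=np.arange(n_frames) % 2, config=cfg, plan=plan
    )


def fret_scene(
    n_molecules: int,
    tau_da: float,
    tau_d: float,
    brightness: float,
    bleach_scale: float,
    seed: int,
    config: AcquisitionConfig,
    background: Optional[BackgroundModel] = None,
    donor_only_fraction: float = 0.5,
    min_separation: float = 6.0,
    psf_sigma: float = 1.0,
    warm_pixel_fraction: float = 0.0,
    warm_pixel_rate: float = 0.0,
    margin: int = 6,
) -> ScenePlan:
    """Scene of donor-only and donor-acceptor molecules.

    Donor-only molecules show a single descending photobleach step at
    lifetime ``tau_d``.  Donor-acceptor molecules start quenched at
    ``tau_da``, step up in brightness by ``tau_d / tau_da`` when the
    acceptor bleaches, then extinguish when the donor bleaches.  Bleach
    waiting times are geometric with mean ``bleach_scale`` frame pairs.
    Positions are uniform with a minimum pairwise separation.
    """
    if tau_da > tau_d:
        raise ValueError("tau_da must not exceed tau_d")
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    rng = np.random.default_rng([seed, 0x5CE])
    h, w = config.sensor_shape
    if n_molecules and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
        raise ValueError("sensor too small for the requested margin")

    positions: list[tuple[float, float]] = []
    max_tries = 1000 * max(n_molecules, 1)
    tries = 0
    while len(positions) < n_molecules:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "could not place molecules with the requested minimum separation; "
                "density too high"
            )
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation ** 2 for pr, pc in positions):
            positions.append((r, c))

    p_bleach = 1.0 / bleach_scale
    emitters = []
    for pos in positions:
        if rng.random() < donor_only_fraction:
            t_off = int(rng.geometric(p_bleach))
            emitters.append(
                EmitterTruth(
                    position=pos,
                    lifetime=tau_d,
                    brightness=brightness * tau_d / tau_da,
                    t_bleach=t_off,
                    psf_sigma=psf_sigma,
                )
            )
        else:
            t_acc = int(rng.geometric(p_bleach))
            t_off = t_acc + int(rng.geometric(p_bleach))
            emitters.append(
                EmitterTruth(
                    position=pos,
                    lifetime=tau_da,
                    brightness=brightness,
                    t_bleach=t_off,
                    lifetime_post_step=tau_d,
                    t_acceptor_bleach=t_acc,
                    psf_sigma=psf_sigma,
                )
            )
    return ScenePlan(
        config=config,
        emitters=emitters,
        background=background or BackgroundModel(),
        warm_pixel_fraction=warm_pixel_fraction,
        warm_pixel_rate=warm_pixel_rate,
        rng_seed=seed,
    )
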
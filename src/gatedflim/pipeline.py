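"""Trace analysis chain for alternating two-gate stacks.

Order of operations: warm-pixel masking -> pile-up correction -> molecule
detection on the early mean image -> 5x5 box trace extraction -> step
segmentation by step-kernel convolution -> trace classification -> static /
dynamic lifetime estimation -> FRET readout -> histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from skimage.feature import blob_log

from . import estimators as est
from .estimators import (
    FretEstimate,
    GatePair,
    LifetimeEstimate,
    empirical_f_value,
    fret_efficiencies,
    lifetime_series,
    two_gate_lifetime,
)
from .simulate import GatedFrameStack

__all__ = [
    "AnalysisParams",
    "PixelMask",
    "GateTrace",
    "TraceSegmentation",
    "LifetimeTrace",
    "build_warm_pixel_mask",
    "detection_image",
    "detect_molecules",
    "extract_traces",
    "detect_steps",
    "classify_trace",
    "static_lifetime",
    "dynamic_lifetime",
    "fret_from_segmentation",
    "lifetime_histogram",
    "throughput_speedup",
    "analyze_stack",
]

CLASS_SINGLE_STEP = "single_step"
CLASS_ACCEPTOR_DONOR = "acceptor_donor"
CLASS_REJECTED = "rejected"

REJECT_NO_STEP = "no_descending_step"
REJECT_MULTI_STEP = "multiple_steps"
REJECT_STEP_ORDER = "ascending_after_descending"
REJECT_DIM = "below_brightness_cutoff"
REJECT_UNSTABLE = "above_stability_limit"

#: Exposure at which the brightness cutoff is specified (ms); the cutoff is
#: rescaled linearly for other exposures.
REFERENCE_EXPOSURE_MS = 20.0


@dataclass
class AnalysisParams:
    """Every analysis threshold in one place.

    Defaults follow the published operating point: LoG detection with sigma
    in [1, 5] px, response threshold 1 and overlap 0.9 on the mean of the
    first 10 early-gate frames; 5x5 px trace boxes; a 10-frame step kernel
    with a 15-photon minimum step; a 50 corrected-photon brightness cutoff
    per 20 ms frame; and an ON-state stability limit of twice the shot
    noise.
    """

    log_min_sigma: float = 1.0
    log_max_sigma: float = 5.0
    log_threshold: float = 1.0
    log_overlap: float = 0.9
    detection_frames: int = 10
    box_halfwidth: int = 2  # 5x5 box
    neighbor_distance: float = 5.0  # px; closer centers flag overlap
    kernel_halfwidth: int = 10  # frames
    min_step: float = 15.0  # corrected photons
    brightness_cutoff: float = 50.0  # corrected photons per 20 ms frame
    stability_factor: float = 2.0  # x shot noise
    mask_threshold_factor: float = 10.0  # x median dark rate
    mask_min_rate: float = 0.1  # counts/frame floor for the mask threshold
    bin_factors: tuple[int, ...] = (2, 10)  # 50 Hz -> 25 Hz / 5 Hz
    histogram_bin_ns: float = 0.1
    histogram_range: tuple[float, float] = (0.0, 10.0)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bin_factors"] = list(self.bin_factors)
        d["histogram_range"] = list(self.histogram_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
        d = dict(d)
        if "bin_factors" in d:
            d["bin_factors"] = tuple(d["bin_factors"])
        if "histogram_range" in d:
            d["histogram_range"] = tuple(d["histogram_range"])
        return cls(**d)


@dataclass
class PixelMask:
    """Excluded (warm) pixels with the dark-rate image that produced them."""

    mask: np.ndarray  # bool, True = excluded
    dark_rate: np.ndarray
    threshold: float


@dataclass
class GateTrace:
    """Box-summed, pile-up-corrected photon time series for one molecule."""

    molecule_id: int
    center: tuple[int, int]  # rounded (row, col)
    n0: np.ndarray  # corrected photons per first-gate frame
    n1: np.ndarray  # corrected photons per second-gate frame
    box_size: int = 5
    overlapping: bool = False  # another center within neighbor_distance
    compensated: bool = False  # masked pixels rescaled out of the box sum

    def __post_init__(self) -> None:
        if len(self.n0) != len(self.n1):
            raise ValueError("gate traces must have equal length")


@dataclass
class TraceSegmentation:
    """Step times, segment levels and classification of one trace."""

    t_up: list[int]
    t_down: list[int]
    boundaries: list[int]  # [0, step..., n]
    levels_n0: list[float]  # mean N0 per segment
    levels_n1: list[float]
    t_off: Optional[int]
    b0: float
    b1: float
    label: str
    reason: Optional[str] = None


@dataclass
class LifetimeTrace:
    """Per-pair, binned and segment-averaged lifetimes for one molecule."""

    tau_native: np.ndarray  # NaN where censored
    binned: dict[int, np.ndarray]  # bin factor -> tau per bin (NaN = gap)
    segment_taus: list[tuple[int, int, float]]  # (start, end, tau)
    f_value: Optional[float]
    n_censored: int


def build_warm_pixel_mask(
    dark_stack: GatedFrameStack,
    threshold_factor: float = 10.0,
    threshold_percentile: Optional[float] = None,
    min_rate: float = 0.1,
) -> PixelMask:
    """Mask pixels whose dark count rate is anomalously high.

    Default rule: rate above ``max(threshold_factor * median rate,
    min_rate)`` counts/frame.  The floor keeps a near-zero median (the
    normal case for a healthy sensor) from masking every pixel that saw a
    single stray dark count.  Alternative rule: mask everything at or above
    the given rate quantile (``threshold_percentile`` in [0, 1]).
    """
    if dark_stack.frames.shape[0] < 10:
        raise ValueError("dark calibration needs at least 10 frames")
    rate = dark_stack.frames.mean(axis=0).astype(float)
    if threshold_percentile is not None:
        if not 0.0 <= threshold_percentile <= 1.0:
            raise ValueError("threshold_percentile must be in [0, 1]")
        thr = float(np.quantile(rate, threshold_percentile))
        mask = rate >= thr
    else:
        thr = max(threshold_factor * float(np.median(rate)), min_rate)
        mask = rate > thr
    if mask.all():
        raise ValueError("warm-pixel threshold masks every pixel")
    return PixelMask(mask=mask, dark_rate=rate, threshold=thr)


def detection_image(
    stack: GatedFrameStack,
    mask: Optional[PixelMask] = None,
    n_frames: int = 10,
) -> np.ndarray:
    """Pile-up-corrected mean of the first early-gate frames.

    Masked pixels are replaced by the image median so they cannot seed
    blobs.
    """
    gate0 = stack.gate_frames(0)[:n_frames].astype(float)
    m = stack.config.max_count
    gate0 = np.minimum(gate0, m - 1)  # saturated pixels pinned for detection only
    img = est.pileup_correct(gate0, stack.config.bit_depth).mean(axis=0)
    if mask is not None:
        img = np.where(mask.mask, np.median(img), img)
    return img


def detect_molecules(
    mean_image: np.ndarray,
    min_sigma: float = 1.0,
    max_sigma: float = 5.0,
    threshold: float = 1.0,
    overlap: float = 0.9,
) -> np.ndarray:
    """Multiscale Laplacian-of-Gaussian blob detection.

    Returns an (n, 3) array of ``(row, col, sigma)``.  The threshold is on
    the scale-normalized LoG response of the pile-up-corrected photon-count
    image.
    """
    img = np.asarray(mean_image, dtype=float)
    if img.size == 0 or not np.any(img):
        return np.empty((0, 3))
    blobs = blob_log(
        img,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        threshold=threshold,
        overlap=overlap,
    )
    return blobs.reshape(-1, 3)


def _corrected_frames(stack: GatedFrameStack) -> np.ndarray:
    """Per-pixel pile-up-corrected frames; saturated pixels become NaN."""
    m = stack.config.max_count
    frames = stack.frames.astype(float)
    sat = frames >= m
    frames = np.where(sat, 0.0, frames)
    out = est.pileup_correct(frames, stack.config.bit_depth)
    out[sat] = np.nan
    return out


def extract_traces(
    stack: GatedFrameStack,
    centers: Sequence[Sequence[float]],
    mask: Optional[PixelMask] = None,
    box_halfwidth: int = 2,
    neighbor_distance: float = 5.0,
) -> tuple[list[GateTrace], list[tuple[int, str]]]:
    """Box-summed corrected traces around each detected center.

    Pile-up correction is applied per pixel per frame before summation.
    Masked pixels are excluded from the box sum, which is rescaled by
    ``box_area / (box_area - n_masked)`` to preserve the expected
    intensity.  Centers with another center closer than
    ``neighbor_distance`` px are kept but flagged overlapping; centers too
    close to the border are dropped with a reason.  Returns
    ``(traces, dropped)`` where dropped holds ``(center_index, reason)``.
    """
    corrected = _corrected_frames(stack)
    h, w = stack.frames.shape[1:]
    hw = box_halfwidth
    box_area = (2 * hw + 1) ** 2
    pts = np.asarray([c[:2] for c in centers], dtype=float).reshape(-1, 2)

    traces: list[GateTrace] = []
    dropped: list[tuple[int, str]] = []
    for i, (r0, c0) in enumerate(pts):
        r, c = int(round(r0)), int(round(c0))
        if r - hw < 0 or c - hw < 0 or r + hw >= h or c + hw >= w:
            dropped.append((i, "border"))
            continue
        box = corrected[:, r - hw : r + hw + 1, c - hw : c + hw + 1]
        n_masked = 0
        if mask is not None:
            sub = mask.mask[r - hw : r + hw + 1, c - hw : c + hw + 1]
            n_masked = int(sub.sum())
            if n_masked >= box_area:
                dropped.append((i, "fully_masked"))
                continue
            box = np.where(sub[None, :, :], 0.0, box)
        sums = box.sum(axis=(1, 2)) * box_area / (box_area - n_masked)
        d2 = np.sum((pts - pts[i]) ** 2, axis=1)
        d2[i] = np.inf
        overlapping = bool(np.any(d2 < neighbor_distance ** 2))
        traces.append(
            GateTrace(
                molecule_id=i,
                center=(r, c),
                n0=sums[0::2],
                n1=sums[1::2],
                box_size=2 * hw + 1,
                overlapping=overlapping,
                compensated=n_masked > 0,
            )
        )
    return traces, dropped


def _step_response(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Difference of forward/backward k-frame means at each interior frame.

    ``resp[j]`` corresponds to a step entering at frame ``times[j]``: the
    mean of the k frames starting there minus the mean of the k frames
    before.
    """
    x = np.nan_to_num(np.asarray(x, dtype=float))
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    times = np.arange(k, n - k + 1)
    fwd = (cs[times + k] - cs[times]) / k
    bwd = (cs[times] - cs[times - k]) / k
    return times, fwd - bwd


def detect_steps(
    trace: np.ndarray,
    kernel_halfwidth: int = 10,
    min_step: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate intensity change points by step-kernel convolution.

    The trace is convolved with an antisymmetric difference-of-means kernel
    (mean of the next ``kernel_halfwidth`` frames minus mean of the
    previous ``kernel_halfwidth``); local extrema of magnitude at least
    ``min_step`` and mutual separation of at least ``kernel_halfwidth``
    frames are reported.  Returns ``(times, amplitudes)`` sorted by time;
    positive amplitude = ascending step.  Ties between equal-magnitude
    candidates resolve toward the earlier frame.
    """
    x = np.asarray(trace, dtype=float)
    k = int(kernel_halfwidth)
    if x.size < 2 * k:
        raise ValueError(f"trace too short for step detection (< {2 * k} frames)")
    times, resp = _step_response(x, k)

    cand: list[tuple[int, float]] = []
    for sign in (1.0, -1.0):
        peaks, props = find_peaks(sign * resp, height=min_step, distance=k)
        for p, a in zip(peaks, props["peak_heights"]):
            cand.append((int(times[p]), sign * float(a)))
    # greedy separation enforcement across signs: strongest first, earlier
    # frame wins ties
    cand.sort(key=lambda ta: (-abs(ta[1]), ta[0]))
    kept: list[tuple[int, float]] = []
    for t, a in cand:
        if all(abs(t - t2) >= k for t2, _ in kept):
            kept.append((t, a))
    kept.sort()
    if not kept:
        return np.empty(0, dtype=int), np.empty(0)
    t_arr = np.array([t for t, _ in kept], dtype=int)
    a_arr = np.array([a for _, a in kept])
    return t_arr, a_arr


def _segment_means(x: np.ndarray, boundaries: list[int]) -> list[float]:
    out = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = x[a:b]
        out.append(float(np.nanmean(seg)) if len(seg) else math.nan)
    return out


def classify_trace(
    trace: GateTrace,
    step_times: np.ndarray,
    step_amplitudes: np.ndarray,
    brightness_cutoff: float = 50.0,
    stability_factor: float = 2.0,
    exposure_ms: float = REFERENCE_EXPOSURE_MS,
    kernel_halfwidth: int = 10,
) -> TraceSegmentation:
    """Segment and classify one trace from its detected steps.

    ``single_step``: exactly one descending step and none ascending, the ON
    segment passes the brightness cutoff (rescaled linearly from its 20 ms
    reference exposure) and its fluctuations stay within
    ``stability_factor`` times the shot-noise level sqrt(mean).
    ``acceptor_donor``: exactly one ascending step followed by one
    descending step, both ON segments passing the same checks.  Everything
    else is ``rejected`` with the first failed criterion as the reason.
    The background level per gate is the lowest segment mean after the last
    descending step.
    """
    n = len(trace.n0)
    cutoff = brightness_cutoff * exposure_ms / REFERENCE_EXPOSURE_MS
    t_up = [int(t) for t, a in zip(step_times, step_amplitudes) if a > 0]
    t_down = [int(t) for t, a in zip(step_times, step_amplitudes) if a < 0]
    boundaries = [0] + sorted(int(t) for t in step_times) + [n]
    levels0 = _segment_means(trace.n0, boundaries)
    levels1 = _segment_means(trace.n1, boundaries)
    t_off = max(t_down) if t_down else None

    # background: lowest post-bleach segment, else trailing-frame mean
    if t_off is not None:
        idx = [j for j, a in enumerate(boundaries[:-1]) if a >= t_off]
        j_min = min(idx, key=lambda j: levels0[j])
        b0, b1 = levels0[j_min], levels1[j_min]
    else:
        tail = max(n - kernel_halfwidth, 0)
        b0 = float(np.nanmean(trace.n0[tail:]))
        b1 = float(np.nanmean(trace.n1[tail:]))

    def seg_checks(a: int, b: int) -> Optional[str]:
        seg = trace.n0[a:b]
        seg = seg[np.isfinite(seg)]
        if len(seg) == 0:
            return REJECT_DIM
        mean = float(np.mean(seg))
        if mean < cutoff:
            return REJECT_DIM
        if len(seg) >= 2 and float(np.std(seg, ddof=1)) > stability_factor * math.sqrt(mean):
            return REJECT_UNSTABLE
        return None

    label, reason = CLASS_REJECTED, None
    if len(t_down) == 1 and len(t_up) == 0:
        reason = seg_checks(0, t_down[0])
        if reason is None:
            label = CLASS_SINGLE_STEP
    elif len(t_down) == 1 and len(t_up) == 1:
        if t_up[0] < t_down[0]:
            reason = seg_checks(0, t_up[0]) or seg_checks(t_up[0], t_down[0])
            if reason is None:
                label = CLASS_ACCEPTOR_DONOR
        else:
            reason = REJECT_STEP_ORDER
    elif len(t_down) == 0:
        reason = REJECT_NO_STEP
    else:
        reason = REJECT_MULTI_STEP

    return TraceSegmentation(
        t_up=t_up,
        t_down=t_down,
        boundaries=boundaries,
        levels_n0=levels0,
        levels_n1=levels1,
        t_off=t_off,
        b0=b0,
        b1=b1,
        label=label,
        reason=reason,
    )


def static_lifetime(
    trace: GateTrace, seg: TraceSegmentation, gate_separation: float
) -> LifetimeEstimate:
    """Single lifetime from ON-segment time averages of both gates.

    The two-gate formula is applied to the mean counts over ``[0, t_off)``
    with the per-gate background from the segmentation.  The available
    photon count is ``2 x sum(N0)`` over the ON segment.  Estimates from
    fewer than 5 frame pairs carry a ``low_n`` flag.
    """
    end = seg.t_off if seg.t_off is not None else len(trace.n0)
    on0 = trace.n0[:end]
    on1 = trace.n1[:end]
    if len(on0) == 0:
        return LifetimeEstimate(
            math.nan, 0.0, censored=True, censor_reason="empty_on_segment"
        )
    pair = GatePair(
        n0=float(np.nanmean(on0)),
        n1=float(np.nanmean(on1)),
        b0=seg.b0,
        b1=seg.b1,
        gate_separation=gate_separation,
    )
    base = two_gate_lifetime(pair)
    flags = ("low_n",) if len(on0) < 5 else ()
    return LifetimeEstimate(
        tau=base.tau,
        n_photons=2.0 * float(np.nansum(on0)),
        censored=base.censored,
        censor_reason=base.censor_reason,
        flags=flags,
    )


def dynamic_lifetime(
    trace: GateTrace,
    seg: TraceSegmentation,
    gate_separation: float,
    bin_factors: Sequence[int] = (2, 10),
) -> LifetimeTrace:
    """Time-resolved lifetimes at the native pair rate and binned rates.

    Binned lifetimes are computed by applying the two-gate formula to the
    time-averaged counts within each bin — not by averaging lifetime
    samples, since the log is nonlinear.  Segment-averaged lifetimes are
    produced for every segment up to the last descending step.  The
    per-molecule empirical F-value uses the native-rate samples over the ON
    interval with ``N = 2 x mean(N0)``.
    """
    tau_native, n_cens = lifetime_series(
        trace.n0, trace.n1, seg.b0, seg.b1, gate_separation
    )
    binned: dict[int, np.ndarray] = {}
    for f in bin_factors:
        f = int(f)
        if f < 1:
            raise ValueError("bin factors must be positive integers")
        nb = len(trace.n0) // f
        if nb == 0:
            binned[f] = np.empty(0)
            continue
        m0 = np.nanmean(trace.n0[: nb * f].reshape(nb, f), axis=1)
        m1 = np.nanmean(trace.n1[: nb * f].reshape(nb, f), axis=1)
        binned[f], _ = lifetime_series(m0, m1, seg.b0, seg.b1, gate_separation)

    end = seg.t_off if seg.t_off is not None else len(trace.n0)
    segment_taus: list[tuple[int, int, float]] = []
    for a, b in zip(seg.boundaries[:-1], seg.boundaries[1:]):
        if a >= end or b > end:
            continue
        pair = GatePair(
            n0=float(np.nanmean(trace.n0[a:b])),
            n1=float(np.nanmean(trace.n1[a:b])),
            b0=seg.b0,
            b1=seg.b1,
            gate_separation=gate_separation,
        )
        segment_taus.append((a, b, two_gate_lifetime(pair).tau))

    f_value = None
    on_tau = tau_native[:end]
    if np.count_nonzero(np.isfinite(on_tau)) >= 2:
        n_avail = 2.0 * float(np.nanmean(trace.n0[:end]))
        if n_avail > 0:
            f_value = empirical_f_value(on_tau, n_avail).f
    return LifetimeTrace(
        tau_native=tau_native,
        binned=binned,
        segment_taus=segment_taus,
        f_value=f_value,
        n_censored=n_cens,
    )


def fret_from_segmentation(
    trace: GateTrace,
    seg: TraceSegmentation,
    gate_separation: float,
    min_segment_pairs: int = 5,
) -> FretEstimate:
    """FRET efficiencies from an acceptor-then-donor photobleaching trace.

    The quenched lifetime comes from the segment before the ascending step,
    the donor-only lifetime from the segment between the ascending and
    descending steps; intensities are background-subtracted first-gate
    segment means.  Segments shorter than ``min_segment_pairs`` flag the
    estimate unreliable.
    """
    if seg.label != CLASS_ACCEPTOR_DONOR:
        raise ValueError("FRET readout requires an acceptor_donor trace")
    tu, td = seg.t_up[0], seg.t_down[0]
    if tu <= 0:
        raise ValueError("quenched (pre-ascending) segment is absent")

    def seg_tau(a: int, b: int) -> float:
        pair = GatePair(
            n0=float(np.nanmean(trace.n0[a:b])),
            n1=float(np.nanmean(trace.n1[a:b])),
            b0=seg.b0,
            b1=seg.b1,
            gate_separation=gate_separation,
        )
        res = two_gate_lifetime(pair)
        if res.censored:
            raise ValueError(f"segment lifetime censored: {res.censor_reason}")
        return res.tau

    tau_da = seg_tau(0, tu)
    tau_d = seg_tau(tu, td)
    n_da = float(np.nanmean(trace.n0[:tu])) - seg.b0
    n_d = float(np.nanmean(trace.n0[tu:td])) - seg.b0
    flags = ("unreliable",) if min(tu, td - tu) < min_segment_pairs else ()
    return fret_efficiencies(tau_da, tau_d, n_da, n_d, flags=flags)


@dataclass
class HistogramSummary:
    counts: np.ndarray
    edges: np.ndarray
    mean: float
    std: float
    mode: float
    n: int
    censored_fraction: float


def lifetime_histogram(
    estimates: Sequence[LifetimeEstimate],
    bin_width: float = 0.1,
    hist_range: tuple[float, float] = (0.0, 10.0),
) -> HistogramSummary:
    """Fixed-width lifetime histogram with summary statistics.

    Censored estimates are dropped and reported as a fraction; an input
    with no usable estimate is an error.
    """
    taus = np.array([e.tau for e in estimates if not e.censored and np.isfinite(e.tau)])
    n_total = len(estimates)
    if taus.size == 0:
        raise ValueError("all lifetime estimates are censored")
    lo, hi = hist_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(taus, bins=edges)
    mode = float(edges[np.argmax(counts)] + bin_width / 2)
    return HistogramSummary(
        counts=counts,
        edges=edges,
        mean=float(taus.mean()),
        std=float(taus.std(ddof=1)) if taus.size > 1 else 0.0,
        mode=mode,
        n=int(taus.size),
        censored_fraction=1.0 - taus.size / n_total,
    )


def throughput_speedup(
    n_molecules: int, per_molecule_time_s: float, acquisition_time_s: float
) -> float:
    """Wide-field acceleration over sequential point scanning.

    Sequential scanning needs ``n_molecules x per_molecule_time_s``; a
    single wide-field acquisition captures them all in
    ``acquisition_time_s``.
    """
    if acquisition_time_s <= 0:
        raise ValueError("acquisition time must be positive")
    return n_molecules * per_molecule_time_s / acquisition_time_s


def analyze_stack(
    stack: GatedFrameStack,
    dark_stack: Optional[GatedFrameStack] = None,
    params: Optional[AnalysisParams] = None,
) -> dict:
    """Full pipeline on one stack; returns a results bundle.

    Keys: ``table`` (one row per detected molecule), ``traces``,
    ``segmentations``, ``lifetime_traces``, ``mask``, ``dropped``.
    """
    p = params or AnalysisParams()
    mask = None
    if dark_stack is not None:
        mask = build_warm_pixel_mask(
            dark_stack,
            threshold_factor=p.mask_threshold_factor,
            min_rate=p.mask_min_rate,
        )
    img = detection_image(stack, mask=mask, n_frames=p.detection_frames)
    blobs = detect_molecules(
        img,
        min_sigma=p.log_min_sigma,
        max_sigma=p.log_max_sigma,
        threshold=p.log_threshold,
        overlap=p.log_overlap,
    )
    traces, dropped = extract_traces(
        stack,
        blobs,
        mask=mask,
        box_halfwidth=p.box_halfwidth,
        neighbor_distance=p.neighbor_distance,
    )
    t_sep = stack.config.gate_separation
    rows = []
    segs: dict[int, TraceSegmentation] = {}
    lts: dict[int, LifetimeTrace] = {}
    for tr in traces:
        times, amps = detect_steps(tr.n0, p.kernel_halfwidth, p.min_step)
        seg = classify_trace(
            tr,
            times,
            amps,
            brightness_cutoff=p.brightness_cutoff,
            stability_factor=p.stability_factor,
            exposure_ms=stack.config.exposure_ms,
            kernel_halfwidth=p.kernel_halfwidth,
        )
        segs[tr.molecule_id] = seg
        row = {
            "molecule_id": tr.molecule_id,
            "row": tr.center[0],
            "col": tr.center[1],
            "label": seg.label,
            "reason": seg.reason,
            "overlapping": tr.overlapping,
            "t_off": seg.t_off,
            "tau": np.nan,
            "n_photons": np.nan,
            "censor_reason": None,
            "f_value": np.nan,
            "e_lifetime": np.nan,
            "e_intensity": np.nan,
        }
        if seg.label == CLASS_SINGLE_STEP:
            estd = static_lifetime(tr, seg, t_sep)
            row["tau"] = estd.tau
            row["n_photons"] = estd.n_photons
            row["censor_reason"] = estd.censor_reason
        lt = dynamic_lifetime(tr, seg, t_sep, bin_factors=p.bin_factors)
        lts[tr.molecule_id] = lt
        if lt.f_value is not None:
            row["f_value"] = lt.f_value
        if seg.label == CLASS_ACCEPTOR_DONOR:
            try:
                fr = fret_from_segmentation(tr, seg, t_sep)
                row["e_lifetime"] = fr.e_lifetime
                row["e_intensity"] = fr.e_intensity
                row["tau"] = fr.tau_d  # donor-only lifetime as the headline tau
            except ValueError as exc:
                row["censor_reason"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "traces": traces,
        "segmentations": segs,
        "lifetime_traces": lts,
        "mask": mask,
        "dropped": dropped,
    }
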
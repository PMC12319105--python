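import numpy as np
import pytest

from gatedflim import AcquisitionConfig, BackgroundModel, EmitterTruth, ScenePlan


@pytest.fixture
def small_cfg():
    """Small-sensor acquisition config for fast simulations."""
    return AcquisitionConfig(
        gate_delays=(0.0, 2.5),
        gate_width=10.0,
        sensor_shape=(48, 48),
        n_frame_pairs=50,
        bit_depth=8,
    )


@pytest.fixture
def single_emitter_plan(small_cfg):
    """One bright emitter in the middle of a small sensor, no background."""
    emitter = EmitterTruth(
        position=(24.0, 24.0), lifetime=2.1, brightness=300.0, t_bleach=10_000
    )
    return ScenePlan(
        config=small_cfg,
        emitters=[emitter],
        background=BackgroundModel(),
        rng_seed=42,
    )


def poisson_gate_pairs(rng, signal, u, b, n):
    """Poisson-sampled (N0, N1) pairs for signal S, normalized delay u, ratio b."""
    bkg = b * signal
    n0 = rng.poisson(signal + bkg, n)
    n1 = rng.poisson(signal * np.exp(-u) + bkg, n)
    return n0, n1
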
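import numpy as np
import pytest

from scrscore import IntervalConfig, PreprocConfig, SimDesign, scr_kernel


@pytest.fixture
def interval_cfg():
    return IntervalConfig()


@pytest.fixture
def preproc_cfg():
    return PreprocConfig()


@pytest.fixture
def nofilter_cfg():
    """Preprocessing with the high-pass disabled (detection-only tests)."""
    return PreprocConfig(hp_cutoff_hz=None)


@pytest.fixture
def small_design():
    """Habituation-only design: quick to render, 8 events."""
    return SimDesign(phases=("habituation",), seed=11)


def make_segment_values(
    fs=50.0,
    length_s=14.0,
    responses=(),
    noise_sd=0.0,
    rng=None,
):
    """A synthetic 50 Hz segment: sum of SCR kernels + optional noise.

    responses: iterable of (onset_s, amplitude) pairs.
    """
    n = int(round(length_s * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    for onset, amp in responses:
        v += scr_kernel(t, onset, amp)
    if noise_sd > 0:
        v += (rng or np.random.default_rng(0)).normal(0, noise_sd, size=n)
    return v
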
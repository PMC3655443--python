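import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulsemap as pm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


GRID = (16, 16)
RESP_FREQ = 0.40  # Hz, exact bin for 300 frames at tr = 0.2 s
CARD_FREQ = 1.20  # Hz, exact bin


def _disjoint_compartments(resp_delay=0.0, card_delay=0.0, amplitude=2.0):
    resp = pm.CompartmentSpec(
        mask=pm.disk_mask(GRID, (4, 4), 3), frequency=RESP_FREQ,
        amplitude=amplitude, delay=resp_delay,
    )
    card = pm.CompartmentSpec(
        mask=pm.disk_mask(GRID, (11, 11), 3), frequency=CARD_FREQ,
        amplitude=amplitude, delay=card_delay,
    )
    return resp, card


@pytest.fixture
def two_band_spec():
    """Respiratory + cardiac compartments at exact bin frequencies, SNR 10."""
    resp, card = _disjoint_compartments()
    return pm.PhantomSpec(
        grid_shape=GRID, n_frames=300, tr=0.2, compartments=[resp, card],
        noise_sd=0.2, baseline=100.0, seed=11,
    )


@pytest.fixture
def two_band_series(two_band_spec):
    return pm.generate_phantom(two_band_spec)


def make_two_band_spec(seed, noise_sd=0.2, n_frames=300, **delays):
    resp, card = _disjoint_compartments(
        resp_delay=delays.get("resp_delay", 0.0),
        card_delay=delays.get("card_delay", 0.0),
    )
    return pm.PhantomSpec(
        grid_shape=GRID, n_frames=n_frames, tr=0.2, compartments=[resp, card],
        noise_sd=noise_sd, baseline=100.0, seed=seed,
    )


def true_waveforms(spec):
    """Ground-truth source time courses of every compartment."""
    t = np.arange(spec.n_frames) * spec.tr
    return [
        c.amplitude * np.cos(2 * np.pi * c.frequency * (t - c.delay))
        for c in spec.compartments
    ]


def circ_dist(a, b, period=2 * np.pi):
    """Smallest signed difference a-b on a circle of the given period."""
    return (np.asarray(a) - np.asarray(b) + period / 2) % period - period / 2
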
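import numpy as np
import pytest

from linespark import DetectionParams, LineScanImage, ScanSimConfig, simulate_linescan

#: Analysis preset matched to the simulated spark timescale (~100 ms events
#: at 1.89 ms/line): the running-baseline window must be long relative to
#: the event, two erosion passes suppress the speckle that boxcar smoothing
#: correlates, and the area cut sits far above the largest noise cluster
#: but far below the smallest spark component.
SIM_PARAMS = DetectionParams(
    half_window=200, threshold_n=0.5, erosion_iterations=2, min_area_px=50
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230604)


@pytest.fixture
def small_image(rng):
    """A 16x64 random positive line scan for oracle comparisons."""
    pixels = rng.uniform(50.0, 150.0, size=(16, 64))
    return LineScanImage(pixels, pixel_size=0.1, line_period=0.002, source_id="small")


@pytest.fixture
def sparky_scan():
    """A 5-spark scan at SNR 5 with its ground truth."""
    config = ScanSimConfig(n_time=4000, n_sparks=5, seed=7, noise_sd=20.0)
    return simulate_linescan(config)


def random_images(seed, count, max_space=32, max_time=128):
    """Stream of random LineScanImage fixtures for oracle sweeps."""
    rng = np.random.default_rng(seed)
    for _ in range(count):
        n_space = int(rng.integers(8, max_space + 1))
        n_time = int(rng.integers(32, max_time + 1))
        pixels = rng.uniform(10.0, 200.0, size=(n_space, n_time))
        yield LineScanImage(pixels, pixel_size=0.1, line_period=0.002)
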
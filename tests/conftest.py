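import numpy as np
import pytest

from resectnet.preprocess import Annotations, EEGRecording
from resectnet.synth import CorticalGeometry, make_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_geometry():
    """10 ROIs x 6 vertices on the standard sphere."""
    return make_geometry(10, 6, seed=3)


@pytest.fixture
def toy_geometry():
    """Hand-built two-hemisphere geometry with controlled distances.

    ROI 0 (left): 20 vertices around (-40, 0, 0).
    ROI 1 (left): vertices 8 mm from ROI 0's resected core.
    ROI 2 (left): vertices 12 mm away.
    ROI 3 (right): mirror of ROI 1 (8 mm in coordinates, contralateral).
    """
    coords = []
    roi = []
    # ROI 0: cluster at x=-40
    for k in range(20):
        coords.append([-40.0, k * 0.1, 0.0])
        roi.append(0)
    # ROI 1: 8 mm from (-40, 0, 0) along -x
    coords.append([-48.0, 0.0, 0.0])
    roi.append(1)
    # ROI 2: 12 mm away
    coords.append([-40.0, 0.0, 12.0])
    roi.append(2)
    # ROI 3: right hemisphere, 8 mm from the resection in plain distance
    coords.append([-32.0, 0.0, 0.0])
    roi.append(3)
    return CorticalGeometry(
        vertex_coords=np.array(coords),
        vertex_roi=np.array(roi),
        roi_names=["L.res", "L.near", "L.far", "R.mirror"],
        roi_hemisphere=["left", "left", "left", "right"],
    )


@pytest.fixture
def sine_recording():
    """Two-channel recording with 10 Hz and 60 Hz sinusoids, 20 s at 256 Hz."""
    fs = 256.0
    t = np.arange(int(20 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 60 * t)])
    return EEGRecording(data=data, fs=fs, sensor_labels=["s10", "s60"],
                        annotations=Annotations())
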
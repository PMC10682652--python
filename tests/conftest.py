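import warnings

import numpy as np
import pytest

from vploop.io import average_beats, mesh_beat, segment_beats
from vploop.loop import build_loop, compute_features, extract_landmarks
from vploop.synthetic import BeatParams, gen_beat_pair


@pytest.fixture(scope="session")
def default_params():
    return BeatParams()


@pytest.fixture(scope="session")
def noiseless_pair(default_params):
    return gen_beat_pair(default_params, noise_sd=0.0, seed=0)


def run_pipeline(pair, mesh_points=256):
    """segment -> mesh -> average -> loop -> landmarks -> features."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pbeat = average_beats(
            [mesh_beat(b, mesh_points) for b in segment_beats(pair.pressure)]
        )
        vbeat = average_beats(
            [mesh_beat(b, mesh_points) for b in segment_beats(pair.velocity)]
        )
    loop = build_loop(pbeat, vbeat)
    landmarks = extract_landmarks(loop)
    return loop, landmarks, compute_features(landmarks)


@pytest.fixture(scope="session")
def pipeline_result(noiseless_pair):
    return run_pipeline(noiseless_pair)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
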
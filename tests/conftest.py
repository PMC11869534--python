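import numpy as np
import pytest

from facegest import DEFAULT_SCHEME, FrameObservation
from facegest.synthetic import eight_class_scenario, generate


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_dataset():
    """A small 8-class synthetic dataset shared across read-only tests."""
    return generate(eight_class_scenario(clips_per_class=3, seed=42))


def random_frame(rng, scheme=DEFAULT_SCHEME, clip_id="clip", frame_index=0):
    """A well-separated random frame with all landmarks present."""
    coords = rng.uniform(50.0, 500.0, size=(len(scheme), 2))
    # keep the normalization pair apart so geometry stays non-degenerate
    i = scheme.index(scheme.normalization_pair[0])
    j = scheme.index(scheme.normalization_pair[1])
    while np.hypot(*(coords[i] - coords[j])) < 1.0:
        coords[j] = rng.uniform(50.0, 500.0, size=2)
    return FrameObservation(
        clip_id=clip_id,
        frame_index=frame_index,
        coords=coords,
        likelihood=rng.uniform(0.7, 1.0, size=len(scheme)),
    )
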
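import numpy as np
import pytest

from herdvitals.synthetic import SyntheticSceneSpec, gen_rgb_sequence


@pytest.fixture(scope="session")
def small_scene():
    """20-s default-noise recording at reduced resolution (shared, read-only)."""
    spec = SyntheticSceneSpec(
        duration_s=20.0, fps=30.0, frame_size=(120, 160), hr_bpm=78.0,
        rr_brpm=30.0, seed=11,
    )
    seq, eye, nose, head, truth = gen_rgb_sequence(spec)
    return {
        "spec": spec, "seq": seq, "eye": eye, "nose": nose, "head": head,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
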
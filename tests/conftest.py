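import numpy as np
import pytest

import ciliaswirl as cs


@pytest.fixture(scope="session")
def cbf_video():
    """250 fps / 3 s recording with tufts beating at 10, 18.3 and 25 Hz."""
    spec = cs.CiliaVideoSpec(
        height=128,
        width=128,
        tuft_coverage=0.2,
        freq_choices=(10.0, 18.3, 25.0),
        noise_sigma=0.0,
        seed=4,
    )
    return cs.generate_cilia_video(spec)


@pytest.fixture(scope="session")
def rigid_rotation_tracks():
    """Noiseless rigid rotation at three radii about the origin."""
    return cs.generate_bead_trajectories(
        center=(0.0, 0.0),
        omega=1.0,
        dt=0.05,
        T=4.0,
        noise_sigma=0.0,
        radii=np.array([50.0, 100.0, 150.0]),
        seed=0,
    )
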
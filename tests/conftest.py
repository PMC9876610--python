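import numpy as np
import pandas as pd
import pytest

from traitgaze.preprocess import Fixation
from traitgaze.simulate import SimulationParams, gen_dataset


def noise_free_params(n_participants=3, seed=7, **overrides):
    """Generator settings with rendering noise and missingness switched off."""
    kwargs = dict(n_participants=n_participants, seed=seed,
                  fixation_noise_px=0.0, interocular_noise_px=0.0,
                  missing_burst_rate=0.0)
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """3 participants x 80 trials, rendered at 300 Hz without noise."""
    return gen_dataset(noise_free_params(), render_gaze=True)


@pytest.fixture(scope="session")
def small_lmm_frame():
    """Trial-level table with known fixed effects and a random intercept."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(18):
        za, zs = rng.normal(), rng.normal()
        sex = ["female", "male"][i % 2]
        u = rng.normal() * 0.4
        for t in range(12):
            emo = ["angry", "fearful", "happy", "sad", "neutral"][t % 5]
            y = 0.3 + 0.2 * zs + 0.15 * za * zs + u + rng.normal() * 0.5
            rows.append((f"p{i:02d}", za, zs, sex, emo, y))
    return pd.DataFrame(rows, columns=["participant_id", "z_aq4", "z_spin",
                                       "sex", "emotion", "y"])


def make_fixations(spec):
    """Build labelled fixations from (aoi, onset, offset) triples."""
    return [Fixation(onset=s, offset=e, cx=0.0, cy=0.0, aoi=a)
            for a, s, e in spec]
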
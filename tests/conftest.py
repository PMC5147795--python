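import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gazescreen import (
    CohortSpec,
    GazeRecording,
    GroupGazeParams,
    TextLayout,
    feature_schema,
    noiseless,
    simulate_recording,
)
from gazescreen.simulate import HR_DEFAULT_PARAMS, LR_DEFAULT_PARAMS


@pytest.fixture(scope="session")
def schema():
    return feature_schema()


@pytest.fixture(scope="session")
def small_layout():
    # 3 lines keep simulated recordings short; line extent is wide enough
    # that every return sweep exceeds the 5 deg sweep threshold.
    return TextLayout(
        n_lines=3, sentences=4, mean_sentence_len=4.0,
        line_extent_deg=12.0, line_spacing_deg=1.5,
    )


@pytest.fixture(scope="session")
def clean_lr():
    return noiseless(LR_DEFAULT_PARAMS)


@pytest.fixture(scope="session")
def clean_hr():
    return noiseless(HR_DEFAULT_PARAMS)


@pytest.fixture(scope="session")
def noiseless_recording(clean_lr, small_layout):
    return simulate_recording(clean_lr, small_layout, seed=5, subject_id="clean")


def make_recording(x, y=None, valid=None, sampling_rate=100.0, **kwargs):
    """Binocular recording with both eyes at the given cyclopean trajectory."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    n = len(x)
    pos = np.column_stack([x, y, x, y])
    v = np.ones((n, 2), dtype=bool) if valid is None else np.asarray(valid)
    pos[~(v[:, 0] & v[:, 1])] = np.nan
    kwargs.setdefault("subject_id", "manual")
    kwargs.setdefault("label", "unknown")
    return GazeRecording(
        sampling_rate=sampling_rate,
        t=np.arange(n) * (1000.0 / sampling_rate),
        pos=pos,
        valid=v,
        **kwargs,
    )


def gaussian_problem(seed, n_per_class=30, n_noise=18, n_informative=2, shift=2.0):
    """Two-class Gaussian feature matrix: informative columns first."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    p = n_informative + n_noise
    X = rng.normal(size=(n, p))
    labels = np.array(["HR"] * n_per_class + ["LR"] * n_per_class)
    X[labels == "HR", :n_informative] += shift
    return X, labels
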
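import numpy as np
import pytest

from thetareg.cluster import build_neighbors
from thetareg.containers import EpochedRecording
from thetareg.headmodel import generate_leadfield, make_head_model
from thetareg.source import eloreta_inverse


@pytest.fixture(scope="session")
def head_model():
    """Reduced 80-voxel spherical head model with the 64-channel montage."""
    return make_head_model(80)


@pytest.fixture(scope="session")
def leadfield(head_model):
    return generate_leadfield(head_model)


@pytest.fixture(scope="session")
def operator_exact(leadfield):
    """Unregularised eLORETA operator (noiseless exact-localisation limit)."""
    return eloreta_inverse(leadfield, alpha_reg=0.0)


@pytest.fixture(scope="session")
def montage_graph(head_model):
    return build_neighbors(head_model.channel_labels,
                           head_model.channel_positions)


def build_epochs(data, sfreq=100.0, t0=-6.0, conditions=None):
    """Wrap a (channels, time, trials) array in an EpochedRecording with a
    circular dummy montage."""
    n_ch, n_t, n_tr = data.shape
    if conditions is None:
        conditions = np.array(["maintain"] * n_tr, dtype=object)
    ang = 2 * np.pi * np.arange(n_ch) / n_ch
    pos = np.column_stack([np.cos(ang), np.sin(ang), np.full(n_ch, 0.5)])
    return EpochedRecording(
        data=np.asarray(data, float),
        time_axis=t0 + np.arange(n_t) / sfreq,
        condition=np.asarray(conditions, dtype=object),
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        channel_positions=pos,
        sfreq=sfreq,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
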
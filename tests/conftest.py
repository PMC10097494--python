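import numpy as np
import pytest

from speedcap import ECAPFrameSet, ExcitationModel, ecap_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smooth_model():
    """Smooth 8-electrode ground truth within the solver's caps."""
    sigma = np.array([2.0, 2.2, 2.5, 2.4, 2.1, 1.9, 1.8, 2.0])
    eta = np.array([0.7, 0.8, 0.9, 1.0, 0.9, 0.7, 0.6, 0.65])
    return ExcitationModel(sigma, eta)


def frameset_from_traces(a, b, c, d, **kwargs):
    return ECAPFrameSet(
        probe_electrode=kwargs.pop("probe", 1),
        masker_electrode=kwargs.pop("masker", 2),
        frames={"A": np.asarray(a, float), "B": np.asarray(b, float),
                "C": np.asarray(c, float), "D": np.asarray(d, float)},
        **kwargs,
    )


@pytest.fixture
def const_frames():
    """Constant 16-sample frames A=5, B=9, C=4, D=1 µV → extracted trace ≡ −1."""
    n = 16
    return frameset_from_traces(np.full(n, 5.0), np.full(n, 9.0), np.full(n, 4.0), np.full(n, 1.0))


@pytest.fixture
def template_32():
    return ecap_template(n_samples=32, amplitude_uv=100.0)
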
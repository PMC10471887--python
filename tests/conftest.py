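import numpy as np
import pytest

from dcfcnn.synthetic import SynthConfig, make_arrays


@pytest.fixture(scope="session")
def tiny_dataset():
    """16 balanced scenes at 32x32, fully separable: fast training fixture."""
    cfg = SynthConfig(n_no_cancer=8, n_partial=6, n_full=2,
                      image_height=32, image_width=32,
                      separability=1.0, seed=42)
    X, y, manifest = make_arrays(cfg)
    return X, y, manifest


@pytest.fixture(scope="session")
def tiny_tensors(tiny_dataset):
    """The tiny dataset standardised and laid out (N, 3, H, W) for the net."""
    X, y, _ = tiny_dataset
    x = X.astype(np.float32) / 255.0
    x = (x - x.mean(axis=(0, 1, 2))) / x.std(axis=(0, 1, 2))
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)), y
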
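import numpy as np
import pytest

from leafkdx import synthgen


@pytest.fixture(scope="session")
def plain_leaf():
    """A healthy leaf: no margin band, no spots, mild wobble."""
    params = synthgen.LeafParams(margin_fraction=0.0, spot_count=0, seed=11)
    img, truth = synthgen.make_leaf(params)
    return params, img, truth


@pytest.fixture(scope="session")
def symptomatic_leaf():
    """A deficient leaf: 20 % yellowing margin plus three spots."""
    params = synthgen.LeafParams(margin_fraction=0.2, spot_count=3, seed=5)
    img, truth = synthgen.make_leaf(params)
    return params, img, truth


@pytest.fixture(scope="session")
def random_leaf_batch():
    """50 leaves across the severity range, for recovery/property tests."""
    rng = np.random.default_rng(42)
    out = []
    for i in range(50):
        params = synthgen.LeafParams(
            margin_fraction=float(rng.uniform(0.0, 0.45)),
            spot_count=int(rng.integers(0, 6)),
            boundary_wobble=float(rng.uniform(0.0, 0.10)),
            illum_gradient=(float(rng.uniform(0, 360)), 0.15),
            seed=1000 + i,
        )
        out.append((params, *synthgen.make_leaf(params)))
    return out


@pytest.fixture(scope="session")
def feature_table():
    """Feature table from a 120-leaf synthetic flowering-period dataset."""
    import warnings

    from leafkdx.pipeline import RunConfig, _dataset_features

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        images, truth = synthgen.make_dataset(120, period="flowering", seed=3)
        feats, _ = _dataset_features(images, truth, RunConfig())
    return feats
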
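import numpy as np
import pytest

import cacscore as c


@pytest.fixture(scope="session")
def small_phantom():
    """One mid-burden phantom exam with distractors."""
    spec = c.PhantomSpec(n_slices=4, image_size=64, seed=11)
    return c.generate_volume(spec)


@pytest.fixture(scope="session")
def stratified_cohort():
    """Ten phantoms cycling buckets I..V (two per bucket)."""
    pairs, counts = c.make_dataset(10, seed=5)
    return pairs, counts


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest config that still satisfies the full output contract."""
    return c.build_model(c.ModelConfig(
        encoder_depth=10, base_channels=4, decoder_channels=(8, 8, 4, 4),
        cardinality=2, se_reduction=2, seed=0))


def random_prob_volume(rng, n_slices=3, size=20):
    """A random but contract-satisfying probability volume."""
    calc = rng.uniform(0.01, 0.99, (n_slices, size, size))
    vessel = rng.uniform(0.05, 1.0, (n_slices, 4, size, size))
    vessel /= vessel.sum(axis=1, keepdims=True)
    return c.ProbabilityVolume(calc, vessel)
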
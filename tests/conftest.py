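import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210319)


@pytest.fixture(scope="session")
def four_class_features():
    """Small labeled 4-class feature table from the default species profiles."""
    from nanogapid import DEFAULT_PROFILES, generate_labeled_feature_dataset

    return generate_labeled_feature_dataset(DEFAULT_PROFILES, n_per_class=120, seed=7)


@pytest.fixture(scope="session")
def separable_features():
    """Four classes with widely separated amplitude supports (almost disjoint)."""
    from nanogapid import SpeciesProfile, generate_labeled_feature_dataset

    shapes = [
        ("rectangular", {"jitter": 0.0}),
        ("ramp", {"floor": 0.1, "jitter": 0.0}),
        ("exp_decay", {"decay": 2.0, "jitter": 0.0}),
        ("noisy_plateau", {"jitter": 0.2}),
    ]
    profiles = [
        SpeciesProfile(name, amp, 1.0, 4.0, 0.5, shape, params)
        for (name, amp), (shape, params) in zip(
            [("a", 30.0), ("b", 90.0), ("c", 150.0), ("d", 210.0)], shapes
        )
    ]
    return generate_labeled_feature_dataset(profiles, n_per_class=60, seed=11, noise_sd_pa=0.5)
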
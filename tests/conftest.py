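import numpy as np
import pytest

from hsitissue import (
    PhantomConfig,
    SampleSet,
    exclude_noisy_channels,
    extract_samples,
    generate_cohort,
    scale_cube,
    simulate_probability_map,
)


@pytest.fixture(scope="session")
def small_config():
    """A small, fast phantom cohort configuration shared across tests."""
    return PhantomConfig(n_patients=4, height=32, width=40,
                         class_contrast=2.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def speckled_maps(small_cohort):
    """Simulated salt-and-pepper probability maps for the small cohort."""
    maps = [simulate_probability_map(ph, flip_rate=0.1, seed=100 + i)
            for i, ph in enumerate(small_cohort)]
    masks = [ph.mask for ph in small_cohort]
    return maps, masks


def _split_samples(cohort, scaling):
    cubes = [scale_cube(exclude_noisy_channels(ph.cube), scaling)
             for ph in cohort]
    pooled = SampleSet.concatenate([
        extract_samples(c, ph.mask, ph.patient_id)
        for c, ph in zip(cubes, cohort)])
    idx = np.random.default_rng(3).permutation(len(pooled))[:500]
    return pooled.subset(idx[:400]), pooled.subset(idx[400:])


@pytest.fixture(scope="session")
def training_samples(small_cohort):
    """Pooled, normalized samples from the small cohort, split 80/20."""
    return _split_samples(small_cohort, "normalization")


@pytest.fixture(scope="session")
def training_samples_standardized(small_cohort):
    """Same split with z-score scaling (the RS-friendly preprocessing)."""
    return _split_samples(small_cohort, "standardization")
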
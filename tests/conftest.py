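"""Shared fixtures. The expensive cross-validated runs are session-scoped and
reused by both the property and the acceptance tests."""

import numpy as np
import pytest

from her2mil import MILConfig, SynthConfig, TrainConfig, generate_cohort, generate_tile_images
from her2mil.train_eval import run_experiment

#: Model scaled to the synthetic embedding width (same architecture family).
SMALL_MIL = MILConfig(d_in=32, d_proj=64, d_attn=32, n_classes=2)


@pytest.fixture(scope="session")
def clean_cohort():
    """Default synthetic cohort: clear witness clusters, no label noise."""
    return generate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def m2_experiment(clean_cohort):
    """10-fold cross-validated neg-vs-high (M2) run on the clean cohort."""
    tc = TrainConfig(seed=1)
    return run_experiment(clean_cohort.manifest, clean_cohort.bags, ["M2"], SMALL_MIL, tc), tc


@pytest.fixture(scope="session")
def noisy_experiments():
    """M2 and M5 runs with 0↔1+ interobserver flip noise ε = 0.3, three replicates."""
    out = []
    for seed in (11, 12, 13):
        cohort = generate_cohort(SynthConfig(seed=seed, label_noise=0.3))
        tc = TrainConfig(seed=seed)
        out.append(run_experiment(cohort.manifest, cohort.bags, ["M2", "M5"], SMALL_MIL, tc))
    return out


@pytest.fixture(scope="session")
def tile_fixtures():
    patches, labels, stain = generate_tile_images(SynthConfig(seed=7), n_per_class=25)
    return patches, labels, stain


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
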
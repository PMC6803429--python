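import numpy as np
import pytest

import batchanchor as ba


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_table(rng):
    data = rng.lognormal(mean=3.0, sigma=0.6, size=(500, 4))
    data[rng.random(data.shape) < 0.2] = 0.0
    return ba.EventTable(
        sample_id="s1",
        batch_id="batch1",
        role="anchor",
        channels=[("Ch1", "CD3"), ("Ch2", "CD4"), ("Ch3", "CD8"), ("Ch4", "IL6")],
        data=data,
    )


@pytest.fixture
def small_experiment():
    """3 batches x 6 channels with multiplicative effects on all non-reference
    batches; one anchor + one study sample per batch."""
    n_channels = 6
    populations = ba.default_populations(n_channels=n_channels, n_populations=2)
    effects = ba.default_batch_effects(
        n_batches=3, n_channels=n_channels, multiplier_range=(0.6, 1.8), seed=7
    )
    tables, truth = ba.generate_experiment(
        populations, effects, n_batches=3, events_per_sample=3000,
        samples_per_batch=1, seed=11,
    )
    return tables, truth


@pytest.fixture
def experiment_dir(tmp_path, small_experiment):
    tables, truth = small_experiment
    in_dir = tmp_path / "input"
    ba.write_experiment(tables, truth, str(in_dir))
    return in_dir


@pytest.fixture
def default_config(small_experiment):
    tables, _ = small_experiment
    return ba.AdjustmentConfig(
        method="percentile",
        percentile_p=95.0,
        reference_batch="batch1",
        channels_to_adjust=[c for c, _ in tables[0].channels],
    )
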
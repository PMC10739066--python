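import numpy as np
import pytest

from aggrisk import synthetic as syn


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 participants x 2 sessions x 15 min, default conditions."""
    return syn.generate_sessions(syn.scaled_preset(0, 2, 2, 900.0))


@pytest.fixture(scope="session")
def strong_dataset():
    """Easy task: large arousal effects, 6 participants x 2 x 30 min."""
    arousal = syn.ArousalConfig(hr_effect_bpm=30.0, scr_rate_effect=6.0)
    return syn.generate_sessions(syn.scaled_preset(0, 6, 2, 1800.0), arousal=arousal)


@pytest.fixture(scope="session")
def strong_instances(strong_dataset):
    from aggrisk.evaluation import prepare_instances

    return prepare_instances(strong_dataset, 180.0, (60.0,))


@pytest.fixture(scope="session")
def disk_dataset(tmp_path_factory, tiny_dataset):
    from aggrisk.synthetic import generate_dataset

    root = tmp_path_factory.mktemp("ds")
    return generate_dataset(syn.scaled_preset(0, 2, 2, 900.0), out_dir=root)
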
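import numpy as np
import pytest

from hgstates import features, pipeline, preprocess, synthetic


@pytest.fixture(scope="session")
def demo_dataset():
    """Default four-state synthetic envelope.

    Six blocks per state so every contiguous CV fold (~34 epochs) spans more
    than three 10-epoch blocks and therefore contains all four states.
    """
    return pipeline.synthesize_default_dataset(seed=0, n_repeats=6)


@pytest.fixture(scope="session")
def demo_epochs(demo_dataset):
    env, blocks, gt = demo_dataset
    es_raw = features.epoch(env, blocks)
    env_z = preprocess.zscore_segments(env)
    es_z = features.epoch(env_z, blocks)
    return es_raw, es_z


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def signflip_dataset():
    """Two states with equal mean/SD and loadings [1,1] vs [1,-1]."""
    def spec(name, col2):
        return synthetic.StateSpec(
            name=name,
            channel_mean=np.array([5.0, 5.0]),
            channel_sd=np.array([1.0, 1.0]),
            loading=np.array([[1.0], [col2]]),
            taus_ms=np.array([1000.0]),
            factor_scale=np.array([1.5]),
        )

    specs = [spec("pos", 1.0), spec("neg", -1.0)]
    sched = synthetic.Schedule.repeated(["pos", "neg"], 2)
    return synthetic.generate_envelope_dataset(specs, sched, seed=21)
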
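import numpy as np
import pytest

from iemgprop import preprocess, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_protocol():
    """Compressed protocol for fast unit tests: 10 kHz, faster sine, 3 reps."""
    return synth.ProtocolSpec(repetitions=3, rest_duration=0.5, sine_frequency=0.5)


@pytest.fixture(scope="session")
def small_session(small_protocol):
    return synth.assemble_session(small_protocol, seed=42)


@pytest.fixture(scope="session")
def filtered_small_session(small_session):
    filt = preprocess.filter_session(small_session, preprocess.CombFilterSpec(n_harmonics=5))
    return small_session, filt


@pytest.fixture(scope="session")
def proportional_segment():
    """One full-protocol single-movement segment with proportional drive,
    plus its normalized true force."""
    proto = synth.single_movement_protocol(repetitions=10)
    units = synth.proportional_units(15, [5, 7])
    cfg = (synth.ChannelConfig("flex", units, 0.0),)
    session = synth.assemble_session(proto, channel_configs=cfg, seed=5)
    filt = preprocess.filter_session(session, preprocess.CombFilterSpec(n_harmonics=5))
    seg = preprocess.segment_by_cues(session, iemg=filt)[0]
    rb = seg.repetition_boundaries
    truth = session.ground_truth["true_force"]["flex"]
    truth_norm = preprocess.normalize_phase(truth, (int(rb[0]), int(rb[2])))
    return session, seg, truth_norm
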
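import pytest

from retwave import (EncoderSpec, PretrainConfig, WaveSimParams,
                     extract_events, make_base_images, simulate_waves)


@pytest.fixture(scope="session")
def tiny_movie():
    """A small structured wave movie with its events."""
    params = WaveSimParams(height=24, width=24, n_frames=400, seed=5)
    movie = simulate_waves(params)
    events = extract_events(movie, 0.5, 2)
    assert len(events) >= 3, "fixture movie must contain several events"
    return movie, events


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest encoder used for unit tests (16x16 input, 16-dim embedding)."""
    return EncoderSpec(backbone="tiny-conv", input_size=(16, 16, 3),
                       projector_dims=(16, 16, 16), embedding_dim=16,
                       base_channels=4)


@pytest.fixture(scope="session")
def tiny_cfg():
    return PretrainConfig(learning_rate=3e-4, epochs=2,
                          batch_frame_threshold=120, seed=0)


@pytest.fixture(scope="session")
def bases10():
    return make_base_images(10, source="synthetic", seed=0)
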
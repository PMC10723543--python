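"""Batch assembly, the temporal NT-Xent objective, and pre-training."""

import numpy as np
import pytest

from retwave import (ContrastiveBatch, Encoder, EncoderSpec, PretrainConfig,
                     WaveEvent, WaveMovie, WaveSimParams, assemble_batches,
                     load_encoder, pretrain_encoder, save_encoder,
                     simulate_waves, temporal_ntxent_loss)
from retwave.contrastive import _ntxent_loss_grad


def make_movie(n_frames):
    rng = np.random.default_rng(1)
    return WaveMovie(rng.random((n_frames, 6, 6)).astype(np.float32), 10.0)


def events_of_sizes(sizes):
    out, pos = [], 0
    for s in sizes:
        out.append(WaveEvent(pos, pos + s))
        pos += s
    return out


class TestAssembleBatches:
    def test_threshold_never_exceeded_gives_one_batch(self):
        events = events_of_sizes([5, 4, 3])
        cfg = PretrainConfig(batch_frame_threshold=3000, seed=0)
        batches = assemble_batches(make_movie(12), events, cfg)
        assert len(batches) == 1
        assert batches[0].frames.shape[0] == 12

    def test_batch_closes_on_first_exceedance(self):
        # cumulative sizes 20, 35 (>30): first batch is exactly two events
        events = events_of_sizes([20, 15, 15])
        cfg = PretrainConfig(batch_frame_threshold=30, seed=0)
        batches = assemble_batches(make_movie(50), events, cfg)
        assert batches[0].frames.shape[0] == 35
        assert len(np.unique(batches[0].event_id)) == 2

    def test_anchor_count_matches_event_lengths(self):
        sizes = [7, 5, 4]
        events = events_of_sizes(sizes)
        for gap in (1, 2):
            cfg = PretrainConfig(batch_frame_threshold=1000, pair_gap=gap, seed=0)
            (batch,) = assemble_batches(make_movie(16), events, cfg)
            assert batch.n_anchors == sum(s - gap for s in sizes)

    def test_every_event_appears_exactly_once_per_epoch(self):
        events = events_of_sizes([6, 9, 4, 7, 5])
        cfg = PretrainConfig(batch_frame_threshold=10, seed=3)
        batches = assemble_batches(make_movie(31), events, cfg, epoch=2)
        seen = np.concatenate([b.event_id for b in batches])
        assert sorted(np.unique(seen)) == [0, 1, 2, 3, 4]
        assert len(seen) == 31

    def test_positive_pairs_share_event(self):
        events = events_of_sizes([6, 9, 4])
        cfg = PretrainConfig(batch_frame_threshold=8, seed=1)
        for batch in assemble_batches(make_movie(19), events, cfg):
            anchors = np.flatnonzero(batch.positive_index >= 0)
            partners = batch.positive_index[anchors]
            assert np.all(batch.event_id[anchors] == batch.event_id[partners])
            mask = batch.negative_mask
            assert not mask.diagonal().any()
            assert np.array_equal(mask, mask.T)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            assemble_batches(make_movie(5), [], PretrainConfig())

    def test_deterministic_given_seed_and_epoch(self):
        events = events_of_sizes([6, 9, 4, 7])
        cfg = PretrainConfig(batch_frame_threshold=10, seed=5)
        a = assemble_batches(make_movie(26), events, cfg, epoch=1)
        b = assemble_batches(make_movie(26), events, cfg, epoch=1)
        assert all(np.array_equal(x.frame_index, y.frame_index)
                   for x, y in zip(a, b))


def batch_for_embeddings(event_id, positive_index):
    n = len(event_id)
    return ContrastiveBatch(frames=np.zeros((n, 1, 2, 2), dtype=np.float32),
                            event_id=np.asarray(event_id),
                            positive_index=np.asarray(positive_index),
                            frame_index=np.arange(n))


class TestNTXent:
    def test_no_negatives_gives_zero_loss(self):
        batch = batch_for_embeddings([0, 0], [1, -1])
        emb = np.array([[1.0, 0.0], [0.8, 0.6]])
        assert temporal_ntxent_loss(emb, batch, tau=1.0) == pytest.approx(0.0)

    def test_orthogonal_negative_closed_form(self):
        # anchor == positive, one orthogonal negative, tau=1:
        # -log(e / (e + 1)) ~= 0.31326
        batch = batch_for_embeddings([0, 0, 1], [1, -1, -1])
        emb = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        expected = -np.log(np.e / (np.e + 1.0))
        assert temporal_ntxent_loss(emb, batch, tau=1.0) == pytest.approx(
            expected, rel=1e-6)

    def test_nonnegative_and_rotation_invariant(self):
        rng = np.random.default_rng(0)
        batch = batch_for_embeddings([0, 0, 0, 1, 1, 2], [1, 2, -1, 4, -1, -1])
        emb = rng.standard_normal((6, 5))
        loss = temporal_ntxent_loss(emb, batch, tau=0.5)
        assert loss >= 0.0
        Q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert temporal_ntxent_loss(emb @ Q, batch, tau=0.5) == pytest.approx(
            loss, rel=1e-9)

    def test_same_event_nonpositive_frames_excluded(self):
        # adding a same-event frame far away must not change the loss
        base = batch_for_embeddings([0, 0, 1], [1, -1, -1])
        rng = np.random.default_rng(2)
        emb = rng.standard_normal((3, 4))
        loss_base = temporal_ntxent_loss(emb, base, tau=0.7)
        bigger = batch_for_embeddings([0, 0, 1, 0], [1, -1, -1, -1])
        emb4 = np.vstack([emb, rng.standard_normal(4)])
        assert temporal_ntxent_loss(emb4, bigger, tau=0.7) == pytest.approx(
            loss_base, rel=1e-9)

    def test_degenerate_batch_rejected(self):
        batch = batch_for_embeddings([0, 1], [-1, -1])
        with pytest.raises(ValueError, match="anchor"):
            temporal_ntxent_loss(np.eye(2), batch, tau=1.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        batch = batch_for_embeddings([0, 0, 1, 1, 2], [1, -1, 3, -1, -1])
        emb = rng.standard_normal((5, 4))
        _, grad = _ntxent_loss_grad(emb, batch, tau=0.6)
        eps = 1e-6
        for i, j in [(0, 0), (1, 2), (2, 3), (4, 1), (3, 0)]:
            e1, e2 = emb.copy(), emb.copy()
            e1[i, j] += eps
            e2[i, j] -= eps
            num = (temporal_ntxent_loss(e1, batch, 0.6)
                   - temporal_ntxent_loss(e2, batch, 0.6)) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestPretrain:
    def test_zero_epochs_returns_fresh_initialization(self, tiny_movie,
                                                      tiny_spec):
        movie, events = tiny_movie
        cfg = PretrainConfig(epochs=0, seed=4)
        enc, history = pretrain_encoder(movie, events, tiny_spec, cfg)
        assert history == []
        assert enc.weights_hash() == Encoder(tiny_spec, seed=4).weights_hash()

    def test_training_reduces_loss_in_majority_of_seeds(self):
        # 200 structured frames, 5 epochs, tiny conv: final <= first mean loss
        params = WaveSimParams(height=16, width=16, n_frames=200, seed=11)
        movie = simulate_waves(params)
        from retwave import extract_events
        events = extract_events(movie)
        spec = EncoderSpec(backbone="tiny-conv", input_size=(16, 16, 3),
                           projector_dims=(16, 16, 16), embedding_dim=16,
                           base_channels=4)
        wins = 0
        for seed in range(3):
            cfg = PretrainConfig(learning_rate=3e-4, epochs=5,
                                 batch_frame_threshold=100, seed=seed)
            _, history = pretrain_encoder(movie, events, spec, cfg)
            wins += history[-1] <= history[0]
        assert wins >= 2

    def test_same_seed_gives_identical_weights(self, tiny_movie, tiny_spec,
                                               tiny_cfg):
        movie, events = tiny_movie
        a, _ = pretrain_encoder(movie, events, tiny_spec, tiny_cfg)
        b, _ = pretrain_encoder(movie, events, tiny_spec, tiny_cfg)
        assert a.weights_hash() == b.weights_hash()

    def test_checkpoint_round_trip(self, tiny_spec, tmp_path):
        enc = Encoder(tiny_spec, seed=8)
        save_encoder(enc, tmp_path / "ckpt.npz")
        back = load_encoder(tmp_path / "ckpt.npz")
        assert back.weights_hash() == enc.weights_hash()
        assert back.spec == tiny_spec
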
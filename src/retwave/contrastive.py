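"""Temporal contrastive pre-training of a convolutional encoder on wave movies.

The objective is SimCLR-style NT-Xent with *temporal* positive pairs:
within a wave event, frame t is pulled toward frame t+pair_gap, and pushed
away from all frames outside that event.  Frames of the same event that are
not the positive partner enter neither the numerator nor the denominator.
Batches are whole wave events, sampled without replacement until the frame
count first exceeds a threshold (3000 at full scale).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from . import _nn
from .wave_data import WaveEvent, WaveMovie, validate_events

__all__ = [
    "EncoderSpec",
    "PretrainConfig",
    "ContrastiveBatch",
    "Encoder",
    "assemble_batches",
    "temporal_ntxent_loss",
    "pretrain_encoder",
    "save_encoder",
    "load_encoder",
]

BACKBONES = ("resnet18-like", "tiny-conv")


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class EncoderSpec:
    """Architecture of the encoder: backbone + 3-stage MLP projector.

    ``projector_dims`` defaults to the full-scale 8192x8192x8192 projector;
    tests use 64x64x64.  ``base_channels`` sets the width of the first
    tiny-conv block (doubling per block).
    """

    backbone: str = "resnet18-like"
    input_size: Tuple[int, int, int] = (32, 32, 3)  # H, W, C
    projector_dims: Tuple[int, int, int] = (8192, 8192, 8192)
    embedding_dim: int = 512
    base_channels: int = 16

    def validate(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; one of {BACKBONES}")
        H, W, C = self.input_size
        if C not in (1, 3):
            raise ValueError("input channels must be 1 or 3")
        if H % 16 or W % 16:
            raise ValueError("input height/width must be multiples of 16")
        if len(self.projector_dims) != 3:
            raise ValueError("projector must have exactly 3 linear stages")
        if any(d < 1 for d in self.projector_dims) or self.embedding_dim < 1:
            raise ValueError("projector/embedding dims must be positive")


@dataclass
class PretrainConfig:
    """Optimization settings for the contrastive phase.

    Defaults mirror full scale: Adam, lr 1e-4, 100 epochs, event-batch
    frame threshold 3000.  ``temperature_tau`` is the NT-Xent temperature
    (0.5, the standard SimCLR setting) and ``pair_gap`` the temporal lag of
    the positive partner.
    """

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_frame_threshold: int = 3000
    temperature_tau: float = 0.5
    pair_gap: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_frame_threshold < 1:
            raise ValueError("batch_frame_threshold must be >= 1")
        if self.temperature_tau <= 0:
            raise ValueError("temperature_tau must be positive")
        if self.pair_gap < 1:
            raise ValueError("pair_gap must be >= 1")


@dataclass
class ContrastiveBatch:
    """Frames with the positive-pair map and negative mask implied by events.

    ``positive_index[i]`` is the batch index of frame i's positive partner or
    -1; a frame j is a valid negative for anchor i iff their event ids differ.
    """

    frames: np.ndarray            # B x C x H x W
    event_id: np.ndarray          # B
    positive_index: np.ndarray    # B, -1 sentinel
    frame_index: np.ndarray       # B, original movie frame numbers

    @property
    def negative_mask(self) -> np.ndarray:
        return self.event_id[:, None] != self.event_id[None, :]

    @property
    def n_anchors(self) -> int:
        return int((self.positive_index >= 0).sum())


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

class Encoder:
    """Backbone + 3-layer projector built from an :class:`EncoderSpec`.

    Construction is He fan-in initialization throughout, so an untrained
    instance *is* the random-initialized control network.
    """

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xE0C0]))
        H, W, C = spec.input_size
        self._pieces: List[Tuple[str, _nn.Layer]] = []

        if spec.backbone == "tiny-conv":
            c = spec.base_channels
            chans = [C, c, 2 * c, 4 * c, 8 * c]
            for b in range(1, 5):
                pool = _nn.GlobalAvgPool() if b == 4 else _nn.AvgPool2d()
                block = _nn.Sequential([
                    _nn.Conv2d(chans[b - 1], chans[b], 3, 1, 1, rng),
                    _nn.ReLU(), pool,
                ])
                self._pieces.append((f"block{b}", block))
            self._pieces.append(("embedding",
                                 _nn.Linear(chans[4], spec.embedding_dim, rng)))
        else:  # resnet18-like
            stem = _nn.Sequential([_nn.Conv2d(C, 64, 3, 1, 1, rng), _nn.ReLU()])
            self._pieces.append(("stem", stem))
            in_ch, i = 64, 0
            for stage, ch in enumerate([64, 128, 256, 512]):
                for j in range(2):
                    stride = 2 if (stage > 0 and j == 0) else 1
                    i += 1
                    self._pieces.append(
                        (f"block{i}", _nn.ResidualBlock(in_ch, ch, stride, rng)))
                    in_ch = ch
            self._pieces.append(("pool", _nn.GlobalAvgPool()))
            if spec.embedding_dim != 512:
                self._pieces.append(
                    ("embedding", _nn.Linear(512, spec.embedding_dim, rng)))

        dims = [spec.embedding_dim] + list(spec.projector_dims)
        proj_layers: List[_nn.Layer] = []
        for a, b in zip(dims[:-1], dims[1:]):
            proj_layers += [_nn.Linear(a, b, rng), _nn.ReLU()]
        proj_layers.pop()  # no ReLU after the last stage
        self.projector = _nn.Sequential(proj_layers)
        self.backbone = _nn.Sequential([p for _, p in self._pieces])

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> List[_nn.Param]:
        return self.backbone.params() + self.projector.params()

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"param_{i}": p.value.copy()
                for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match architecture")
        for i, p in enumerate(params):
            p.value[...] = state[f"param_{i}"]

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.value).tobytes())
        return h.hexdigest()

    # -- forward passes -----------------------------------------------------

    def embed(self, images: np.ndarray, chunk: int = 512) -> np.ndarray:
        """Backbone features (projector removed), chunked inference."""
        outs = [self.backbone.forward(images[i:i + chunk], train=False)
                for i in range(0, images.shape[0], chunk)]
        return np.concatenate(outs, axis=0)

    def forward_train(self, frames: np.ndarray) -> np.ndarray:
        h = self.backbone.forward(frames, train=True)
        return self.projector.forward(h, train=True)

    def backward(self, grad_out: np.ndarray) -> None:
        self.backbone.backward(self.projector.backward(grad_out))

    def piece_activations(self, images: np.ndarray, chunk: int = 512):
        """Ordered {piece_name: flattened activations} for geometry analyses."""
        names = [n for n, _ in self._pieces if n != "pool"]
        rows: Dict[str, List[np.ndarray]] = {n: [] for n in names}
        for i in range(0, images.shape[0], chunk):
            x = images[i:i + chunk]
            for name, piece in self._pieces:
                x = piece.forward(x, train=False)
                if name != "pool":
                    rows[name].append(x.reshape(x.shape[0], -1).copy())
        return {n: np.concatenate(rows[n], axis=0) for n in names}


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------

def assemble_batches(movie: WaveMovie, events: Sequence[WaveEvent],
                     cfg: PretrainConfig, epoch: int = 0,
                     frames_override: Optional[np.ndarray] = None,
                     ) -> List[ContrastiveBatch]:
    """Group whole wave events into batches for one epoch.

    Events are permuted (deterministically from ``cfg.seed`` and ``epoch``)
    and accumulated until the cumulative frame count first exceeds
    ``cfg.batch_frame_threshold``; leftovers form a final smaller batch, so
    every event appears exactly once per epoch.  ``frames_override`` lets the
    caller substitute preprocessed (resized / channel-replicated) frames
    indexed like the movie.
    """
    cfg.validate()
    validate_events(events, movie.n_frames)
    if len(events) == 0:
        raise ValueError("cannot assemble batches from zero events")

    src = frames_override if frames_override is not None else movie.frames
    if src.ndim == 3:
        src = src[:, None]  # add channel axis

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch, 0xBA7C]))
    order = rng.permutation(len(events))

    batches: List[ContrastiveBatch] = []
    group: List[int] = []
    count = 0

    def close(group_ids: List[int]) -> None:
        frame_idx, event_id, pos = [], [], []
        offset = 0
        for eid in group_ids:
            ev = events[eid]
            L = len(ev)
            frame_idx.append(ev.frame_indices())
            event_id.append(np.full(L, eid))
            p = np.arange(L) + cfg.pair_gap
            p = np.where(p < L, p + offset, -1)
            pos.append(p)
            offset += L
        fi = np.concatenate(frame_idx)
        batches.append(ContrastiveBatch(
            frames=np.ascontiguousarray(src[fi]),
            event_id=np.concatenate(event_id),
            positive_index=np.concatenate(pos),
            frame_index=fi,
        ))

    for eid in order:
        group.append(int(eid))
        count += len(events[eid])
        if count > cfg.batch_frame_threshold:
            close(group)
            group, count = [], 0
    if group:
        close(group)
    return batches


# ---------------------------------------------------------------------------
# NT-Xent with temporal positives
# ---------------------------------------------------------------------------

def _ntxent_loss_grad(embeddings: np.ndarray, batch: ContrastiveBatch,
                      tau: float, want_grad: bool = True):
    if tau <= 0:
        raise ValueError("tau must be positive")
    if embeddings.shape[0] != batch.frames.shape[0]:
        raise ValueError("embeddings are not row-aligned with the batch")
    pos = batch.positive_index
    anchors = np.flatnonzero(pos >= 0)
    if anchors.size == 0:
        raise ValueError("degenerate batch: no anchor has a positive partner")

    e = embeddings.astype(np.float64)
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    z = e / norms
    S = (z @ z.T) / tau

    B = e.shape[0]
    denom_mask = batch.negative_mask.copy()
    denom_mask[anchors, pos[anchors]] = True  # positive joins its denominator

    A = anchors.size
    S_masked = np.where(denom_mask, S, -np.inf)
    Sa = S_masked[anchors]
    mx = Sa.max(axis=1)
    ez = np.exp(Sa - mx[:, None])
    sez = ez.sum(axis=1)
    lse = mx + np.log(sez)
    pos_sims = S[anchors, pos[anchors]]
    loss = float(np.mean(lse - pos_sims))
    if not want_grad:
        return loss, None

    dS = np.zeros((B, B))
    dS[anchors] = ez / sez[:, None] / A
    dS[anchors, pos[anchors]] -= 1.0 / A
    G = (dS @ z + dS.T @ z) / tau
    grad = (G - z * np.sum(G * z, axis=1, keepdims=True)) / norms
    return loss, grad.astype(np.float32)


def temporal_ntxent_loss(embeddings: np.ndarray, batch: ContrastiveBatch,
                         tau: float = 0.5) -> float:
    """NT-Xent loss with temporal positives; cosine similarities at
    temperature ``tau``; mean over anchors that have a positive partner."""
    loss, _ = _ntxent_loss_grad(embeddings, batch, tau, want_grad=False)
    return loss


# ---------------------------------------------------------------------------
# Pre-training
# ---------------------------------------------------------------------------

def prepare_frames(movie: WaveMovie, spec: EncoderSpec) -> np.ndarray:
    """Min-max normalize the movie, bilinearly resize to the encoder input,
    and replicate grayscale to the required channel count."""
    H, W, C = spec.input_size
    frames = movie.frames.astype(np.float32)
    lo, hi = float(frames.min()), float(frames.max())
    frames = (frames - lo) / max(hi - lo, 1e-12)
    if frames.shape[1:] != (H, W):
        zoom = (1.0, H / frames.shape[1], W / frames.shape[2])
        frames = ndimage.zoom(frames, zoom, order=1).astype(np.float32)
        frames = frames[:, :H, :W]
    out = np.repeat(frames[:, None], C, axis=1)
    return np.ascontiguousarray(out)


def pretrain_encoder(movie: WaveMovie, events: Sequence[WaveEvent],
                     spec: EncoderSpec, cfg: PretrainConfig,
                     ) -> Tuple[Encoder, List[float]]:
    """Train backbone + projector with the temporal contrastive objective.

    Returns the encoder and the per-epoch mean loss curve.  ``epochs=0``
    returns a freshly He-initialized encoder (the random control).
    Reproducible given ``cfg.seed``.
    """
    cfg.validate()
    encoder = Encoder(spec, seed=cfg.seed)
    history: List[float] = []
    if cfg.epochs == 0:
        return encoder, history

    if len(events) < 2:
        raise ValueError("need at least 2 events to pre-train")
    frames = prepare_frames(movie, spec)
    opt = _nn.Adam(encoder.parameters(), lr=cfg.learning_rate)

    for epoch in range(cfg.epochs):
        losses = []
        for batch in assemble_batches(movie, events, cfg, epoch=epoch,
                                      frames_override=frames):
            if batch.n_anchors == 0:
                continue
            emb = encoder.forward_train(batch.frames)
            loss, grad = _ntxent_loss_grad(emb, batch, cfg.temperature_tau)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(batch of {batch.frames.shape[0]} frames); "
                    "lower the learning rate or temperature")
            opt.zero_grad()
            encoder.backward(grad)
            opt.step()
            losses.append(loss)
        if not losses:
            raise ValueError("no batch produced an anchor; events too short "
                             f"for pair_gap={cfg.pair_gap}")
        history.append(float(np.mean(losses)))
    return encoder, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _spec_blob(spec: EncoderSpec, seed: int) -> str:
    d = asdict(spec)
    d["seed"] = seed
    return json.dumps(d, sort_keys=True)


def save_encoder(encoder: Encoder, path) -> None:
    blob = _spec_blob(encoder.spec, encoder.seed)
    cfg_hash = hashlib.sha256(blob.encode()).hexdigest()
    np.savez_compressed(Path(path), __config__=np.frombuffer(
        blob.encode(), dtype=np.uint8), __config_hash__=np.frombuffer(
        cfg_hash.encode(), dtype=np.uint8), **encoder.state_dict())


def load_encoder(path) -> Encoder:
    with np.load(Path(path)) as z:
        blob = bytes(z["__config__"]).decode()
        d = json.loads(blob)
        seed = d.pop("seed")
        d["input_size"] = tuple(d["input_size"])
        d["projector_dims"] = tuple(d["projector_dims"])
        spec = EncoderSpec(**d)
        enc = Encoder(spec, seed=seed)
        enc.load_state_dict({k: z[k] for k in z.files
                             if not k.startswith("__")})
    return enc
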
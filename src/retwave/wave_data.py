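"""Synthetic retinal-wave movies, event segmentation, and shuffle controls.

Developing retinas fire in spatially contiguous, propagating bursts of
activity ("retinal waves") separated by quiet periods.  This module provides

* an excitable-medium cellular automaton that emits calcium-imaging-like
  grayscale movies with that statistical structure,
* segmentation of a movie into *wave events* (maximal runs of active frames),
* the three shuffle controls (spatial, temporal, spatiotemporal) used to
  dissect which statistics of the waves matter for downstream learning,
* TIFF / NPZ movie I/O with a JSON metadata sidecar and CSV event lists.

Frames are indexed 0-based and events are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import tifffile

__all__ = [
    "WaveMovie",
    "WaveEvent",
    "WaveSimParams",
    "ShuffleKind",
    "simulate_waves",
    "extract_events",
    "shuffle_movie",
    "save_movie",
    "load_movie",
    "save_events",
    "load_events",
]

#: Per-cell, per-frame spontaneous initiation probability at strength_alpha=1.
INIT_RATE_AT_UNIT_ALPHA = 1e-4

SHUFFLE_KINDS = ("none", "spatial", "temporal", "spatiotemporal")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class WaveMovie:
    """A grayscale frame stack with acquisition metadata.

    ``frames`` has shape (T, H, W) with intensities in [0, 1].
    """

    frames: np.ndarray
    frame_rate_hz: float
    source_tag: str = "simulated"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a T x H x W stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1 or min(self.frames.shape[1:]) < 1:
            raise ValueError("movie must have T >= 1 and H, W >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(
                f"frame intensities must lie in [0, 1]; observed [{lo:.4g}, {hi:.4g}]"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


@dataclass(frozen=True, order=True)
class WaveEvent:
    """Half-open frame range [start_frame, end_frame) of continuous activity."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(
                f"invalid event range [{self.start_frame}, {self.end_frame})"
            )

    def __len__(self) -> int:
        return self.end_frame - self.start_frame

    def frame_indices(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame)


@dataclass
class WaveSimParams:
    """Parameters of the excitable-medium wave simulator.

    ``strength_alpha`` scales the per-cell spontaneous initiation rate (the
    wave-frequency knob; 0.5 is the default operating point, which keeps
    waves frequent without long silent stretches).  Each cell cycles
    quiescent -> active (``active_duration_frames``) -> refractory
    (``refractory_mean_frames`` +/- jitter) -> quiescent, and active cells
    recruit quiescent 4-neighbours with ``recruit_prob`` per frame.  Rendered
    intensity is a leaky calcium trace of the active state
    (``calcium_decay_per_frame``) plus clipped Gaussian noise.
    """

    height: int = 32
    width: int = 32
    n_frames: int = 3000
    strength_alpha: float = 0.5
    recruit_prob: float = 0.35
    active_duration_frames: int = 3
    refractory_mean_frames: int = 40
    refractory_jitter_frames: int = 10
    calcium_decay_per_frame: float = 0.85
    noise_sd: float = 0.02
    frame_rate_hz: float = 11.7
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.strength_alpha < 0:
            raise ValueError("strength_alpha must be >= 0")
        if not 0.0 <= self.recruit_prob <= 1.0:
            raise ValueError("recruit_prob must lie in [0, 1]")
        if self.active_duration_frames < 1:
            raise ValueError("active_duration_frames must be >= 1")
        if self.refractory_mean_frames < 1:
            raise ValueError("refractory_mean_frames must be >= 1")
        if self.refractory_jitter_frames < 0:
            raise ValueError("refractory_jitter_frames must be >= 0")
        if not 0.0 <= self.calcium_decay_per_frame < 1.0:
            raise ValueError("calcium_decay_per_frame must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")


@dataclass(frozen=True)
class ShuffleKind:
    """Which structure of the movie to destroy: none / spatial / temporal / both."""

    kind: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SHUFFLE_KINDS:
            raise ValueError(
                f"unknown shuffle kind {self.kind!r}; expected one of {SHUFFLE_KINDS}"
            )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _simulate_states(params: WaveSimParams):
    """Run the cellular automaton; return (active_history, init_history).

    ``active_history`` is a (T, H, W) boolean stack of the active state and
    ``init_history`` marks cells that initiated spontaneously on each frame.
    Exposed for tests that assert wave contiguity on the internal state.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W, T = params.height, params.width, params.n_frames
    p_init = min(1.0, INIT_RATE_AT_UNIT_ALPHA * params.strength_alpha)

    # state encoding: 0 quiescent; >0 active frames remaining; <0 refractory
    state = np.zeros((H, W), dtype=np.int32)
    active_hist = np.zeros((T, H, W), dtype=bool)
    init_hist = np.zeros((T, H, W), dtype=bool)

    for t in range(T):
        active = state > 0
        quiescent = state == 0

        # recruitment by active 4-neighbours
        n_active_nb = np.zeros((H, W), dtype=np.int32)
        n_active_nb[1:, :] += active[:-1, :]
        n_active_nb[:-1, :] += active[1:, :]
        n_active_nb[:, 1:] += active[:, :-1]
        n_active_nb[:, :-1] += active[:, 1:]
        p_recruit = 1.0 - (1.0 - params.recruit_prob) ** n_active_nb
        recruited = quiescent & (rng.random((H, W)) < p_recruit)

        # spontaneous initiation of fresh waves
        spont = quiescent & ~recruited & (rng.random((H, W)) < p_init)

        # advance clocks
        expiring = state == 1
        state[active] -= 1
        refr_len = np.rint(
            rng.normal(params.refractory_mean_frames,
                       params.refractory_jitter_frames, size=(H, W))
        ).astype(np.int32)
        refr_len = np.maximum(refr_len, 1)
        state[expiring] = -refr_len[expiring]
        state[state < 0] += 1
        newly = recruited | spont
        state[newly] = params.active_duration_frames

        active_hist[t] = state > 0
        init_hist[t] = spont

    return active_hist, init_hist


def simulate_waves(params: WaveSimParams) -> WaveMovie:
    """Simulate a retinal-wave movie from the excitable-medium model.

    Deterministic given ``params`` (including ``params.seed``).
    """
    active_hist, _ = _simulate_states(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    decay = params.calcium_decay_per_frame
    T = params.n_frames
    frames = np.zeros(active_hist.shape, dtype=np.float32)
    trace = np.zeros(active_hist.shape[1:], dtype=np.float32)
    for t in range(T):
        trace *= decay
        trace[active_hist[t]] = 1.0
        frames[t] = trace
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, size=frames.shape).astype(np.float32)
    np.clip(frames, 0.0, 1.0, out=frames)
    return WaveMovie(frames=frames, frame_rate_hz=params.frame_rate_hz,
                     source_tag="simulated", seed=params.seed)


# ---------------------------------------------------------------------------
# Event segmentation
# ---------------------------------------------------------------------------

def extract_events(movie: WaveMovie, activity_threshold: float = 0.5,
                   min_event_frames: int = 2) -> List[WaveEvent]:
    """Segment a movie into maximal runs of active frames.

    A frame is active iff any pixel exceeds ``activity_threshold``; maximal
    runs of at least ``min_event_frames`` active frames become events.
    """
    if not 0.0 <= activity_threshold <= 1.0:
        raise ValueError("activity_threshold must lie in [0, 1]")
    if min_event_frames < 1:
        raise ValueError("min_event_frames must be >= 1")
    if movie.n_frames == 0:
        raise ValueError("cannot extract events from an empty movie")

    active = (movie.frames > activity_threshold).any(axis=(1, 2))
    padded = np.concatenate([[False], active, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [WaveEvent(int(s), int(e)) for s, e in zip(starts, ends)
            if e - s >= min_event_frames]


def validate_events(events: Sequence[WaveEvent], n_frames: int) -> None:
    """Check that events are in range, sorted, and pairwise disjoint."""
    prev_end = 0
    for ev in events:
        if ev.start_frame < prev_end:
            raise ValueError(f"events overlap or are unsorted at {ev}")
        if ev.end_frame > n_frames:
            raise ValueError(f"event {ev} exceeds movie length {n_frames}")
        prev_end = ev.end_frame


# ---------------------------------------------------------------------------
# Shuffle controls
# ---------------------------------------------------------------------------

def _subseeds(seed: int) -> Tuple[np.random.SeedSequence, np.random.SeedSequence]:
    """Temporal and spatial child seeds; the spatiotemporal shuffle composes
    the two single shuffles with exactly these sub-seeds."""
    temporal_ss, spatial_ss = np.random.SeedSequence(seed).spawn(2)
    return temporal_ss, spatial_ss


def _spatial_shuffle(frames: np.ndarray, ss: np.random.SeedSequence) -> np.ndarray:
    rng = np.random.default_rng(ss)
    T, H, W = frames.shape
    flat = frames.reshape(T, H * W)
    out = np.empty_like(flat)
    for t in range(T):
        out[t] = flat[t, rng.permutation(H * W)]
    return out.reshape(T, H, W)


def _temporal_shuffle(frames: np.ndarray, ss: np.random.SeedSequence) -> np.ndarray:
    rng = np.random.default_rng(ss)
    return frames[rng.permutation(frames.shape[0])]


def shuffle_movie(movie: WaveMovie, events: Sequence[WaveEvent],
                  shuffle: ShuffleKind) -> Tuple[WaveMovie, List[WaveEvent]]:
    """Produce a shuffled control movie and the event list to use with it.

    * ``spatial`` — an independent pixel permutation per frame (keeps each
      frame's intensity histogram, destroys spatial contiguity).
    * ``temporal`` — one random permutation of frame order over the whole
      movie; the original event index-ranges are retained so that batch
      assembly still samples "events" of temporally scrambled content.
    * ``spatiotemporal`` — temporal then spatial, with sub-seeds derived
      from ``shuffle.seed``; equals the composition of the two singles.
    * ``none`` — identity.
    """
    validate_events(events, movie.n_frames)
    temporal_ss, spatial_ss = _subseeds(shuffle.seed)

    frames = movie.frames
    if shuffle.kind == "none":
        return movie, list(events)
    if shuffle.kind in ("temporal", "spatiotemporal"):
        frames = _temporal_shuffle(frames, temporal_ss)
    if shuffle.kind in ("spatial", "spatiotemporal"):
        frames = _spatial_shuffle(frames, spatial_ss)

    out = WaveMovie(frames=frames, frame_rate_hz=movie.frame_rate_hz,
                    source_tag=f"shuffled-{shuffle.kind}", seed=shuffle.seed)
    return out, list(events)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_movie(movie: WaveMovie, path) -> None:
    """Write a movie as a grayscale TIFF stack or ``.npz`` archive plus a
    JSON metadata sidecar (frame rate, source tag, seed)."""
    path = Path(path)
    meta = {"frame_rate_hz": movie.frame_rate_hz,
            "source_tag": movie.source_tag,
            "seed": movie.seed}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.frames, photometric="minisblack")
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, frames=movie.frames)
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r} (use .tif or .npz)")
    _sidecar_path(path).write_text(json.dumps(meta))


def load_movie(path, rescale: bool = True) -> WaveMovie:
    """Load a grayscale movie saved by :func:`save_movie`.

    Integer stacks are divided by their dtype maximum; float stacks outside
    [0, 1] are min-max rescaled when ``rescale`` is true, otherwise rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix.lower() == ".npz":
        with np.load(path) as z:
            frames = z["frames"]
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"expected a grayscale T x H x W stack, got shape {frames.shape}; "
            "multi-channel stacks are not supported"
        )
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32) / np.iinfo(frames.dtype).max
    else:
        frames = frames.astype(np.float32)
        lo, hi = float(frames.min()), float(frames.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            if not rescale:
                raise ValueError(
                    f"intensities outside [0, 1] (range [{lo:.4g}, {hi:.4g}]) "
                    "and rescaling is disabled"
                )
            frames = (frames - lo) / max(hi - lo, 1e-12)

    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return WaveMovie(frames=frames,
                     frame_rate_hz=float(meta.get("frame_rate_hz", 1.0)),
                     source_tag=str(meta.get("source_tag", "real")),
                     seed=meta.get("seed"))


def save_events(events: Sequence[WaveEvent], path) -> None:
    lines = ["start_frame,end_frame"]
    lines += [f"{ev.start_frame},{ev.end_frame}" for ev in events]
    Path(path).write_text("\n".join(lines) + "\n")


def load_events(path) -> List[WaveEvent]:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0] != "start_frame,end_frame":
        raise ValueError(f"{path}: not an event CSV (missing header)")
    out = []
    for ln in lines[1:]:
        s, e = ln.split(",")
        out.append(WaveEvent(int(s), int(e)))
    return out
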
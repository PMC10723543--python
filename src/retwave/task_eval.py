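"""Labeled task datasets and frozen-encoder linear readout evaluation.

Three tasks probe what pre-training put into the encoder:

* **classification** — 10-way image classification (CIFAR-10 when a local
  copy is supplied, else a synthetic 10-class shape/color stand-in),
* **translation** — classify integer spatial translations (up to 16 px in x
  and y, zero-filled) of 10 base images back to their base,
* **color** — classify color-jittered versions (50–100% changes in
  brightness, contrast, saturation, hue) of the same 10 base images.

Each base yields 5000 training and 1000 test images at full scale.  The
readout is a single linear layer on frozen backbone features trained with
Adam and cross-entropy.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy import ndimage

from . import _nn
from .contrastive import Encoder

__all__ = [
    "TaskDataset",
    "ReadoutResult",
    "make_base_images",
    "gen_translation_dataset",
    "gen_color_dataset",
    "gen_classification_dataset",
    "train_linear_readout",
    "fit_linear_readout",
    "aggregate_readouts",
]

LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float32)


@dataclass
class TaskDataset:
    task: str
    train_images: np.ndarray   # n x 32 x 32 x 3 in [0, 1]
    train_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    base_images: Optional[np.ndarray] = None
    gen_params: Dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return int(self.train_labels.max()) + 1


@dataclass
class ReadoutResult:
    task: str
    seed: int
    test_accuracy: float
    train_accuracy: float
    per_class_accuracy: np.ndarray


# ---------------------------------------------------------------------------
# Base images
# ---------------------------------------------------------------------------

def _synthetic_base(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """One 32x32 RGB image: textured background plus 1-3 colored shapes."""
    img = ndimage.gaussian_filter(
        rng.random((size, size, 3)).astype(np.float32), sigma=(4, 4, 0))
    img = (img - img.min()) / max(img.max() - img.min(), 1e-9) * 0.5
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(1, 4)):
        kind = rng.integers(0, 3)
        cx, cy = rng.uniform(6, size - 6, size=2)
        r = rng.uniform(3, 8)
        color = rng.uniform(0.3, 1.0, size=3).astype(np.float32)
        if kind == 0:       # disk
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        elif kind == 1:     # square
            mask = (np.abs(xx - cx) <= r) & (np.abs(yy - cy) <= r)
        else:               # triangle
            mask = ((np.abs(xx - cx) <= (yy - cy + r) / 2)
                    & (yy >= cy - r) & (yy <= cy + r))
        img[mask] = color
    return np.clip(img, 0.0, 1.0)


def _load_cifar(cifar_dir: Path, n: int, rng: np.random.Generator) -> np.ndarray:
    train_file = Path(cifar_dir) / "train"
    if not train_file.exists():
        raise FileNotFoundError(
            f"CIFAR archive not found under {cifar_dir}; "
            "use source='synthetic' for a download-free base-image set")
    with open(train_file, "rb") as fh:
        d = pickle.load(fh, encoding="bytes")
    data = d[b"data"].reshape(-1, 3, 32, 32).transpose(0, 2, 3, 1) / 255.0
    labels = np.asarray(d.get(b"fine_labels", d.get(b"labels")))
    classes = rng.choice(np.unique(labels), size=n, replace=False)
    picks = [rng.choice(np.flatnonzero(labels == c)) for c in classes]
    return data[picks].astype(np.float32)


def make_base_images(n: int, source: str = "synthetic", seed: int = 0,
                     cifar_dir: Optional[str] = None) -> np.ndarray:
    """Draw ``n`` base images, one per class.

    ``synthetic`` renders distinct shape/texture images; ``cifar100`` draws
    one random image from each of ``n`` random classes of a local CIFAR-100
    python archive (``cifar_dir``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    if source == "synthetic":
        bases = np.stack([_synthetic_base(rng) for _ in range(n)])
    elif source == "cifar100":
        if cifar_dir is None:
            raise FileNotFoundError(
                "cifar100 source requires cifar_dir; "
                "use source='synthetic' for a download-free base-image set")
        bases = _load_cifar(Path(cifar_dir), n, rng)
    else:
        raise ValueError(f"unknown source {source!r}")
    flat = bases.reshape(n, -1)
    if n > 1 and (np.linalg.norm(flat[:, None] - flat[None], axis=2)
                  + np.eye(n)).min() == 0:
        raise RuntimeError("base images are not pairwise distinct")
    return bases


# ---------------------------------------------------------------------------
# Dataset generators
# ---------------------------------------------------------------------------

def _translate(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift by (dx, dy) pixels with zero fill (dx: columns, dy: rows)."""
    H, W = img.shape[:2]
    out = np.zeros_like(img)
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    ys_src = slice(max(-dy, 0), H + min(-dy, 0))
    xs_src = slice(max(-dx, 0), W + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def _translation_split(bases, max_shift, n_per_base, rng):
    n_bases = bases.shape[0]
    n = n_bases * n_per_base
    images = np.empty((n,) + bases.shape[1:], dtype=np.float32)
    labels = np.repeat(np.arange(n_bases), n_per_base)
    shifts = rng.integers(-max_shift, max_shift + 1, size=(n, 2))
    for b in range(n_bases):
        idx = np.flatnonzero(labels == b)
        cache: Dict[Tuple[int, int], np.ndarray] = {}
        for i in idx:
            key = (int(shifts[i, 0]), int(shifts[i, 1]))
            if key not in cache:
                cache[key] = _translate(bases[b], *key)
            images[i] = cache[key]
    return images, labels, shifts


def gen_translation_dataset(bases: np.ndarray, max_shift_px: int = 16,
                            n_train_per_base: int = 5000,
                            n_test_per_base: int = 1000,
                            seed: int = 0) -> TaskDataset:
    """Integer translations up to ``max_shift_px`` in x and y, zero-filled."""
    bases = np.asarray(bases, dtype=np.float32)
    if bases.ndim != 4 or bases.shape[3] != 3:
        raise ValueError("bases must be n x H x W x 3")
    if max_shift_px < 0 or max_shift_px >= bases.shape[2]:
        raise ValueError("max_shift_px must lie in [0, image width)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A5]))
    tr_img, tr_lab, tr_shifts = _translation_split(
        bases, max_shift_px, n_train_per_base, rng)
    te_img, te_lab, te_shifts = _translation_split(
        bases, max_shift_px, n_test_per_base, rng)
    return TaskDataset("translation", tr_img, tr_lab, te_img, te_lab, bases,
                       {"max_shift_px": max_shift_px, "seed": seed,
                        "n_train_per_base": n_train_per_base,
                        "n_test_per_base": n_test_per_base})


def color_jitter(images: np.ndarray, factors: np.ndarray,
                 hue_shift: np.ndarray) -> np.ndarray:
    """Apply brightness, contrast, saturation factors then a hue rotation.

    ``factors`` is (n, 3) of multiplicative factors; ``hue_shift`` (n,) in
    hue-wheel units (0.5 = half turn).  Values are clipped to [0, 1].
    """
    x = images.astype(np.float32).copy()
    fb, fc, fs = (factors[:, i][:, None, None, None] for i in range(3))
    x = np.clip(x * fb, 0, 1)
    mean = x.mean(axis=(1, 2, 3), keepdims=True)
    x = np.clip((x - mean) * fc + mean, 0, 1)
    gray = (x @ LUMA)[..., None]
    x = np.clip(gray + fs * (x - gray), 0, 1)
    hsv = rgb_to_hsv(x)
    hsv[..., 0] = (hsv[..., 0] + hue_shift[:, None, None]) % 1.0
    return np.clip(hsv_to_rgb(hsv), 0, 1).astype(np.float32)


def _color_split(bases, lo, hi, n_per_base, rng):
    n_bases = bases.shape[0]
    n = n_bases * n_per_base
    labels = np.repeat(np.arange(n_bases), n_per_base)
    images = np.empty((n,) + bases.shape[1:], dtype=np.float32)
    mag = rng.uniform(lo, hi, size=(n, 4))
    sign = rng.choice([-1.0, 1.0], size=(n, 4))
    factors = np.maximum(1.0 + sign[:, :3] * mag[:, :3], 0.0)
    hue = sign[:, 3] * mag[:, 3] * 0.5
    chunk = 4096
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        images[s:e] = color_jitter(bases[labels[s:e]], factors[s:e], hue[s:e])
    return images, labels


def gen_color_dataset(bases: np.ndarray, jitter_lo: float = 0.5,
                      jitter_hi: float = 1.0, n_train_per_base: int = 5000,
                      n_test_per_base: int = 1000, seed: int = 0) -> TaskDataset:
    """Random recolorations: each of brightness, contrast, saturation, hue is
    changed by a magnitude drawn from [jitter_lo, jitter_hi] (random sign),
    applied in that fixed order."""
    bases = np.asarray(bases, dtype=np.float32)
    if not 0 <= jitter_lo <= jitter_hi:
        raise ValueError("need 0 <= jitter_lo <= jitter_hi")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0103]))
    tr_img, tr_lab = _color_split(bases, jitter_lo, jitter_hi,
                                  n_train_per_base, rng)
    te_img, te_lab = _color_split(bases, jitter_lo, jitter_hi,
                                  n_test_per_base, rng)
    return TaskDataset("color", tr_img, tr_lab, te_img, te_lab, bases,
                       {"jitter_lo": jitter_lo, "jitter_hi": jitter_hi,
                        "order": ["brightness", "contrast", "saturation", "hue"],
                        "hue_unit": "fraction of half-turn", "seed": seed,
                        "n_train_per_base": n_train_per_base,
                        "n_test_per_base": n_test_per_base})


def gen_classification_dataset(n_classes: int = 10, n_train_per_class: int = 5000,
                               n_test_per_class: int = 1000, seed: int = 0,
                               source: str = "synthetic",
                               cifar_dir: Optional[str] = None) -> TaskDataset:
    """10-way classification.  With ``source='synthetic'`` each class is a
    base shape/texture image plus mild translation (2 px) and color jitter
    (up to 30%) — a stand-in for CIFAR-10 when no local archive exists."""
    if source == "cifar10":
        raise NotImplementedError(
            "supply CIFAR-10 through gen_params/cifar_dir plumbing or use "
            "source='synthetic'")
    bases = make_base_images(n_classes, source="synthetic", seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A55]))

    def split(n_per):
        img, lab, _ = _translation_split(bases, 2, n_per, rng)
        n = img.shape[0]
        mag = rng.uniform(0.0, 0.3, size=(n, 4))
        sign = rng.choice([-1.0, 1.0], size=(n, 4))
        fac = np.maximum(1.0 + sign[:, :3] * mag[:, :3], 0.0)
        return color_jitter(img, fac, sign[:, 3] * mag[:, 3] * 0.5), lab

    tr_img, tr_lab = split(n_train_per_class)
    te_img, te_lab = split(n_test_per_class)
    return TaskDataset("classification", tr_img, tr_lab, te_img, te_lab, bases,
                       {"source": "synthetic-standin", "seed": seed})


# ---------------------------------------------------------------------------
# Linear readout
# ---------------------------------------------------------------------------

def fit_linear_readout(train_X: np.ndarray, train_y: np.ndarray,
                       test_X: np.ndarray, test_y: np.ndarray,
                       n_classes: int, lr: float = 1e-4, epochs: int = 100,
                       batch_size: int = 100, seed: int = 0,
                       task: str = "features") -> ReadoutResult:
    """Train a single linear layer with Adam + cross-entropy on fixed features."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x8EAD]))
    layer = _nn.Linear(train_X.shape[1], n_classes, rng)
    opt = _nn.Adam(layer.params(), lr=lr)
    n = train_X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            logits = layer.forward(train_X[idx], train=True)
            _, gl = _nn.softmax_xent(logits, train_y[idx])
            opt.zero_grad()
            layer.backward(gl)
            opt.step()

    def acc(X, y):
        pred = layer.forward(X, train=False).argmax(axis=1)
        return pred, float((pred == y).mean())

    tr_pred, tr_acc = acc(train_X, train_y)
    te_pred, te_acc = acc(test_X, test_y)
    per_class = np.array([float((te_pred[test_y == c] == c).mean())
                          if (test_y == c).any() else np.nan
                          for c in range(n_classes)])
    return ReadoutResult(task, seed, te_acc, tr_acc, per_class)


def encode_images(encoder: Encoder, images: np.ndarray) -> np.ndarray:
    """HWC image batch -> frozen backbone features."""
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2).astype(np.float32))
    return encoder.embed(x)


def train_linear_readout(encoder: Encoder, dataset: TaskDataset,
                         lr: float = 1e-4, epochs: int = 100,
                         batch_size: int = 100, seed: int = 0) -> ReadoutResult:
    """Frozen-encoder linear evaluation: embed with the backbone (projector
    removed), then fit an embedding_dim x n_classes readout."""
    H, W, C = encoder.spec.input_size
    if dataset.train_images.shape[1:] != (H, W, C):
        raise ValueError(
            f"dataset images {dataset.train_images.shape[1:]} do not match "
            f"encoder input {(H, W, C)}")
    before = encoder.weights_hash()
    ftr_train = encode_images(encoder, dataset.train_images)
    ftr_test = encode_images(encoder, dataset.test_images)
    res = fit_linear_readout(ftr_train, dataset.train_labels, ftr_test,
                             dataset.test_labels, dataset.n_classes,
                             lr=lr, epochs=epochs, batch_size=batch_size,
                             seed=seed, task=dataset.task)
    assert encoder.weights_hash() == before, "encoder was mutated during readout"
    return res


def aggregate_readouts(results: Sequence[ReadoutResult]) -> Dict[str, float]:
    accs = np.array([r.test_accuracy for r in results])
    return {"mean_test_accuracy": float(accs.mean()),
            "sd_test_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            "seeds": [r.seed for r in results]}
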
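"""End-to-end orchestration of the nine experimental conditions.

A *condition* is a pre-training dataset choice — {real, simulated} source x
{unshuffled, spatial, temporal, spatiotemporal} shuffle — or the
He-random-initialized control, for nine in total.  ``run_condition``
executes wave preparation -> (optional) contrastive pre-training -> linear
readout on the three tasks -> layerwise geometry, for each network seed,
and writes accuracy/geometry CSVs.  ``compare_conditions`` assembles the
cross-condition report and evaluates the directional checks (does
unshuffled-wave pre-training beat random init on translation accuracy and
capacity; do temporally shuffled conditions blow up participation ratio).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .contrastive import (Encoder, EncoderSpec, PretrainConfig,
                          pretrain_encoder, save_encoder)
from .geometry import (build_classification_manifolds,
                       build_color_manifolds, build_translation_manifolds,
                       layer_geometry_summary)
from .task_eval import (TaskDataset, gen_classification_dataset,
                        gen_color_dataset, gen_translation_dataset,
                        make_base_images, train_linear_readout)
from .wave_data import (ShuffleKind, WaveSimParams, extract_events,
                        load_movie, shuffle_movie, simulate_waves)

__all__ = ["Condition", "ExperimentConfig", "all_conditions",
           "run_condition", "compare_conditions"]

logger = logging.getLogger("retwave")

SHUFFLE_NAMES = {"none": "unshuffled", "spatial": "spatial",
                 "temporal": "temporal", "spatiotemporal": "spatiotemporal"}
TASKS = ("classification", "translation", "color")


@dataclass(frozen=True)
class Condition:
    source: str = "simulated"            # {simulated, real}
    shuffle_kind: str = "none"
    pretrained: bool = True

    def __post_init__(self):
        if self.source not in ("simulated", "real"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.shuffle_kind not in SHUFFLE_NAMES:
            raise ValueError(f"unknown shuffle kind {self.shuffle_kind!r}")

    @property
    def name(self) -> str:
        if not self.pretrained:
            return "random-init"
        return f"{self.source}-{SHUFFLE_NAMES[self.shuffle_kind]}"


def all_conditions() -> List[Condition]:
    """The nine conditions: 2 sources x 4 shuffles, plus the random control."""
    conds = [Condition(src, kind, True)
             for src in ("real", "simulated") for kind in SHUFFLE_NAMES]
    conds.append(Condition(pretrained=False))
    return conds


@dataclass
class ExperimentConfig:
    """All sub-configurations plus the scale switch.

    ``desk`` keeps every stage CPU-runnable; ``full`` mirrors the
    full-scale hyperparameters (ResNet backbone, 8192^3 projector, 100
    epochs, 5000/1000 images per base, P=50/M=20 manifolds) and is intended
    for cluster use.
    """

    scale: str = "desk"
    seeds: Tuple[int, ...] = (0, 1, 2)
    wave: WaveSimParams = field(default_factory=WaveSimParams)
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    shuffle_seed: int = 0
    activity_threshold: float = 0.5
    min_event_frames: int = 2
    base_source: str = "synthetic"
    base_seed: int = 0
    n_train_per_base: int = 5000
    n_test_per_base: int = 1000
    max_shift_px: int = 16
    jitter_lo: float = 0.5
    jitter_hi: float = 1.0
    readout_lr: float = 1e-4
    readout_epochs: int = 100
    readout_batch: int = 100
    geometry_tasks: Tuple[str, ...] = TASKS
    P: int = 50
    M: int = 20
    n_gaussian_samples: int = 200
    max_N: int = 2000
    layer_policy: str = "per-block"
    out_dir: Optional[str] = None

    # -- profiles -----------------------------------------------------------

    @classmethod
    def full(cls) -> "ExperimentConfig":
        return cls(scale="full",
                   wave=WaveSimParams(n_frames=237_000),
                   encoder=EncoderSpec(backbone="resnet18-like",
                                       projector_dims=(8192, 8192, 8192),
                                       embedding_dim=512),
                   pretrain=PretrainConfig(epochs=100,
                                           batch_frame_threshold=3000))

    @classmethod
    def desk(cls) -> "ExperimentConfig":
        return cls(scale="desk",
                   wave=WaveSimParams(height=32, width=32, n_frames=3000),
                   encoder=EncoderSpec(backbone="tiny-conv",
                                       projector_dims=(64, 64, 64),
                                       embedding_dim=128, base_channels=16),
                   pretrain=PretrainConfig(epochs=20,
                                           batch_frame_threshold=600),
                   n_train_per_base=500, n_test_per_base=100,
                   readout_epochs=40, P=20, M=10,
                   n_gaussian_samples=150, max_N=512)

    @classmethod
    def tiny(cls) -> "ExperimentConfig":
        """Smallest structured profile; used by the test suite."""
        return cls(scale="desk",
                   wave=WaveSimParams(height=24, width=24, n_frames=900),
                   encoder=EncoderSpec(backbone="tiny-conv",
                                       projector_dims=(64, 64, 64),
                                       embedding_dim=64, base_channels=8),
                   pretrain=PretrainConfig(epochs=6,
                                           batch_frame_threshold=300),
                   n_train_per_base=120, n_test_per_base=40,
                   readout_epochs=25, P=10, M=8,
                   geometry_tasks=("translation",),
                   n_gaussian_samples=100, max_N=256)

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["wave"] = WaveSimParams(**d["wave"])
        enc = d["encoder"]
        enc["input_size"] = tuple(enc["input_size"])
        enc["projector_dims"] = tuple(enc["projector_dims"])
        d["encoder"] = EncoderSpec(**enc)
        d["pretrain"] = PretrainConfig(**d["pretrain"])
        for k in ("seeds", "geometry_tasks"):
            d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _prepare_movie(cond: Condition, cfg: ExperimentConfig,
                   movie_path: Optional[str]):
    if cond.source == "real":
        if movie_path is None:
            raise ValueError("source='real' requires a movie path")
        movie = load_movie(movie_path)
    else:
        movie = simulate_waves(cfg.wave)
    events = extract_events(movie, cfg.activity_threshold, cfg.min_event_frames)
    movie, events = shuffle_movie(
        movie, events, ShuffleKind(cond.shuffle_kind, cfg.shuffle_seed))
    return movie, events


def _task_datasets(cfg: ExperimentConfig) -> Dict[str, TaskDataset]:
    bases = make_base_images(10, cfg.base_source, seed=cfg.base_seed)
    return {
        "classification": gen_classification_dataset(
            10, cfg.n_train_per_base, cfg.n_test_per_base, seed=cfg.base_seed),
        "translation": gen_translation_dataset(
            bases, cfg.max_shift_px, cfg.n_train_per_base,
            cfg.n_test_per_base, seed=cfg.base_seed),
        "color": gen_color_dataset(
            bases, cfg.jitter_lo, cfg.jitter_hi, cfg.n_train_per_base,
            cfg.n_test_per_base, seed=cfg.base_seed),
    }


def _geometry_rows(cond: Condition, cfg: ExperimentConfig, encoder: Encoder,
                   datasets: Dict[str, TaskDataset], seed: int) -> List[Dict]:
    bases_pool = make_base_images(max(cfg.P, 10), cfg.base_source,
                                  seed=cfg.base_seed + 1)
    rows = []
    for task in cfg.geometry_tasks:
        if task == "translation":
            mans = build_translation_manifolds(
                bases_pool[:cfg.P], encoder, M=cfg.M, seed=seed,
                layer_policy=cfg.layer_policy, max_N=cfg.max_N)
        elif task == "color":
            mans = build_color_manifolds(
                bases_pool[:cfg.P], encoder, M=cfg.M, seed=seed,
                layer_policy=cfg.layer_policy, max_N=cfg.max_N)
        elif task == "classification":
            ds = datasets["classification"]
            mans = build_classification_manifolds(
                ds.test_images, ds.test_labels, encoder,
                P=min(cfg.P, ds.n_classes), M=cfg.M, seed=seed,
                layer_policy=cfg.layer_policy, max_N=cfg.max_N)
        else:
            raise ValueError(f"unknown geometry task {task!r}")
        for order, (layer, ms) in enumerate(mans.items()):
            s = layer_geometry_summary(ms, cfg.n_gaussian_samples, seed)
            rows.append({"condition": cond.name, "task": task, "seed": seed,
                         "layer_order": order, "layer": layer,
                         "alpha_c": s.alpha_c, "D_M": s.D_M, "R_M": s.R_M,
                         "center_corr": s.center_corr,
                         "participation_ratio": s.participation_ratio,
                         "ev_dims": s.ev_dims})
    return rows


# ---------------------------------------------------------------------------
# run / compare
# ---------------------------------------------------------------------------

def run_condition(cond: Condition, cfg: ExperimentConfig,
                  movie_path: Optional[str] = None,
                  out_dir: Optional[str] = None,
                  datasets: Optional[Dict[str, TaskDataset]] = None,
                  ) -> Dict[str, pd.DataFrame]:
    """Execute one condition for every seed; returns accuracy and geometry
    tables (also written as CSV when ``out_dir`` is given; completed stage
    outputs on disk are reused on re-runs)."""
    out = Path(out_dir or cfg.out_dir) / cond.name if (out_dir or cfg.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        acc_csv, geo_csv = out / "accuracy.csv", out / "geometry.csv"
        if acc_csv.exists() and geo_csv.exists():
            logger.info("%s: reusing completed artifacts in %s", cond.name, out)
            return {"accuracy": pd.read_csv(acc_csv),
                    "geometry": pd.read_csv(geo_csv)}

    t0 = time.time()
    if datasets is None:
        datasets = _task_datasets(cfg)
    movie = events = None
    if cond.pretrained:
        movie, events = _prepare_movie(cond, cfg, movie_path)
        logger.info("%s: movie %s, %d events", cond.name, movie.shape, len(events))

    acc_rows, geo_rows = [], []
    for seed in cfg.seeds:
        t_seed = time.time()
        if cond.pretrained:
            pcfg = replace(cfg.pretrain, seed=seed)
            encoder, history = pretrain_encoder(movie, events, cfg.encoder, pcfg)
        else:
            encoder, history = Encoder(cfg.encoder, seed=seed), []
        if out is not None:
            save_encoder(encoder, out / f"ckpt-seed{seed}.npz")
            if history:
                pd.DataFrame({"epoch": range(len(history)),
                              "mean_loss": history}).to_csv(
                    out / f"loss-seed{seed}.csv", index=False)
        for task, ds in datasets.items():
            res = train_linear_readout(encoder, ds, lr=cfg.readout_lr,
                                       epochs=cfg.readout_epochs,
                                       batch_size=cfg.readout_batch, seed=seed)
            acc_rows.append({"condition": cond.name, "source": cond.source,
                             "task": task, "seed": seed,
                             "test_accuracy": res.test_accuracy,
                             "train_accuracy": res.train_accuracy})
        geo_rows.extend(_geometry_rows(cond, cfg, encoder, datasets, seed))
        logger.info("%s seed %d: %.1fs", cond.name, seed, time.time() - t_seed)

    acc = pd.DataFrame(acc_rows)
    geo = pd.DataFrame(geo_rows)
    if out is not None:
        acc.to_csv(out / "accuracy.csv", index=False)
        geo.to_csv(out / "geometry.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(
            {"condition": cond.name, "seeds": list(cfg.seeds),
             "scale": cfg.scale, "wall_time_s": time.time() - t0}))
    logger.info("%s: done in %.1fs", cond.name, time.time() - t0)
    return {"accuracy": acc, "geometry": geo}


def _majority_flag(a: pd.Series, b: pd.Series) -> str:
    """'pass' if a > b in a majority of seeds, 'tie' on equality."""
    merged = pd.merge(a.reset_index(), b.reset_index(), on="seed")
    wins = (merged.iloc[:, 1] > merged.iloc[:, 2]).sum()
    losses = (merged.iloc[:, 1] < merged.iloc[:, 2]).sum()
    if wins > losses:
        return "pass"
    if wins == losses:
        return "tie"
    return "fail"


def compare_conditions(bundles: Dict[str, Dict[str, pd.DataFrame]]):
    """Cross-condition report: accuracy table (mean +/- sd over seeds),
    per-layer geometry tables, and the directional pass/fail flags."""
    if len(bundles) < 2:
        raise ValueError("need at least 2 condition bundles to compare")
    acc = pd.concat([b["accuracy"] for b in bundles.values()], ignore_index=True)
    geo = pd.concat([b["geometry"] for b in bundles.values()], ignore_index=True)
    layer_sets = {tuple(sorted(b["geometry"]["layer"].unique()))
                  for b in bundles.values()}
    if len(layer_sets) != 1:
        raise ValueError(f"mismatched layer sets across bundles: {layer_sets}")

    acc_table = (acc.groupby(["condition", "task"])["test_accuracy"]
                 .agg(["mean", "std"]).reset_index())
    final = geo[geo["layer_order"] == geo["layer_order"].max()]
    geo_table = (geo.groupby(["condition", "task", "layer_order", "layer"])
                 [["alpha_c", "D_M", "R_M", "center_corr",
                   "participation_ratio"]].mean().reset_index())

    def acc_series(cond, task):
        s = acc[(acc.condition == cond) & (acc.task == task)]
        return s.set_index("seed")["test_accuracy"]

    def geo_series(cond, task, col):
        s = final[(final.condition == cond) & (final.task == task)]
        return s.set_index("seed")[col]

    flags = {}
    conds = set(acc["condition"].unique())

    def have(*cs):
        return all(c in conds for c in cs)

    for unsh in ("simulated-unshuffled", "real-unshuffled"):
        if have(unsh, "random-init"):
            flags[f"{unsh}>random-init:translation-accuracy"] = _majority_flag(
                acc_series(unsh, "translation"),
                acc_series("random-init", "translation"))
            flags[f"{unsh}>random-init:translation-alpha_c"] = _majority_flag(
                geo_series(unsh, "translation", "alpha_c"),
                geo_series("random-init", "translation", "alpha_c"))
        for shuf in ("temporal", "spatiotemporal"):
            sc = unsh.replace("unshuffled", shuf)
            if have(unsh, sc):
                flags[f"{sc}>{unsh}:final-PR"] = _majority_flag(
                    geo_series(sc, "translation", "participation_ratio"),
                    geo_series(unsh, "translation", "participation_ratio"))

    return {"accuracy_table": acc_table, "geometry_table": geo_table,
            "flags": flags}
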